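"""Small summary-statistics helpers used in reporting.

These cover the bookkeeping numbers quoted alongside the spectroscopy:
standard errors of replicate means and the carbon mass fraction of the
carbon substrates (used to argue that all media carry a similar carbon
load regardless of the isotope).
"""

from __future__ import annotations

import math

#: Atomic masses (u). ¹²C is exactly 12 by definition.
ATOMIC_MASS = {"C12": 12.0, "C13": 13.00335, "H": 1.00794, "O": 15.9994}

#: Elemental composition (C, H, O counts) of the carbon substrates.
FORMULAS = {"glucose": (6, 12, 6), "glycerol": (3, 8, 3)}


def standard_error(sd: float, n: int) -> float:
    """Standard error of the mean from a standard deviation and n."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return sd / math.sqrt(n)


def carbon_mass_fraction(compound: str = "glucose", isotope: int = 12) -> float:
    """Carbon mass fraction (percent w/w) of a substrate.

    With ¹²C, both glucose and glycerol are close to 40% carbon by mass,
    so media differing only in the glucose:glycerol ratio carry a similar
    carbon load.
    """
    try:
        nc, nh, no = FORMULAS[compound]
    except KeyError:
        raise KeyError(f"unknown compound {compound!r}; "
                       f"available: {sorted(FORMULAS)}")
    if isotope not in (12, 13):
        raise ValueError("isotope must be 12 or 13")
    mc = ATOMIC_MASS[f"C{isotope}"]
    carbon = nc * mc
    total = carbon + nh * ATOMIC_MASS["H"] + no * ATOMIC_MASS["O"]
    return 100.0 * carbon / total
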