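"""Marker-band model: band positions, isotope shifts, and component spectra.

Vibrational frequencies depend on the masses of the vibrating nuclei, so
replacing ¹²C with the heavier ¹³C red-shifts carbon-involving bands by
roughly 10-60 cm⁻¹. The packaged band table records, per metabolite and
per technique (Raman vs infrared), the ¹²C position and — where a carbon
vibration is involved and the shifted band is resolved — the ¹³C partner.
Phosphate vibrations (polyphosphate P=O, P-O, P-O-P) contain no carbon and
do not shift.

A :class:`MetaboliteComponent` turns a list of bands into a spectrum for a
given ¹³C fraction ``f13``:

* ``two_bands`` (default): each band contributes ``(1-f13)`` of its area at
  the ¹²C position and ``f13`` at the ¹³C position — a two-population
  isotopologue mixture.
* ``interpolate_position``: a single band whose centre slides linearly from
  the ¹²C to the ¹³C position with ``f13``. This emulates intramolecular
  isotope mixing in large conjugated molecules: β-carotene assembled from
  both ¹²C and ¹³C precursors shows a continuum of peak positions between
  the pure-isotope extremes rather than two discrete bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .axes import FT_RAMAN, FTIR_MICRO, HTS_FTIR, RAMAN_MICRO, WavenumberAxis
from .spectra import Spectrum

METABOLITES = ("TAG", "protein", "carbohydrate", "polyphosphate", "carotenoid")

#: Technique class per modality: the band table distinguishes Raman
#: scattering from infrared absorption, not individual instruments.
TECHNIQUE = {
    FT_RAMAN: "raman",
    RAMAN_MICRO: "raman",
    HTS_FTIR: "ftir",
    FTIR_MICRO: "ftir",
}

TWO_BANDS = "two_bands"
INTERPOLATE_POSITION = "interpolate_position"


# ---------------------------------------------------------------------------
# Lineshapes (all unit area, so band areas are governed by rel_intensity)
# ---------------------------------------------------------------------------

def lorentzian(nu: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    hw = fwhm / 2.0
    return (hw / np.pi) / ((nu - center) ** 2 + hw ** 2)


def gaussian(nu: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((nu - center) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def pseudo_voigt(nu: np.ndarray, center: float, fwhm: float,
                 eta: float = 0.7) -> np.ndarray:
    """Area-normalised pseudo-Voigt: eta Lorentzian + (1-eta) Gaussian."""
    return eta * lorentzian(nu, center, fwhm) + (1 - eta) * gaussian(nu, center, fwhm)


_SHAPES = {"lorentzian": lorentzian, "gaussian": gaussian}


@dataclass(frozen=True)
class Band:
    """One vibrational band with its isotopologue positions.

    ``center13 is None`` for vibrations without a resolved ¹³C partner
    (for example the carbon-free polyphosphate bands).
    """

    center12: float
    center13: float | None = None
    fwhm: float = 15.0
    rel_intensity: float = 1.0
    shape: str = "pseudo_voigt"
    eta: float = 0.7
    label: str = ""

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.rel_intensity < 0:
            raise ValueError("rel_intensity must be non-negative")
        if self.center13 is not None and self.center13 >= self.center12:
            raise ValueError("isotope shift must be to the red: center13 < center12")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("pseudo-Voigt mixing eta must be in [0, 1]")

    @property
    def shift(self) -> float | None:
        return None if self.center13 is None else self.center12 - self.center13

    def line(self, nu: np.ndarray, center: float) -> np.ndarray:
        if self.shape == "pseudo_voigt":
            return pseudo_voigt(nu, center, self.fwhm, self.eta)
        try:
            fn = _SHAPES[self.shape]
        except KeyError:
            raise ValueError(f"unknown lineshape {self.shape!r}")
        return fn(nu, center, self.fwhm)


# ---------------------------------------------------------------------------
# Packaged band table
# ---------------------------------------------------------------------------

def _b(c12, c13=None, fwhm=15.0, rel=1.0, label=""):
    return Band(center12=c12, center13=c13, fwhm=fwhm, rel_intensity=rel, label=label)


def _default_entries() -> dict[tuple[str, str], list[Band]]:
    """Band positions for fungal biomass constituents.

    Only unambiguous ¹²C/¹³C position pairs are encoded; the C-H
    stretching/deformation multiplets whose sub-band pairing is not
    resolvable are represented by their strongest members (the CH₂
    stretches at 2930/2855 cm⁻¹ used as lipid markers). Widths and
    relative intensities are generator defaults by band class, not
    measured values.
    """
    return {
        # --- triglyceride lipids (TAG) ---
        ("TAG", "raman"): [
            _b(3010, 2995, fwhm=18, rel=0.3, label="=C-H stretch"),
            _b(2930, 2918, fwhm=22, rel=0.6, label="CH3/CH2 stretch"),
            _b(2855, 2846, fwhm=18, rel=1.0, label="CH2 stretch"),
            _b(1747, 1705, fwhm=14, rel=0.5, label="ester C=O stretch"),
            _b(1656, 1598, fwhm=14, rel=0.8, label="C=C stretch"),
            _b(1454, 1452, fwhm=16, rel=0.5, label="CH2/CH3 deformation"),
            _b(1081, 1055, fwhm=14, rel=0.3, label="C-C/C-O stretch"),
        ],
        ("TAG", "ftir"): [
            _b(3010, 2994, fwhm=16, rel=0.2, label="=C-H stretch"),
            _b(2925, 2915, fwhm=22, rel=0.8, label="CH2 asym stretch"),
            _b(2855, 2848, fwhm=18, rel=0.5, label="CH2 sym stretch"),
            _b(1745, 1701, fwhm=14, rel=1.0, label="ester C=O stretch"),
            _b(1155, 1135, fwhm=16, rel=0.3, label="C-O-C stretch"),
            _b(1066, 1040, fwhm=16, rel=0.2, label="C-O-C stretch"),
            _b(723, 718, fwhm=10, rel=0.15, label="CH2 rock"),
        ],
        # --- proteins ---
        ("protein", "raman"): [
            _b(1660, 1624, fwhm=20, rel=1.0, label="amide I"),
            _b(1605, 1565, fwhm=12, rel=0.2, label="phenyl C=C"),
            _b(1268, 1262, fwhm=16, rel=0.3, label="amide III"),
            _b(1005, 966, fwhm=8, rel=0.4, label="phenyl ring"),
        ],
        ("protein", "ftir"): [
            _b(1640, 1615, fwhm=22, rel=1.0, label="amide I"),
            _b(1550, 1540, fwhm=20, rel=0.6, label="amide II"),
        ],
        # --- cell wall carbohydrates ---
        ("carbohydrate", "raman"): [
            _b(2900, 2886, fwhm=24, rel=0.5, label="CH stretch"),
            _b(1650, 1625, fwhm=18, rel=0.2, label="chitin amide I"),
            _b(1442, 1439, fwhm=16, rel=0.3, label="CH2/CH3 deformation"),
            _b(1127, 1095, fwhm=20, rel=0.5, label="C-C/C-O/C-O-C stretch"),
        ],
        ("carbohydrate", "ftir"): [
            _b(2958, 2948, fwhm=22, rel=0.4, label="CH stretch"),
            _b(1650, 1615, fwhm=20, rel=0.3, label="chitin amide I"),
            _b(1745, 1705, fwhm=14, rel=0.05, label="glucuronan ester C=O"),
            _b(1080, 1051, fwhm=20, rel=0.6, label="C-O-C/COH"),
            _b(1036, 1013, fwhm=18, rel=0.4, label="C-O-C/COH"),
        ],
        # --- polyphosphates (no carbon: no isotope shift) ---
        ("polyphosphate", "raman"): [
            _b(1170, None, fwhm=16, rel=1.0, label="P=O stretch"),
            _b(700, None, fwhm=18, rel=0.4, label="P-O-P stretch"),
        ],
        ("polyphosphate", "ftir"): [
            _b(1268, None, fwhm=18, rel=1.0, label="P=O stretch"),
            _b(1084, None, fwhm=20, rel=0.7, label="P-O stretch"),
            _b(886, None, fwhm=18, rel=0.3, label="P-O-P stretch"),
        ],
        # --- carotenoids (resonance-enhanced Raman only; below FTIR
        #     detection at fungal concentrations) ---
        ("carotenoid", "raman"): [
            _b(1523, 1490, fwhm=12, rel=1.0, label="C=C stretch"),
            _b(1157, 1124, fwhm=12, rel=0.7, label="C-C stretch/CH def"),
        ],
        ("carotenoid", "ftir"): [],
    }


#: Position aliases accepted in lookups: figure-caption wavenumbers that
#: differ by a few cm⁻¹ from the tabulated assignment.
POSITION_ALIASES = {1525.0: 1523.0, 1746.0: 1745.0, 1700.0: 1701.0, 1263.0: 1268.0}


@dataclass
class BandTable:
    """Map (metabolite, technique) -> bands. Default content packaged."""

    entries: dict[tuple[str, str], list[Band]] = field(default_factory=_default_entries)
    #: Carotenoid resonance enhancement per modality: the 785 nm microscope
    #: excitation is closer to the carotenoid electronic absorption than the
    #: 1064 nm FT laser, amplifying carotenoid bands.
    carotenoid_enhancement: dict[str, float] = field(
        default_factory=lambda: {FT_RAMAN: 1.0, RAMAN_MICRO: 8.0})

    def lookup(self, metabolite: str, modality: str) -> list[Band]:
        """Bands for a metabolite under a given modality (may be empty)."""
        if metabolite not in METABOLITES:
            raise KeyError(f"unknown metabolite {metabolite!r}")
        tech = TECHNIQUE.get(modality, modality)
        return list(self.entries.get((metabolite, tech), []))

    def lookup_band(self, metabolite: str, modality: str, nu: float,
                    tol: float = 3.0) -> Band:
        """Find the band whose ¹²C or ¹³C position matches ``nu``
        (rounded figure-caption positions are aliased first)."""
        nu = POSITION_ALIASES.get(float(nu), float(nu))
        for band in self.lookup(metabolite, modality):
            if abs(band.center12 - nu) <= tol:
                return band
            if band.center13 is not None and abs(band.center13 - nu) <= tol:
                return band
        raise KeyError(f"no {metabolite} band near {nu} cm^-1 for {modality}")

    def component(self, metabolite: str, modality: str) -> "MetaboliteComponent":
        bands = self.lookup(metabolite, modality)
        if metabolite == "carotenoid":
            gain = self.carotenoid_enhancement.get(modality, 1.0)
            bands = [replace(b, rel_intensity=b.rel_intensity * gain) for b in bands]
            mode = INTERPOLATE_POSITION
        else:
            mode = TWO_BANDS
        return MetaboliteComponent(name=metabolite, bands=bands, isotope_mode=mode)


def default_band_table() -> BandTable:
    """The packaged band-assignment table (overridable by the caller)."""
    return BandTable()


# ---------------------------------------------------------------------------
# Component spectra
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteComponent:
    name: str
    bands: list[Band]
    isotope_mode: str = TWO_BANDS

    def __post_init__(self) -> None:
        if self.isotope_mode not in (TWO_BANDS, INTERPOLATE_POSITION):
            raise ValueError(f"unknown isotope mode {self.isotope_mode!r}")


def component_spectrum(component: MetaboliteComponent, axis: WavenumberAxis,
                       f13: float = 0.0) -> Spectrum:
    """Spectrum of one metabolite at ¹³C fraction ``f13``.

    Band areas are conserved: the integral is proportional to the sum of
    the component's relative intensities independent of ``f13`` (up to
    truncation of band tails at the axis edges).
    """
    if not 0.0 <= f13 <= 1.0:
        raise ValueError(f"f13 must be in [0, 1], got {f13}")
    nu = axis.values
    y = np.zeros_like(nu)
    covered = False
    for band in component.bands:
        if band.center13 is None:
            y += band.rel_intensity * band.line(nu, band.center12)
        elif component.isotope_mode == INTERPOLATE_POSITION:
            center = band.center12 - f13 * (band.center12 - band.center13)
            y += band.rel_intensity * band.line(nu, center)
        else:
            y += band.rel_intensity * ((1.0 - f13) * band.line(nu, band.center12)
                                       + f13 * band.line(nu, band.center13))
        lo, hi = nu[0], nu[-1]
        if lo - 3 * band.fwhm <= band.center12 <= hi + 3 * band.fwhm:
            covered = True
    if component.bands and not covered:
        warnings.warn(f"axis does not cover any band of {component.name}; "
                      "only far tails contribute", stacklevel=2)
    return Spectrum(axis, y, meta={"component": component.name, "f13": f13})
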