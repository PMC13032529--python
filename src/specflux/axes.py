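"""Wavenumber axes for the four measurement modalities.

A :class:`WavenumberAxis` is a strictly monotone grid of wavenumbers
(cm⁻¹). Instrument axes are uniform; truncation to disjoint spectral
regions produces a non-uniform axis, which is permitted but flagged so
that grid-sensitive operations (Savitzky–Golay filtering) can refuse it.

Values are stored in ascending order internally; instrument exports that
list wavenumbers descending are reversed on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical modality names used throughout the package.
FT_RAMAN = "FTRaman"
HTS_FTIR = "HTSFTIR"
RAMAN_MICRO = "RamanMicro"
FTIR_MICRO = "FTIRMicro"

MODALITIES = (FT_RAMAN, HTS_FTIR, RAMAN_MICRO, FTIR_MICRO)

#: Instrument grid settings: (high end, low end, digital spacing), all cm⁻¹.
#: The grid starts exactly at the high end and steps down by the spacing;
#: the last point is the lowest grid value still >= the low end.
INSTRUMENT_GRIDS: dict[str, tuple[float, float, float]] = {
    FT_RAMAN: (3785.0, 50.0, 1.928),
    HTS_FTIR: (4000.0, 400.0, 1.928),
    FTIR_MICRO: (3850.0, 900.0, 3.851),
    # The dispersive Raman microscope covers 2920-0 cm⁻¹; its digital step
    # is not a round number, so the FT digital resolution is reused for the
    # synthetic grid.
    RAMAN_MICRO: (2920.0, 0.0, 1.928),
}

_UNIFORM_RTOL = 1e-9


@dataclass(frozen=True)
class WavenumberAxis:
    """Ordered wavenumber grid (cm⁻¹), ascending."""

    values: np.ndarray
    modality: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("axis needs at least two wavenumbers")
        if np.any(np.diff(v) <= 0):
            if np.all(np.diff(v) < 0):
                v = v[::-1].copy()
            else:
                raise ValueError("wavenumber axis must be strictly monotone")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def range_lo(self) -> float:
        return float(self.values[0])

    @property
    def range_hi(self) -> float:
        return float(self.values[-1])

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.values)
        return bool(np.all(np.abs(d - d[0]) <= _UNIFORM_RTOL * np.abs(d[0]) + 1e-12))

    @property
    def spacing(self) -> float:
        """Grid step (cm⁻¹); raises for non-uniform (truncated) axes."""
        if not self.is_uniform:
            raise ValueError("axis is not uniform (truncated to disjoint regions?)")
        return float(self.values[1] - self.values[0])

    def index_range(self, lo: float, hi: float) -> np.ndarray:
        """Indices of grid points with ``lo <= nu <= hi`` (inclusive)."""
        if lo > hi:
            lo, hi = hi, lo
        return np.nonzero((self.values >= lo) & (self.values <= hi))[0]

    @classmethod
    def from_grid(cls, hi: float, lo: float, spacing: float,
                  modality: str | None = None) -> "WavenumberAxis":
        n = int(np.floor((hi - lo) / spacing)) + 1
        values = hi - spacing * np.arange(n)
        return cls(values[::-1].copy(), modality=modality)

    @classmethod
    def for_modality(cls, modality: str) -> "WavenumberAxis":
        try:
            hi, lo, spacing = INSTRUMENT_GRIDS[modality]
        except KeyError:
            raise KeyError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
        return cls.from_grid(hi, lo, spacing, modality=modality)


def default_axis(modality: str) -> WavenumberAxis:
    """The instrument grid for a modality (see :data:`INSTRUMENT_GRIDS`)."""
    return WavenumberAxis.for_modality(modality)
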