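"""Spectrum and SpectralDataset containers.

These are the currency of every pipeline stage: a :class:`Spectrum` is one
intensity trace on a wavenumber axis; a :class:`SpectralDataset` is a stack
of spectra sharing one axis, with a per-sample metadata table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .axes import WavenumberAxis


@dataclass
class Spectrum:
    """One intensity trace (absorbance or Raman counts) on an axis."""

    axis: WavenumberAxis
    intensity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)
    derivative_order: int = 0

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=float)
        if y.shape != (len(self.axis),):
            raise ValueError(
                f"intensity length {y.shape} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensity contains non-finite values")
        self.intensity = y

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.axis.values

    def replace(self, *, axis: WavenumberAxis | None = None,
                intensity: np.ndarray | None = None,
                derivative_order: int | None = None) -> "Spectrum":
        return Spectrum(
            axis=axis if axis is not None else self.axis,
            intensity=intensity if intensity is not None else self.intensity.copy(),
            meta=dict(self.meta),
            derivative_order=(self.derivative_order if derivative_order is None
                              else derivative_order),
        )


class SpectralDataset:
    """Spectra (n_samples x n_wavenumbers) on a common axis, plus metadata.

    Parameters
    ----------
    axis
        Shared wavenumber axis.
    intensities
        2-D array, one row per sample.
    meta
        Per-sample metadata; must contain a ``sample_id`` column with
        unique values. Row order matches ``intensities``.
    derivative_order
        0 for raw spectra, 1/2 after Savitzky-Golay differentiation.
    """

    def __init__(self, axis: WavenumberAxis, intensities: np.ndarray,
                 meta: pd.DataFrame | None = None, derivative_order: int = 0,
                 truth: pd.DataFrame | None = None) -> None:
        X = np.atleast_2d(np.asarray(intensities, dtype=float))
        if X.shape[1] != len(axis):
            raise ValueError(
                f"intensity width {X.shape[1]} does not match axis length {len(axis)}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("intensities contain non-finite values")
        if meta is None:
            meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(X.shape[0])]})
        if len(meta) != X.shape[0]:
            raise ValueError("metadata row count does not match spectrum count")
        if "sample_id" not in meta.columns:
            raise ValueError("metadata must contain a 'sample_id' column")
        ids = meta["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        self.axis = axis
        self.intensities = X
        self.meta = meta.reset_index(drop=True)
        self.derivative_order = derivative_order
        #: Optional generator ground truth (per-sample composition), carried
        #: alongside for recovery checks; never used by the pipeline itself.
        self.truth = truth

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.axis.values

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta["sample_id"])

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.intensities[i].copy(),
                        meta=self.meta.iloc[i].to_dict(),
                        derivative_order=self.derivative_order)

    def __iter__(self):
        for i in range(len(self)):
            yield self.spectrum(i)

    def replace(self, *, axis: WavenumberAxis | None = None,
                intensities: np.ndarray | None = None,
                derivative_order: int | None = None) -> "SpectralDataset":
        return SpectralDataset(
            axis=axis if axis is not None else self.axis,
            intensities=(intensities if intensities is not None
                         else self.intensities.copy()),
            meta=self.meta.copy(),
            derivative_order=(self.derivative_order if derivative_order is None
                              else derivative_order),
            truth=self.truth,
        )

    def select(self, mask) -> "SpectralDataset":
        """Subset samples by boolean mask or index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        out = SpectralDataset(self.axis, self.intensities[idx],
                              self.meta.iloc[idx].reset_index(drop=True),
                              self.derivative_order)
        out.truth = self.truth
        return out

    def mean_spectrum(self) -> Spectrum:
        return Spectrum(self.axis, self.intensities.mean(axis=0),
                        derivative_order=self.derivative_order)

    # -- replicate handling ------------------------------------------------
    def average_replicates(self, keys: tuple[str, ...] = ("medium", "timepoint_h"),
                           ) -> "SpectralDataset":
        """Average technical replicates over the given metadata keys.

        Used before multiblock analysis so that blocks from different
        modalities line up sample-to-sample.
        """
        for k in keys:
            if k not in self.meta.columns:
                raise KeyError(f"metadata column {k!r} missing")
        groups = self.meta.groupby(list(keys), sort=True).indices
        rows, meta_rows = [], []
        for key, idx in sorted(groups.items(), key=lambda kv: str(kv[0])):
            rows.append(self.intensities[np.asarray(idx)].mean(axis=0))
            rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
            rec["sample_id"] = "_".join(str(v) for v in rec.values())
            rec["n_replicates"] = len(idx)
            meta_rows.append(rec)
        return SpectralDataset(self.axis, np.array(rows), pd.DataFrame(meta_rows),
                               self.derivative_order)

    @classmethod
    def from_spectra(cls, spectra: list[Spectrum]) -> "SpectralDataset":
        if not spectra:
            raise ValueError("empty spectrum list")
        axis = spectra[0].axis
        for s in spectra[1:]:
            if not np.allclose(s.axis.values, axis.values):
                raise ValueError("spectra do not share a common axis")
        X = np.stack([s.intensity for s in spectra])
        meta = pd.DataFrame([s.meta for s in spectra])
        if "sample_id" not in meta.columns:
            meta["sample_id"] = [f"s{i}" for i in range(len(spectra))]
        return cls(axis, X, meta, spectra[0].derivative_order)
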