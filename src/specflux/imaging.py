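"""Hyperspectral image handling: pixel QC, block binning, basis analysis.

A focal-plane-array FTIR measurement (or a scanned Raman map) yields one
spectrum per pixel. The operations here mirror the imaging workflow:
remove noisy pixels from empty regions, bin the survivors into 10 x 10
pixel blocks (edge blocks smaller), fit every pixel spectrum as a
non-negative linear combination of basis spectra to produce component
maps, and plot single-wavenumber absorbance maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .axes import WavenumberAxis
from .spectra import SpectralDataset, Spectrum


@dataclass
class HyperspectralImage:
    """x-by-y-by-wavenumber cube with a validity mask."""

    cube: np.ndarray
    axis: WavenumberAxis
    valid_mask: np.ndarray | None = None
    pixel_size: float = 2.7  # µm
    truth: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.cube, dtype=float)
        if c.ndim != 3:
            raise ValueError("cube must be rows x cols x wavenumbers")
        if c.shape[2] != len(self.axis):
            raise ValueError("cube depth does not match axis length")
        if not np.all(np.isfinite(c)):
            raise ValueError("cube contains non-finite values")
        self.cube = c
        if self.valid_mask is not None and self.valid_mask.shape != c.shape[:2]:
            raise ValueError("valid_mask shape does not match cube")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]

    @property
    def n_pixels(self) -> int:
        return self.cube.shape[0] * self.cube.shape[1]

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.axis, self.cube[row, col].copy(),
                        meta={"row": row, "col": col})


# ---------------------------------------------------------------------------
# Pixel quality control
# ---------------------------------------------------------------------------

def remove_empty_pixels(image: HyperspectralImage,
                        snr_region: tuple[float, float] = (1700.0, 1500.0),
                        k_sigma: float = 3.0,
                        min_signal: float = 0.2) -> np.ndarray:
    """Mask out noisy pixels from empty or nearly empty regions.

    The per-pixel statistic is the integrated absolute signal over
    ``snr_region`` after subtracting the straight line through the region
    endpoints (which removes smooth baseline offsets but keeps real
    bands). A pixel is kept only if its statistic reaches both an absolute
    floor ``min_signal`` (intensity x cm⁻¹, tied to the expected band
    scale) and a robust background threshold: median + ``k_sigma`` scaled
    MAD of the lowest-decile pixels.

    Returns the boolean validity mask and stores it on the image.
    """
    lo, hi = sorted(snr_region)
    idx = image.axis.index_range(lo, hi)
    if idx.size < 3:
        raise ValueError("snr_region contains fewer than 3 grid points")
    nu = image.axis.values[idx]
    seg = image.cube[:, :, idx]
    # endpoint line per pixel
    y0, y1 = seg[:, :, 0], seg[:, :, -1]
    t = (nu - nu[0]) / (nu[-1] - nu[0])
    line = y0[..., None] + (y1 - y0)[..., None] * t[None, None, :]
    metric = np.trapezoid(np.abs(seg - line), nu, axis=2)

    flat = np.sort(metric.ravel())
    decile = flat[: max(1, flat.size // 10)]
    med = float(np.median(decile))
    mad = float(np.median(np.abs(decile - med)))
    threshold = max(min_signal, med + k_sigma * 1.4826 * mad)
    valid = metric >= threshold
    image.valid_mask = valid
    return valid


# ---------------------------------------------------------------------------
# Block binning
# ---------------------------------------------------------------------------

@dataclass
class BlockGrid:
    """Tiling of the image into nominal ``block``-sized blocks.

    Full blocks tile from the top-left; a single remainder strip per axis
    forms the smaller edge blocks (10x8 / 8x10 / 8x8 for 128-pixel axes).
    Blocks with fewer than ``min_pixels`` valid pixels are dropped at
    binning time.
    """

    block: int = 10
    min_pixels: int = 5
    blocks: list[tuple[range, range]] = field(default_factory=list)

    @classmethod
    def for_shape(cls, shape: tuple[int, int], block: int = 10,
                  min_pixels: int = 5) -> "BlockGrid":
        def edges(n: int) -> list[range]:
            q, r = divmod(n, block)
            out = [range(i * block, (i + 1) * block) for i in range(q)]
            if r:
                out.append(range(q * block, n))
            return out
        grid = cls(block=block, min_pixels=min_pixels)
        grid.blocks = [(rr, cc) for rr in edges(shape[0]) for cc in edges(shape[1])]
        return grid


def bin_image(image: HyperspectralImage,
              grid: BlockGrid | None = None) -> SpectralDataset:
    """Average valid pixels within each block into one spectrum.

    Requires a validity mask (run :func:`remove_empty_pixels`, or set
    ``image.valid_mask`` to all-True for fully valid data). Blocks with
    fewer than ``grid.min_pixels`` valid members are dropped.
    """
    if image.valid_mask is None:
        raise ValueError("valid_mask not computed; run remove_empty_pixels first")
    grid = grid or BlockGrid.for_shape(image.shape)
    rows, meta = [], []
    for bi, (rr, cc) in enumerate(grid.blocks):
        sub_mask = image.valid_mask[rr.start:rr.stop, cc.start:cc.stop]
        n = int(sub_mask.sum())
        if n < grid.min_pixels:
            continue
        sub = image.cube[rr.start:rr.stop, cc.start:cc.stop]
        rows.append(sub[sub_mask].mean(axis=0))
        meta.append({
            "sample_id": f"block_{rr.start}_{cc.start}",
            "row_start": rr.start, "row_stop": rr.stop,
            "col_start": cc.start, "col_stop": cc.stop,
            "n_pixels": n,
        })
    if not rows:
        raise ValueError("no blocks survive the minimum-pixel criterion")
    return SpectralDataset(image.axis, np.array(rows), pd.DataFrame(meta))


# ---------------------------------------------------------------------------
# Basis analysis
# ---------------------------------------------------------------------------

@dataclass
class BasisSet:
    """Component ("basis") spectra on the image axis."""

    spectra: np.ndarray  # K x n_wavenumbers
    names: list[str]
    axis: WavenumberAxis | None = None

    def __post_init__(self) -> None:
        B = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        if B.shape[0] != len(self.names):
            raise ValueError("one name per basis spectrum required")
        for i in range(B.shape[0]):
            for j in range(i + 1, B.shape[0]):
                if np.allclose(B[i], B[j]):
                    raise ValueError(f"basis spectra {i} and {j} are identical")
        self.spectra = B

    @property
    def k(self) -> int:
        return self.spectra.shape[0]


@dataclass
class BasisFitResult:
    """Per-pixel fitting factors and residuals of the basis analysis."""

    factors: np.ndarray       # rows x cols x K
    residual_norm: np.ndarray  # rows x cols
    basis: BasisSet

    def component_map(self, k: int) -> np.ndarray:
        return self.factors[:, :, k]


_CONDITION_WARN = 1e8


def basis_fit(image: HyperspectralImage, basis: BasisSet,
              nonneg: bool = True, offset: bool = False) -> BasisFitResult:
    """Fit every pixel spectrum as a linear combination of basis spectra.

    Solves ``min ||s - B f||²`` per pixel (with ``f >= 0`` when ``nonneg``).
    With ``offset`` a constant column is appended to absorb a per-pixel
    baseline level (its coefficient is unconstrained in sign and is not
    reported as a component).
    """
    B = basis.spectra.T  # n_nu x K
    if B.shape[0] < basis.k:
        raise ValueError("more basis components than wavenumbers")
    if np.linalg.cond(B) > _CONDITION_WARN:
        warnings.warn("basis set is nearly degenerate; factors may be unstable",
                      stacklevel=2)
    design = B
    if offset:
        design = np.column_stack([B, np.ones(B.shape[0])])
    nr, nc = image.shape
    k = basis.k
    factors = np.zeros((nr, nc, k))
    resid = np.zeros((nr, nc))
    Y = image.cube.reshape(-1, B.shape[0])
    if not nonneg and not offset:
        # one shared least-squares solve for all pixels
        sol, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
        factors = sol.T.reshape(nr, nc, k)
        resid = np.linalg.norm(Y - (design @ sol).T, axis=1).reshape(nr, nc)
        return BasisFitResult(factors, resid, basis)
    flat_f = np.zeros((Y.shape[0], design.shape[1]))
    flat_r = np.zeros(Y.shape[0])
    for i in range(Y.shape[0]):
        if nonneg and not offset:
            f, rn = nnls(design, Y[i])
        elif nonneg and offset:
            # non-negativity on components, free offset: solve with the
            # offset split into +/- parts
            aug = np.column_stack([B, np.ones(B.shape[0]), -np.ones(B.shape[0])])
            f_aug, rn = nnls(aug, Y[i])
            f = np.concatenate([f_aug[:k], [f_aug[k] - f_aug[k + 1]]])
        else:
            f, *_ = np.linalg.lstsq(design, Y[i], rcond=None)
            rn = float(np.linalg.norm(Y[i] - design @ f))
        flat_f[i, : len(f)] = f
        flat_r[i] = rn
    factors = flat_f[:, :k].reshape(nr, nc, k)
    resid = flat_r.reshape(nr, nc)
    return BasisFitResult(factors, resid, basis)


def derive_basis(image: HyperspectralImage, k: int, method: str = "kmeans",
                 seed: int = 0,
                 pixel_coords: list[tuple[int, int]] | None = None) -> BasisSet:
    """Derive basis spectra from the image itself.

    ``kmeans``: k-means centroids of area-normalised valid-pixel spectra.
    ``manual``: the spectra at caller-supplied pixel coordinates.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if method == "manual":
        if not pixel_coords or len(pixel_coords) != k:
            raise ValueError("manual method needs exactly k pixel coordinates")
        B = np.stack([image.cube[r, c] for r, c in pixel_coords])
        return BasisSet(B, [f"pixel_{r}_{c}" for r, c in pixel_coords], image.axis)
    if method != "kmeans":
        raise ValueError(f"unknown method {method!r}")
    from sklearn.cluster import KMeans

    mask = (image.valid_mask if image.valid_mask is not None
            else np.ones(image.shape, dtype=bool))
    Y = image.cube[mask]
    if Y.shape[0] < k:
        raise ValueError("fewer valid pixels than requested components")
    area = np.trapezoid(np.abs(Y), image.axis.values, axis=1)
    area = np.where(area > 0, area, 1.0)
    Yn = Y / area[:, None]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Yn)
    order = np.argsort(-np.bincount(km.labels_, minlength=k))
    B = km.cluster_centers_[order]
    return BasisSet(B, [f"component_{i + 1}" for i in range(k)], image.axis)


# ---------------------------------------------------------------------------
# Single-wavenumber maps
# ---------------------------------------------------------------------------

def absorbance_map(image: HyperspectralImage, nu: float = 1745.0,
                   halfwidth: float = 4.0) -> np.ndarray:
    """Per-pixel maximum intensity within ``nu ± halfwidth`` (cm⁻¹)."""
    idx = image.axis.index_range(nu - halfwidth, nu + halfwidth)
    if idx.size == 0:
        raise ValueError(f"window {nu}±{halfwidth} cm^-1 outside the axis")
    return image.cube[:, :, idx].max(axis=2)
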