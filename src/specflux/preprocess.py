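"""Spectral preprocessing primitives and the packaged per-modality recipes.

Each primitive accepts either a :class:`~specflux.spectra.Spectrum` or a
:class:`~specflux.spectra.SpectralDataset` and returns the same type.
Recipes are immutable ordered step lists; the packaged ones reproduce the
study workflow per modality, with parameters exactly as published:

==================  =========================================================
recipe              steps
==================  =========================================================
htsftir_bandratio   truncate 1800-800; linear baseline; band-area normalise
                    1670-1600 (amide I); SG(poly 2, window 15, 2nd deriv)
htsftir_mva         SG(2, 11, 2); truncate 3200-2600 + 2000-600; MSC
ftraman_bandratio   SG(2, 15, 2); truncate 3200-2500 + 1800-600; MSC
ftraman_mva         rubberband; SG(2, 11, 2); truncate 1800-400; vector norm
ftraman_plsr        SG(2, 15, 0) smoothing; rubberband; truncate
                    3200-2400 + 1900-500; EMSC degree 3
ramanmicro_point    cosmic-ray removal; rubberband; truncate 1800-400;
                    area normalisation
ramanmicro_image    cosmic-ray removal; polynomial baseline; truncate 1800-400
ftirmicro_mva       pixel QC; 10x10 binning; SG(2, 9, 2); EMSC degree 2 with
                    the mean of all block spectra as reference
==================  =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .axes import WavenumberAxis
from .spectra import SpectralDataset, Spectrum


class RecipeError(ValueError):
    """A preprocessing step failed, with recipe/step context attached."""


# ---------------------------------------------------------------------------
# dispatch helpers
# ---------------------------------------------------------------------------

def _unpack(obj) -> tuple[WavenumberAxis, np.ndarray, int, bool]:
    if isinstance(obj, Spectrum):
        return obj.axis, obj.intensity[None, :], obj.derivative_order, True
    if isinstance(obj, SpectralDataset):
        return obj.axis, obj.intensities, obj.derivative_order, False
    raise TypeError(f"expected Spectrum or SpectralDataset, got {type(obj).__name__}")


def _repack(obj, axis: WavenumberAxis, Y: np.ndarray, deriv: int):
    if isinstance(obj, Spectrum):
        return Spectrum(axis, Y[0], meta=dict(obj.meta), derivative_order=deriv)
    return obj.replace(axis=axis, intensities=Y, derivative_order=deriv)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def truncate(obj, regions: list[tuple[float, float]]):
    """Keep grid points inside any of the (lo, hi) regions, inclusive."""
    axis, Y, deriv, _ = _unpack(obj)
    norm = sorted((min(r), max(r)) for r in regions)
    for (l0, h0), (l1, _h1) in zip(norm, norm[1:]):
        if l1 <= h0:
            raise ValueError(f"regions overlap: ({l0}, {h0}) and ({l1}, {_h1})")
    nu = axis.values
    mask = np.zeros(nu.size, dtype=bool)
    for lo, hi in norm:
        mask |= (nu >= lo) & (nu <= hi)
    if mask.sum() < 2:
        raise ValueError("empty result: fewer than 2 grid points inside the regions")
    return _repack(obj, WavenumberAxis(nu[mask], modality=axis.modality),
                   Y[:, mask], deriv)


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay settings: odd window (points), polynomial order,
    derivative order."""

    window: int = 15
    polyorder: int = 2
    deriv: int = 2

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be an odd count >= 3")
        if self.polyorder >= self.window:
            raise ValueError("polyorder must be smaller than window")
        if self.deriv > self.polyorder:
            raise ValueError("derivative order must not exceed polyorder")


def savgol(obj, params: SGParams | None = None, **kwargs):
    """Savitzky-Golay smoothing/differentiation on a uniform grid.

    Differentiation is with respect to the point index (the vendor
    convention); multiply by ``(1/spacing)**deriv`` for per-cm⁻¹ units.
    Edge points come from one-sided polynomial fits, so the output length
    equals the input length.
    """
    p = params or SGParams(**kwargs)
    axis, Y, deriv, _ = _unpack(obj)
    if not axis.is_uniform:
        raise ValueError("Savitzky-Golay requires a uniform axis "
                         "(apply before multi-region truncation)")
    if Y.shape[1] < p.window:
        raise ValueError("spectrum shorter than the SG window")
    out = savgol_filter(Y, p.window, p.polyorder, deriv=p.deriv, delta=1.0,
                        axis=-1, mode="interp")
    return _repack(obj, axis, out, p.deriv if p.deriv > 0 else deriv)


def _lower_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull vertices (x is ascending)."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            cross = (x[b] - x[a]) * (y[i] - y[a]) - (y[b] - y[a]) * (x[i] - x[a])
            if cross <= 0:  # b lies on or above the chord a->i: not a lower vertex
                hull.pop()
            else:
                break
        hull.append(i)
    return np.array(hull)


def rubberband_baseline(obj):
    """Rubber-band correction: baseline = lower convex hull of the spectrum.

    Returns ``(baseline, corrected)`` of the same type as the input.
    """
    axis, Y, deriv, _ = _unpack(obj)
    if Y.shape[1] < 3:
        raise ValueError("need at least 3 points for a rubber band")
    nu = axis.values
    base = np.empty_like(Y)
    for i in range(Y.shape[0]):
        h = _lower_hull(nu, Y[i])
        base[i] = np.interp(nu, nu[h], Y[i, h])
    corrected = Y - base
    return (_repack(obj, axis, base, deriv),
            _repack(obj, axis, corrected, deriv))


def linear_baseline(obj):
    """Subtract the straight line through the first and last points."""
    axis, Y, deriv, _ = _unpack(obj)
    nu = axis.values
    t = (nu - nu[0]) / (nu[-1] - nu[0])
    line = Y[:, :1] + (Y[:, -1:] - Y[:, :1]) * t[None, :]
    return _repack(obj, axis, Y - line, deriv)


def polynomial_baseline(obj, degree: int = 3, max_iter: int = 20):
    """Subtract an iteratively re-fitted least-squares polynomial.

    After each fit, points above the fitted curve are excluded and the
    polynomial is re-fitted to the remainder, until the retained point set
    stabilises (or ``max_iter`` passes). This pulls the fit under the
    peaks and onto the smooth background.
    """
    axis, Y, deriv, _ = _unpack(obj)
    if degree < 0:
        raise ValueError("degree must be non-negative")
    if degree >= Y.shape[1]:
        raise ValueError("degree must be smaller than the spectrum length")
    nu = axis.values
    out = np.empty_like(Y)
    for i in range(Y.shape[0]):
        y = Y[i]
        keep = np.ones(y.size, dtype=bool)
        fit = np.zeros_like(y)
        for _ in range(max_iter):
            if keep.sum() <= degree:
                break
            poly = np.polynomial.Polynomial.fit(nu[keep], y[keep], degree)
            fit = poly(nu)
            new_keep = y <= fit
            if new_keep.sum() <= degree or np.array_equal(new_keep, keep):
                keep = new_keep if new_keep.sum() > degree else keep
                break
            keep = new_keep
        out[i] = y - fit
    return _repack(obj, axis, out, deriv)


def msc(dataset: SpectralDataset, reference: Spectrum | str = "mean"
        ) -> tuple[SpectralDataset, pd.DataFrame]:
    """Multiplicative signal correction against a reference spectrum.

    Per spectrum, fit ``y ~ a + b*ref`` by least squares and return
    ``(y - a)/b``. ``reference="mean"`` uses the dataset mean spectrum.
    Returns the corrected dataset and the (a, b) coefficients.
    """
    ref = (dataset.intensities.mean(axis=0) if reference == "mean"
           else np.asarray(reference.intensity, dtype=float))
    if ref.shape != (dataset.intensities.shape[1],):
        raise ValueError("reference length does not match the dataset axis")
    D = np.column_stack([np.ones_like(ref), ref])
    coef, *_ = np.linalg.lstsq(D, dataset.intensities.T, rcond=None)
    a, b = coef[0], coef[1]
    if np.any(np.abs(b) < 1e-12):
        raise ValueError("multiplicative coefficient b is numerically zero")
    corrected = (dataset.intensities - a[:, None]) / b[:, None]
    coeffs = pd.DataFrame({"sample_id": dataset.sample_ids, "a": a, "b": b})
    return dataset.replace(intensities=corrected), coeffs


def emsc(dataset: SpectralDataset, reference: Spectrum | str = "mean",
         poly_degree: int = 2) -> tuple[SpectralDataset, pd.DataFrame]:
    """Extended MSC: MSC plus polynomial baseline components.

    Per spectrum, fit ``y ~ b*ref + sum_k c_k * x^k`` (k = 0..degree, with
    ``x`` the wavenumber axis mapped affinely to [-1, 1]); corrected
    spectrum is ``(y - sum_k c_k x^k)/b``.
    """
    if poly_degree not in (1, 2, 3):
        raise ValueError("poly_degree must be 1, 2 or 3")
    ref = (dataset.intensities.mean(axis=0) if reference == "mean"
           else np.asarray(reference.intensity, dtype=float))
    nu = dataset.wavenumbers
    x = 2.0 * (nu - nu[0]) / (nu[-1] - nu[0]) - 1.0
    P = np.vander(x, poly_degree + 1, increasing=True)  # columns 1, x, x², ...
    D = np.column_stack([ref, P])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("EMSC design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(D, dataset.intensities.T, rcond=None)
    b, c = coef[0], coef[1:]
    if np.any(np.abs(b) < 1e-12):
        raise ValueError("multiplicative coefficient b is numerically zero")
    corrected = (dataset.intensities - (P @ c).T) / b[:, None]
    cols = {"sample_id": dataset.sample_ids, "b": b}
    cols.update({f"c{k}": c[k] for k in range(poly_degree + 1)})
    return dataset.replace(intensities=corrected), pd.DataFrame(cols)


def vector_normalize(obj):
    """Divide each spectrum by its Euclidean norm."""
    axis, Y, deriv, _ = _unpack(obj)
    norms = np.linalg.norm(Y, axis=1)
    if np.any(norms < 1e-300):
        raise ValueError("cannot vector-normalise a zero spectrum")
    return _repack(obj, axis, Y / norms[:, None], deriv)


def area_normalize(obj):
    """Divide each spectrum by its total trapezoid area of |intensity|."""
    axis, Y, deriv, _ = _unpack(obj)
    areas = np.trapezoid(np.abs(Y), axis.values, axis=1)
    if np.any(areas < 1e-300):
        raise ValueError("cannot area-normalise a zero spectrum")
    return _repack(obj, axis, Y / areas[:, None], deriv)


def band_area_normalize(obj, region: tuple[float, float] = (1670.0, 1600.0)):
    """Divide each spectrum by its trapezoid area over a band region
    (default the amide I protein band, 1670-1600 cm⁻¹)."""
    axis, Y, deriv, _ = _unpack(obj)
    lo, hi = sorted(region)
    idx = axis.index_range(lo, hi)
    if idx.size < 2:
        raise ValueError(f"band region ({lo}, {hi}) not inside the axis")
    areas = np.trapezoid(Y[:, idx], axis.values[idx], axis=1)
    if np.any(np.abs(areas) < 1e-300):
        raise ValueError("band area is numerically zero")
    return _repack(obj, axis, Y / areas[:, None], deriv)


def cosmic_ray_remove(obj, z_thresh: float = 8.0, passes: int = 2):
    """Remove cosmic-ray spikes.

    Points whose second difference exceeds ``z_thresh`` in modified z-score
    (median/MAD) are replaced by linear interpolation between the nearest
    unflagged neighbours; at most ``passes`` passes.
    """
    axis, Y, deriv, _ = _unpack(obj)
    if Y.shape[1] < 5:
        raise ValueError("need at least 5 points for spike detection")
    out = Y.copy()
    for i in range(out.shape[0]):
        y = out[i]
        for _ in range(passes):
            d2 = np.zeros_like(y)
            d2[1:-1] = y[:-2] - 2 * y[1:-1] + y[2:]
            med = np.median(d2)
            mad = np.median(np.abs(d2 - med))
            if mad < 1e-300:
                break
            z = 0.6745 * np.abs(d2 - med) / mad
            flagged = z > z_thresh
            if not flagged.any():
                break
            good = np.nonzero(~flagged)[0]
            y[flagged] = np.interp(np.nonzero(flagged)[0], good, y[good])
        out[i] = y
    return _repack(obj, axis, out, deriv)


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessRecipe:
    """Named, immutable, ordered list of (step, parameters)."""

    name: str
    steps: tuple[tuple[str, tuple[tuple[str, Any], ...]], ...]

    @classmethod
    def make(cls, name: str, steps: list[tuple[str, dict]]) -> "PreprocessRecipe":
        return cls(name, tuple((s, tuple(sorted(p.items()))) for s, p in steps))

    def step_list(self) -> list[tuple[str, dict]]:
        return [(s, dict(p)) for s, p in self.steps]

    # -- text serialisation ------------------------------------------------
    def to_text(self) -> str:
        # parameter values are written without internal whitespace so the
        # line can be split on spaces when reading back
        lines = [f"recipe = {self.name}"]
        for s, p in self.step_list():
            kv = " ".join(f"{k}={v!r}".replace(" ", "") for k, v in p.items())
            lines.append(f"step = {s} {kv}".rstrip())
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PreprocessRecipe":
        import ast
        name, steps = None, []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition("=")
            key, rest = key.strip(), rest.strip()
            if key == "recipe":
                name = rest
            elif key == "step":
                parts = rest.split()
                params = {}
                for kv in parts[1:]:
                    k, _, v = kv.partition("=")
                    params[k] = ast.literal_eval(v)
                steps.append((parts[0], params))
        if name is None:
            raise ValueError("recipe text lacks a 'recipe =' line")
        return cls.make(name, steps)


def _r(name: str, steps: list[tuple[str, dict]]) -> PreprocessRecipe:
    return PreprocessRecipe.make(name, steps)


RECIPES: dict[str, PreprocessRecipe] = {r.name: r for r in (
    _r("htsftir_bandratio", [
        ("truncate", {"regions": ((800.0, 1800.0),)}),
        ("linear_baseline", {}),
        ("band_area_normalize", {"region": (1670.0, 1600.0)}),
        ("savgol", {"window": 15, "polyorder": 2, "deriv": 2}),
    ]),
    _r("htsftir_mva", [
        ("savgol", {"window": 11, "polyorder": 2, "deriv": 2}),
        ("truncate", {"regions": ((2600.0, 3200.0), (600.0, 2000.0))}),
        ("msc", {}),
    ]),
    _r("ftraman_bandratio", [
        ("savgol", {"window": 15, "polyorder": 2, "deriv": 2}),
        ("truncate", {"regions": ((2500.0, 3200.0), (600.0, 1800.0))}),
        ("msc", {}),
    ]),
    _r("ftraman_mva", [
        ("rubberband", {}),
        ("savgol", {"window": 11, "polyorder": 2, "deriv": 2}),
        ("truncate", {"regions": ((400.0, 1800.0),)}),
        ("vector_normalize", {}),
    ]),
    _r("ftraman_plsr", [
        ("savgol", {"window": 15, "polyorder": 2, "deriv": 0}),
        ("rubberband", {}),
        ("truncate", {"regions": ((2400.0, 3200.0), (500.0, 1900.0))}),
        ("emsc", {"poly_degree": 3}),
    ]),
    _r("ramanmicro_point", [
        ("cosmic_ray_remove", {}),
        ("rubberband", {}),
        ("truncate", {"regions": ((400.0, 1800.0),)}),
        ("area_normalize", {}),
    ]),
    _r("ramanmicro_image", [
        ("cosmic_ray_remove", {}),
        ("polynomial_baseline", {"degree": 3}),
        ("truncate", {"regions": ((400.0, 1800.0),)}),
    ]),
    _r("ftirmicro_mva", [
        ("pixel_qc", {}),
        ("binning", {"block": 10, "min_pixels": 5}),
        ("savgol", {"window": 9, "polyorder": 2, "deriv": 2}),
        ("emsc", {"poly_degree": 2, "reference": "mean"}),
    ]),
)}


def _run_step(data, step: str, params: dict):
    if step == "truncate":
        return truncate(data, list(params["regions"]))
    if step == "savgol":
        return savgol(data, SGParams(**params))
    if step == "linear_baseline":
        return linear_baseline(data)
    if step == "polynomial_baseline":
        return polynomial_baseline(data, **params)
    if step == "rubberband":
        return rubberband_baseline(data)[1]
    if step == "band_area_normalize":
        return band_area_normalize(data, **params)
    if step == "vector_normalize":
        return vector_normalize(data)
    if step == "area_normalize":
        return area_normalize(data)
    if step == "cosmic_ray_remove":
        return cosmic_ray_remove(data, **params)
    if step == "msc":
        return msc(data, **params)[0]
    if step == "emsc":
        return emsc(data, **params)[0]
    raise ValueError(f"unknown preprocessing step {step!r}")


def get_recipe(name: str) -> PreprocessRecipe:
    try:
        return RECIPES[name]
    except KeyError:
        raise KeyError(f"unknown recipe {name!r}; available: {sorted(RECIPES)}")


def apply_recipe(data, recipe: str | PreprocessRecipe):
    """Apply a recipe's steps in order to a dataset (or hyperspectral image
    for recipes that start with pixel QC and binning).

    Recipes expect raw (derivative order 0) input; re-applying a recipe to
    already-differentiated spectra raises.
    """
    from .imaging import HyperspectralImage, bin_image, remove_empty_pixels, BlockGrid

    rec = get_recipe(recipe) if isinstance(recipe, str) else recipe
    steps = rec.step_list()
    if isinstance(data, HyperspectralImage):
        i = 0
        while i < len(steps) and steps[i][0] in ("pixel_qc", "binning"):
            step, params = steps[i]
            if step == "pixel_qc":
                remove_empty_pixels(data, **params)
            else:
                if data.valid_mask is None:
                    data.valid_mask = np.ones(data.shape, dtype=bool)
                data = bin_image(data, BlockGrid.for_shape(data.shape, **params))
            i += 1
        steps = steps[i:]
    else:
        steps = [s for s in steps if s[0] not in ("pixel_qc", "binning")]
        if getattr(data, "derivative_order", 0) != 0:
            raise RecipeError(
                f"recipe {rec.name!r} expects raw spectra, got derivative order "
                f"{data.derivative_order} (recipe already applied?)")
    for step, params in steps:
        try:
            data = _run_step(data, step, params)
        except Exception as exc:
            raise RecipeError(f"recipe {rec.name!r}, step {step!r}: {exc}") from exc
    return data
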