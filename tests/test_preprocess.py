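import numpy as np
import pandas as pd
import pytest

from specflux.axes import FT_RAMAN, HTS_FTIR, WavenumberAxis
from specflux.preprocess import (PreprocessRecipe, RECIPES, RecipeError,
                                 SGParams, apply_recipe, area_normalize,
                                 band_area_normalize, cosmic_ray_remove, emsc,
                                 get_recipe, linear_baseline, msc,
                                 polynomial_baseline, rubberband_baseline,
                                 savgol, truncate, vector_normalize)
from specflux.spectra import SpectralDataset, Spectrum


def _dataset(rng, n=6, p=200, lo=600.0, hi=1800.0):
    axis = WavenumberAxis(np.linspace(lo, hi, p))
    base = np.exp(-0.5 * ((axis.values - 1200.0) / 60.0) ** 2)
    b = rng.uniform(0.5, 2.0, n)
    a = rng.uniform(-0.2, 0.2, n)
    Y = a[:, None] + b[:, None] * base[None, :] + rng.normal(0, 1e-3, (n, p))
    meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)]})
    return SpectralDataset(axis, Y, meta), base, a, b


# ---------------------------------------------------------------------------
# truncate
# ---------------------------------------------------------------------------

def test_truncate_keeps_inclusive_regions(rng):
    ds, *_ = _dataset(rng, p=121)
    out = truncate(ds, [(700.0, 900.0), (1500.0, 1600.0)])
    nu = out.wavenumbers
    # oracle: direct enumeration
    expect = [v for v in ds.wavenumbers
              if 700.0 <= v <= 900.0 or 1500.0 <= v <= 1600.0]
    np.testing.assert_allclose(nu, expect)
    assert out.intensities.shape == (len(ds), len(expect))


def test_truncate_rejects_overlap_and_empty(rng):
    ds, *_ = _dataset(rng)
    with pytest.raises(ValueError):
        truncate(ds, [(700.0, 1000.0), (900.0, 1200.0)])
    with pytest.raises(ValueError):
        truncate(ds, [(10.0, 20.0)])


# ---------------------------------------------------------------------------
# Savitzky-Golay vs per-point polynomial-fit oracle
# ---------------------------------------------------------------------------

def _sg_oracle(y, window, polyorder, deriv):
    """Fit a polynomial in the window around each interior point and take
    the requested derivative at the centre (index units)."""
    half = window // 2
    out = np.full_like(y, np.nan)
    x = np.arange(-half, half + 1, dtype=float)
    for i in range(half, y.size - half):
        c = np.polyfit(x, y[i - half:i + half + 1], polyorder)
        dc = np.polyder(np.poly1d(c), deriv)
        out[i] = dc(0.0)
    return out


@pytest.mark.parametrize("window,polyorder,deriv",
                         [(15, 2, 2), (11, 2, 2), (9, 3, 1), (7, 2, 0)])
def test_savgol_matches_polyfit_oracle(rng, window, polyorder, deriv):
    axis = WavenumberAxis(np.linspace(1000.0, 1200.0, 160))
    y = np.sin(axis.values / 17.0) + 0.3 * rng.standard_normal(160)
    sp = Spectrum(axis, y)
    got = savgol(sp, SGParams(window, polyorder, deriv)).intensity
    want = _sg_oracle(y, window, polyorder, deriv)
    half = window // 2
    np.testing.assert_allclose(got[half:-half], want[half:-half], atol=1e-10)


def test_savgol_sets_derivative_order_and_refuses_nonuniform(rng):
    ds, *_ = _dataset(rng)
    out = savgol(ds, SGParams(15, 2, 2))
    assert out.derivative_order == 2
    cut = truncate(ds, [(700.0, 900.0), (1500.0, 1600.0)])
    with pytest.raises(ValueError):
        savgol(cut, SGParams(15, 2, 2))


def test_sgparams_validation():
    with pytest.raises(ValueError):
        SGParams(window=10, polyorder=2, deriv=2)
    with pytest.raises(ValueError):
        SGParams(window=5, polyorder=5, deriv=2)
    with pytest.raises(ValueError):
        SGParams(window=7, polyorder=2, deriv=3)


# ---------------------------------------------------------------------------
# rubberband vs brute-force lower-hull oracle
# ---------------------------------------------------------------------------

def _rubberband_oracle(x, y):
    """Pointwise maximum over all affine under-estimators through data
    point pairs (O(n^3), small n only)."""
    n = x.size
    base = np.full(n, -np.inf)
    for i in range(n):
        for k in range(i + 1, n):
            slope = (y[k] - y[i]) / (x[k] - x[i])
            line = y[i] + slope * (x - x[i])
            if np.all(line <= y + 1e-9):
                base = np.maximum(base, line)
    return np.minimum(base, y)


def test_rubberband_matches_hull_oracle(rng):
    axis = WavenumberAxis(np.linspace(400.0, 1800.0, 80))
    y = (np.exp(-0.5 * ((axis.values - 1000.0) / 40.0) ** 2)
         + 0.001 * axis.values + 0.2 * np.sin(axis.values / 300.0)
         + 0.05 * rng.standard_normal(80))
    sp = Spectrum(axis, y)
    base, corr = rubberband_baseline(sp)
    want = _rubberband_oracle(axis.values, y)
    np.testing.assert_allclose(base.intensity, want, atol=1e-8)
    np.testing.assert_allclose(corr.intensity, y - want, atol=1e-8)
    assert np.all(corr.intensity >= -1e-8)  # baseline never exceeds the data


def test_rubberband_endpoints_are_zeroed(rng):
    axis = WavenumberAxis(np.linspace(0.0, 10.0, 50))
    y = rng.standard_normal(50) ** 2 + 1.0
    _, corr = rubberband_baseline(Spectrum(axis, y))
    assert corr.intensity[0] == pytest.approx(0.0, abs=1e-12)
    assert corr.intensity[-1] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def test_linear_baseline_removes_straight_line(rng):
    axis = WavenumberAxis(np.linspace(0.0, 100.0, 60))
    y = 3.0 + 0.05 * axis.values
    out = linear_baseline(Spectrum(axis, y))
    np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)


def test_polynomial_baseline_recovers_known_background(rng):
    axis = WavenumberAxis(np.linspace(400.0, 1800.0, 300))
    x = axis.values
    bg = 1e-7 * (x - 1000.0) ** 2 + 0.01 * x
    peaks = 5.0 * np.exp(-0.5 * ((x - 1200.0) / 10.0) ** 2)
    out = polynomial_baseline(Spectrum(axis, bg + peaks), degree=2)
    # peak region survives, smooth background is gone
    assert out.intensity.max() == pytest.approx(peaks.max(), rel=0.05)
    off_peak = np.abs(x - 1200.0) > 100.0
    assert np.abs(out.intensity[off_peak]).max() < 0.05 * peaks.max()


# ---------------------------------------------------------------------------
# MSC / EMSC vs closed-form least squares
# ---------------------------------------------------------------------------

def test_msc_matches_closed_form(rng):
    ds, *_ = _dataset(rng)
    out, coeffs = msc(ds)
    ref = ds.intensities.mean(axis=0)
    D = np.column_stack([np.ones_like(ref), ref])
    # closed-form normal equations oracle per spectrum
    G = np.linalg.inv(D.T @ D)
    for i in range(len(ds)):
        a, b = G @ D.T @ ds.intensities[i]
        np.testing.assert_allclose([coeffs["a"][i], coeffs["b"][i]], [a, b],
                                   atol=1e-10)
        np.testing.assert_allclose(out.intensities[i],
                                   (ds.intensities[i] - a) / b, atol=1e-10)


def test_msc_undoes_multiplicative_and_offset_effects(rng):
    ds, base, a, b = _dataset(rng)
    out, _ = msc(ds)
    # corrected spectra collapse onto a common shape
    spread_before = ds.intensities.std(axis=0).max()
    spread_after = out.intensities.std(axis=0).max()
    assert spread_after < 0.05 * spread_before


def test_emsc_matches_closed_form(rng):
    ds, *_ = _dataset(rng)
    out, coeffs = emsc(ds, poly_degree=2)
    ref = ds.intensities.mean(axis=0)
    nu = ds.wavenumbers
    x = 2.0 * (nu - nu[0]) / (nu[-1] - nu[0]) - 1.0
    D = np.column_stack([ref, np.ones_like(x), x, x ** 2])
    G = np.linalg.inv(D.T @ D)
    for i in range(len(ds)):
        beta = G @ D.T @ ds.intensities[i]
        b, c = beta[0], beta[1:]
        poly = c[0] + c[1] * x + c[2] * x ** 2
        np.testing.assert_allclose(coeffs["b"][i], b, atol=1e-10)
        np.testing.assert_allclose(out.intensities[i],
                                   (ds.intensities[i] - poly) / b, atol=1e-9)


def test_emsc_removes_polynomial_baselines(rng):
    ds, base, _, b = _dataset(rng)
    nu = ds.wavenumbers
    x = 2.0 * (nu - nu[0]) / (nu[-1] - nu[0]) - 1.0
    drift = rng.uniform(-0.5, 0.5, (len(ds), 1)) * (x ** 2)[None, :]
    noisy = ds.replace(intensities=ds.intensities + drift)
    out, _ = emsc(noisy, poly_degree=2)
    spread = out.intensities.std(axis=0).max()
    assert spread < 0.05 * noisy.intensities.std(axis=0).max()


def test_emsc_rejects_bad_degree(rng):
    ds, *_ = _dataset(rng)
    with pytest.raises(ValueError):
        emsc(ds, poly_degree=5)


# ---------------------------------------------------------------------------
# normalisations
# ---------------------------------------------------------------------------

def test_vector_normalize_unit_norm(rng):
    ds, *_ = _dataset(rng)
    out = vector_normalize(ds)
    np.testing.assert_allclose(np.linalg.norm(out.intensities, axis=1), 1.0,
                               atol=1e-12)


def test_area_normalize_unit_area(rng):
    ds, *_ = _dataset(rng)
    out = area_normalize(ds)
    areas = np.trapezoid(np.abs(out.intensities), out.wavenumbers, axis=1)
    np.testing.assert_allclose(areas, 1.0, atol=1e-12)


def test_band_area_normalize_scales_by_window_area(rng):
    ds, *_ = _dataset(rng, lo=1000.0, hi=1800.0)
    out = band_area_normalize(ds, region=(1670.0, 1600.0))
    idx = out.axis.index_range(1600.0, 1670.0)
    areas = np.trapezoid(out.intensities[:, idx], out.wavenumbers[idx], axis=1)
    np.testing.assert_allclose(areas, 1.0, atol=1e-10)
    with pytest.raises(ValueError):
        band_area_normalize(ds, region=(100.0, 120.0))


# ---------------------------------------------------------------------------
# cosmic rays
# ---------------------------------------------------------------------------

def test_cosmic_ray_remove_interpolates_spikes(rng):
    axis = WavenumberAxis(np.linspace(400.0, 1800.0, 400))
    clean = np.exp(-0.5 * ((axis.values - 1000.0) / 30.0) ** 2)
    y = clean + rng.normal(0, 1e-3, clean.size)
    spiked = y.copy()
    for j in (50, 200, 310):
        spiked[j] += 5.0
    out = cosmic_ray_remove(Spectrum(axis, spiked))
    assert np.abs(out.intensity - y).max() < 0.05
    # a clean spectrum passes through nearly unchanged
    out2 = cosmic_ray_remove(Spectrum(axis, y))
    assert np.abs(out2.intensity - y).max() < 0.02


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

def test_eight_published_recipes_exist():
    assert set(RECIPES) == {
        "htsftir_bandratio", "htsftir_mva", "ftraman_bandratio",
        "ftraman_mva", "ftraman_plsr", "ramanmicro_point",
        "ramanmicro_image", "ftirmicro_mva"}


def test_recipe_text_round_trip():
    for rec in RECIPES.values():
        back = PreprocessRecipe.from_text(rec.to_text())
        assert back == rec


def test_get_recipe_unknown_name():
    with pytest.raises(KeyError):
        get_recipe("ftraman_typo")


def test_apply_recipe_produces_second_derivative(small_datasets):
    out = apply_recipe(small_datasets[HTS_FTIR], "htsftir_bandratio")
    assert out.derivative_order == 2
    assert out.wavenumbers[0] >= 800.0 and out.wavenumbers[-1] <= 1800.0


def test_apply_recipe_refuses_derivative_input(small_datasets):
    once = apply_recipe(small_datasets[FT_RAMAN], "ftraman_bandratio")
    with pytest.raises(RecipeError):
        apply_recipe(once, "ftraman_bandratio")


def test_apply_recipe_wraps_step_errors(small_datasets):
    bad = PreprocessRecipe.make("bad", [("truncate", {"regions": ((1.0, 2.0),)})])
    with pytest.raises(RecipeError, match="bad"):
        apply_recipe(small_datasets[FT_RAMAN], bad)
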