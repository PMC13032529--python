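import itertools

import numpy as np
import pytest

from specflux.axes import WavenumberAxis
from specflux.imaging import (BasisFitResult, BasisSet, BlockGrid,
                              HyperspectralImage, absorbance_map, basis_fit,
                              bin_image, derive_basis, remove_empty_pixels)


def _flat_axis(n=32, lo=1400.0, hi=1800.0):
    return WavenumberAxis(np.linspace(lo, hi, n))


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

def test_image_validation():
    axis = _flat_axis()
    with pytest.raises(ValueError):
        HyperspectralImage(np.zeros((4, 4)), axis)  # not 3-D
    with pytest.raises(ValueError):
        HyperspectralImage(np.zeros((4, 4, 10)), axis)  # depth mismatch
    cube = np.zeros((4, 4, len(axis)))
    cube[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        HyperspectralImage(cube, axis)


# ---------------------------------------------------------------------------
# pixel QC: the four behavioural contracts
# ---------------------------------------------------------------------------

def _gauss_band(axis, center=1600.0, fwhm=40.0, amp=1.0):
    s = fwhm / 2.355
    return amp * np.exp(-0.5 * ((axis.values - center) / s) ** 2)


def test_qc_all_empty_image_removes_everything(rng):
    axis = _flat_axis(64)
    cube = rng.normal(0.0, 5e-4, (16, 16, len(axis)))
    img = HyperspectralImage(cube, axis)
    valid = remove_empty_pixels(img, snr_region=(1700.0, 1500.0))
    assert not valid.any()
    assert img.valid_mask is valid


def test_qc_uniform_noise_free_sample_keeps_everything():
    axis = _flat_axis(64)
    band = _gauss_band(axis)
    cube = np.tile(band, (16, 16, 1))
    img = HyperspectralImage(cube, axis)
    valid = remove_empty_pixels(img, snr_region=(1700.0, 1500.0))
    assert valid.all()


def test_qc_mixed_scene_confusion_rates(rng):
    """Background sensitivity >= 95%, sample-pixel loss <= 5%."""
    axis = _flat_axis(64)
    band = _gauss_band(axis)
    truth = np.zeros((40, 40), dtype=bool)
    truth[8:30, 5:35] = True  # sample region
    cube = rng.normal(0.0, 5e-4, (40, 40, len(axis)))
    cube[truth] += band * rng.uniform(0.7, 1.3, (truth.sum(), 1))
    img = HyperspectralImage(cube, axis)
    valid = remove_empty_pixels(img, snr_region=(1700.0, 1500.0))
    background_removed = np.mean(~valid[~truth])
    sample_lost = np.mean(~valid[truth])
    assert background_removed >= 0.95
    assert sample_lost <= 0.05


def test_qc_stores_mask_and_validates_region(rng):
    axis = _flat_axis(8)
    img = HyperspectralImage(rng.normal(size=(4, 4, len(axis))), axis)
    with pytest.raises(ValueError):
        remove_empty_pixels(img, snr_region=(100.0, 101.0))


# ---------------------------------------------------------------------------
# block binning
# ---------------------------------------------------------------------------

def test_blockgrid_128_yields_169_blocks():
    grid = BlockGrid.for_shape((128, 128))
    assert len(grid.blocks) == 13 * 13  # 12 full + 1 remainder strip per axis
    sizes = {(len(rr), len(cc)) for rr, cc in grid.blocks}
    assert sizes == {(10, 10), (10, 8), (8, 10), (8, 8)}


def test_blockgrid_exact_multiple_has_no_remainder():
    grid = BlockGrid.for_shape((40, 40))
    assert len(grid.blocks) == 16
    assert all(len(rr) == 10 and len(cc) == 10 for rr, cc in grid.blocks)


def test_bin_image_conserves_mass_on_fully_valid_image(rng):
    axis = _flat_axis(16)
    cube = rng.random((40, 40, len(axis)))
    img = HyperspectralImage(cube, axis, valid_mask=np.ones((40, 40), bool))
    binned = bin_image(img)
    assert len(binned) == 16
    # block means times block sizes reproduce the cube sum exactly
    total = sum(binned.intensities[i] * binned.meta["n_pixels"][i]
                for i in range(len(binned)))
    np.testing.assert_allclose(total, cube.sum(axis=(0, 1)), atol=1e-10)


def test_bin_image_drops_sparse_blocks(rng):
    axis = _flat_axis(8)
    cube = rng.random((20, 20, len(axis)))
    mask = np.zeros((20, 20), bool)
    mask[:10, :10] = True       # one fully valid block
    mask[10, 10:13] = True      # 3 valid pixels elsewhere: below min_pixels
    img = HyperspectralImage(cube, axis, valid_mask=mask)
    binned = bin_image(img)
    assert len(binned) == 1
    assert binned.meta["n_pixels"][0] == 100


def test_bin_image_requires_mask(rng):
    axis = _flat_axis(8)
    img = HyperspectralImage(rng.random((20, 20, len(axis))), axis)
    with pytest.raises(ValueError):
        bin_image(img)


# ---------------------------------------------------------------------------
# basis fit vs subset-enumeration NNLS oracle
# ---------------------------------------------------------------------------

def _nnls_oracle(B, y):
    """Global NNLS optimum by enumerating active sets (small K only)."""
    k = B.shape[1]
    best_f, best_r = np.zeros(k), np.linalg.norm(y)
    for size in range(1, k + 1):
        for subset in itertools.combinations(range(k), size):
            sub = B[:, subset]
            f_sub, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.any(f_sub < -1e-12):
                continue
            f = np.zeros(k)
            f[list(subset)] = np.clip(f_sub, 0.0, None)
            r = np.linalg.norm(y - B @ f)
            if r < best_r - 1e-15:
                best_f, best_r = f, r
    return best_f, best_r


def test_basis_fit_matches_nnls_oracle(rng):
    axis = _flat_axis(24)
    B = np.abs(rng.random((3, len(axis)))) + 0.1
    basis = BasisSet(B, ["a", "b", "c"], axis)
    # mixtures with some negative-leaning targets to exercise the constraint
    cube = np.empty((4, 4, len(axis)))
    for i in range(4):
        for j in range(4):
            f = rng.uniform(-0.4, 1.0, 3)
            cube[i, j] = f @ B + 0.02 * rng.standard_normal(len(axis))
    img = HyperspectralImage(cube, axis)
    res = basis_fit(img, basis, nonneg=True)
    for i in range(4):
        for j in range(4):
            f_oracle, r_oracle = _nnls_oracle(B.T, cube[i, j])
            np.testing.assert_allclose(res.factors[i, j], f_oracle, atol=1e-8)
            assert res.residual_norm[i, j] == pytest.approx(r_oracle, abs=1e-8)
    assert np.all(res.factors >= 0.0)


def test_basis_fit_unconstrained_matches_lstsq(rng):
    axis = _flat_axis(24)
    B = rng.standard_normal((3, len(axis)))
    basis = BasisSet(B, ["a", "b", "c"], axis)
    cube = rng.standard_normal((3, 3, len(axis)))
    img = HyperspectralImage(cube, axis)
    res = basis_fit(img, basis, nonneg=False)
    for i in range(3):
        for j in range(3):
            f, *_ = np.linalg.lstsq(B.T, cube[i, j], rcond=None)
            np.testing.assert_allclose(res.factors[i, j], f, atol=1e-9)


def test_basis_fit_offset_absorbs_constant(rng):
    axis = _flat_axis(24)
    B = np.abs(rng.random((2, len(axis)))) + 0.1
    basis = BasisSet(B, ["a", "b"], axis)
    f_true = np.array([0.7, 0.3])
    cube = (f_true @ B - 0.25)[None, None, :]  # negative constant offset
    img = HyperspectralImage(np.ascontiguousarray(cube), axis)
    res = basis_fit(img, basis, nonneg=True, offset=True)
    np.testing.assert_allclose(res.factors[0, 0], f_true, atol=1e-6)


def test_basis_set_rejects_duplicates():
    row = np.linspace(0.0, 1.0, 10)
    with pytest.raises(ValueError):
        BasisSet(np.stack([row, row]), ["a", "b"])
    with pytest.raises(ValueError):
        BasisSet(np.stack([row, row + 1.0]), ["only_one_name"])


def test_basis_fit_warns_on_degenerate_basis(rng):
    axis = _flat_axis(24)
    r1 = np.abs(rng.random(len(axis))) + 0.1
    r2 = np.abs(rng.random(len(axis))) + 0.1
    # third spectrum nearly a linear combination: no pairwise duplicate,
    # but the design matrix is almost rank-deficient
    r3 = 0.5 * (r1 + r2) + 1e-10 * rng.standard_normal(len(axis))
    basis = BasisSet(np.stack([r1, r2, r3]), ["a", "b", "c"], axis)
    img = HyperspectralImage(rng.random((2, 2, len(axis))), axis)
    with pytest.warns(UserWarning):
        basis_fit(img, basis)


# ---------------------------------------------------------------------------
# basis derivation + component maps on a simulated scene
# ---------------------------------------------------------------------------

def _auc(score, truth):
    """Rank AUC of score separating truth=True from truth=False."""
    pos, neg = score[truth], score[~truth]
    order = np.argsort(np.concatenate([pos, neg]), kind="mergesort")
    ranks = np.empty(order.size)
    ranks[order] = np.arange(1, order.size + 1)
    r_pos = ranks[: pos.size].sum()
    return (r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)


def test_component_map_recovers_lipid_bodies(small_image):
    scene, img = small_image
    remove_empty_pixels(img)
    basis = derive_basis(img, 3, seed=5)
    res = basis_fit(img, basis)
    lipid_truth = img.truth["lipid_body"].astype(bool)
    # pick the component whose map best tracks the lipid bodies
    best = max(_auc(res.factors[:, :, k].ravel(), lipid_truth.ravel())
               for k in range(3))
    assert best >= 0.9


def test_derive_basis_manual_and_errors(small_image):
    _, img = small_image
    basis = derive_basis(img, 2, method="manual",
                         pixel_coords=[(0, 0), (24, 24)])
    assert basis.k == 2
    with pytest.raises(ValueError):
        derive_basis(img, 2, method="manual", pixel_coords=[(0, 0)])
    with pytest.raises(ValueError):
        derive_basis(img, 0)
    with pytest.raises(ValueError):
        derive_basis(img, 2, method="nmf")


def test_absorbance_map_tracks_ester_band(small_image):
    scene, img = small_image
    amap = absorbance_map(img, nu=1745.0, halfwidth=4.0)
    assert amap.shape == img.shape
    lipid = img.truth["lipid_body"].astype(bool)
    bg = ~scene.hyphae_mask
    assert amap[lipid].mean() > 3.0 * amap[bg].mean()
    with pytest.raises(ValueError):
        absorbance_map(img, nu=99999.0)
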