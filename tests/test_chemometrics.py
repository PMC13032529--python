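import numpy as np
import pytest

from specflux.chemometrics import (CorrelationLoadings, correlation_loadings,
                                   cpca_fit, pca_fit, plsr_fit,
                                   plsr_flag_outliers, plsr_predict)


def _random_lowrank(rng, n=30, p=80, rank=4, noise=1e-3):
    U = rng.standard_normal((n, rank))
    V = rng.standard_normal((rank, p))
    return U @ V + noise * rng.standard_normal((n, p))


# ---------------------------------------------------------------------------
# PCA vs covariance-eigendecomposition oracle
# ---------------------------------------------------------------------------

def test_pca_matches_eigendecomposition_oracle(rng):
    X = _random_lowrank(rng)
    ncomp = 4
    model = pca_fit(X, ncomp)
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / 1.0
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for k in range(ncomp):
        v = evecs[:, k]
        # resolve the eigenvector sign with the model's convention
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v = -v
        np.testing.assert_allclose(model.loadings[k], v, atol=1e-9)
        np.testing.assert_allclose(model.scores[:, k], Xc @ v, atol=1e-9)
    pct_oracle = 100.0 * evals[:ncomp] / evals.sum()
    np.testing.assert_allclose(model.pct_variance, pct_oracle, atol=1e-9)


def test_pca_transform_reconstruct_round_trip(rng):
    X = _random_lowrank(rng, rank=3, noise=0.0)
    model = pca_fit(X, 3)
    np.testing.assert_allclose(model.transform(X), model.scores, atol=1e-9)
    np.testing.assert_allclose(model.reconstruct(), X, atol=1e-8)


def test_pca_sign_convention_is_deterministic(rng):
    X = _random_lowrank(rng)
    a = pca_fit(X, 3)
    b = pca_fit(X.copy(), 3)
    np.testing.assert_array_equal(a.loadings, b.loadings)
    for k in range(3):
        assert a.loadings[k, np.argmax(np.abs(a.loadings[k]))] > 0


def test_pca_errors(rng):
    X = _random_lowrank(rng, n=5, p=10)
    with pytest.raises(ValueError):
        pca_fit(X, 5)  # > n-1
    with pytest.raises(ValueError):
        pca_fit(np.ones((6, 4)), 1)  # constant matrix


# ---------------------------------------------------------------------------
# CPCA vs explicit super-matrix SVD oracle
# ---------------------------------------------------------------------------

def test_cpca_matches_supermatrix_svd_oracle(rng):
    blocks = {"A": _random_lowrank(rng, p=50), "B": _random_lowrank(rng, p=70)}
    ncomp = 4
    model = cpca_fit(blocks, ncomp)

    # oracle: scale and concatenate explicitly, then SVD
    scaled = []
    for name in ("A", "B"):
        Mc = blocks[name] - blocks[name].mean(axis=0)
        w = np.linalg.norm(Mc)
        assert model.block_weights[name] == pytest.approx(w)
        scaled.append(Mc / w)
    S = np.hstack(scaled)
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    for k in range(ncomp):
        v, t = Vt[k], U[:, k] * s[k]
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v, t = -v, -t
        np.testing.assert_allclose(model.global_scores[:, k], t, atol=1e-9)
        np.testing.assert_allclose(
            np.concatenate([model.block_loadings["A"][k],
                            model.block_loadings["B"][k]]), v, atol=1e-9)
    pct = 100.0 * s[:ncomp] ** 2 / np.sum(s ** 2)
    np.testing.assert_allclose(model.pct_variance_global, pct, atol=1e-9)


def test_cpca_block_scores_project_onto_block_loadings(rng):
    blocks = {"A": _random_lowrank(rng, p=40), "B": _random_lowrank(rng, p=60)}
    model = cpca_fit(blocks, 3)
    for name, M in blocks.items():
        Sb = (M - model.block_means[name]) / model.block_weights[name]
        for k in range(3):
            pb = model.block_loadings[name][k]
            want = Sb @ pb / (pb @ pb)
            np.testing.assert_allclose(model.block_scores[name][:, k], want,
                                       atol=1e-9)


def test_cpca_per_block_variance_sums_sensibly(rng):
    blocks = {"A": _random_lowrank(rng, rank=3, noise=0.0)}
    model = cpca_fit(blocks, 3)
    # one noiseless rank-3 block: 3 components explain everything
    assert model.pct_variance_per_block["A"].sum() == pytest.approx(100.0, abs=1e-6)
    assert np.all(model.pct_variance_per_block["A"] >= -1e-9)


def test_cpca_input_validation(rng):
    with pytest.raises(ValueError):
        cpca_fit({}, 2)
    with pytest.raises(ValueError):
        cpca_fit({"A": _random_lowrank(rng, n=10), "B": _random_lowrank(rng, n=12)}, 2)
    with pytest.raises(ValueError):
        cpca_fit({"A": np.ones((8, 5))}, 2)  # constant block
    with pytest.raises(ValueError):
        cpca_fit({"A": _random_lowrank(rng)}, 2, scaling="pareto")


# ---------------------------------------------------------------------------
# correlation loadings
# ---------------------------------------------------------------------------

def test_correlation_loadings_bounded_with_circles(rng):
    blocks = {"A": _random_lowrank(rng, p=30), "B": _random_lowrank(rng, p=20)}
    model = cpca_fit(blocks, 3)
    cl = correlation_loadings(model, blocks)
    assert cl.r.shape == (50, 3)
    assert np.nanmax(np.abs(cl.r)) <= 1.0 + 1e-9
    assert cl.circle_radii == (pytest.approx(np.sqrt(0.5)), 1.0)


def test_correlation_loadings_flags_zero_variance(rng):
    X = _random_lowrank(rng, p=20)
    X[:, 5] = 2.5  # constant variable
    model = pca_fit(X, 2)
    cl = correlation_loadings(model, X)
    assert cl.zero_variance[5]
    assert np.all(cl.r[5] == 0.0)


# ---------------------------------------------------------------------------
# PLSR vs OLS oracle, Q-residual outliers
# ---------------------------------------------------------------------------

def test_plsr_full_rank_equals_ols_oracle(rng):
    n, p = 40, 6
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + 0.01 * rng.standard_normal(n)
    model = plsr_fit(X, y, n_lv=p)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
    np.testing.assert_allclose(model.coef, beta_ols, atol=1e-8)
    y_hat, _ = plsr_predict(model, X)
    np.testing.assert_allclose(y_hat, y.mean() + Xc @ beta_ols, atol=1e-8)


def test_plsr_beats_noise_with_few_lvs(rng):
    n, p = 60, 120
    t = rng.standard_normal(n)
    X = np.outer(t, rng.standard_normal(p)) + 0.05 * rng.standard_normal((n, p))
    y = 2.0 * t + 0.05 * rng.standard_normal(n)
    model = plsr_fit(X, y, n_lv=2)
    y_hat, _ = plsr_predict(model, X)
    rmse = np.sqrt(np.mean((y_hat - y) ** 2))
    assert rmse < 0.2


def test_plsr_q_residual_flags_foreign_spectra(rng):
    n, p = 80, 60
    basis = rng.standard_normal((3, p))
    X = rng.standard_normal((n, 3)) @ basis + 0.01 * rng.standard_normal((n, p))
    y = X @ rng.standard_normal(p) * 0.1 + rng.standard_normal(n) * 0.01
    model = plsr_fit(X, y, n_lv=3)
    # in-space test samples: mostly unflagged
    Xin = rng.standard_normal((40, 3)) @ basis + 0.01 * rng.standard_normal((40, p))
    _, q_in = plsr_predict(model, Xin)
    # out-of-space samples carry structure the calibration never saw
    Xout = Xin + 0.5 * rng.standard_normal((40, p))
    _, q_out = plsr_predict(model, Xout)
    flags_in = plsr_flag_outliers(model, q_in)
    flags_out = plsr_flag_outliers(model, q_out)
    assert flags_in.mean() <= 0.1
    assert flags_out.mean() >= 0.95


def test_plsr_input_validation(rng):
    X = rng.standard_normal((10, 5))
    with pytest.raises(ValueError):
        plsr_fit(X, np.ones(10), 2)  # zero-variance response
    with pytest.raises(ValueError):
        plsr_fit(X, rng.standard_normal(8), 2)  # size mismatch
    with pytest.raises(ValueError):
        plsr_fit(X, rng.standard_normal(10), 9)  # exceeds rank
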