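"""Chemometric models: PCA, multiblock consensus PCA, and PLS regression.

Consensus PCA (CPCA) analyses several preprocessed spectral blocks (for
instance HTS-FTIR and FT-Raman, with technical replicates averaged so the
blocks line up sample-to-sample). Each mean-centred block is scaled by a
block weight (Frobenius norm by default), the scaled blocks are
concatenated column-wise, and the super-matrix is decomposed by SVD.
Global scores describe the consensus variation between techniques; block
scores, the variation each single block contributes to the consensus
directions. Correlation loadings (the per-variable correlation with each
global score) visualise which vibrational bands drive each component.

PLS1 regression (NIPALS) is provided for spectral calibrations, with
Q residuals — the squared spectral variation a projected sample leaves
unexplained — used to flag samples outside the calibration space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: the largest-|loading| element of each
    component is positive."""
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    return loadings, scores


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    mean: np.ndarray            # variable means
    loadings: np.ndarray        # ncomp x nvar, orthonormal rows
    scores: np.ndarray          # nsamples x ncomp
    pct_variance: np.ndarray    # percent of total variance per component

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings.T

    def reconstruct(self, scores: np.ndarray | None = None) -> np.ndarray:
        t = self.scores if scores is None else scores
        return t @ self.loadings + self.mean


def pca_fit(X: np.ndarray, ncomp: int) -> PCAModel:
    """Column-mean-centred SVD principal component analysis."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if ncomp > min(n - 1, p):
        raise ValueError(f"ncomp={ncomp} exceeds min(n-1, p)={min(n - 1, p)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    total = float(np.sum(Xc ** 2))
    if total < 1e-300:
        raise ValueError("matrix is constant; PCA undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:ncomp].copy()
    scores = (U[:, :ncomp] * s[:ncomp]).copy()
    loadings, scores = _fix_signs(loadings, scores)
    pct = 100.0 * s[:ncomp] ** 2 / np.sum(s ** 2)
    return PCAModel(mean=mean, loadings=loadings, scores=scores, pct_variance=pct)


# ---------------------------------------------------------------------------
# Consensus PCA
# ---------------------------------------------------------------------------

@dataclass
class CPCAModel:
    block_names: list[str]
    block_weights: dict[str, float]
    block_means: dict[str, np.ndarray]
    global_scores: np.ndarray                 # nsamples x ncomp
    block_scores: dict[str, np.ndarray]       # per block, nsamples x ncomp
    block_loadings: dict[str, np.ndarray]     # per block, ncomp x nvar_block
    pct_variance_global: np.ndarray
    pct_variance_per_block: dict[str, np.ndarray]  # cumulative-increment per PC

    @property
    def ncomp(self) -> int:
        return self.global_scores.shape[1]


def cpca_fit(blocks: dict[str, np.ndarray], ncomp: int,
             scaling: str = "frobenius") -> CPCAModel:
    """Consensus PCA of named blocks sharing sample order.

    Each block is mean-centred and divided by its block weight (the
    Frobenius norm of the centred block, or 1 with ``scaling="none"``);
    the global solution is the PCA of the column-concatenated scaled
    super-matrix. Block scores are the projections of each scaled block
    onto its own part of the global loadings, renormalised; per-block
    explained variance is the share of each block's (scaled) sum of
    squares captured by successive global components.
    """
    if not blocks:
        raise ValueError("no blocks given")
    if scaling not in ("frobenius", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    names = list(blocks)
    mats = [np.asarray(blocks[n], dtype=float) for n in names]
    n_samples = mats[0].shape[0]
    for nm, M in zip(names, mats):
        if M.size == 0:
            raise ValueError(f"block {nm!r} is empty")
        if M.shape[0] != n_samples:
            raise ValueError(f"block {nm!r} has {M.shape[0]} samples, "
                             f"expected {n_samples}")
    means = {nm: M.mean(axis=0) for nm, M in zip(names, mats)}
    centred = [M - means[nm] for nm, M in zip(names, mats)]
    weights = {}
    scaled = []
    for nm, Mc in zip(names, centred):
        w = float(np.linalg.norm(Mc)) if scaling == "frobenius" else 1.0
        if w < 1e-300:
            raise ValueError(f"block {nm!r} is constant")
        weights[nm] = w
        scaled.append(Mc / w)
    supermat = np.hstack(scaled)
    if ncomp > min(n_samples - 1, supermat.shape[1]):
        raise ValueError("ncomp too large for the concatenated blocks")
    U, s, Vt = np.linalg.svd(supermat, full_matrices=False)
    gload = Vt[:ncomp].copy()
    gscores = (U[:, :ncomp] * s[:ncomp]).copy()
    gload, gscores = _fix_signs(gload, gscores)
    pct_global = 100.0 * s[:ncomp] ** 2 / np.sum(s ** 2)

    # split global loadings back into per-block sub-vectors
    block_loadings: dict[str, np.ndarray] = {}
    block_scores: dict[str, np.ndarray] = {}
    pct_block: dict[str, np.ndarray] = {}
    offset = 0
    for nm, Sb in zip(names, scaled):
        p = Sb.shape[1]
        sub = gload[:, offset:offset + p]
        offset += p
        block_loadings[nm] = sub
        tb = np.zeros((n_samples, ncomp))
        for k in range(ncomp):
            norm2 = float(sub[k] @ sub[k])
            tb[:, k] = Sb @ sub[k] / norm2 if norm2 > 1e-300 else 0.0
        block_scores[nm] = tb
        # explained variance per component: decrease in residual SS when
        # reconstructing the scaled block from successive global scores
        # and the block's part of the global loadings
        total = float(np.sum(Sb ** 2))
        expl = np.zeros(ncomp)
        prev = 0.0
        for k in range(1, ncomp + 1):
            recon = gscores[:, :k] @ sub[:k]
            cum = 100.0 * (1.0 - np.sum((Sb - recon) ** 2) / total)
            expl[k - 1] = cum - prev
            prev = cum
        pct_block[nm] = expl

    return CPCAModel(
        block_names=names, block_weights=weights, block_means=means,
        global_scores=gscores, block_scores=block_scores,
        block_loadings=block_loadings, pct_variance_global=pct_global,
        pct_variance_per_block=pct_block,
    )


@dataclass
class CorrelationLoadings:
    """Per-variable Pearson correlation with each global score, plotted
    with circles at 100% and 50% explained variance (r = 1 and √0.5)."""

    r: np.ndarray                     # nvar x ncomp
    circle_radii: tuple[float, float] = (np.sqrt(0.5), 1.0)
    zero_variance: np.ndarray | None = None   # flag per variable


def correlation_loadings(model: CPCAModel | PCAModel,
                         blocks: dict[str, np.ndarray] | np.ndarray
                         ) -> CorrelationLoadings:
    """Correlation loadings of the fitting data against the global scores."""
    if isinstance(model, PCAModel):
        X = np.asarray(blocks, dtype=float)
        scores = model.scores
    else:
        X = np.hstack([np.asarray(blocks[n], dtype=float) for n in model.block_names])
        scores = model.global_scores
    Xc = X - X.mean(axis=0)
    Tc = scores - scores.mean(axis=0)
    xs = np.sqrt(np.sum(Xc ** 2, axis=0))
    ts = np.sqrt(np.sum(Tc ** 2, axis=0))
    zero = xs < 1e-300
    denom = np.where(zero, 1.0, xs)
    r = (Xc.T @ Tc) / denom[:, None] / ts[None, :]
    r[zero] = 0.0
    return CorrelationLoadings(r=r, zero_variance=zero)


# ---------------------------------------------------------------------------
# PLS regression (PLS1, NIPALS)
# ---------------------------------------------------------------------------

@dataclass
class PLSRModel:
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # n_lv x nvar
    x_loadings: np.ndarray    # n_lv x nvar
    y_loadings: np.ndarray    # n_lv
    coef: np.ndarray          # regression vector, nvar
    training_q: np.ndarray    # Q residual per training sample
    q_quantile: float = 0.99

    @property
    def q_threshold(self) -> float:
        return float(np.quantile(self.training_q, self.q_quantile))


def plsr_fit(X: np.ndarray, y: np.ndarray, n_lv: int,
             q_quantile: float = 0.99) -> PLSRModel:
    """NIPALS PLS1 fit of a single response on spectra."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y sample counts differ")
    if np.std(y) < 1e-300:
        raise ValueError("response y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    rank = np.linalg.matrix_rank(E)
    if n_lv > rank:
        raise ValueError(f"n_lv={n_lv} exceeds rank of centred X ({rank})")
    W = np.zeros((n_lv, X.shape[1]))
    P = np.zeros((n_lv, X.shape[1]))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-300:
            raise ValueError("degenerate deflation: no covariance left")
        w /= nw
        t = E @ w
        tt = float(t @ t)
        p = E.T @ t / tt
        qa = float(f @ t / tt)
        E = E - np.outer(t, p)
        f = f - qa * t
        W[a], P[a], q[a] = w, p, qa
    coef = W.T @ np.linalg.solve(P @ W.T, q)
    training_q = np.sum(E ** 2, axis=1)
    return PLSRModel(n_lv=n_lv, x_mean=x_mean, y_mean=y_mean, weights=W,
                     x_loadings=P, y_loadings=q, coef=coef,
                     training_q=training_q, q_quantile=q_quantile)


def plsr_predict(model: PLSRModel, X: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Predict the response and the per-sample Q residual.

    The Q residual is the squared norm of the spectrum after deflating it
    through the model's weights/loadings — spectral variation the
    calibration cannot represent. Compare against
    ``model.q_threshold`` (a quantile of training residuals) to flag
    unreliable predictions.
    """
    X = np.asarray(X, dtype=float)
    E = X - model.x_mean
    y_hat = model.y_mean + E @ model.coef
    for a in range(model.n_lv):
        t = E @ model.weights[a]
        E = E - np.outer(t, model.x_loadings[a])
    q_res = np.sum(E ** 2, axis=1)
    return y_hat, q_res


def plsr_flag_outliers(model: PLSRModel, q_res: np.ndarray) -> np.ndarray:
    """Reliability flag: True where the Q residual exceeds the training
    quantile threshold (prediction likely outside the calibration)."""
    return np.asarray(q_res) > model.q_threshold
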