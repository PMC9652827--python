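"""Population structure: genotype PCA and ancestry-coefficient estimation.

PCA follows the usual genotype convention: each variant is centered by its
mean dosage 2p and scaled by the binomial standard deviation sqrt(2p(1-p))
at the observed allele frequency, with missing dosages mean-imputed; scores
come from the SVD of the standardized matrix.

Ancestry coefficients are estimated by least-squares nonnegative matrix
factorization of the dosage/2 matrix into Q (samples x K, rows on the
probability simplex) and F (K x variants, ancestral allele frequencies in
[0,1]), solved by alternating projected-gradient steps with Lipschitz step
sizes, which makes the loss non-increasing by construction. An F1 hybrid
between two source populations has expected dosage (p1+p2), i.e. an exact
Q = (1/2, 1/2) representation, which is what the hybrid flag detects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import rng_from
from .variants_io import GenotypeMatrix


@dataclass
class PCAResult:
    coordinates: np.ndarray  # samples x components
    explained_var: np.ndarray  # fraction of total variance per component
    loadings: np.ndarray | None = None  # variants x components


@dataclass
class AncestryResult:
    K: int
    Q: np.ndarray  # samples x K, rows sum to 1
    F: np.ndarray  # K x variants, in [0,1]
    loss: float
    converged: bool = True


def _standardized_dosage(gm: GenotypeMatrix) -> np.ndarray:
    d = gm.dosage.astype(np.float64)
    miss = d < 0
    d[miss] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    # mean-impute missing entries, then center/scale
    col_mean = 2.0 * p
    d = np.where(np.isnan(d), col_mean, d)
    sd = np.sqrt(2.0 * p * (1.0 - p))
    x = d - col_mean
    informative = sd > 0
    x[:, informative] /= sd[informative]
    x[:, ~informative] = 0.0
    return x


def genotype_pca(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of the standardized genotype matrix.

    Raises if the input has no polymorphic variant. Explained-variance
    fractions are relative to the total variance of the standardized matrix,
    so a degenerate (all-identical) matrix reports zeros.
    """
    if gm.n_samples < 2 or gm.n_variants < 1:
        raise ValueError("need >= 2 samples and >= 1 variant")
    x = _standardized_dosage(gm)
    if not np.any(x != 0):
        raise ValueError("all variants are monomorphic")
    n_components = min(n_components, *x.shape)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s**2))
    coords = u[:, :n_components] * s[:n_components]
    ev = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return PCAResult(
        coordinates=coords, explained_var=ev, loadings=vt[:n_components].T
    )


def _project_simplex(q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = q.shape
    srt = np.sort(q, axis=1)[:, ::-1]
    css = np.cumsum(srt, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = srt - css / ind > 0
    rho = np.count_nonzero(cond, axis=1)
    theta = css[np.arange(n), rho - 1] / rho
    return np.maximum(q - theta[:, None], 0.0)


def ancestry_coefficients(
    gm: GenotypeMatrix,
    K: int,
    seed: int | None = None,
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 300,
) -> AncestryResult:
    """Least-squares NMF ancestry estimate, best of ``n_restarts`` by loss."""
    if not 1 <= K <= gm.n_samples:
        raise ValueError("K must be in [1, n_samples]")
    d = gm.dosage.astype(np.float64)
    miss = d < 0
    d[miss] = np.nan
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    x = np.where(np.isnan(d), col_mean[None, :], d) / 2.0
    rng = rng_from(seed)
    best: AncestryResult | None = None
    for _ in range(n_restarts):
        res = _als_fit(x, K, rng, tol, max_iter)
        if best is None or res.loss < best.loss:
            best = res
    return best


def _als_fit(x, K, rng, tol, max_iter, n_inner: int = 10) -> AncestryResult:
    n, v = x.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    F = np.clip(x[rng.choice(n, size=K, replace=False)], 0.0, 1.0)
    loss = _loss(x, Q, F)
    converged = False
    for _ in range(max_iter):
        # F block: several projected-gradient steps with 1/L step size
        qtq = Q.T @ Q
        qtx = Q.T @ x
        L_f = max(np.linalg.norm(qtq, 2), 1e-12)
        for _ in range(n_inner):
            F = np.clip(F - (qtq @ F - qtx) / L_f, 0.0, 1.0)
        # Q block: projected gradient onto the simplex
        fft = F @ F.T
        xft = x @ F.T
        L_q = max(np.linalg.norm(fft, 2), 1e-12)
        for _ in range(n_inner):
            Q = _project_simplex(Q - (Q @ fft - xft) / L_q)
        new_loss = _loss(x, Q, F)
        if loss - new_loss <= tol * max(loss, 1e-12):
            loss = new_loss
            converged = True
            break
        loss = new_loss
    return AncestryResult(K=K, Q=Q, F=F, loss=float(loss), converged=converged)


def _loss(x, Q, F) -> float:
    r = x - Q @ F
    return float(np.sum(r * r))


def hybrid_flag(
    ancestry: AncestryResult, lo: float = 0.35, hi: float = 0.65
) -> np.ndarray:
    """Per-sample boolean: both K=2 ancestry coefficients inside [lo, hi]."""
    if ancestry.K != 2:
        raise ValueError("hybrid_flag requires K = 2")
    q = ancestry.Q
    return np.all((q >= lo) & (q <= hi), axis=1)
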