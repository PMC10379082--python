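"""Population structure: Patterson-normalized PCA and admixture EM.

The admixture model is the standard unsupervised one: each dosage
g_ij ~ Binomial(2, f_ij) with f_ij = sum_k q_ik p_kj, Q the samples x K
ancestry fractions (rows simplex) and P the K x sites ancestral allele
frequencies.  It is fit by EM block updates (frappe-style), which makes
the log-likelihood non-decreasing every iteration; K is chosen by
cross-validation on masked genotype cells scored with binomial deviance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

_P_EPS = 1e-6


@dataclass
class PCAResult:
    coords: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray | None = None


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """Principal components of the dosage matrix.

    Missing dosages are mean-imputed per site; sites are centered by
    2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat)) (Patterson
    normalization); all-missing and monomorphic sites are dropped.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs >=2 samples")
    dos = gm.dosages.astype(float)
    dos[gm.dosages == MISSING] = np.nan
    p = np.nanmean(dos, axis=0) / 2.0
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    if keep.sum() < 1:
        raise ValueError("PCA needs at least one polymorphic site")
    dos = dos[:, keep]
    p = p[keep]
    X = np.where(np.isnan(dos), 2 * p, dos)
    X = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    X -= X.mean(axis=0)  # exact column centering after imputation
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(s))
    eig = (s**2) / (gm.n_samples - 1)
    return PCAResult(
        coords=u[:, :k] * s[:k],
        eigenvalues=eig[:k],
        loadings=vt[:k].T,
    )


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray
    P: np.ndarray
    loglik: float
    loglik_path: np.ndarray
    converged: bool
    seed: int
    cv_error: float | None = None


def _loglik(dos, mask, Q, P):
    F = Q @ P
    F = np.clip(F, _P_EPS, 1 - _P_EPS)
    with np.errstate(invalid="ignore"):
        ll = np.where(mask, dos * np.log(F) + (2 - dos) * np.log1p(-F), 0.0)
    # binomial coefficient: log C(2, g) = log 2 for heterozygotes
    ll = ll + np.where(mask & (dos == 1), np.log(2.0), 0.0)
    return float(ll.sum())


def admixture_em(
    gm: GenotypeMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-2,
    mask: np.ndarray | None = None,
) -> AdmixtureFit:
    """Maximum-likelihood admixture fit by EM.

    Missing dosages (and any cells masked out via ``mask=False``)
    contribute nothing to the likelihood.  Q starts from a symmetric
    Dirichlet, P from Uniform(0.05, 0.95), both seeded.  Stops when the
    log-likelihood gain drops below ``tol`` or at ``max_iter``; a
    non-converged fit returns the best iterate, flagged.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    dos = gm.dosages.astype(float)
    called = gm.dosages != MISSING
    if mask is not None:
        called = called & mask
    dos = np.where(called, dos, 0.0)
    n, J = dos.shape
    g = dos
    h = np.where(called, 2.0 - dos, 0.0)  # ref-allele counts

    if K == 1:
        denom = called.sum(axis=0) * 2.0
        p = np.where(denom > 0, g.sum(axis=0) / np.maximum(denom, 1), 0.5)
        P = np.clip(p, _P_EPS, 1 - _P_EPS)[None, :]
        Q = np.ones((n, 1))
        ll = _loglik(dos, called, Q, P)
        return AdmixtureFit(1, Q, P, ll, np.array([ll]), True, seed)

    Q = rng.dirichlet(np.ones(K), size=n)
    P = rng.uniform(0.05, 0.95, size=(K, J))
    L_i = np.maximum(2.0 * called.sum(axis=1), 1.0)[:, None]
    lls = []
    converged = False
    for it in range(max_iter):
        F = Q @ P
        F = np.clip(F, _P_EPS, 1 - _P_EPS)
        # responsibilities for alt and ref allele copies
        with np.errstate(divide="ignore", invalid="ignore"):
            A = (g / F)[:, None, :] * (Q[:, :, None] * P[None, :, :])  # n x K x J
            B = (h / (1 - F))[:, None, :] * (Q[:, :, None] * (1 - P)[None, :, :])
        sA = A.sum(axis=2)
        sB = B.sum(axis=2)
        Q = (sA + sB) / L_i
        Q = np.clip(Q, 0, None)
        Q /= Q.sum(axis=1, keepdims=True)
        colA = A.sum(axis=0)
        colB = B.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = colA / np.maximum(colA + colB, 1e-300)
        P = np.clip(P, _P_EPS, 1 - _P_EPS)
        ll = _loglik(dos * called, called, Q, P)
        lls.append(ll)
        if it > 0 and abs(lls[-1] - lls[-2]) < tol:
            converged = True
            break
    if not converged:
        log.warning("admixture_em: not converged after %d iterations", max_iter)
    return AdmixtureFit(K, Q, P, lls[-1], np.array(lls), converged, seed)


def best_of_runs(gm, K, n_runs: int, seed: int, **kw) -> AdmixtureFit:
    """Best-likelihood fit over ``n_runs`` seeded restarts."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    best = None
    for s in seeds:
        fit = admixture_em(gm, K, seed=int(s), **kw)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def _holdout_deviance(gm, K, holdout, n_runs, seed, **kw) -> float:
    """Refit with ``holdout`` cells masked, score them by binomial deviance."""
    train_mask = ~holdout
    fit = best_of_runs(gm, K, n_runs, seed, mask=train_mask, **kw)
    F = np.clip(fit.Q @ fit.P, _P_EPS, 1 - _P_EPS)
    called = gm.dosages != MISSING
    cells = holdout & called
    g = gm.dosages.astype(float)
    dev = -2.0 * (g[cells] * np.log(F[cells]) + (2 - g[cells]) * np.log1p(-F[cells]))
    return float(dev.mean())


def choose_k(
    gm: GenotypeMatrix,
    k_range=range(2, 11),
    n_runs: int = 20,
    cv_folds: int = 5,
    holdout_frac: float = 0.1,
    seed: int = 0,
    **kw,
) -> pd.DataFrame:
    """Cross-validated choice of the number of ancestral components K.

    For each K: the best-of-``n_runs`` fit on the full data gives the
    log-likelihood; ``cv_folds`` independent random holdouts of
    ``holdout_frac`` of the called cells are each masked, the model
    refit, and the held-out dosages scored by mean binomial deviance.
    Returns a per-K table (K, loglik, cv_error); the optimal K minimizes
    cv_error.
    """
    called = gm.dosages != MISSING
    rng = np.random.default_rng(seed)
    rows = []
    for K in k_range:
        full = best_of_runs(gm, K, n_runs, seed=int(rng.integers(2**31 - 1)), **kw)
        devs = []
        for _ in range(cv_folds):
            hold = (rng.random(gm.dosages.shape) < holdout_frac) & called
            devs.append(
                _holdout_deviance(
                    gm, K, hold, n_runs=max(1, n_runs // 4),
                    seed=int(rng.integers(2**31 - 1)), **kw,
                )
            )
        rows.append({"K": K, "loglik": full.loglik, "cv_error": float(np.mean(devs))})
        log.info("choose_k: K=%d loglik=%.1f cv=%.4f", K, full.loglik, rows[-1]["cv_error"])
    return pd.DataFrame(rows)
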