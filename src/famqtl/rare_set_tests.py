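"""Family-based rare-variant set tests: burden, SKAT, SKAT-O, meta-analysis.

All three tests share a null kinship mixed model y = X alpha + delta + eps
(no genotypes) whose fitted covariance V = 2*Phi*sigma2_G + I*sigma2_E
defines the projection P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1 and the
per-variant scores S_j = g_j' P y.

* Burden collapses the set into b_i = sum_j w_j g_ij and tests it as a
  single covariate in the mixed model (likelihood ratio); the equivalent
  score-form statistic Q_burden = (sum_j w_j S_j)^2 is also reported and
  is what SKAT-O interpolates to at rho = 1.
* SKAT uses the weighted score quadratic form Q = sum_j w_j^2 S_j^2,
  whose null law is a mixture of chi-squares with eigenvalues of
  W G'PG W.
* SKAT-O scans Q_rho = (1-rho) Q_SKAT + rho Q_burden over a rho grid and
  combines the per-rho p-values by the one-dimensional min-p integration.

Weights default to the Beta(1,25) density of the minor allele frequency,
w_j = 25 (1 - MAF_j)^24, which up-weights the rarest variants. Study-level
results combine by Fisher's method (or sample-size-weighted Stouffer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._mixture_chi2 import mixture_isf, mixture_sf
from .mixed_assoc import PolygenicModel
from .pedigree_io import KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_RHO_GRID",
    "WeightSpec",
    "GeneSetResult",
    "beta_weights",
    "burden_test",
    "skat_test",
    "skato_test",
    "meta_combine",
]

#: standard SKAT-O correlation grid
DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(256)
_U_MAX = 6.5  # upper limit on u = sqrt(chi2_1 variable); P(Z > 6.5) ~ 4e-11


@dataclass(frozen=True)
class WeightSpec:
    """Per-variant weights w_j = Beta-density(MAF_j; 1, 25)."""

    maf: np.ndarray
    weights: np.ndarray


@dataclass
class GeneSetResult:
    """Statistics and p-values for one variant set under one trait."""

    n_variants: int
    n: int
    weights: np.ndarray
    q_burden: float | None = None
    q_skat: float | None = None
    p_burden: float | None = None  # likelihood-ratio burden p
    p_burden_score: float | None = None  # score-form (SKAT-O rho=1) p
    p_skat: float | None = None
    p_skato: float | None = None
    rho_grid: tuple[float, ...] | None = None
    p_per_rho: np.ndarray | None = None
    lambdas: np.ndarray | None = field(default=None, repr=False)


def beta_weights(maf: np.ndarray | pd.Series) -> WeightSpec:
    """Beta(1,25)-density weights: w = 25 (1 - MAF)^24, decreasing in MAF."""
    maf = np.asarray(maf, dtype=float)
    if np.any((maf < 0) | (maf >= 1)):
        raise ValueError("MAF must lie in [0, 1)")
    if np.any(maf >= 0.5):
        logger.warning(
            "MAF >= 0.5 encountered — allele coding may be flipped; weights "
            "will be near zero"
        )
    return WeightSpec(maf=maf, weights=stats.beta.pdf(maf, 1.0, 25.0))


def _ingredients(
    trait: pd.Series,
    genotypes: pd.DataFrame,
    kinship: KinshipMatrix,
    covariates: pd.DataFrame | None,
):
    """Align samples, fit the genotype-free null, return score quantities."""
    t_all = trait.reindex(kinship.samples).to_numpy(float)
    G_all = genotypes.reindex(kinship.samples).to_numpy(float)
    ok = np.isfinite(t_all) & np.isfinite(G_all).all(axis=1)
    C_all = None
    if covariates is not None:
        C_all = np.asarray(covariates.reindex(kinship.samples), float).reshape(
            len(kinship.samples), -1
        )
        ok &= np.isfinite(C_all).all(axis=1)
    keep = np.flatnonzero(ok)
    samples = [kinship.samples[k] for k in keep]
    sub = kinship.subset(samples)
    y = t_all[keep]
    G = G_all[keep]
    X = np.ones((len(y), 1))
    if C_all is not None:
        X = np.column_stack([X, C_all[keep]])
    poly = np.var(G, axis=0) > 0
    if not poly.any():
        raise ValueError("all variants in the set are monomorphic")
    if not poly.all():
        logger.info("dropping %d monomorphic variants from the set", int(~poly.sum()))
    if len(keep) == len(kinship.samples):
        from .mixed_assoc import _get_model

        model = _get_model(kinship)
    else:
        model = PolygenicModel(sub)
    fit0 = model.fit(y, X)
    Py, project = model.null_projection(y, X, fit0)
    S = G.T @ Py
    M = G.T @ project(G)
    return model, fit0, y, X, G, S, M, poly


def burden_test(
    trait: pd.Series,
    genotypes: pd.DataFrame,
    weights: WeightSpec | np.ndarray,
    kinship: KinshipMatrix,
    covariates: pd.DataFrame | None = None,
) -> GeneSetResult:
    """Weighted burden score tested as one covariate in the kinship LMM."""
    w = weights.weights if isinstance(weights, WeightSpec) else np.asarray(weights)
    model, fit0, y, X, G, S, M, poly = _ingredients(
        trait, genotypes, kinship, covariates
    )
    b = G @ w
    if np.var(b) == 0:
        raise ValueError("burden score is constant")
    fit1 = model.fit(y, np.column_stack([X, b]))
    lrt = max(2.0 * (fit1.loglik - fit0.loglik), 0.0)
    p = float(stats.chi2.sf(lrt, 1)) if lrt > 0 else 1.0
    sw = w * S
    qb = float(sw.sum() ** 2)
    lam_b = float(w @ M @ w)
    return GeneSetResult(
        n_variants=G.shape[1],
        n=len(y),
        weights=w,
        q_burden=qb,
        p_burden=p,
        p_burden_score=mixture_sf(qb, [lam_b]),
    )


def skat_test(
    trait: pd.Series,
    genotypes: pd.DataFrame,
    weights: WeightSpec | np.ndarray,
    kinship: KinshipMatrix,
    covariates: pd.DataFrame | None = None,
) -> GeneSetResult:
    """Kernel score test; null law from eigenvalues of W G'PG W."""
    w = weights.weights if isinstance(weights, WeightSpec) else np.asarray(weights)
    model, fit0, y, X, G, S, M, poly = _ingredients(
        trait, genotypes, kinship, covariates
    )
    sw = w * S
    q = float((sw**2).sum())
    K = (w[:, None] * M) * w[None, :]
    lam = np.linalg.eigvalsh(K)
    lam = lam[lam > max(lam.max(), 0) * 1e-12]
    return GeneSetResult(
        n_variants=G.shape[1],
        n=len(y),
        weights=w,
        q_skat=q,
        p_skat=mixture_sf(q, lam),
        lambdas=lam,
    )


def _rho_sqrt(rho: float, k: int) -> np.ndarray:
    """Symmetric square root of R_rho = (1-rho) I + rho 11'."""
    a = np.sqrt(1.0 - rho)
    b = (np.sqrt(1.0 - rho + k * rho) - a) / k
    return a * np.eye(k) + b * np.ones((k, k))


def _per_rho(q_skat: float, q_burden: float, K: np.ndarray, rho: float):
    """Q_rho and its mixture eigenvalues."""
    k = K.shape[0]
    q = (1.0 - rho) * q_skat + rho * q_burden
    if rho >= 1.0:
        lam = np.array([float(np.ones(k) @ K @ np.ones(k))])
    else:
        Rh = _rho_sqrt(rho, k)
        lam = np.linalg.eigvalsh(Rh @ K @ Rh)
        lam = lam[lam > max(lam.max(), 0) * 1e-12]
    return q, lam


def skato_test(
    trait: pd.Series,
    genotypes: pd.DataFrame,
    weights: WeightSpec | np.ndarray,
    kinship: KinshipMatrix,
    covariates: pd.DataFrame | None = None,
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID,
) -> GeneSetResult:
    """Optimal unified test over Q_rho = (1-rho) Q_SKAT + rho Q_burden.

    Per-rho p-values are computed from the corresponding mixture law
    (exactly matching :func:`skat_test` at rho = 0 and the score-form
    burden at rho = 1); the omnibus p-value integrates the minimum-p
    statistic over the shared one-degree-of-freedom component.
    """
    if len(rho_grid) == 0:
        raise ValueError("empty rho grid")
    w = weights.weights if isinstance(weights, WeightSpec) else np.asarray(weights)
    model, fit0, y, X, G, S, M, poly = _ingredients(
        trait, genotypes, kinship, covariates
    )
    k = G.shape[1]
    sw = w * S
    q_skat = float((sw**2).sum())
    q_burden = float(sw.sum() ** 2)
    K = (w[:, None] * M) * w[None, :]

    p_rho = np.empty(len(rho_grid))
    lam_rho = []
    for i, rho in enumerate(rho_grid):
        q, lam = _per_rho(q_skat, q_burden, K, rho)
        p_rho[i] = mixture_sf(q, lam)
        lam_rho.append(lam)

    t_min = float(p_rho.min())
    if len(rho_grid) == 1:
        p_skato = t_min
    else:
        p_skato = _min_p_integration(q_skat, q_burden, K, rho_grid, t_min)

    return GeneSetResult(
        n_variants=k,
        n=len(y),
        weights=w,
        q_burden=q_burden,
        q_skat=q_skat,
        p_skat=float(p_rho[list(rho_grid).index(0.0)]) if 0.0 in rho_grid else None,
        p_burden_score=float(p_rho[list(rho_grid).index(1.0)]) if 1.0 in rho_grid else None,
        p_skato=float(min(max(p_skato, 1e-300), 1.0)),
        rho_grid=tuple(rho_grid),
        p_per_rho=p_rho,
    )


def _min_p_integration(
    q_skat: float,
    q_burden: float,
    K: np.ndarray,
    rho_grid,
    t_min: float,
) -> float:
    """Lee-style one-dimensional integration of the min-p statistic.

    Decomposes each Q_rho into tau(rho) * eta (a shared 1-df chi-square
    along the common burden direction) plus a remainder mixture; the
    omnibus p is one minus the probability that every Q_rho stays below
    its own min-p quantile, integrated over eta.
    """
    k = K.shape[0]
    one = np.ones(k)
    rho_c = np.minimum(np.asarray(rho_grid, float), 0.999)

    # quantiles of Q_rho at level t_min, under the capped grid
    q_quant = np.empty(len(rho_c))
    for i, rho in enumerate(rho_c):
        _, lam = _per_rho(q_skat, q_burden, K, rho)
        q_quant[i] = mixture_isf(t_min, lam)

    m1 = K @ one
    s_tot = float(one @ m1)
    if s_tot <= 0:
        return t_min * len(rho_c)
    zbar2 = s_tot / k**2
    cof = k * m1 / s_tot
    K_rem = K - zbar2 * np.outer(cof, cof)
    lam = np.linalg.eigvalsh(K_rem)
    lam = lam[lam > max(lam.max(), 0.0) * 1e-12]
    if lam.size == 0:
        return t_min * len(rho_c)
    mu_q = lam.sum()
    var_rem = 4.0 * zbar2 * float(cof @ K_rem @ cof)
    var_q = 2.0 * (lam**2).sum() + var_rem
    ker_q = 12.0 * (lam**4).sum() / (lam**2).sum() ** 2
    df = 12.0 / ker_q if ker_q > 0 else 1e6
    tau = (k**2 * rho_c + (1.0 - rho_c) * (cof**2).sum()) * zbar2

    # integrate over the shared chi2_1 variable with x = u^2 (the
    # substitution removes the x^-1/2 density singularity, so fixed
    # Gauss-Legendre nodes converge fast): chi2_1(x) dx = 2 phi(u) du
    u = 0.5 * (_GL_NODES + 1.0) * _U_MAX
    wq = _GL_WEIGHTS * 0.5 * _U_MAX
    x = u**2
    bound = np.min(
        (q_quant[:, None] - tau[:, None] * x[None, :]) / (1.0 - rho_c)[:, None],
        axis=0,
    )
    tq = (bound - mu_q) / np.sqrt(var_q) * np.sqrt(2.0 * df) + df
    F = np.where(tq > 0, stats.chi2.cdf(np.maximum(tq, 0.0), df), 0.0)
    val = float(np.sum(wq * F * 2.0 * stats.norm.pdf(u)))
    p = 1.0 - val
    # the omnibus p can never beat Bonferroni over the grid
    p = min(p, t_min * len(rho_c))
    return p


def meta_combine(
    pvalues,
    method: str = "fisher",
    sample_sizes=None,
) -> float:
    """Combine per-study p-values.

    Fisher (default): -2 sum ln p ~ chi2 with 2k df. Stouffer: z-scores
    weighted by sqrt(n) when sample sizes are given. Zero p-values are
    clipped to the smallest positive float with a warning.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no studies to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("zero p-value clipped to machine minimum")
        p = np.maximum(p, np.finfo(float).tiny)
    if method == "fisher":
        x = -2.0 * np.log(p).sum()
        return float(stats.chi2.sf(x, 2 * p.size))
    if method == "stouffer":
        w = (
            np.sqrt(np.asarray(sample_sizes, float))
            if sample_sizes is not None
            else np.ones(p.size)
        )
        z = stats.norm.isf(np.minimum(p, 1 - 1e-16))
        return float(stats.norm.sf((w * z).sum() / np.sqrt((w**2).sum())))
    raise ValueError(f"unknown method {method!r}")
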