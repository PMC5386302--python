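"""Variance-component linkage scanning with per-family LOD decomposition.

At each grid position the trait covariance within a family is modelled as

    V = Pi * sigma2_QTL + 2*Phi * sigma2_G + I * sigma2_E,

where Pi holds the posterior expected IBD sharing at the position, Phi is
the pedigree kinship and sigma2_E the residual. Linkage is a likelihood
ratio test of H0: sigma2_QTL = 0 against the one-sided alternative; the
LOD score is the log10 likelihood ratio, clipped at zero (boundary test,
asymptotically a 50:50 mixture of chi2_0 and chi2_1). Families are
independent, so the log-likelihood — and hence the LOD — decomposes into
per-family contributions evaluated at the overall maximum-likelihood
estimates.

Fixed-effect covariates (e.g. a genotype risk score for conditional
linkage) are absorbed by generalized least squares inside both the null
and alternative fits. :class:`LinkageScanner` aligns the data and caches
the per-position IBD matrices once, so that many conditional scans
against the same trait (the resampled-SNP LOD-drop null) pay only for
the likelihood optimizations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .ibd import IBDResult
from .pedigree_io import KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "VCFit",
    "LinkageCurve",
    "LinkageScanner",
    "vc_linkage_scan",
    "conditional_scan",
    "region_2lod",
    "fit_polygenic_null",
]

LN10 = np.log(10.0)
_MIN_RESID = 1e-6  # lower bound for residual variance (standardized scale)


@dataclass
class VCFit:
    """One maximized variance-component model."""

    variances: np.ndarray  # per component, on the trait scale
    component_names: tuple[str, ...]
    beta: np.ndarray
    loglik: float
    family_logliks: dict[str, float]
    converged: bool
    params_std: np.ndarray  # standardized-scale variances (warm starts)

    @property
    def sigma2(self) -> dict[str, float]:
        return dict(zip(self.component_names, map(float, self.variances)))


@dataclass
class LinkageCurve:
    """LOD scores along a chromosome with per-family decomposition."""

    chrom: str
    positions: np.ndarray
    lod: np.ndarray
    per_family: pd.DataFrame  # index positions, one column per family
    fits: list[VCFit] = field(default_factory=list, repr=False)
    null_fit: VCFit | None = field(default=None, repr=False)

    @property
    def mlod(self) -> float:
        return float(np.nanmax(self.lod))

    @property
    def mlod_position(self) -> float:
        return float(self.positions[int(np.nanargmax(self.lod))])

    def to_frame(self, per_family: bool = False) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "cm": self.positions, "lod": self.lod})
        if per_family:
            df = pd.concat([df, self.per_family.reset_index(drop=True)], axis=1)
        return df

    def to_tsv(self, path, per_family: bool = False) -> None:
        self.to_frame(per_family).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


class _Blocks:
    """Per-family data grouped by family size for batched linear algebra."""

    def __init__(self, fam_ids, ys, Xs):
        self.fam_ids = list(fam_ids)
        self.p = Xs[0].shape[1]
        sizes: dict[int, list[int]] = {}
        for k, y in enumerate(ys):
            sizes.setdefault(len(y), []).append(k)
        self.groups = []
        for s, idx in sizes.items():
            self.groups.append(
                {
                    "fam_pos": idx,
                    "Y": np.stack([ys[k] for k in idx]),
                    "X": np.stack([Xs[k] for k in idx]),
                    "C": None,  # (ncomp, F, s, s)
                    "Cflat": None,  # (F, s, ncomp*s) for one-shot solves
                }
            )
        self.n_total = sum(len(y) for y in ys)

    def set_components(self, comps_per_family) -> None:
        """comps_per_family[k] = list of (s,s) covariance design matrices."""
        for g in self.groups:
            C = np.stack(
                [
                    np.stack([comps_per_family[k][c] for k in g["fam_pos"]])
                    for c in range(len(comps_per_family[0]))
                ]
            )
            g["C"] = C
            ncomp, F, s, _ = C.shape
            g["Cflat"] = C.transpose(1, 2, 0, 3).reshape(F, s, ncomp * s)

    def nll_grad(self, s2: np.ndarray) -> tuple[float, np.ndarray, dict]:
        """Negative profile log-likelihood (beta profiled by GLS) + gradient.

        The gradient with respect to the variance parameters is exact for
        the profiled likelihood (envelope theorem: d ll/d beta = 0 at the
        GLS solution). One batched solve per size group covers the GLS
        right-hand sides and all component matrices.
        """
        ncomp = len(s2)
        p = self.p
        A = np.zeros((p, p))
        bvec = np.zeros(p)
        cache = []
        for g in self.groups:
            V = np.tensordot(s2, g["C"], axes=1)  # (F, s, s)
            L = np.linalg.cholesky(V)
            F, s, _ = V.shape
            rhs = np.concatenate([g["Y"][..., None], g["X"], g["Cflat"]], axis=2)
            sol = np.linalg.solve(V, rhs)
            Viy = sol[..., 0]
            ViX = sol[..., 1 : 1 + p]
            ViC = sol[..., 1 + p :].reshape(F, s, ncomp, s)
            A += np.einsum("fsp,fsq->pq", g["X"], ViX)
            bvec += np.einsum("fsp,fs->p", g["X"], Viy)
            logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
            cache.append((Viy, ViX, ViC, logdet))
        beta = np.linalg.solve(A, bvec)

        ll = 0.0
        grad = np.zeros(ncomp)
        fam_ll = np.empty(len(self.fam_ids))
        for g, (Viy, ViX, ViC, logdet) in zip(self.groups, cache):
            r = g["Y"] - np.einsum("fsp,p->fs", g["X"], beta)
            Vir = Viy - np.einsum("fsp,p->fs", ViX, beta)
            quad = np.einsum("fs,fs->f", r, Vir)
            s = g["Y"].shape[1]
            llf = -0.5 * (logdet + quad + s * np.log(2 * np.pi))
            fam_ll[g["fam_pos"]] = llf
            ll += llf.sum()
            t1 = np.einsum("fs,kfst,ft->k", Vir, g["C"], Vir)
            tr = np.einsum("fsks->k", ViC)
            grad += 0.5 * (t1 - tr)
        return -ll, -grad, {"beta": beta, "fam_ll": fam_ll}


def _fit(
    blocks: _Blocks,
    comps_per_family,
    component_names: tuple[str, ...],
    starts,
    y_scale: float,
    free_lower,
    ftol: float = 1e-12,
) -> VCFit:
    """Maximize the MVN likelihood over variance components (bounded L-BFGS)."""
    blocks.set_components(comps_per_family)
    bounds = [(lo, None) for lo in free_lower]
    best = None
    for x0 in starts:
        x0 = np.maximum(np.asarray(x0, float), [b[0] for b in bounds])
        res = minimize(
            lambda x: blocks.nll_grad(x)[:2],
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": ftol, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    _, _, aux = blocks.nll_grad(best.x)
    # undo trait standardization: variances scale with y_scale^2, the
    # log-likelihood shifts by -n*log(y_scale)
    shift = np.log(y_scale)
    fam_sizes = {}
    for g in blocks.groups:
        for k in g["fam_pos"]:
            fam_sizes[blocks.fam_ids[k]] = g["Y"].shape[1]
    return VCFit(
        variances=best.x * y_scale**2,
        component_names=component_names,
        beta=aux["beta"] * y_scale,
        loglik=float(-best.fun) - blocks.n_total * shift,
        family_logliks={
            fid: float(v) - fam_sizes[fid] * shift
            for fid, v in zip(blocks.fam_ids, aux["fam_ll"])
        },
        converged=bool(best.success),
        params_std=best.x.copy(),
    )


class LinkageScanner:
    """Aligned trait/kinship/IBD data ready for repeated scans.

    Construction aligns phenotyped individuals with the IBD result and the
    kinship matrix, standardizes the trait, and extracts the per-position
    IBD matrices once. Each :meth:`scan` call then only optimizes the
    likelihoods — cheap enough to repeat hundreds of times with different
    conditioning covariates, as the resampled LOD-drop null requires.
    """

    def __init__(
        self,
        trait: pd.Series,
        kinship: KinshipMatrix,
        ibd: IBDResult,
        covariates: pd.DataFrame | None = None,
    ):
        self.ibd = ibd
        fam_ids, ys, Xs, phi2s, keys = [], [], [], [], []
        fam_rows = []
        for fid, fam in ibd.families.items():
            rows, ids = [], []
            for k, iid in enumerate(fam.ids):
                key = (fid, iid)
                if key not in trait.index or not np.isfinite(trait[key]):
                    continue
                if covariates is not None and key not in covariates.index:
                    continue
                rows.append(k)
                ids.append(iid)
            if not rows:
                continue
            y = np.array([trait[(fid, iid)] for iid in ids], float)
            if covariates is not None:
                C = covariates.loc[[(fid, iid) for iid in ids]].to_numpy(float)
                X = np.column_stack([np.ones(len(ids)), C])
            else:
                X = np.ones((len(ids), 1))
            kin_rows = [kinship.index(fid, iid) for iid in ids]
            fam_ids.append(fid)
            ys.append(y)
            Xs.append(X)
            phi2s.append(kinship.two_phi[np.ix_(kin_rows, kin_rows)])
            keys.append([(fid, iid) for iid in ids])
            fam_rows.append((fam, rows))
        if not fam_ids:
            raise ValueError("no phenotyped individuals overlap the IBD result")
        X_all = np.vstack(Xs)
        if np.linalg.matrix_rank(X_all) < X_all.shape[1]:
            raise ValueError(
                "covariate design is rank deficient (collinear covariate?)"
            )
        self.fam_ids = fam_ids
        self.keys = keys
        self._ys = ys
        self._Xs = Xs
        self._phi2s = phi2s
        self.y_scale = float(np.std(np.concatenate(ys))) or 1.0
        self._ys_std = [y / self.y_scale for y in ys]
        # per-position QTL component matrices, extracted once
        self.positions = ibd.positions
        self._eyes = [np.eye(len(y)) for y in ys]
        self._pi_by_pos = [
            [
                fam.pi_matrix(t)[np.ix_(rows, rows)]
                for fam, rows in fam_rows
            ]
            for t in range(len(self.positions))
        ]
        self._null_comps = [
            [self._phi2s[k], self._eyes[k]] for k in range(len(ys))
        ]
        self._base_null: VCFit | None = None

    # ----------------------------------------------------------- internals
    def _blocks(self, covariate: pd.Series | None) -> _Blocks:
        if covariate is None:
            return _Blocks(self.fam_ids, self._ys_std, self._Xs)
        Xs = []
        for k, fam_keys in enumerate(self.keys):
            c = np.asarray(covariate.reindex(fam_keys), float)
            if not np.all(np.isfinite(c)):
                raise ValueError("conditioning covariate has missing values")
            Xs.append(np.column_stack([self._Xs[k], c]))
        X_all = np.vstack(Xs)
        if np.linalg.matrix_rank(X_all) < X_all.shape[1]:
            raise ValueError(
                "conditioning covariate is collinear with the existing design"
            )
        return _Blocks(self.fam_ids, self._ys_std, Xs)

    def fit_null(self, covariate: pd.Series | None = None, ftol: float = 1e-12) -> VCFit:
        blocks = self._blocks(covariate)
        starts = [np.array(s) for s in ((0.5, 0.5), (0.2, 0.8), (0.9, 0.1))]
        if self._base_null is not None:
            starts.insert(0, self._base_null.params_std)
            if covariate is not None:
                # warm-started covariate-null refits: one start suffices in
                # fast mode, two otherwise
                starts = starts[:1] if ftol > 1e-12 else starts[:2]
        null = _fit(
            blocks,
            self._null_comps,
            ("polygenic", "residual"),
            starts,
            self.y_scale,
            free_lower=(0.0, _MIN_RESID),
            ftol=ftol,
        )
        if covariate is None and self._base_null is None:
            self._base_null = null
        return null

    # ---------------------------------------------------------------- scan
    def scan(
        self,
        positions: np.ndarray | None = None,
        covariate: pd.Series | None = None,
        warm_fits: Sequence[VCFit] | None = None,
        n_starts: int = 3,
        ftol: float = 1e-12,
    ) -> LinkageCurve:
        """LOD curve over ``positions`` (default: the whole IBD grid).

        ``covariate`` adds one fixed-effect column to both null and
        alternative models (conditional scan); ``warm_fits`` supplies one
        fit per requested position as an optimization start, e.g. the
        unconditional fits when computing null drops.
        """
        if covariate is not None and np.allclose(
            covariate.to_numpy(float), 0.0
        ):
            logger.warning("conditioning covariate is identically zero; ignored")
            covariate = None
        null = self.fit_null(covariate, ftol=ftol)
        sg, se = null.params_std

        if positions is None:
            positions = self.positions
        positions = np.asarray(positions, float)
        pos_index = {round(float(c), 9): t for t, c in enumerate(self.positions)}
        blocks = self._blocks(covariate)

        lod = np.full(len(positions), np.nan)
        per_fam = np.full((len(positions), len(self.fam_ids)), np.nan)
        fits: list[VCFit] = []
        prev: np.ndarray | None = None
        for t, pos in enumerate(positions):
            ti = pos_index.get(round(float(pos), 9))
            if ti is None:
                raise ValueError(f"position {pos} not on the IBD grid")
            comps = [
                [self._pi_by_pos[ti][k], self._phi2s[k], self._eyes[k]]
                for k in range(len(self.fam_ids))
            ]
            starts = [
                np.array([0.0, sg, se]),
                np.array([0.3, max(sg - 0.15, 0.0), se]),
            ]
            if warm_fits is not None:
                starts.insert(0, warm_fits[t].params_std)
            elif prev is not None:
                starts.insert(0, prev)
            alt = _fit(
                blocks,
                comps,
                ("qtl", "polygenic", "residual"),
                starts[:n_starts],
                self.y_scale,
                free_lower=(0.0, 0.0, _MIN_RESID),
                ftol=ftol,
            )
            if alt.loglik < null.loglik - 1e-9 and n_starts == 1:
                # the single warm start landed below the nested null: retry
                # from the null embedding so the boundary is always reachable
                retry = _fit(
                    blocks,
                    comps,
                    ("qtl", "polygenic", "residual"),
                    [np.array([0.0, sg, se])],
                    self.y_scale,
                    free_lower=(0.0, 0.0, _MIN_RESID),
                    ftol=ftol,
                )
                if retry.loglik > alt.loglik:
                    alt = retry
            prev = alt.params_std
            diff = alt.loglik - null.loglik
            if diff <= 0:
                # boundary: sigma2_QTL = 0 reproduces the null exactly
                lod[t] = 0.0
                per_fam[t] = 0.0
            else:
                lod[t] = diff / LN10
                per_fam[t] = np.array(
                    [
                        (alt.family_logliks[f] - null.family_logliks[f]) / LN10
                        for f in self.fam_ids
                    ]
                )
            fits.append(alt)

        return LinkageCurve(
            chrom=self.ibd.chrom,
            positions=positions,
            lod=lod,
            per_family=pd.DataFrame(per_fam, index=positions, columns=self.fam_ids),
            fits=fits,
            null_fit=null,
        )


def fit_polygenic_null(
    trait: pd.Series,
    kinship: KinshipMatrix,
    ibd: IBDResult,
    covariates: pd.DataFrame | None = None,
) -> VCFit:
    """Fit the no-QTL model (polygenic + residual) shared by a whole scan."""
    return LinkageScanner(trait, kinship, ibd, covariates).fit_null()


def vc_linkage_scan(
    trait: pd.Series,
    kinship: KinshipMatrix,
    ibd: IBDResult,
    covariates: pd.DataFrame | None = None,
    positions: np.ndarray | None = None,
    n_starts: int = 3,
    warm_fits: Sequence[VCFit] | None = None,
) -> LinkageCurve:
    """Scan the IBD grid, maximizing the three-component model per position.

    ``trait`` is a Series indexed by (family_id, individual_id) tuples
    (typically covariate residuals); optional ``covariates`` is a
    DataFrame on the same index whose columns enter the fixed effects of
    both null and alternative models. Returns the LOD curve with
    per-family contributions that sum to the total at every position.
    """
    scanner = LinkageScanner(trait, kinship, ibd, covariates)
    return scanner.scan(positions=positions, warm_fits=warm_fits, n_starts=n_starts)


def conditional_scan(
    trait: pd.Series,
    kinship: KinshipMatrix,
    ibd: IBDResult,
    covariate: pd.Series,
    covariates: pd.DataFrame | None = None,
    positions: np.ndarray | None = None,
    n_starts: int = 3,
    warm_fits: Sequence[VCFit] | None = None,
) -> LinkageCurve:
    """Re-scan with an extra fixed-effect covariate (e.g. a risk score).

    The covariate enters both null and alternative models, so the LOD
    drop relative to the unconditional scan measures how much linkage
    evidence the covariate absorbs. Raises if the covariate is collinear
    with the existing design; an identically zero covariate is ignored.
    """
    scanner = LinkageScanner(trait, kinship, ibd, covariates)
    return scanner.scan(
        positions=positions,
        covariate=covariate,
        warm_fits=warm_fits,
        n_starts=n_starts,
    )


def _cross(positions, lod, peak, thresh, step) -> float:
    """Linear-interpolated cM where the curve first drops below thresh."""
    t = peak
    while 0 <= t + step < len(positions) and lod[t + step] >= thresh:
        t += step
    if not (0 <= t + step < len(positions)):
        return float(positions[t])  # chromosome end reached
    x0, x1 = positions[t], positions[t + step]
    y0, y1 = lod[t], lod[t + step]
    frac = (y0 - thresh) / (y0 - y1)
    return float(x0 + frac * (x1 - x0))


def region_2lod(
    curve: LinkageCurve, target_width_cm: float = 20.0
) -> tuple[str, float, float]:
    """Support interval: 2-LOD drop around the peak, widened to a minimum.

    Extends from the (leftmost) maximum until the LOD falls 2 below the
    MLOD or the chromosome ends; intervals narrower than
    ``target_width_cm`` are widened symmetrically about the peak (clipped
    to the scanned span, compensating on the other side when clipped).
    """
    lod = curve.lod
    if np.nanmax(lod) <= 0:
        raise ValueError("no peak: flat LOD curve (MLOD = 0)")
    peak = int(np.nanargmax(lod))
    thresh = lod[peak] - 2.0
    lo = _cross(curve.positions, lod, peak, thresh, -1)
    hi = _cross(curve.positions, lod, peak, thresh, +1)
    if hi - lo < target_width_cm:
        center = float(curve.positions[peak])
        half = target_width_cm / 2.0
        lo, hi = center - half, center + half
        span_lo, span_hi = float(curve.positions[0]), float(curve.positions[-1])
        if lo < span_lo:
            hi = min(span_hi, hi + (span_lo - lo))
            lo = span_lo
        if hi > span_hi:
            lo = max(span_lo, lo - (hi - span_hi))
            hi = span_hi
    return curve.chrom, lo, hi
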