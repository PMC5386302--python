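"""Candidate-variant discovery under a linkage peak.

The procedure localizes the variants that generate a variance-component
linkage signal:

1. Take the exonic variants inside the 2-LOD support interval of the
   peak and fit each with the kinship mixed model.
2. Keep variants with association evidence (p <= 0.1 or |beta| >= 5
   mmHg) that are carried at least twice in at least one family whose
   family-specific LOD at the peak is >= 0.1 — i.e. variants that could
   plausibly drive some family's linkage contribution.
3. Collapse the selected variants into a per-individual genotype risk
   score r_i = x_i' beta (marginal single-variant betas).
4. Re-run the linkage scan conditioning on the risk score; the MLOD drop
   measures how much linkage evidence the candidates explain.
5. Calibrate the drop against an empirical null: condition instead on
   each of N randomly sampled off-chromosome SNPs (which cannot carry
   the region's linkage information) and rank the observed drop among
   the null drops (add-one empirical p-value).

Two small analytic utilities used when judging replication consistency
are included: the binomial tail for direction consistency across tests,
and the normal probability that a true effect of given standardized size
shows the opposite sign in a replication study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_assoc import MixedModelFit
from .pedigree_io import KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateFilter",
    "RiskScore",
    "LodDropNull",
    "filter_candidates",
    "build_risk_score",
    "lod_drop_null",
    "direction_binomial",
    "opposite_direction_prob",
]


@dataclass(frozen=True)
class CandidateFilter:
    """Selection thresholds for variants under the peak.

    A variant passes iff (p <= p_threshold OR |beta| >= beta_threshold)
    AND it has >= min_family_carriers carriers in at least one family
    whose family-specific LOD at the peak is >= min_family_lod.
    """

    p_threshold: float = 0.1
    beta_threshold: float = 5.0
    min_family_carriers: int = 2
    min_family_lod: float = 0.1


@dataclass
class RiskScore:
    """Per-individual genotype score r_i = x_i' beta over selected variants."""

    scores: pd.Series  # indexed by (family_id, individual_id)
    variants: list[str]
    betas: np.ndarray
    n_missing_contributions: int = 0


@dataclass
class LodDropNull:
    """Observed conditional MLOD drop against a resampled-SNP null."""

    observed_drop: float
    null_drops: np.ndarray
    sampled_markers: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.null_drops)

    @property
    def empirical_p(self) -> float:
        """Add-one estimator: (1 + #{null >= observed}) / (1 + N)."""
        return float(
            (1 + np.sum(self.null_drops >= self.observed_drop)) / (1 + self.n)
        )

    def summary(self) -> dict:
        return {
            "observed_drop": self.observed_drop,
            "n_null": self.n,
            "null_max": float(self.null_drops.max()) if self.n else np.nan,
            "null_q95": float(np.quantile(self.null_drops, 0.95)) if self.n else np.nan,
            "empirical_p": self.empirical_p,
        }


def filter_candidates(
    fits: Mapping[str, MixedModelFit],
    family_lods_at_peak: Mapping[str, float],
    config: CandidateFilter = CandidateFilter(),
    positions: Mapping[str, float] | None = None,
) -> list[str]:
    """Apply the candidate filter to per-variant association fits.

    ``fits`` maps variant id to its mixed-model fit (which carries the
    per-family carrier counts); ``family_lods_at_peak`` gives each
    family's LOD contribution at the peak position. Returns the selected
    variant ids ordered by ``positions`` when given (else by input
    order). An empty input yields an empty list with a warning.
    """
    if not fits:
        logger.warning("candidate filter applied to an empty region")
        return []
    chosen = []
    for vid, fit in fits.items():
        effect_ok = fit.p <= config.p_threshold or abs(fit.beta1) >= config.beta_threshold
        if not effect_ok:
            continue
        seg_ok = any(
            cnt >= config.min_family_carriers
            and family_lods_at_peak.get(fid, 0.0) >= config.min_family_lod
            for fid, cnt in fit.family_carriers.items()
        )
        if seg_ok:
            chosen.append(vid)
    if positions is not None:
        chosen.sort(key=lambda v: positions[v])
    return chosen


def build_risk_score(
    variants: Sequence[str],
    fits: Mapping[str, MixedModelFit],
    dosages: pd.DataFrame,
) -> RiskScore:
    """Inner product of dosages with marginal betas, r_i = x_i' beta.

    Missing genotypes contribute zero to the score (count logged);
    a variant absent from ``dosages`` raises ``KeyError``.
    """
    for v in variants:
        if v not in dosages.columns:
            raise KeyError(f"variant {v!r} missing from genotype data")
    betas = np.array([fits[v].beta1 for v in variants], float)
    X = dosages[list(variants)].to_numpy(float)
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        logger.info("risk score: %d missing dosages contribute 0", n_missing)
    X = np.nan_to_num(X, nan=0.0)
    r = X @ betas
    return RiskScore(
        scores=pd.Series(r, index=dosages.index, name="risk_score"),
        variants=list(variants),
        betas=betas,
        n_missing_contributions=n_missing,
    )


def lod_drop_null(
    trait: pd.Series,
    kinship: KinshipMatrix,
    ibd,
    unconditional_mlod: float,
    observed_drop: float,
    snp_pool: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    region_positions: np.ndarray | None = None,
    n_samples: int = 1000,
    seed: int | None = None,
    n_starts: int = 2,
    warm_fits=None,
) -> LodDropNull:
    """Empirical null for the conditional MLOD drop.

    ``snp_pool`` holds dosage columns for SNPs from chromosomes other
    than the linkage chromosome (they carry no information about the
    region, so conditioning on them measures the drop expected by
    chance). Each sampled SNP is used as a covariate in a conditional
    scan restricted to ``region_positions``; the drop is the
    unconditional MLOD minus the conditional MLOD in the region. If the
    pool is smaller than ``n_samples`` every SNP is used once, with a
    warning.
    """
    from .linkage import LinkageScanner

    rng = np.random.default_rng(seed)
    cols = list(snp_pool.columns)
    if len(cols) < n_samples:
        logger.warning(
            "SNP pool (%d) smaller than requested %d samples; using all",
            len(cols),
            n_samples,
        )
        picked = cols
    else:
        picked = [cols[i] for i in rng.choice(len(cols), size=n_samples, replace=False)]
    # one scanner: the alignment and per-position IBD matrices are shared
    # by every null scan, only the conditioning column changes
    scanner = LinkageScanner(trait, kinship, ibd, covariates)
    scanner.fit_null()
    drops = np.empty(len(picked))
    for k, vid in enumerate(picked):
        cond = scanner.scan(
            positions=region_positions,
            covariate=snp_pool[vid].astype(float),
            warm_fits=warm_fits,
            n_starts=n_starts,
            ftol=1e-10,
        )
        drops[k] = unconditional_mlod - cond.mlod
    return LodDropNull(
        observed_drop=float(observed_drop),
        null_drops=drops,
        sampled_markers=picked,
    )


def direction_binomial(n_tests: int, n_protective: int, tail: str = "strict") -> float:
    """Tail probability of the direction-consistency sign test.

    Under no consistent direction each of ``n_tests`` independent effect
    estimates is protective with probability 1/2. ``tail='strict'``
    returns P(X > k) (the default); ``tail='inclusive'`` returns
    P(X >= k).
    """
    if not (0 <= n_protective <= n_tests):
        raise ValueError("need 0 <= n_protective <= n_tests")
    if tail == "strict":
        return float(stats.binom.sf(n_protective, n_tests, 0.5))
    if tail == "inclusive":
        return float(stats.binom.sf(n_protective - 1, n_tests, 0.5))
    raise ValueError(f"unknown tail {tail!r}")


def opposite_direction_prob(beta_std: float, se_std: float = 1.0) -> float:
    """P(replication estimate has the opposite sign of a true effect).

    For a true standardized effect ``beta_std`` whose replication
    estimate is normal with standard error ``se_std`` (both in trait SD
    units), the opposite-sign probability is Phi(-|beta|/se). A quarter-SD
    effect against a unit-SD error gives ~0.401 — sign flips in modest
    replication samples are expected, not evidence of inconsistency.
    """
    if se_std <= 0:
        raise ValueError("standard error must be positive")
    return float(stats.norm.cdf(-abs(beta_std) / se_std))
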