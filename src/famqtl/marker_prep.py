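"""Marker panel preparation for linkage: MAF filtering and LD pruning.

Multipoint IBD assumes linkage equilibrium between markers, so the dense
array panel is thinned before the HMM: low-MAF markers are dropped first
(uninformative for IBD), then a sliding-window greedy prune removes one
marker of any pair whose genotypic r^2 exceeds the threshold. r^2 is the
squared Pearson correlation of dosages, computed on founders by default so
that family-induced correlation does not masquerade as population LD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree_io import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["PruneConfig", "prune_ld"]


@dataclass(frozen=True)
class PruneConfig:
    """Sliding-window LD pruning parameters.

    Defaults: 50 kb window, 5-variant step, r^2 threshold 0.2, MAF >= 0.2.
    A stricter profile (r2_threshold=0.1) is available for sensitivity
    analysis of the linkage curve.
    """

    window_kb: float = 50.0
    step_variants: int = 5
    r2_threshold: float = 0.2
    maf_min: float = 0.2
    founders_only: bool = True

    def __post_init__(self):
        if not (0 < self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in (0, 1]")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if self.window_kb <= 0 or self.step_variants < 1:
            raise ValueError("window must be positive and step >= 1")


def _pairwise_r2(dose: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns (NaN-aware)."""
    d = np.ma.masked_invalid(dose)
    r = np.ma.corrcoef(d, rowvar=False)
    return np.asarray(r.filled(0.0)) ** 2


def prune_ld(
    gm: GenotypeMatrix,
    config: PruneConfig = PruneConfig(),
    founder_rows: np.ndarray | None = None,
) -> list[str]:
    """Return the marker ids retained after MAF filtering and LD pruning.

    Within each 50 kb window (advanced ``step_variants`` at a time, per
    chromosome), every pair with r^2 above the threshold loses its
    lower-MAF member (position order breaks ties). Monomorphic markers are
    removed with a log entry. The output is sorted by position and, by
    construction, no retained pair within a window exceeds the threshold.
    """
    if config.founders_only and founder_rows is None:
        logger.warning("founders_only pruning requested without founder rows; using all")
    rows = founder_rows if (config.founders_only and founder_rows is not None) else None
    calls = gm.calls if rows is None else gm.calls[np.asarray(rows, int)]
    dose = calls.sum(axis=2).astype(float)
    dose[(calls < 0).any(axis=2)] = np.nan

    with np.errstate(invalid="ignore"):
        f2 = np.nanmean(dose, axis=0) / 2.0
    maf = np.minimum(f2, 1.0 - f2)
    mono = np.nan_to_num(np.nanvar(dose, axis=0)) <= 0
    if mono.any():
        logger.info("removing %d monomorphic markers", int(mono.sum()))
    low = maf < config.maf_min
    alive = ~(mono | low)

    markers = gm.markers
    order = np.lexsort((markers["bp"].to_numpy(), markers["chrom"].to_numpy(str)))
    window_bp = config.window_kb * 1000.0

    for chrom in pd.unique(markers["chrom"].astype(str)):
        cidx = order[(markers["chrom"].astype(str).to_numpy()[order] == chrom)]
        start = 0
        while start < len(cidx):
            w = [j for j in cidx[start:] if markers["bp"].iloc[j] - markers["bp"].iloc[cidx[start]] <= window_bp]
            live = [j for j in w if alive[j]]
            if len(live) > 1:
                r2 = _pairwise_r2(dose[:, live])
                changed = True
                while changed:
                    changed = False
                    k = len(live)
                    for a in range(k):
                        if not alive[live[a]]:
                            continue
                        for b in range(a + 1, k):
                            if not alive[live[b]]:
                                continue
                            if r2[a, b] > config.r2_threshold:
                                # drop the lower-MAF member; ties -> later position
                                if maf[live[a]] < maf[live[b]]:
                                    alive[live[a]] = False
                                else:
                                    alive[live[b]] = False
                                changed = True
            start += config.step_variants

    kept = [markers["marker_id"].iloc[j] for j in order if alive[j]]
    logger.info(
        "LD pruning kept %d of %d markers (r2<=%.3g, MAF>=%.3g)",
        len(kept),
        gm.n_markers,
        config.r2_threshold,
        config.maf_min,
    )
    return kept
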