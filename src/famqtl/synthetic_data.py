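"""Gene-dropping study simulator.

Generates pedigrees, linkage-marker genotypes, exome-style rare variants
and blood-pressure phenotypes with the covariance structure the analysis
stack assumes, emulating a family blood-pressure cohort: ~130 families
of mixed sizes including one 17-member three-generation family, a rare
protective variant (nominal MAF ~0.004) segregating only in that family
(carriers average ~8 mmHg lower SBP), additional rare protective coding
variants, a polygenic component with covariance 2*Phi*sigma2_G,
covariate effects (sex, age, age^2, BMI) and antihypertensive-medication
masking of the observed pressures.

Founder haplotypes are drawn from the nominal allele frequencies and
transmitted down each pedigree with Haldane recombination, so simulated
genotypes are Mendelian-consistent by construction. One master seed fans
out to independent streams for pedigree structure, gene dropping and
traits, and all writers are byte-deterministic, so any stage can be
regenerated independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .pedigree_io import (
    GenotypeMatrix,
    Individual,
    Pedigree,
    haldane_theta,
    write_ped_map,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerBlock",
    "CausalVariant",
    "SimConfig",
    "SimStudy",
    "default_config",
    "scaled_config",
    "simulate_pedigrees",
    "gene_drop",
    "simulate_traits",
    "simulate_study",
    "write_study",
]


@dataclass(frozen=True)
class MarkerBlock:
    """An evenly spaced panel of common markers on one chromosome."""

    chrom: str
    n_markers: int
    spacing_cm: float
    start_cm: float = 0.0
    maf_range: tuple[float, float] = (0.2, 0.5)
    prefix: str = "m"


@dataclass(frozen=True)
class CausalVariant:
    """A trait-affecting variant added to the marker panel.

    ``restrict_family`` confines the minor allele to one family: a single
    founder copy is planted (in ``carrier_founder``, default the first
    founder) and the family's gene drop is rejection-sampled until at
    least ``min_carriers`` members carry it (capped attempts, logged).
    """

    marker_id: str
    chrom: str
    cm: float
    maf: float
    beta_sbp: float  # effect on SBP conditional on BMI (the analysis scale)
    beta_dbp: float = 0.0
    beta_bmi: float = 0.0  # kg/m^2 per allele; lets carriers be obese yet normotensive
    restrict_family: str | None = None
    carrier_founder: str | None = None
    min_carriers: int = 0


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation settings (see :func:`default_config`)."""

    n_families: int = 130
    family_size_probs: tuple[tuple[int, float], ...] = (
        (3, 0.40),
        (4, 0.40),
        (5, 0.15),
        (6, 0.05),
    )
    big_family: str | None = "seventeen"  # 'seventeen' | 'ten' | None
    marker_blocks: tuple[MarkerBlock, ...] = ()
    causal: tuple[CausalVariant, ...] = ()
    mean_sbp: float = 125.3
    mean_dbp: float = 74.5
    sigma2_g_sbp: float = 100.0
    sigma2_e_sbp: float = 110.0
    sigma2_g_dbp: float = 40.0
    sigma2_e_dbp: float = 55.0
    effect_sex_sbp: float = 4.0
    effect_age_sbp: float = 0.35
    effect_age2_sbp: float = 0.004
    effect_bmi_sbp: float = 0.6
    effect_sex_dbp: float = 2.0
    effect_age_dbp: float = 0.15
    effect_age2_dbp: float = 0.0
    effect_bmi_dbp: float = 0.25
    medication: bool = True
    med_threshold: float = 137.0  # logistic midpoint on latent SBP (mmHg)
    med_slope: float = 0.125  # per mmHg; ~25% treated at these defaults
    mean_age: float = 46.9
    mean_bmi: float = 31.8
    sd_bmi: float = 8.5
    max_reject: int = 1000


BIG_FAMILY_ID = "F001"


def _default_blocks() -> tuple[MarkerBlock, ...]:
    return (
        MarkerBlock("16", 31, 3.0, prefix="c16"),
        MarkerBlock("1", 15, 10.0, prefix="c1"),
        MarkerBlock("2", 15, 10.0, prefix="c2"),
        MarkerBlock("3", 15, 10.0, prefix="c3"),
        MarkerBlock("4", 15, 10.0, prefix="c4"),
    )


def default_config() -> SimConfig:
    """Full-scale emulation: 130 families, one 17-member family carrying a
    rare protective SBP variant, plus additional rare protective coding
    variants under the chromosome-16 peak."""
    causal = (
        # the single-family variant: obese-but-normotensive carriers — the
        # BMI-conditional SBP effect of -16.4 plus +28 kg/m^2 on BMI gives a
        # raw carrier-noncarrier SBP difference of about -8 mmHg
        CausalVariant(
            "rv1", "16", 30.0, 0.004, -24.8, -3.5, beta_bmi=28.0,
            restrict_family=BIG_FAMILY_ID, carrier_founder="gm", min_carriers=5,
        ),
        CausalVariant("rv2", "16", 27.0, 0.02, -5.0, -2.0),
        CausalVariant("rv3", "16", 33.0, 0.03, -4.0, -1.5),
        CausalVariant("rv4", "16", 29.0, 0.015, -6.0, -2.0),
        CausalVariant("rv5", "16", 31.0, 0.02, -3.0, -1.0),
    )
    return SimConfig(marker_blocks=_default_blocks(), causal=causal)


def scaled_config(n_families: int = 40) -> SimConfig:
    """Desk-scale scenario for end-to-end runs.

    A third-scale cohort with a 10-member three-generation carrier family
    (exactly solvable by the inheritance-vector HMM) and region variants
    whose combined QTL variance keeps the locus detectable at the reduced
    sample size, preserving the regime of the full design: one rare
    protective variant (beta = -8 mmHg) segregating in a single family
    plus several lower-frequency protective variants under the peak.
    """
    causal = (
        CausalVariant(
            "rv1", "16", 30.0, 0.004, -24.8, -3.5, beta_bmi=28.0,
            restrict_family=BIG_FAMILY_ID, carrier_founder="gm", min_carriers=5,
        ),
        # region QTL variance ~20% of the residual trait variance: the
        # scaled cohort (~200 vs 517 individuals) keeps the linkage
        # non-centrality of the full design by trading sample size for
        # effect size
        CausalVariant("rv2", "16", 26.0, 0.08, -13.0, -4.0),
        CausalVariant("rv3", "16", 34.0, 0.08, -13.0, -4.0),
        CausalVariant("rv4", "16", 28.0, 0.08, -12.0, -4.0),
        CausalVariant("rv5", "16", 32.0, 0.08, -12.0, -3.5),
    )
    # off-region chromosomes feed the resampled-SNP LOD-drop null, so the
    # pool must comfortably exceed the 200 draws used there
    blocks = (
        MarkerBlock("16", 16, 4.0, prefix="c16"),
        MarkerBlock("1", 45, 5.0, prefix="c1"),
        MarkerBlock("2", 45, 5.0, prefix="c2"),
        MarkerBlock("3", 45, 5.0, prefix="c3"),
        MarkerBlock("4", 45, 5.0, prefix="c4"),
        MarkerBlock("5", 45, 5.0, prefix="c5"),
        MarkerBlock("6", 45, 5.0, prefix="c6"),
    )
    return SimConfig(
        n_families=n_families,
        big_family="ten",
        family_size_probs=((4, 0.3), (5, 0.4), (6, 0.3)),
        marker_blocks=blocks,
        causal=causal,
    )


@dataclass
class SimStudy:
    pedigrees: dict[str, Pedigree]
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: dict


# --------------------------------------------------------------- pedigrees


def _nuclear(fid: str, n_children: int, rng: np.random.Generator) -> Pedigree:
    members = [
        Individual("fa", fid, sex="male"),
        Individual("mo", fid, sex="female"),
    ]
    for c in range(n_children):
        members.append(
            Individual(
                f"c{c + 1}", fid, father="fa", mother="mo",
                sex="male" if rng.random() < 0.5 else "female",
            )
        )
    return Pedigree(members)


def _three_gen(fid: str, layout: str, rng: np.random.Generator) -> Pedigree:
    """Three-generation family around founding grandparents gf/gm.

    'seventeen': 4 children, 3 married with 3+3+2 grandchildren
    (17 members, bit complexity 19 — beyond exact enumeration, the
    Monte-Carlo IBD regime). 'ten': 3 children, 2 married with 2+1
    grandchildren (10 members, bit complexity 8 — exactly solvable).
    """
    plans = {
        "seventeen": (4, ((0, 3), (1, 3), (2, 2))),
        "ten": (3, ((0, 2), (1, 1))),
    }
    n_children, couples = plans[layout]
    members = [
        Individual("gf", fid, sex="male"),
        Individual("gm", fid, sex="female"),
    ]
    for c in range(n_children):
        members.append(
            Individual(
                f"c{c + 1}", fid, father="gf", mother="gm",
                sex="male" if rng.random() < 0.5 else "female",
            )
        )
    gk = 0
    for ci, n_gk in couples:
        child = members[2 + ci]
        spouse_sex = "female" if child.sex == "male" else "male"
        spouse = Individual(f"s{ci + 1}", fid, sex=spouse_sex)
        members.append(spouse)
        father, mother = (
            (child.iid, spouse.iid) if child.sex == "male" else (spouse.iid, child.iid)
        )
        for _ in range(n_gk):
            gk += 1
            members.append(
                Individual(
                    f"g{gk}", fid, father=father, mother=mother,
                    sex="male" if rng.random() < 0.5 else "female",
                )
            )
    return Pedigree(members)


def simulate_pedigrees(
    config: SimConfig, rng: np.random.Generator
) -> dict[str, Pedigree]:
    """Draw the family set: optional big family first, then nuclear families
    with sizes from the configured distribution."""
    peds: dict[str, Pedigree] = {}
    next_no = 1
    if config.big_family is not None:
        peds[BIG_FAMILY_ID] = _three_gen(BIG_FAMILY_ID, config.big_family, rng)
        next_no = 2
    sizes = np.array([s for s, _ in config.family_size_probs])
    probs = np.array([p for _, p in config.family_size_probs], float)
    probs = probs / probs.sum()
    n_rest = config.n_families - len(peds)
    for k in range(n_rest):
        fid = f"F{next_no + k:03d}"
        size = int(rng.choice(sizes, p=probs))
        peds[fid] = _nuclear(fid, size - 2, rng)
    for fid, ped in peds.items():
        logger.debug("family %s: %d members, bits=%d", fid, len(ped), ped.bit_complexity)
    return peds


# --------------------------------------------------------------- genotypes


def _marker_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for blk in config.marker_blocks:
        mafs = rng.uniform(*blk.maf_range, size=blk.n_markers)
        for i in range(blk.n_markers):
            cm = blk.start_cm + i * blk.spacing_cm
            rows.append(
                (f"{blk.prefix}_{i + 1:03d}", blk.chrom, int(cm * 1e6) + 1, cm,
                 "1", "2", float(mafs[i]), None)
            )
    for cv in config.causal:
        freq = 0.0 if cv.restrict_family else cv.maf
        rows.append(
            (cv.marker_id, cv.chrom, int(cv.cm * 1e6) + 1, cv.cm, "1", "2",
             freq, cv.restrict_family)
        )
    df = pd.DataFrame(
        rows,
        columns=["marker_id", "chrom", "bp", "cm", "allele1", "allele2",
                 "founder_freq", "restrict_family"],
    )
    return df.sort_values(["chrom", "cm", "bp"], kind="stable").reset_index(drop=True)


def _drop_family(
    ped: Pedigree,
    markers: pd.DataFrame,
    rng: np.random.Generator,
    planted: dict[str, list[int]],
) -> np.ndarray:
    """One gene drop: (n_members, n_markers, 2) allele indices."""
    n, M = len(ped), len(markers)
    haps = np.zeros((n, 2, M), dtype=np.int8)
    idx = {iid: k for k, iid in enumerate(ped.ids)}
    freq = markers["founder_freq"].to_numpy(float)
    for iid in ped.founders:
        haps[idx[iid]] = (rng.random((2, M)) < freq[None, :]).astype(np.int8)
    for iid, cols in planted.items():
        haps[idx[iid], 0, cols] = 1  # single founder copy of a planted allele
    chrom_arr = markers["chrom"].to_numpy(str)
    cm_arr = markers["cm"].to_numpy(float)
    for chrom in dict.fromkeys(chrom_arr):
        cols = np.flatnonzero(chrom_arr == chrom)
        theta = np.asarray(
            haldane_theta(np.diff(cm_arr[cols]) / 100.0), dtype=float
        )
        for iid in ped.topological_order:
            ind = ped[iid]
            if ind.is_founder:
                continue
            for gamete, parent in ((0, ind.father), (1, ind.mother)):
                path = np.empty(len(cols), dtype=np.int8)
                path[0] = rng.integers(0, 2)
                flips = rng.random(len(cols) - 1) < theta
                path[1:] = (path[0] + np.cumsum(flips)) % 2
                haps[idx[iid], gamete, cols] = haps[idx[parent], path, cols]
    return np.stack([haps[:, 0, :], haps[:, 1, :]], axis=2)


def gene_drop(
    pedigrees: Mapping[str, Pedigree],
    markers: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, dict]:
    """Drop founder haplotypes through every pedigree.

    Returns the genotype matrix plus a record of realized carrier counts
    for the restricted (single-family) variants.
    """
    restricted = [cv for cv in config.causal if cv.restrict_family]
    realized: dict[str, int] = {}
    samples: list[tuple[str, str]] = []
    call_blocks = []
    for fid, ped in pedigrees.items():
        my_restricted = [cv for cv in restricted if cv.restrict_family == fid]
        planted: dict[str, list[int]] = {}
        for cv in my_restricted:
            founder = cv.carrier_founder or ped.founders[0]
            col = int(np.flatnonzero(markers["marker_id"] == cv.marker_id)[0])
            planted.setdefault(founder, []).append(col)
        best, best_count = None, -1
        for attempt in range(config.max_reject if my_restricted else 1):
            calls = _drop_family(ped, markers, rng, planted)
            if not my_restricted:
                best = calls
                break
            count = min(
                int((calls[:, int(np.flatnonzero(markers["marker_id"] == cv.marker_id)[0]), :].sum(axis=1) >= 1).sum())
                for cv in my_restricted
            )
            if count > best_count:
                best, best_count = calls, count
            if count >= max(cv.min_carriers for cv in my_restricted):
                break
        else:
            if my_restricted:
                logger.warning(
                    "family %s: carrier target not reached after %d attempts "
                    "(best %d)", fid, config.max_reject, best_count,
                )
        for cv in my_restricted:
            col = int(np.flatnonzero(markers["marker_id"] == cv.marker_id)[0])
            realized[cv.marker_id] = int((best[:, col, :].sum(axis=1) >= 1).sum())
        samples.extend((fid, iid) for iid in ped.ids)
        call_blocks.append(best)
    gm = GenotypeMatrix(
        samples,
        markers[["marker_id", "chrom", "bp", "cm", "allele1", "allele2"]],
        np.concatenate(call_blocks, axis=0),
    )
    return gm, {"restricted_carriers": realized}


# ------------------------------------------------------------------ traits


def simulate_traits(
    pedigrees: Mapping[str, Pedigree],
    gm: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Latent BP = covariates + variant effects + polygenes + noise;
    observed BP subtracts the medication masking (-15/-10) for treated
    individuals, which :func:`famqtl.pheno_prep.adjust_medication` undoes."""
    dose_cols = {cv.marker_id: gm.marker_index(cv.marker_id) for cv in config.causal}
    dosage = gm.calls.sum(axis=2).astype(float)

    rows = []
    for fid, ped in pedigrees.items():
        idx = {iid: k for k, iid in enumerate(ped.ids)}
        depth = _generation_depth(ped)
        max_depth = max(depth.values())
        _, phi = ped.kinship()
        L = np.linalg.cholesky(2.0 * phi + 1e-10 * np.eye(len(ped)))
        delta_sbp = np.sqrt(config.sigma2_g_sbp) * (L @ rng.standard_normal(len(ped)))
        delta_dbp = np.sqrt(config.sigma2_g_dbp) * (L @ rng.standard_normal(len(ped)))
        for iid in ped.ids:
            k = idx[iid]
            ind = ped[iid]
            age = float(
                np.clip(rng.normal(25.0 + 25.0 * (max_depth - depth[iid]), 6.0), 18, 95)
            )
            male = 1.0 if ind.sex == "male" else 0.0
            pc1 = float(rng.standard_normal())
            row_g = gm.sample_index(fid, iid)
            gsum_bmi = sum(
                cv.beta_bmi * dosage[row_g, dose_cols[cv.marker_id]]
                for cv in config.causal
            )
            bmi = float(
                np.clip(rng.normal(config.mean_bmi, config.sd_bmi) + gsum_bmi, 16, 75)
            )
            gsum_sbp = sum(
                cv.beta_sbp * dosage[row_g, dose_cols[cv.marker_id]]
                for cv in config.causal
            )
            gsum_dbp = sum(
                cv.beta_dbp * dosage[row_g, dose_cols[cv.marker_id]]
                for cv in config.causal
            )
            ca = age - config.mean_age
            sbp_lat = (
                config.mean_sbp
                + config.effect_sex_sbp * male
                + config.effect_age_sbp * ca
                + config.effect_age2_sbp * (ca**2 - 100.0)
                + config.effect_bmi_sbp * (bmi - config.mean_bmi)
                + gsum_sbp
                + delta_sbp[k]
                + rng.normal(0.0, np.sqrt(config.sigma2_e_sbp))
            )
            dbp_lat = (
                config.mean_dbp
                + config.effect_sex_dbp * male
                + config.effect_age_dbp * ca
                + config.effect_age2_dbp * (ca**2 - 100.0)
                + config.effect_bmi_dbp * (bmi - config.mean_bmi)
                + gsum_dbp
                + delta_dbp[k]
                + rng.normal(0.0, np.sqrt(config.sigma2_e_dbp))
            )
            if config.medication:
                p_med = 1.0 / (
                    1.0 + np.exp(-config.med_slope * (sbp_lat - config.med_threshold))
                )
                med = int(rng.random() < p_med)
            else:
                med = 0
            rows.append(
                {
                    "family_id": fid,
                    "individual_id": iid,
                    "sex": ind.sex,
                    "age": round(age, 2),
                    "bmi": round(bmi, 2),
                    "pc1": round(pc1, 4),
                    "med": med,
                    "sbp": round(sbp_lat - (15.0 if med else 0.0), 2),
                    "dbp": round(dbp_lat - (10.0 if med else 0.0), 2),
                }
            )
    return pd.DataFrame(rows)


def _generation_depth(ped: Pedigree) -> dict[str, int]:
    """Generation index: children are one below their parents; married-in
    founders sit at their partner's generation."""
    depth = {}
    for iid in ped.topological_order:
        ind = ped[iid]
        depth[iid] = 0 if ind.is_founder else max(depth[ind.father], depth[ind.mother]) + 1
    # pull married-in founders down to co-parent level
    for iid in ped.ids:
        ind = ped[iid]
        if not ind.is_founder:
            d = depth[iid] - 1
            depth[ind.father] = max(depth[ind.father], d)
            depth[ind.mother] = max(depth[ind.mother], d)
    return depth


# ------------------------------------------------------------------ driver


def simulate_study(config: SimConfig, seed: int) -> SimStudy:
    """Full deterministic simulation from one master seed."""
    ss = np.random.SeedSequence(seed)
    rng_ped, rng_geno, rng_trait = (np.random.default_rng(s) for s in ss.spawn(3))
    pedigrees = simulate_pedigrees(config, rng_ped)
    markers = _marker_table(config, rng_geno)
    gm, drop_info = gene_drop(pedigrees, markers, config, rng_geno)
    pheno = simulate_traits(pedigrees, gm, config, rng_trait)
    truth = {
        "seed": seed,
        "n_families": len(pedigrees),
        "n_individuals": int(sum(len(p) for p in pedigrees.values())),
        "sigma2_g_sbp": config.sigma2_g_sbp,
        "sigma2_e_sbp": config.sigma2_e_sbp,
        "sigma2_g_dbp": config.sigma2_g_dbp,
        "sigma2_e_dbp": config.sigma2_e_dbp,
        "causal": [asdict(cv) for cv in config.causal],
        "restricted_carriers": drop_info["restricted_carriers"],
    }
    return SimStudy(pedigrees=pedigrees, genotypes=gm, phenotypes=pheno, truth=truth)


def write_study(study: SimStudy, outdir) -> dict[str, Path]:
    """Write PED/MAP, the phenotype TSV and the truth JSON (byte-stable)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": outdir / "study.ped",
        "map": outdir / "study.map",
        "pheno": outdir / "phenotypes.tsv",
        "truth": outdir / "truth.json",
    }
    write_ped_map(study.pedigrees, study.genotypes, paths["ped"], paths["map"])
    study.phenotypes.to_csv(paths["pheno"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
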