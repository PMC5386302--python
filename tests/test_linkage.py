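"""Variance-component linkage scanning, conditioning and region selection."""

import numpy as np
import pandas as pd
import pytest

from famqtl.ibd import multipoint_ibd
from famqtl.linkage import (
    LinkageCurve,
    conditional_scan,
    region_2lod,
    vc_linkage_scan,
)
from famqtl.pedigree_io import compute_kinship
from famqtl.synthetic_data import _drop_family, scaled_config, simulate_study
from helpers import marker_table, nuclear


def _null_families(n_fam, rng, sg=0.4, se=0.6, n_children=3):
    """Polygenic-only trait on nuclear families plus gene-dropped markers."""
    peds = {f"F{k}": nuclear(f"F{k}", n_children) for k in range(n_fam)}
    mt = marker_table([0.0, 4.0, 8.0, 12.0, 16.0], freq=0.4)
    samples, blocks, ys = [], [], {}
    for fid, ped in peds.items():
        blocks.append(_drop_family(ped, mt, rng, {}))
        samples.extend((fid, iid) for iid in ped.ids)
        _, phi = ped.kinship()
        L = np.linalg.cholesky(2 * phi + 1e-10 * np.eye(len(ped)))
        y = np.sqrt(sg) * (L @ rng.standard_normal(len(ped))) + np.sqrt(
            se
        ) * rng.standard_normal(len(ped))
        for iid, v in zip(ped.ids, y):
            ys[(fid, iid)] = v
    from famqtl.pedigree_io import GenotypeMatrix

    gm = GenotypeMatrix(
        samples,
        mt[["marker_id", "chrom", "bp", "cm", "allele1", "allele2"]],
        np.concatenate(blocks, axis=0),
    )
    trait = pd.Series(ys)
    trait.index = pd.MultiIndex.from_tuples(trait.index)
    return peds, gm, trait


def test_per_family_lods_sum_to_total(rng):
    peds, gm, trait = _null_families(12, rng)
    kin = compute_kinship(peds)
    ibd = multipoint_ibd(peds, gm, "1", step_cm=4.0)
    curve = vc_linkage_scan(trait, kin, ibd)
    total = curve.per_family.sum(axis=1).to_numpy()
    assert np.nanmax(np.abs(total - curve.lod)) < 1e-8
    assert np.all(curve.lod >= 0.0)


def test_qtl_boundary_gives_exact_zero_lod(rng):
    # under a pure polygenic model many positions sit at sigma2_qtl = 0
    peds, gm, trait = _null_families(10, rng)
    kin = compute_kinship(peds)
    ibd = multipoint_ibd(peds, gm, "1", step_cm=8.0)
    curve = vc_linkage_scan(trait, kin, ibd)
    assert np.any(curve.lod == 0.0)


def test_zero_covariate_leaves_curve_unchanged(rng):
    peds, gm, trait = _null_families(8, rng)
    kin = compute_kinship(peds)
    ibd = multipoint_ibd(peds, gm, "1", step_cm=8.0)
    base = vc_linkage_scan(trait, kin, ibd)
    zero = pd.Series(0.0, index=trait.index)
    cond = conditional_scan(trait, kin, ibd, zero)
    assert np.nanmax(np.abs(base.lod - cond.lod)) < 1e-8


def test_collinear_covariate_rejected(rng):
    peds, gm, trait = _null_families(6, rng)
    kin = compute_kinship(peds)
    ibd = multipoint_ibd(peds, gm, "1", step_cm=8.0)
    const = pd.Series(3.0, index=trait.index)  # collinear with intercept
    with pytest.raises(ValueError, match="collinear"):
        conditional_scan(trait, kin, ibd, const)


def test_conditioning_on_causal_genotype_drops_mlod(rng):
    """Conditioning on the true causal dosage removes more linkage signal
    than conditioning on a permuted copy of it (paired comparison)."""
    drops_true, drops_perm = [], []
    for seed in (3, 5, 7):
        study = simulate_study(scaled_config(25), seed=seed)
        from famqtl.pheno_prep import adjust_medication, residualize

        ph = adjust_medication(study.phenotypes)
        resid = residualize(ph, "sbp_adj")
        trait = pd.Series(
            resid.values,
            index=pd.MultiIndex.from_frame(ph[["family_id", "individual_id"]]),
        )
        kin = compute_kinship(study.pedigrees)
        gm = study.genotypes
        common = [
            i
            for i in range(gm.n_markers)
            if gm.markers["marker_id"].iloc[i].startswith("c16")
        ]
        ibd = multipoint_ibd(study.pedigrees, gm.subset_markers(common), "16", step_cm=4.0)
        curve = vc_linkage_scan(trait, kin, ibd)
        dose, _ = gm.minor_dosage()
        gidx = pd.MultiIndex.from_tuples(gm.samples)
        causal = sum(
            dose[:, gm.marker_index(v)] for v in ("rv2", "rv3", "rv4", "rv5")
        )
        g = pd.Series(causal, index=gidx)
        gp = pd.Series(
            np.random.default_rng(seed).permutation(causal), index=gidx
        )
        cond_t = conditional_scan(trait, kin, ibd, g, warm_fits=curve.fits, n_starts=2)
        cond_p = conditional_scan(trait, kin, ibd, gp, warm_fits=curve.fits, n_starts=2)
        drops_true.append(curve.mlod - cond_t.mlod)
        drops_perm.append(curve.mlod - cond_p.mlod)
    assert np.mean(drops_true) > np.mean(drops_perm)


def _curve(positions, lod):
    return LinkageCurve(
        chrom="16",
        positions=np.asarray(positions, float),
        lod=np.asarray(lod, float),
        per_family=pd.DataFrame(index=positions),
    )


def test_region_2lod_triangular_support_interval():
    pos = np.arange(0.0, 61.0, 1.0)
    lod = np.maximum(0.0, 2.81 - np.abs(pos - 30.0) * 0.1)  # peak 2.81 at 30
    chrom, lo, hi = region_2lod(_curve(pos, lod), target_width_cm=20.0)
    # crosses 0.81 at 30 +/- 20
    assert lo == pytest.approx(10.0, abs=1e-6)
    assert hi == pytest.approx(50.0, abs=1e-6)


def test_region_2lod_widens_narrow_interval():
    pos = np.arange(0.0, 61.0, 1.0)
    lod = np.maximum(0.0, 3.0 - np.abs(pos - 30.0) * 0.67)  # ~3 cM half-width
    chrom, lo, hi = region_2lod(_curve(pos, lod), target_width_cm=20.0)
    assert hi - lo == pytest.approx(20.0, abs=1e-9)
    assert (lo + hi) / 2 == pytest.approx(30.0, abs=1e-9)


def test_region_2lod_monotone_curve_hits_chromosome_end():
    pos = np.arange(0.0, 41.0, 1.0)
    lod = pos * 0.1  # increasing to the end
    chrom, lo, hi = region_2lod(_curve(pos, lod), target_width_cm=20.0)
    assert hi == 40.0
    assert lo == pytest.approx(40.0 - 20.0)


def test_region_2lod_flat_curve_errors():
    pos = np.arange(0.0, 10.0, 1.0)
    with pytest.raises(ValueError, match="no peak"):
        region_2lod(_curve(pos, np.zeros_like(pos)))


def test_curve_tsv_round_trip(tmp_path, rng):
    peds, gm, trait = _null_families(6, rng)
    kin = compute_kinship(peds)
    ibd = multipoint_ibd(peds, gm, "1", step_cm=8.0)
    curve = vc_linkage_scan(trait, kin, ibd)
    curve.to_tsv(tmp_path / "c.tsv", per_family=True)
    back = pd.read_csv(tmp_path / "c.tsv", sep="\t")
    assert np.allclose(back["lod"], curve.lod, atol=1e-5)
    assert back.shape[1] == 3 + len(peds)
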