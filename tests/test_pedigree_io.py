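"""Pedigree/genotype I/O, validation, kinship and the Haldane map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famqtl.pedigree_io import (
    GenotypeMatrix,
    Individual,
    Pedigree,
    PedigreeError,
    check_mendelian,
    compute_kinship,
    haldane_theta,
    read_ped_map,
    write_ped_map,
)
from helpers import dropped_gm, four_gen, mc_kinship, nuclear, three_gen


# ------------------------------------------------------------------ file I/O


def test_ped_map_round_trip(tmp_path, rng):
    ped = nuclear("FAM1", 3)
    gm = dropped_gm(ped, [0.0, 5.0, 12.0], rng, missing=0.1)
    write_ped_map({"FAM1": ped}, gm, tmp_path / "t.ped", tmp_path / "t.map")
    peds2, gm2 = read_ped_map(tmp_path / "t.ped", tmp_path / "t.map")
    assert list(peds2) == ["FAM1"]
    assert peds2["FAM1"].ids == ped.ids
    assert [peds2["FAM1"][i].father for i in ped.ids] == [ped[i].father for i in ped.ids]
    assert np.array_equal(
        np.sort(gm2.calls, axis=2), np.sort(gm.calls, axis=2)
    )
    assert (gm2.markers["cm"] == gm.markers["cm"]).all()


def test_unknown_sex_code_reads_as_unknown(tmp_path):
    (tmp_path / "t.map").write_text("1\tm1\t0\t1\n")
    (tmp_path / "t.ped").write_text("F1 i1 0 0 0 -9 1 2\n")
    peds, gm = read_ped_map(tmp_path / "t.ped", tmp_path / "t.map")
    assert peds["F1"]["i1"].sex == "unknown"


def test_missing_parent_strict_vs_lenient(tmp_path):
    (tmp_path / "t.map").write_text("1\tm1\t0\t1\n")
    (tmp_path / "t.ped").write_text(
        "F1 mom 0 0 2 -9 1 1\nF1 kid dad mom 1 -9 1 1\n"
    )
    with pytest.raises(PedigreeError, match="dad"):
        read_ped_map(tmp_path / "t.ped", tmp_path / "t.map")
    peds, _ = read_ped_map(tmp_path / "t.ped", tmp_path / "t.map", lenient=True)
    assert "dad" in peds["F1"]
    assert peds["F1"]["dad"].is_founder and peds["F1"]["dad"].sex == "male"


def test_duplicate_individual_rejected(tmp_path):
    (tmp_path / "t.map").write_text("1\tm1\t0\t1\n")
    (tmp_path / "t.ped").write_text("F1 a 0 0 1 -9 1 1\nF1 a 0 0 1 -9 1 1\n")
    with pytest.raises(PedigreeError, match="duplicated"):
        read_ped_map(tmp_path / "t.ped", tmp_path / "t.map")


def test_malformed_line_reports_line_number(tmp_path):
    (tmp_path / "t.map").write_text("1\tm1\t0\t1\n")
    (tmp_path / "t.ped").write_text("F1 a 0 0 1 -9 1\n")
    with pytest.raises(PedigreeError, match="line 1"):
        read_ped_map(tmp_path / "t.ped", tmp_path / "t.map")


def test_single_parent_named_is_invalid():
    with pytest.raises(PedigreeError, match="both"):
        Individual("x", "F", father="dad", mother=None)


def test_cyclic_pedigree_rejected():
    with pytest.raises(PedigreeError, match="cycle"):
        Pedigree(
            [
                Individual("a", "F", father="b", mother="c"),
                Individual("b", "F", father="a", mother="c"),
                Individual("c", "F"),
            ]
        )


# ------------------------------------------------------------------ kinship


def test_kinship_closed_forms():
    ped = three_gen()
    ids, phi = ped.kinship()
    k = {iid: i for i, iid in enumerate(ids)}
    assert phi[k["gf"], k["c1"]] == 0.25  # parent-offspring
    assert phi[k["c1"], k["c2"]] == 0.25  # full sibs
    assert phi[k["gf"], k["g1"]] == 0.125  # grandparent
    assert phi[k["g1"], k["g1"]] == 0.5  # non-inbred self
    assert phi[k["c2"], k["g1"]] == 0.125  # avuncular
    # half sibs and first cousins on a dedicated pedigree
    ped2 = Pedigree(
        [
            Individual("f", "H", sex="male"),
            Individual("m1", "H", sex="female"),
            Individual("m2", "H", sex="female"),
            Individual("a", "H", "f", "m1"),
            Individual("b", "H", "f", "m2"),
        ]
    )
    ids2, phi2 = ped2.kinship()
    k2 = {iid: i for i, iid in enumerate(ids2)}
    assert phi2[k2["a"], k2["b"]] == 0.125
    gp = four_gen()
    ids3, phi3 = gp.kinship()
    k3 = {iid: i for i, iid in enumerate(ids3)}
    assert phi3[k3["c1"], k3["c2"]] == 0.25


def test_first_cousins_kinship():
    members = [
        Individual("gf", "C", sex="male"),
        Individual("gm", "C", sex="female"),
        Individual("p1", "C", "gf", "gm", sex="male"),
        Individual("p2", "C", "gf", "gm", sex="female"),
        Individual("s1", "C", sex="female"),
        Individual("s2", "C", sex="male"),
        Individual("x", "C", "p1", "s1"),
        Individual("y", "C", "s2", "p2"),
    ]
    ids, phi = Pedigree(members).kinship()
    k = {iid: i for i, iid in enumerate(ids)}
    assert phi[k["x"], k["y"]] == pytest.approx(0.0625)


def test_kinship_symmetric_and_2phi_psd(small_study):
    kin = compute_kinship(small_study.pedigrees)
    assert np.allclose(kin.phi, kin.phi.T)
    eig = np.linalg.eigvalsh(kin.two_phi)
    assert eig.min() >= -1e-10


def test_kinship_matches_gene_drop_monte_carlo(rng):
    """Tabular kinship equals the probability of sampling IBD alleles,
    estimated by 100k labelled gene drops on a 4-generation pedigree."""
    ped = four_gen()
    ids, phi = ped.kinship()
    phi_mc = mc_kinship(ped, 100_000, rng)
    se = np.sqrt(0.25 / 100_000)  # conservative binomial SE bound
    assert np.max(np.abs(phi - phi_mc)) < 3 * 4 * se  # 4 allele pairings


def test_kinship_tsv_round_trip(tmp_path, small_study):
    from famqtl.pedigree_io import KinshipMatrix

    kin = compute_kinship(small_study.pedigrees)
    kin.to_tsv(tmp_path / "k.tsv")
    back = KinshipMatrix.from_tsv(tmp_path / "k.tsv")
    assert back.samples == kin.samples
    assert np.allclose(back.phi, kin.phi)


# ----------------------------------------------------------------- mendelian


@pytest.mark.parametrize(
    "father,mother,child,n_errors",
    [
        ((0, 0), (0, 0), (0, 0), 0),  # AA x AA -> AA fine
        ((0, 0), (0, 0), (0, 1), 1),  # AA x AA -> AB impossible
        ((0, 1), (0, 0), (1, 1), 1),  # AB x AA -> BB impossible
        ((0, 1), (0, 1), (1, 1), 0),
        ((-1, -1), (0, 0), (1, 1), 1),  # father missing, but mother AA cannot give B
        ((-1, -1), (0, 1), (1, 1), 0),  # missing parent unconstrained
    ],
)
def test_mendelian_trio_rules(father, mother, child, n_errors):
    ped = nuclear("F", 1)
    mt = pd.DataFrame(
        [("m1", "1", 1, 0.0, "1", "2")],
        columns=["marker_id", "chrom", "bp", "cm", "allele1", "allele2"],
    )
    calls = np.array([[father], [mother], [child]], dtype=np.int8)
    gm = GenotypeMatrix([("F", "fa"), ("F", "mo"), ("F", "c1")], mt, calls)
    report = check_mendelian({"F": ped}, gm)
    assert len(report) == n_errors


def test_gene_dropped_data_is_mendelian_clean(small_study):
    report = check_mendelian(small_study.pedigrees, small_study.genotypes)
    assert len(report) == 0


# ------------------------------------------------------------------- haldane


def test_haldane_values():
    assert haldane_theta(0.0) == 0.0
    assert haldane_theta(10.0) == pytest.approx(0.5, abs=1e-8)
    assert haldane_theta(0.20) == pytest.approx(0.5 * (1 - np.exp(-0.4)), abs=1e-12)
    assert haldane_theta(0.20) == pytest.approx(0.16484, abs=5e-6)
    with pytest.raises(ValueError):
        haldane_theta(-0.1)


@settings(deadline=None, max_examples=50)
@given(st.one_of(st.just(0.0), st.floats(min_value=1e-9, max_value=50.0)))
def test_haldane_bounds_and_monotone(d):
    th = haldane_theta(d)
    assert 0.0 <= th <= 0.5
    assert (th == 0.0) == (d == 0.0)  # theta = 0 iff d = 0 (away from underflow)
    assert haldane_theta(d + 0.1) >= th


# ---------------------------------------------------------------------- vcf


def test_vcf_reader_maps_gt_to_calls(tmp_path):
    from famqtl.pedigree_io import read_vcf

    vcf = tmp_path / "t.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=1>\n'
        '##INFO=<ID=CM,Number=1,Type=Float,Description="genetic position">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tfa\tmo\tc1\n"
        "1\t1000\trs1\tA\tG\t.\t.\tCM=0.5\tGT\t0/1\t0/0\t0/1\n"
        "1\t2000\trs2\tC\tT\t.\t.\tCM=1.5\tGT\t1/1\t0/1\t./.\n"
        "1\t3000\trs3\tC\tT,G\t.\t.\t.\tGT\t0/1\t0/0\t0/0\n"
    )
    ped = Pedigree(
        [
            Individual("fa", "F", sex="male"),
            Individual("mo", "F", sex="female"),
            Individual("c1", "F", "fa", "mo"),
        ]
    )
    gm = read_vcf(vcf, {"F": ped})
    assert gm.samples == [("F", "fa"), ("F", "mo"), ("F", "c1")]
    assert gm.n_markers == 2  # multi-allelic rs3 skipped
    assert list(gm.markers["cm"]) == [0.5, 1.5]
    assert tuple(gm.calls[0, 0]) == (0, 1)  # fa het at rs1
    assert tuple(gm.calls[2, 1]) == (-1, -1)  # c1 missing at rs2


def test_ibs_report_orders_with_kinship(small_study):
    from famqtl.pedigree_io import ibs_relatedness_report

    rep = ibs_relatedness_report(small_study.pedigrees, small_study.genotypes)
    assert {"kinship", "mean_ibs"} <= set(rep.columns)
    # higher-kinship pairs share more alleles identical-by-state on average
    close = rep.loc[rep["kinship"] >= 0.25, "mean_ibs"].mean()
    far = rep.loc[rep["kinship"] < 0.05, "mean_ibs"].mean()
    assert close > far
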