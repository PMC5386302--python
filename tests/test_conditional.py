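"""Candidate filtering, risk scores, the LOD-drop null and analytics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from famqtl.conditional_pipeline import (
    CandidateFilter,
    LodDropNull,
    build_risk_score,
    direction_binomial,
    filter_candidates,
    opposite_direction_prob,
)
from famqtl.mixed_assoc import MixedModelFit


def _fit(p, beta, carriers):
    return MixedModelFit(
        beta1=beta, se1=1.0, beta=np.array([0.0, beta]), sigma2_g=1.0,
        sigma2_e=1.0, ll_null=0.0, ll_alt=0.0, lrt=0.0, p=p, n=100,
        family_carriers=carriers,
    )


def test_filter_passes_strong_single_family_variant():
    # association p = 0.0016 with 5 carriers in a family whose LOD is 0.697
    fits = {"v": _fit(0.0016, -8.0, {"FAM": 5})}
    assert filter_candidates(fits, {"FAM": 0.697}) == ["v"]


def test_filter_rejects_weak_effect():
    fits = {"v": _fit(0.5, -2.0, {"FAM": 5})}
    assert filter_candidates(fits, {"FAM": 0.697}) == []


def test_filter_large_beta_clause():
    # p = 0.2 fails the p clause but |beta| = 6 >= 5 passes; 2 carriers in a
    # family with LOD 0.15 satisfies segregation
    fits = {"v": _fit(0.2, 6.0, {"FAM": 2})}
    assert filter_candidates(fits, {"FAM": 0.15}) == ["v"]


def test_filter_requires_carriers_and_family_lod_together():
    fits = {
        "a": _fit(0.01, -9.0, {"F1": 1, "F2": 3}),  # F2 has carriers, low LOD
        "b": _fit(0.01, -9.0, {"F1": 2}),  # F1 has the LOD and carriers
    }
    lods = {"F1": 0.3, "F2": 0.0}
    assert filter_candidates(fits, lods) == ["b"]


def test_filter_orders_by_position_and_handles_empty():
    fits = {
        "x": _fit(0.01, -9.0, {"F": 2}),
        "y": _fit(0.01, -9.0, {"F": 2}),
    }
    out = filter_candidates(fits, {"F": 0.5}, positions={"x": 20.0, "y": 10.0})
    assert out == ["y", "x"]
    assert filter_candidates({}, {}) == []


@settings(deadline=None, max_examples=60)
@given(
    p=st.floats(0.0, 1.0),
    beta=st.floats(-10, 10),
    carriers=st.integers(0, 6),
    famlod=st.floats(-1, 1),
    dp=st.floats(0, 0.5),
    dbeta=st.floats(0, 5),
    dc=st.integers(0, 2),
    dl=st.floats(0, 0.5),
)
def test_filter_monotone_in_thresholds(p, beta, carriers, famlod, dp, dbeta, dc, dl):
    """Relaxing any threshold never shrinks the selected set."""
    fits = {"v": _fit(p, beta, {"F": carriers})}
    lods = {"F": famlod}
    tight = CandidateFilter()
    loose = CandidateFilter(
        p_threshold=tight.p_threshold + dp,
        beta_threshold=max(tight.beta_threshold - dbeta, 0.0),
        min_family_carriers=max(tight.min_family_carriers - dc, 0),
        min_family_lod=tight.min_family_lod - dl,
    )
    assert set(filter_candidates(fits, lods, tight)) <= set(
        filter_candidates(fits, lods, loose)
    )


# ------------------------------------------------------------- risk score


def test_risk_score_inner_product():
    idx = pd.MultiIndex.from_tuples([("F", "1")])
    dosages = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=idx)
    fits = {"a": _fit(0.5, 2.0, {}), "b": _fit(0.5, -3.0, {})}
    rs = build_risk_score(["a", "b"], fits, dosages)
    assert rs.scores.iloc[0] == -4.0


def test_risk_score_zero_dosage_and_missing():
    idx = pd.MultiIndex.from_tuples([("F", "1"), ("F", "2")])
    dosages = pd.DataFrame({"a": [0.0, np.nan]}, index=idx)
    fits = {"a": _fit(0.5, 2.0, {})}
    rs = build_risk_score(["a"], fits, dosages)
    assert (rs.scores == 0.0).all()
    assert rs.n_missing_contributions == 1
    with pytest.raises(KeyError):
        build_risk_score(["zzz"], fits, dosages)


def test_risk_score_slope_near_one(small_inputs, small_study):
    """Regressing the trait on the risk score built from the true effects
    gives a slope near 1 (the score is on the trait scale)."""
    trait, kin, dose, maf = small_inputs
    truth = {c["marker_id"]: c["beta_sbp"] for c in small_study.truth["causal"]}
    fits = {v: _fit(0.5, b, {}) for v, b in truth.items()}
    rs = build_risk_score(list(truth), fits, dose[list(truth)])
    common = trait.dropna().index.intersection(rs.scores.index)
    y = trait.loc[common].to_numpy()
    x = rs.scores.loc[common].to_numpy()
    slope, _, _, _, stderr = stats.linregress(x, y)
    assert abs(slope - 1.0) < 4 * stderr + 0.3


# -------------------------------------------------------------- LOD drop


def test_empirical_p_add_one_rule():
    null = np.linspace(0.0, 0.3, 1000)
    nd = LodDropNull(observed_drop=0.9, null_drops=null)
    assert nd.empirical_p == pytest.approx(1 / 1001)
    nd2 = LodDropNull(observed_drop=float(np.median(null)), null_drops=null)
    assert 0.45 < nd2.empirical_p < 0.55


def test_lod_drop_null_reproducible(small_inputs, small_study):
    from famqtl.conditional_pipeline import lod_drop_null
    from famqtl.ibd import multipoint_ibd
    from famqtl.linkage import vc_linkage_scan

    trait, kin, dose, maf = small_inputs
    gm = small_study.genotypes
    common16 = [
        i for i in range(gm.n_markers)
        if gm.markers["marker_id"].iloc[i].startswith("c16")
    ]
    ibd = multipoint_ibd(small_study.pedigrees, gm.subset_markers(common16), "16", step_cm=8.0)
    curve = vc_linkage_scan(trait, kin, ibd)
    pool_cols = [m for m in dose.columns if m.startswith(("c1_", "c2_"))][:6]
    pool = dose[pool_cols]
    kw = dict(
        region_positions=curve.positions, n_samples=4, seed=77,
        warm_fits=curve.fits,
    )
    a = lod_drop_null(trait, kin, ibd, curve.mlod, 0.5, pool, **kw)
    b = lod_drop_null(trait, kin, ibd, curve.mlod, 0.5, pool, **kw)
    assert np.array_equal(a.null_drops, b.null_drops)
    assert a.sampled_markers == b.sampled_markers
    # pool smaller than requested: uses every SNP once
    c = lod_drop_null(
        trait, kin, ibd, curve.mlod, 0.5, pool.iloc[:, :2],
        region_positions=curve.positions, n_samples=10, seed=1,
        warm_fits=curve.fits,
    )
    assert c.n == 2


# -------------------------------------------------------------- analytics


def test_direction_binomial_strict_tail_values():
    assert direction_binomial(23, 16) == pytest.approx(0.0173, abs=5e-5)
    assert direction_binomial(23, 11) == pytest.approx(0.5, abs=1e-12)
    assert direction_binomial(23, 23) == 0.0
    # inclusive tail for comparison: P(X >= 16) is the milder ~0.047
    assert direction_binomial(23, 16, tail="inclusive") == pytest.approx(
        0.0466, abs=5e-4
    )
    with pytest.raises(ValueError):
        direction_binomial(10, 11)


def test_opposite_direction_probability():
    assert opposite_direction_prob(0.0) == 0.5
    assert opposite_direction_prob(0.25, 1.0) == pytest.approx(0.4013, abs=1e-4)
    assert opposite_direction_prob(1.96, 1.0) == pytest.approx(0.025, abs=1e-4)
    with pytest.raises(ValueError):
        opposite_direction_prob(0.5, 0.0)
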