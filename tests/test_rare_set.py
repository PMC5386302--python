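"""Burden / SKAT / SKAT-O set tests, weights, mixture-chi2, meta-analysis."""

import numpy as np
import pandas as pd
import pytest

from famqtl._mixture_chi2 import mixture_isf, mixture_sf
from famqtl.mixed_assoc import fit_lmm_assoc
from famqtl.pedigree_io import KinshipMatrix
from famqtl.rare_set_tests import (
    beta_weights,
    burden_test,
    meta_combine,
    skat_test,
    skato_test,
)


def _unrelated(n):
    samples = [(f"U{i}", "x") for i in range(n)]
    return KinshipMatrix(samples, 0.5 * np.eye(n)), pd.MultiIndex.from_tuples(samples)


def _toy_set(rng, n=200, k=5, maf=None, beta=None):
    kin, idx = _unrelated(n)
    maf = maf if maf is not None else rng.uniform(0.02, 0.1, k)
    G = rng.binomial(2, maf, size=(n, k)).astype(float)
    y = rng.standard_normal(n)
    if beta is not None:
        y = y + G @ beta
    return (
        pd.Series(y, index=idx),
        pd.DataFrame(G, index=idx, columns=[f"v{j}" for j in range(k)]),
        kin,
        maf,
    )


# ------------------------------------------------------------------ weights


def test_beta_weights_closed_forms():
    w = beta_weights(np.array([0.0, 0.0036, 0.5])).weights
    assert w[0] == pytest.approx(25.0, abs=1e-12)
    assert w[1] == pytest.approx(25 * (1 - 0.0036) ** 24, rel=1e-12)
    assert w[1] == pytest.approx(22.93, abs=0.01)
    assert w[2] == pytest.approx(25 * 0.5**24, rel=1e-12)
    assert w[2] == pytest.approx(1.49e-6, rel=0.01)


def test_weights_monotone_decreasing_in_maf(rng):
    maf = np.sort(rng.uniform(0, 0.49, 20))
    w = beta_weights(maf).weights
    assert np.all(np.diff(w) <= 0)
    with pytest.raises(ValueError):
        beta_weights(np.array([-0.1]))


# ----------------------------------------------------------------- identities


def test_single_variant_burden_equals_lmm(rng):
    y, G, kin, maf = _toy_set(rng, k=1, maf=np.array([0.2]))
    w = beta_weights(maf)
    rb = burden_test(y, G, w, kin)
    fit = fit_lmm_assoc(y, G["v0"] * w.weights[0], kin)
    assert abs(rb.p_burden - fit.p) < 1e-10


def test_single_variant_skat_equals_burden_score(rng):
    y, G, kin, maf = _toy_set(rng, k=1, maf=np.array([0.2]))
    w = beta_weights(maf)
    rb = burden_test(y, G, w, kin)
    rs = skat_test(y, G, w, kin)
    assert abs(rs.p_skat - rb.p_burden_score) < 1e-10


def test_skato_boundaries_match_skat_and_burden(rng):
    y, G, kin, maf = _toy_set(rng)
    w = beta_weights(maf)
    rs = skat_test(y, G, w, kin)
    rb = burden_test(y, G, w, kin)
    r0 = skato_test(y, G, w, kin, rho_grid=(0.0,))
    r1 = skato_test(y, G, w, kin, rho_grid=(1.0,))
    assert abs(r0.p_skato - rs.p_skat) < 1e-10
    assert abs(r1.p_skato - rb.p_burden_score) < 1e-10
    full = skato_test(y, G, w, kin)
    assert abs(full.p_per_rho[0] - rs.p_skat) < 1e-10
    assert abs(full.p_per_rho[-1] - rb.p_burden_score) < 1e-10
    assert full.p_skato >= 0.5 * full.p_per_rho.min()
    assert full.p_skato <= 1.0
    with pytest.raises(ValueError):
        skato_test(y, G, w, kin, rho_grid=())


def test_eigenvalues_sum_to_kernel_trace(rng):
    y, G, kin, maf = _toy_set(rng)
    w = beta_weights(maf)
    rs = skat_test(y, G, w, kin)
    # reconstruct the kernel trace independently from the score machinery
    from famqtl.rare_set_tests import _ingredients

    model, fit0, yv, X, Gm, S, M, poly = _ingredients(y, G, kin, None)
    K = (w.weights[:, None] * M) * w.weights[None, :]
    assert abs(rs.lambdas.sum() - np.trace(K)) < 1e-8


def test_results_reproducible(rng):
    y, G, kin, maf = _toy_set(rng)
    w = beta_weights(maf)
    a = skato_test(y, G, w, kin)
    b = skato_test(y, G, w, kin)
    assert a.p_skato == b.p_skato
    assert np.array_equal(a.p_per_rho, b.p_per_rho)


# ---------------------------------------------------------------- oracles


def test_skat_p_matches_permutations(rng):
    """Analytic mixture-chi2 p within 3 Monte-Carlo SEs of a 2,000-row
    permutation p on unrelated individuals."""
    y, G, kin, maf = _toy_set(rng, n=200, beta=np.array([0.3, 0, 0, -0.2, 0]))
    w = beta_weights(maf)
    rs = skat_test(y, G, w, kin)

    from famqtl.rare_set_tests import _ingredients

    model, fit0, yv, X, Gm, S, M, poly = _ingredients(y, G, kin, None)
    Py, project = model.null_projection(yv, X, fit0)
    q_obs = float(((w.weights * (Gm.T @ Py)) ** 2).sum())
    R = 2000
    perm_rng = np.random.default_rng(99)
    qs = np.empty(R)
    for r in range(R):
        Pp = Py[perm_rng.permutation(len(Py))]
        qs[r] = float(((w.weights * (Gm.T @ Pp)) ** 2).sum())
    p_hat = (1 + np.sum(qs >= q_obs)) / (1 + R)
    se = np.sqrt(p_hat * (1 - p_hat) / R)
    assert abs(rs.p_skat - p_hat) < 3 * se + 0.01


def test_mixture_chi2_against_simulation(rng):
    lam = np.array([1.0, 0.6, 0.25, 0.1])
    draws = (lam[None, :] * rng.chisquare(1, size=(200_000, 4))).sum(axis=1)
    for q in (2.0, 5.0, 9.0):
        p_emp = (draws > q).mean()
        se = np.sqrt(p_emp * (1 - p_emp) / len(draws))
        assert abs(mixture_sf(q, lam) - p_emp) < 4 * se + 2e-3


def test_mixture_isf_inverts_sf():
    lam = np.array([1.2, 0.5, 0.3])
    for p in (0.3, 0.05, 0.005):
        q = mixture_isf(p, lam)
        assert mixture_sf(q, lam) == pytest.approx(p, rel=0.15)


# ----------------------------------------------------------------- meta


def test_meta_single_study_is_identity():
    assert meta_combine([0.03]) == pytest.approx(0.03, rel=1e-12)


def test_meta_fisher_four_studies():
    stat = -2 * 4 * np.log(0.05)
    assert stat == pytest.approx(23.97, abs=0.01)
    assert meta_combine([0.05] * 4) == pytest.approx(0.0023, abs=2e-4)


def test_meta_adding_null_study_weakens_evidence():
    base = meta_combine([0.01, 0.02])
    assert meta_combine([0.01, 0.02, 1.0]) > base


def test_meta_stouffer_weighted():
    p = meta_combine([0.05, 0.5], method="stouffer", sample_sizes=[10000, 10])
    # dominated by the large study
    assert p < 0.1
    with pytest.raises(ValueError):
        meta_combine([])


def test_zero_p_clipped_not_crashing():
    assert 0 < meta_combine([0.0, 0.5]) < 1
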