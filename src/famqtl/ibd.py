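"""Multipoint IBD estimation via the inheritance-vector HMM.

For each family, the hidden state at a locus is the inheritance vector:
one bit per meiosis (paternal and maternal, for every nonfounder)
recording which grandparental allele was transmitted. Along a chromosome
the vector evolves as a Markov chain in which each bit flips
independently between adjacent positions with the Haldane recombination
fraction. The emission at a marker sums, over all assignments of alleles
to founder genes, the probability of assignments consistent with the
observed genotypes (missing genotypes are marginalized). A scaled
forward–backward pass yields the exact posterior distribution of the
inheritance vector on a cM grid, from which the expected proportion of
alleles shared IBD (pi-hat) — and the 0/1/2 sharing distribution — is
read off for every relative pair.

Exact enumeration is feasible up to a configurable bit complexity
(``2*nonfounders - founders``, default cap 16). Larger families fall back
to a Monte-Carlo mode: inheritance-vector paths are gene-dropped from the
recombination prior and weighted by their genotype likelihood
(importance sampling), which is unbiased but noisier; the effective
sample size of the weights is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .pedigree_io import GenotypeMatrix, Pedigree, haldane_theta

logger = logging.getLogger(__name__)

__all__ = ["FamilyIBD", "IBDResult", "multipoint_ibd", "BitComplexityError"]

_STATE_CHUNK = 4096  # states per emission block, bounds peak memory


class BitComplexityError(ValueError):
    """Pedigree too large for exact inheritance-vector enumeration."""


@dataclass
class FamilyIBD:
    """Posterior IBD sharing for one family along one chromosome."""

    fid: str
    ids: list[str]
    positions: np.ndarray  # cM, ascending
    pairs: list[tuple[int, int]]  # index pairs (i < j) into ids
    pi: np.ndarray  # (n_positions, n_pairs) expected proportion IBD
    kdist: np.ndarray | None = None  # (n_positions, n_pairs, 3) P(share 0/1/2)
    mode: str = "exact"
    ess: float | None = None  # MC effective sample size, None for exact

    def pi_matrix(self, pos_index: int) -> np.ndarray:
        """Dense (n, n) matrix of pi-hat at one position; diagonal 1."""
        n = len(self.ids)
        out = np.eye(n)
        for k, (i, j) in enumerate(self.pairs):
            out[i, j] = out[j, i] = self.pi[pos_index, k]
        return out


@dataclass
class IBDResult:
    """Per-family multipoint IBD posteriors on a common position grid."""

    chrom: str
    positions: np.ndarray
    families: dict[str, FamilyIBD] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for fid, fam in self.families.items():
            for k, (i, j) in enumerate(fam.pairs):
                for t, pos in enumerate(fam.positions):
                    rows.append(
                        (self.chrom, pos, fid, fam.ids[i], fam.ids[j], fam.pi[t, k])
                    )
        return pd.DataFrame(
            rows, columns=["chrom", "cm", "family_id", "id1", "id2", "pi_hat"]
        )


class _LanderGreen:
    """Inheritance-vector machinery for a single family.

    Meiosis bits are ordered (paternal, maternal) per nonfounder in
    topological order; bit value selects the transmitting parent's own
    paternal (0) or maternal (1) gene. Founder ``f`` owns founder-gene
    slots ``2f`` and ``2f+1``.
    """

    def __init__(self, ped: Pedigree):
        self.ped = ped
        self.ids = ped.ids
        self.n = len(self.ids)
        self._idx = {iid: k for k, iid in enumerate(self.ids)}
        self.founders = [iid for iid in self.ids if ped[iid].is_founder]
        self._founder_no = {iid: k for k, iid in enumerate(self.founders)}
        topo = [iid for iid in ped.topological_order if not ped[iid].is_founder]
        self.nonfounders = topo
        self.n_bits = 2 * len(topo)
        self.n_slots = 2 * len(self.founders)
        self.pairs = [
            (i, j) for i in range(self.n) for j in range(i + 1, self.n)
        ]

    # ------------------------------------------------------------- descent
    def slots_for(self, bits: np.ndarray) -> np.ndarray:
        """Founder-gene slot of each individual's (paternal, maternal) gene.

        ``bits``: (B, n_bits) array of inheritance vectors. Returns
        (B, n, 2) int16.
        """
        B = bits.shape[0]
        slot = np.empty((B, self.n, 2), dtype=np.int16)
        for iid in self.founders:
            i = self._idx[iid]
            f = self._founder_no[iid]
            slot[:, i, 0] = 2 * f
            slot[:, i, 1] = 2 * f + 1
        for k, iid in enumerate(self.nonfounders):
            i = self._idx[iid]
            ind = self.ped[iid]
            fi, mi = self._idx[ind.father], self._idx[ind.mother]
            pb = bits[:, 2 * k]
            mb = bits[:, 2 * k + 1]
            slot[:, i, 0] = np.where(pb == 0, slot[:, fi, 0], slot[:, fi, 1])
            slot[:, i, 1] = np.where(mb == 0, slot[:, mi, 0], slot[:, mi, 1])
        return slot

    def pair_share_counts(self, slot: np.ndarray) -> np.ndarray:
        """Number of alleles IBD (0/1/2) per pair from slots; (B, n_pairs)."""
        B = slot.shape[0]
        out = np.empty((B, len(self.pairs)), dtype=np.int8)
        for k, (i, j) in enumerate(self.pairs):
            si0, si1 = slot[:, i, 0], slot[:, i, 1]
            sj0, sj1 = slot[:, j, 0], slot[:, j, 1]
            out[:, k] = (
                (si0 == sj0).astype(np.int8)
                + (si0 == sj1)
                + (si1 == sj0)
                + (si1 == sj1)
            )
        return out

    # ------------------------------------------------------------ emission
    def emissions(
        self, bits: np.ndarray, calls: np.ndarray, freq2: np.ndarray
    ) -> np.ndarray:
        """P(observed genotypes | inheritance vector) for each row of bits.

        ``calls``: (n, T, 2) allele-index calls (-1 missing) aligned to
        ``self.ids``; ``freq2``: (T,) founder frequency of allele 2.
        Returns (B, T). Individuals with any missing allele at a marker
        are marginalized out at that marker.
        """
        B = bits.shape[0]
        T = calls.shape[1]
        nS = self.n_slots
        A = 1 << nS
        assign = ((np.arange(A)[:, None] >> np.arange(nS)[None, :]) & 1).astype(
            np.int8
        )  # (A, nS)
        slot = self.slots_for(bits)
        e = np.empty((B, T))
        for t in range(T):
            typed = [
                i for i in range(self.n) if calls[i, t, 0] >= 0 and calls[i, t, 1] >= 0
            ]
            f2 = freq2[t]
            pa = np.prod(np.where(assign == 1, f2, 1.0 - f2), axis=1)  # (A,)
            if not typed:
                e[:, t] = 1.0
                continue
            for lo in range(0, B, _STATE_CHUNK):
                hi = min(lo + _STATE_CHUNK, B)
                ok = np.ones((hi - lo, A), dtype=bool)
                for i in typed:
                    a0 = assign[:, slot[lo:hi, i, 0]].T  # (chunk, A)
                    a1 = assign[:, slot[lo:hi, i, 1]].T
                    g0, g1 = calls[i, t, 0], calls[i, t, 1]
                    ok &= ((a0 == g0) & (a1 == g1)) | ((a0 == g1) & (a1 == g0))
                e[lo:hi, t] = ok @ pa
        return e

    # --------------------------------------------------------- transitions
    def transmit(self, p: np.ndarray, theta: float) -> np.ndarray:
        """One HMM step: each meiosis bit flips independently w.p. theta."""
        if self.n_bits == 0 or theta == 0.0:
            return p
        q = p.reshape((2,) * self.n_bits)
        for ax in range(self.n_bits):
            q = (1.0 - theta) * q + theta * np.flip(q, axis=ax)
        return q.reshape(-1)


def _family_calls(
    ped: Pedigree, gm: GenotypeMatrix, marker_index: np.ndarray
) -> np.ndarray:
    """(n_members, T, 2) calls aligned to pedigree order; absent => missing."""
    T = len(marker_index)
    calls = np.full((len(ped), T, 2), -1, dtype=np.int8)
    for k, iid in enumerate(ped.ids):
        key = (ped.fid, iid)
        if key in gm._sample_index:
            calls[k] = gm.calls[gm._sample_index[key]][marker_index]
    return calls


def _exact_family(
    lg: _LanderGreen,
    calls: np.ndarray,
    freq2: np.ndarray,
    positions: np.ndarray,
    marker_at: np.ndarray,
    want_kdist: bool,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Forward–backward over all 2^n_bits inheritance vectors."""
    m = lg.n_bits
    S = 1 << m
    P = len(positions)
    bits = ((np.arange(S)[:, None] >> np.arange(m)[None, :]) & 1).astype(np.uint8)
    share = lg.pair_share_counts(lg.slots_for(bits)).astype(np.float64)  # (S, npairs)

    emis_markers = lg.emissions(bits, calls, freq2) if calls.shape[1] else None
    thetas = np.asarray(haldane_theta(np.diff(positions) / 100.0), dtype=float)

    def emis_at(t: int) -> np.ndarray | None:
        mk = marker_at[t]
        return None if mk < 0 else emis_markers[:, mk]

    # forward (scaled)
    alphas = np.empty((P, S))
    a = np.full(S, 1.0 / S)
    for t in range(P):
        if t > 0:
            a = lg.transmit(a, thetas[t - 1])
        e = emis_at(t)
        if e is not None:
            a = a * e
        tot = a.sum()
        if tot <= 0:
            raise ValueError(
                f"family {lg.ped.fid}: genotype data impossible under the "
                "pedigree (zero likelihood) — check Mendelian errors"
            )
        a = a / tot
        alphas[t] = a

    # backward, accumulate posteriors
    pi = np.empty((P, len(lg.pairs)))
    kdist = np.empty((P, len(lg.pairs), 3)) if want_kdist else None
    b = np.ones(S)
    for t in range(P - 1, -1, -1):
        post = alphas[t] * b
        post /= post.sum()
        pi[t] = (post @ share) / 2.0
        if want_kdist:
            for kk in range(3):
                kdist[t, :, kk] = post @ (share == kk)
        if t > 0:
            e = emis_at(t)
            bb = b if e is None else b * e
            b = lg.transmit(bb, thetas[t - 1])
            b /= b.max()
    return pi, kdist


def _mc_family(
    lg: _LanderGreen,
    calls: np.ndarray,
    freq2: np.ndarray,
    positions: np.ndarray,
    marker_at: np.ndarray,
    n_draws: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Likelihood-weighted conditional gene-dropping (importance sampling).

    Paths of the inheritance vector are simulated from the recombination
    prior and weighted by the product of marker emissions along the path.
    Unbiased for the posterior mean; weight degeneracy is reported via the
    effective sample size.
    """
    m = lg.n_bits
    P = len(positions)
    thetas = np.asarray(haldane_theta(np.diff(positions) / 100.0), dtype=float)
    bits = rng.integers(0, 2, size=(n_draws, m), dtype=np.uint8)
    logw = np.zeros(n_draws)
    packed = np.empty((P, n_draws), dtype=np.uint64)
    weights_bits = (1 << np.arange(m, dtype=np.uint64))[None, :]
    for t in range(P):
        if t > 0 and thetas[t - 1] > 0:
            bits ^= (rng.random((n_draws, m)) < thetas[t - 1]).astype(np.uint8)
        packed[t] = (bits.astype(np.uint64) * weights_bits).sum(axis=1)
        mk = marker_at[t]
        if mk >= 0:
            e = lg.emissions(bits, calls[:, [mk]], freq2[[mk]])[:, 0]
            with np.errstate(divide="ignore"):
                logw += np.log(e)
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    ess = float(1.0 / np.sum(w**2))
    if ess < 200:
        logger.warning(
            "family %s: MC IBD effective sample size %.0f of %d draws — "
            "increase n_draws for stable estimates",
            lg.ped.fid,
            ess,
            n_draws,
        )
    pi = np.empty((P, len(lg.pairs)))
    for t in range(P):
        b = ((packed[t][:, None] >> np.arange(m, dtype=np.uint64)[None, :]) & 1).astype(
            np.uint8
        )
        share = lg.pair_share_counts(lg.slots_for(b)).astype(float)
        pi[t] = (w @ share) / 2.0
    return pi, ess


def multipoint_ibd(
    pedigrees: Mapping[str, Pedigree],
    gm: GenotypeMatrix,
    chrom: str | None = None,
    *,
    step_cm: float = 1.0,
    positions: np.ndarray | None = None,
    bit_cap: int = 16,
    mode: str = "auto",
    n_draws: int = 10000,
    seed: int | None = None,
    freq_pseudocount: float = 0.5,
    want_kdist: bool = False,
) -> IBDResult:
    """Posterior expected IBD sharing along one chromosome.

    Parameters
    ----------
    chrom
        Chromosome to scan (defaults to the only chromosome present).
    step_cm, positions
        Evaluation grid; by default every ``step_cm`` across the marker
        span, plus every marker position.
    bit_cap
        Maximum bit complexity (``2*nonfounders - founders``) for exact
        enumeration. Families beyond it use Monte-Carlo mode when
        ``mode='auto'`` or ``'mc'``; ``mode='exact'`` raises
        :class:`BitComplexityError` advising pedigree splitting.
    freq_pseudocount
        Smoothing added to founder allele counts so unseen alleles keep
        positive emission probability.
    """
    chroms = list(dict.fromkeys(gm.markers["chrom"].astype(str)))
    if chrom is None:
        if len(chroms) != 1:
            raise ValueError(f"chrom must be given (found {chroms})")
        chrom = chroms[0]
    sel = np.flatnonzero((gm.markers["chrom"].astype(str) == str(chrom)).to_numpy())
    if len(sel) == 0:
        raise ValueError(f"no markers on chromosome {chrom}")
    cm = gm.markers["cm"].to_numpy(float)[sel]
    order = np.argsort(cm, kind="stable")
    sel = sel[order]
    cm = cm[order]

    founder_rows = [
        gm._sample_index[(fid, iid)]
        for fid, ped in pedigrees.items()
        for iid in ped.founders
        if (fid, iid) in gm._sample_index
    ]
    freq2 = gm.allele2_freq(
        rows=np.asarray(founder_rows, int), pseudocount=freq_pseudocount
    )[sel]

    if positions is None:
        lo, hi = cm[0], cm[-1]
        grid = np.arange(lo, hi + 1e-9, step_cm)
    else:
        grid = np.asarray(positions, dtype=float)
    # markers always participate in the forward-backward pass
    positions = np.unique(np.concatenate([grid, cm]))
    # map each evaluation position to a marker index (or -1)
    marker_at = np.full(len(positions), -1, dtype=int)
    for k, c in enumerate(cm):
        hit = np.flatnonzero(np.isclose(positions, c))
        if len(hit):
            marker_at[hit[0]] = k
    used_markers = marker_at[marker_at >= 0]

    rng = np.random.default_rng(seed)
    result = IBDResult(chrom=str(chrom), positions=positions)
    for fid, ped in pedigrees.items():
        lg = _LanderGreen(ped)
        calls = _family_calls(ped, gm, sel)
        # exact enumeration runs over 2^(2*nonfounders) states (no
        # founder-phase reduction); cap the actual state space too
        exact_ok = ped.bit_complexity <= bit_cap and lg.n_bits <= 20
        use_mc = mode == "mc" or (mode == "auto" and not exact_ok)
        if not exact_ok and mode == "exact":
            raise BitComplexityError(
                f"family {fid}: bit complexity {ped.bit_complexity} exceeds cap "
                f"{bit_cap}; split the pedigree or use mode='auto'/'mc'"
            )
        if use_mc:
            pi, ess = _mc_family(
                lg, calls, freq2, positions, marker_at, n_draws, rng
            )
            fam = FamilyIBD(
                fid=fid,
                ids=lg.ids,
                positions=positions,
                pairs=lg.pairs,
                pi=pi,
                mode="mc",
                ess=ess,
            )
        else:
            pi, kdist = _exact_family(
                lg, calls, freq2, positions, marker_at, want_kdist
            )
            fam = FamilyIBD(
                fid=fid,
                ids=lg.ids,
                positions=positions,
                pairs=lg.pairs,
                pi=pi,
                kdist=kdist,
            )
        result.families[fid] = fam
    return result
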