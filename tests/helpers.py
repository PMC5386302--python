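"""Shared test utilities: small pedigrees, gene drops, and independent
brute-force oracles kept deliberately naive (itertools enumeration, dense
transition matrices) so they share no code path with the package."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from famqtl.pedigree_io import GenotypeMatrix, Individual, Pedigree, haldane_theta
from famqtl.synthetic_data import _drop_family


def nuclear(fid: str, n_children: int, sexes=None) -> Pedigree:
    members = [
        Individual("fa", fid, sex="male"),
        Individual("mo", fid, sex="female"),
    ]
    for c in range(n_children):
        sex = sexes[c] if sexes else ("male" if c % 2 == 0 else "female")
        members.append(Individual(f"c{c + 1}", fid, father="fa", mother="mo", sex=sex))
    return Pedigree(members)


def three_gen(fid: str = "T") -> Pedigree:
    """7-member three-generation pedigree (bit complexity 5)."""
    return Pedigree(
        [
            Individual("gf", fid, sex="male"),
            Individual("gm", fid, sex="female"),
            Individual("c1", fid, "gf", "gm", sex="male"),
            Individual("c2", fid, "gf", "gm", sex="female"),
            Individual("s1", fid, sex="female"),
            Individual("g1", fid, "c1", "s1"),
            Individual("g2", fid, "c1", "s1"),
        ]
    )


def four_gen(fid: str = "Q") -> Pedigree:
    return Pedigree(
        [
            Individual("a1", fid, sex="male"),
            Individual("a2", fid, sex="female"),
            Individual("b1", fid, "a1", "a2", sex="male"),
            Individual("b2", fid, sex="female"),
            Individual("c1", fid, "b1", "b2", sex="female"),
            Individual("c2", fid, "b1", "b2", sex="male"),
            Individual("c3", fid, sex="male"),
            Individual("d1", fid, "c3", "c1", sex="female"),
            Individual("d2", fid, "c3", "c1", sex="male"),
        ]
    )


def marker_table(cms, chrom="1", freq=0.4):
    rows = [
        (f"m{k}", chrom, int(c * 1e6) + 1, float(c), "1", "2", freq, None)
        for k, c in enumerate(cms)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "marker_id", "chrom", "bp", "cm", "allele1", "allele2",
            "founder_freq", "restrict_family",
        ],
    )


def dropped_gm(ped: Pedigree, cms, rng, freq=0.4, missing=0.0) -> GenotypeMatrix:
    """Mendelian-consistent genotypes for one family via gene dropping."""
    mt = marker_table(cms, freq=freq)
    calls = _drop_family(ped, mt, rng, {})
    if missing:
        calls[rng.random(calls.shape) < missing] = -1
    samples = [(ped.fid, iid) for iid in ped.ids]
    return GenotypeMatrix(
        samples, mt[["marker_id", "chrom", "bp", "cm", "allele1", "allele2"]], calls
    )


def mc_kinship(ped: Pedigree, n_reps: int, rng) -> np.ndarray:
    """Monte-Carlo kinship: single-locus gene drops with labelled founder
    alleles; phi-hat(i,j) = E[#IBD allele matches among the 4 pairings]/4."""
    founders = ped.founders
    nonf = [i for i in ped.topological_order if not ped[i].is_founder]
    idx = {iid: k for k, iid in enumerate(ped.ids)}
    n = len(ped.ids)
    slot = np.empty((n_reps, n, 2), dtype=np.int16)
    for f, iid in enumerate(founders):
        slot[:, idx[iid], 0] = 2 * f
        slot[:, idx[iid], 1] = 2 * f + 1
    for iid in nonf:
        ind = ped[iid]
        for gi, parent in ((0, ind.father), (1, ind.mother)):
            pick = rng.integers(0, 2, size=n_reps)
            ps = slot[:, idx[parent], :]
            slot[:, idx[iid], gi] = np.where(pick == 0, ps[:, 0], ps[:, 1])
    phi = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            matches = sum(
                (slot[:, a, x] == slot[:, b, y]).mean()
                for x in range(2)
                for y in range(2)
            )
            phi[a, b] = matches / 4.0
    return phi


def brute_ibd(ped: Pedigree, calls: np.ndarray, freq2: np.ndarray,
              positions: np.ndarray, marker_cm: np.ndarray) -> list[np.ndarray]:
    """Reference multipoint IBD by full enumeration: dense Hamming-distance
    transition matrices and itertools emission sums."""
    ids = ped.ids
    n = len(ids)
    founders = [i for i in ids if ped[i].is_founder]
    nonf = [i for i in ped.topological_order if not ped[i].is_founder]
    m = 2 * len(nonf)
    S = 2 ** m
    F = len(founders)
    fno = {f: k for k, f in enumerate(founders)}

    def slots(v):
        bits = [(v >> b) & 1 for b in range(m)]
        sl = {f: (2 * fno[f], 2 * fno[f] + 1) for f in founders}
        for k, iid in enumerate(nonf):
            ind = ped[iid]
            sl[iid] = (sl[ind.father][bits[2 * k]], sl[ind.mother][bits[2 * k + 1]])
        return [sl[i] for i in ids]

    def emission(v, t):
        sl = slots(v)
        tot = 0.0
        for assign in itertools.product([0, 1], repeat=2 * F):
            p = 1.0
            for a in assign:
                p *= freq2[t] if a == 1 else 1 - freq2[t]
            ok = True
            for i in range(n):
                g = calls[i, t]
                if g[0] < 0 or g[1] < 0:
                    continue
                if sorted([assign[sl[i][0]], assign[sl[i][1]]]) != sorted(g.tolist()):
                    ok = False
                    break
            if ok:
                tot += p
        return tot

    def pair_pi(v):
        sl = slots(v)
        out = np.eye(n)
        for a in range(n):
            for b in range(n):
                if a != b:
                    out[a, b] = sum(x == y for x in sl[a] for y in sl[b]) / 2.0
        return out

    states = np.arange(S)
    ham = np.zeros((S, S), dtype=np.int16)
    for b in range(m):
        ham += (((states[:, None] >> b) & 1) != ((states[None, :] >> b) & 1)).astype(
            np.int16
        )
    marker_at = {}
    for k, c in enumerate(marker_cm):
        for t, p in enumerate(positions):
            if abs(p - c) < 1e-9:
                marker_at[t] = k
    T = len(positions)
    E = np.ones((T, S))
    for t, mk in marker_at.items():
        for v in range(S):
            E[t, v] = emission(v, mk)
    alphas = np.zeros((T, S))
    a = np.full(S, 1.0 / S) * E[0]
    a /= a.sum()
    alphas[0] = a
    for t in range(1, T):
        th = haldane_theta((positions[t] - positions[t - 1]) / 100.0)
        Tr = th ** ham * (1 - th) ** (m - ham)
        a = (a @ Tr) * E[t]
        a /= a.sum()
        alphas[t] = a
    pis = []
    b = np.ones(S)
    betas = [None] * T
    betas[T - 1] = b
    for t in range(T - 2, -1, -1):
        th = haldane_theta((positions[t + 1] - positions[t]) / 100.0)
        Tr = th ** ham * (1 - th) ** (m - ham)
        b = Tr @ (b * E[t + 1])
        b /= b.max()
        betas[t] = b
    for t in range(T):
        post = alphas[t] * betas[t]
        post /= post.sum()
        pi = np.zeros((n, n))
        for v in range(S):
            if post[v] > 0:
                pi += post[v] * pair_pi(v)
        pis.append(pi)
    return pis
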