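"""Pedigrees, genotypes, genetic maps, phenotypes, and kinship.

This module provides the containers shared by every analysis stage:

* :class:`Pedigree` — one family's structure, validated (parents both
  present or both missing, no cycles), with founder bookkeeping and the
  Lander–Green bit complexity ``2*nonfounders - founders``.
* :class:`GenotypeMatrix` — biallelic marker calls for all individuals,
  with physical (bp) and genetic (cM) coordinates.
* :class:`GeneticMap` — per-chromosome cM positions and Haldane
  recombination fractions for the multipoint HMM.
* :class:`KinshipMatrix` — expected relatedness Phi; ``2*Phi`` scales the
  polygenic covariance in every mixed model downstream.

File formats are the whitespace-delimited PLINK text PED/MAP dialect
("0" = missing allele / unknown sex / missing parent) and, optionally,
VCF (via cyvcf2) with family structure supplied as a 6-column FAM table.
Autosomal, non-looped pedigrees only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "GenotypeMatrix",
    "GeneticMap",
    "KinshipMatrix",
    "haldane_theta",
    "read_ped_map",
    "write_ped_map",
    "read_fam",
    "read_vcf",
    "read_phenotypes",
    "compute_kinship",
    "check_mendelian",
    "ibs_relatedness_report",
]

MISSING = "0"

_SEX_FROM_CODE = {"1": "male", "2": "female"}
_CODE_FROM_SEX = {"male": "1", "female": "2", "unknown": "0"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or malformed files."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father``/``mother`` are ``None`` for founders; a named parent must
    exist in the same family (or is synthesized in lenient mode).
    """

    iid: str
    fid: str
    father: str | None = None
    mother: str | None = None
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if (self.father is None) != (self.mother is None):
            raise PedigreeError(
                f"individual {self.fid}:{self.iid}: parents must be both "
                "present or both missing"
            )
        if self.sex not in ("male", "female", "unknown"):
            raise PedigreeError(f"invalid sex {self.sex!r}")

    @property
    def is_founder(self) -> bool:
        return self.father is None


class Pedigree:
    """A single family, validated and topologically ordered.

    Parameters
    ----------
    individuals
        Members in input order. Named parents must be members unless
        ``lenient`` is set, in which case missing parents are synthesized
        as founders of unknown sex.
    """

    def __init__(self, individuals: Sequence[Individual], *, lenient: bool = False):
        if not individuals:
            raise PedigreeError("empty pedigree")
        fids = {ind.fid for ind in individuals}
        if len(fids) != 1:
            raise PedigreeError(f"mixed family ids in one pedigree: {sorted(fids)}")
        self.fid = individuals[0].fid

        members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.iid in members:
                raise PedigreeError(f"duplicated individual id {self.fid}:{ind.iid}")
            members[ind.iid] = ind

        # resolve missing parents
        synthesized: list[Individual] = []
        for ind in list(members.values()):
            for pid, psex in ((ind.father, "male"), (ind.mother, "female")):
                if pid is not None and pid not in members:
                    if not lenient:
                        raise PedigreeError(
                            f"{self.fid}:{ind.iid} names parent {pid!r} absent "
                            "from the family (use lenient mode to synthesize)"
                        )
                    founder = Individual(iid=pid, fid=self.fid, sex=psex)
                    members[pid] = founder
                    synthesized.append(founder)
        if synthesized:
            logger.warning(
                "family %s: synthesized %d missing parents as founders",
                self.fid,
                len(synthesized),
            )

        self.members: list[Individual] = list(members.values())
        self._by_id = members
        self._topo_order = self._toposort()

    def _toposort(self) -> list[str]:
        """Kahn's algorithm; raises on cyclic (self-ancestral) pedigrees."""
        indeg = {ind.iid: 0 for ind in self.members}
        children: dict[str, list[str]] = {ind.iid: [] for ind in self.members}
        for ind in self.members:
            if ind.father is not None:
                indeg[ind.iid] = 2
                children[ind.father].append(ind.iid)
                children[ind.mother].append(ind.iid)
        queue = [iid for iid, d in indeg.items() if d == 0]
        order: list[str] = []
        while queue:
            iid = queue.pop()
            order.append(iid)
            for ch in children[iid]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(order) != len(self.members):
            raise PedigreeError(f"family {self.fid}: pedigree contains a cycle")
        return order

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    @property
    def ids(self) -> list[str]:
        return [ind.iid for ind in self.members]

    @property
    def founders(self) -> list[str]:
        return [ind.iid for ind in self.members if ind.is_founder]

    @property
    def nonfounders(self) -> list[str]:
        return [ind.iid for ind in self.members if not ind.is_founder]

    @property
    def topological_order(self) -> list[str]:
        """Member ids with parents before children."""
        return list(self._topo_order)

    @property
    def bit_complexity(self) -> int:
        """Lander–Green complexity ``2*nonfounders - founders``."""
        return 2 * len(self.nonfounders) - len(self.founders)

    def kinship(self) -> tuple[list[str], np.ndarray]:
        """Kinship coefficients by the standard recursive (tabular) method.

        Phi(i,i) = 1/2 (1 + Phi(father_i, mother_i));
        Phi(i,j) = 1/2 (Phi(father_i, j) + Phi(mother_i, j)) for j
        processed before i. Founders are mutually unrelated and non-inbred.
        """
        order = self._topo_order
        idx = {iid: k for k, iid in enumerate(order)}
        n = len(order)
        phi = np.zeros((n, n))
        for k, iid in enumerate(order):
            ind = self._by_id[iid]
            if ind.is_founder:
                phi[k, k] = 0.5
            else:
                f, m = idx[ind.father], idx[ind.mother]
                phi[k, k] = 0.5 * (1.0 + phi[f, m])
                for j in range(k):
                    phi[k, j] = phi[j, k] = 0.5 * (phi[f, j] + phi[m, j])
        # return in member order, not topological order
        perm = [idx[ind.iid] for ind in self.members]
        return self.ids, phi[np.ix_(perm, perm)]


def haldane_theta(d: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: recombination fraction for distance d Morgans.

    theta = (1 - exp(-2 d)) / 2, so theta(0) = 0 and theta -> 1/2 as
    d -> infinity (no interference assumed).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    theta = 0.5 * (1.0 - np.exp(-2.0 * d))
    return float(theta) if theta.ndim == 0 else theta


class GeneticMap:
    """Per-chromosome genetic positions (cM) with Haldane recombination.

    Positions must be non-decreasing within a chromosome; inter-marker
    recombination fractions are theta_k = haldane_theta(delta_cM / 100).
    """

    def __init__(self, positions: Mapping[str, np.ndarray]):
        self.positions: dict[str, np.ndarray] = {}
        for chrom, cm in positions.items():
            cm = np.asarray(cm, dtype=float)
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chromosome {chrom}: cM positions decrease")
            self.positions[chrom] = cm

    @classmethod
    def from_markers(cls, markers: pd.DataFrame) -> "GeneticMap":
        return cls(
            {
                chrom: grp["cm"].to_numpy(float)
                for chrom, grp in markers.groupby("chrom", sort=False)
            }
        )

    def thetas(self, chrom: str) -> np.ndarray:
        """Recombination fractions between adjacent markers of ``chrom``."""
        d_morgans = np.diff(self.positions[chrom]) / 100.0
        return np.asarray(haldane_theta(d_morgans), dtype=float)


class GenotypeMatrix:
    """Biallelic calls for ``samples`` at ``markers``.

    ``calls`` has shape (n_samples, n_markers, 2) with entries 0 (allele1),
    1 (allele2) or -1 (missing); the two entries of a call are unordered.
    """

    def __init__(
        self,
        samples: Sequence[tuple[str, str]],
        markers: pd.DataFrame,
        calls: np.ndarray,
    ):
        required = {"marker_id", "chrom", "bp", "cm", "allele1", "allele2"}
        missing_cols = required - set(markers.columns)
        if missing_cols:
            raise ValueError(f"markers table lacks columns {sorted(missing_cols)}")
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(markers), 2):
            raise ValueError("calls shape does not match samples x markers x 2")
        for chrom, grp in markers.groupby("chrom", sort=False):
            if np.any(np.diff(grp["cm"].to_numpy(float)) < 0):
                raise ValueError(f"chromosome {chrom}: cM not non-decreasing")
        self.samples = list(samples)
        self.markers = markers.reset_index(drop=True)
        self.calls = calls
        self._sample_index = {s: k for k, s in enumerate(self.samples)}

    # ---------------------------------------------------------------- basic
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, fid: str, iid: str) -> int:
        return self._sample_index[(fid, iid)]

    def marker_index(self, marker_id: str) -> int:
        hits = np.flatnonzero((self.markers["marker_id"] == marker_id).to_numpy())
        if len(hits) == 0:
            raise KeyError(f"marker {marker_id!r} not in genotype data")
        return int(hits[0])

    def genetic_map(self) -> GeneticMap:
        return GeneticMap.from_markers(self.markers)

    def subset_markers(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            self.samples, self.markers.iloc[index], self.calls[:, index, :]
        )

    def subset_samples(self, which: Sequence[tuple[str, str]]) -> "GenotypeMatrix":
        rows = [self._sample_index[s] for s in which]
        return GenotypeMatrix(list(which), self.markers, self.calls[rows])

    # ------------------------------------------------------------- derived
    def allele2_freq(self, rows: np.ndarray | None = None, pseudocount: float = 0.0) -> np.ndarray:
        """Frequency of allele2 per marker, optionally on a row subset.

        ``pseudocount`` is added to both allele counts (smoothing for HMM
        founder frequencies so unseen alleles keep positive mass).
        """
        calls = self.calls if rows is None else self.calls[rows]
        observed = calls >= 0
        n2 = (calls == 1).sum(axis=(0, 2)).astype(float)
        tot = observed.sum(axis=(0, 2)).astype(float)
        return (n2 + pseudocount) / np.maximum(tot + 2 * pseudocount, 1e-300)

    def dosage(self) -> np.ndarray:
        """Allele2 counts per sample x marker; NaN where any allele missing."""
        d = self.calls.sum(axis=2).astype(float)
        d[(self.calls < 0).any(axis=2)] = np.nan
        return d

    def minor_dosage(self) -> tuple[np.ndarray, np.ndarray]:
        """(dosage of minor allele, MAF per marker).

        The minor allele is whichever of allele1/allele2 is less frequent
        in the full sample (ties keep allele2).
        """
        d = self.dosage()
        f2 = self.allele2_freq()
        flip = f2 > 0.5
        d[:, flip] = 2.0 - d[:, flip]
        maf = np.where(flip, 1.0 - f2, f2)
        return d, maf


class KinshipMatrix:
    """Block-diagonal kinship for the full sample, indexed by (fid, iid)."""

    def __init__(self, samples: Sequence[tuple[str, str]], phi: np.ndarray):
        phi = np.asarray(phi, dtype=float)
        if phi.shape != (len(samples), len(samples)):
            raise ValueError("phi shape mismatch")
        if not np.allclose(phi, phi.T):
            raise ValueError("kinship matrix must be symmetric")
        self.samples = list(samples)
        self.phi = phi
        self._index = {s: k for k, s in enumerate(self.samples)}

    @property
    def two_phi(self) -> np.ndarray:
        """Expected additive relationship 2*Phi (polygenic covariance scale)."""
        return 2.0 * self.phi

    def index(self, fid: str, iid: str) -> int:
        return self._index[(fid, iid)]

    def subset(self, which: Sequence[tuple[str, str]]) -> "KinshipMatrix":
        rows = [self._index[s] for s in which]
        return KinshipMatrix(list(which), self.phi[np.ix_(rows, rows)])

    def to_tsv(self, path) -> None:
        ids = [f"{f}:{i}" for f, i in self.samples]
        df = pd.DataFrame(self.phi, index=ids, columns=ids)
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        samples = [tuple(s.split(":", 1)) for s in df.index]
        return cls(samples, df.to_numpy(float))


def compute_kinship(pedigrees: Mapping[str, Pedigree]) -> KinshipMatrix:
    """Assemble the block-diagonal kinship matrix over all families."""
    samples: list[tuple[str, str]] = []
    blocks: list[np.ndarray] = []
    for fid, ped in pedigrees.items():
        ids, phi = ped.kinship()
        samples.extend((fid, iid) for iid in ids)
        blocks.append(phi)
    n = len(samples)
    full = np.zeros((n, n))
    at = 0
    for blk in blocks:
        k = blk.shape[0]
        full[at : at + k, at : at + k] = blk
        at += k
    return KinshipMatrix(samples, full)


# ----------------------------------------------------------------- file I/O


def _parse_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise PedigreeError(
                    f"{map_path}: line {lineno}: expected 4 fields, got {len(parts)}"
                )
            chrom, mid, cm, bp = parts
            rows.append((mid, chrom, int(bp), float(cm)))
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "bp", "cm"])


def read_ped_map(
    ped_path, map_path, *, lenient: bool = False
) -> tuple[dict[str, Pedigree], GenotypeMatrix]:
    """Read whitespace-delimited PED/MAP files.

    PED columns: FID IID FATHER MOTHER SEX PHENO then two allele codes per
    marker; "0" marks missing alleles, parents and unknown sex. Returns one
    :class:`Pedigree` per family plus the genotype matrix. Allele codes are
    collected per marker; more than two observed codes is an error.
    """
    markers = _parse_map(map_path)
    m = len(markers)
    samples: list[tuple[str, str]] = []
    fam_members: dict[str, list[Individual]] = {}
    raw_calls: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise PedigreeError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields, "
                    f"got {len(parts)}"
                )
            fid, iid, fat, mot, sex_code = parts[:5]
            key = (fid, iid)
            if key in set(samples):
                raise PedigreeError(
                    f"{ped_path}: line {lineno}: duplicated individual {fid}:{iid}"
                )
            ind = Individual(
                iid=iid,
                fid=fid,
                father=None if fat == MISSING else fat,
                mother=None if mot == MISSING else mot,
                sex=_SEX_FROM_CODE.get(sex_code, "unknown"),
            )
            fam_members.setdefault(fid, []).append(ind)
            samples.append(key)
            raw_calls.append(parts[6:])

    alleles: list[list[str]] = [[] for _ in range(m)]
    calls = np.full((len(samples), m, 2), -1, dtype=np.int8)
    for si, row in enumerate(raw_calls):
        for mi in range(m):
            for slot in range(2):
                code = row[2 * mi + slot]
                if code == MISSING:
                    continue
                if code not in alleles[mi]:
                    if len(alleles[mi]) == 2:
                        raise PedigreeError(
                            f"marker {markers['marker_id'][mi]}: more than two "
                            f"allele codes observed (third: {code!r})"
                        )
                    alleles[mi].append(code)
                calls[si, mi, slot] = alleles[mi].index(code)
    # normalize allele order lexicographically so round trips are stable
    for mi in range(m):
        if len(alleles[mi]) == 2 and alleles[mi][0] > alleles[mi][1]:
            alleles[mi].reverse()
            sel = calls[:, mi, :] >= 0
            calls[:, mi, :][sel] = 1 - calls[:, mi, :][sel]
        while len(alleles[mi]) < 2:
            alleles[mi].append(MISSING)
    markers["allele1"] = [a[0] for a in alleles]
    markers["allele2"] = [a[1] for a in alleles]

    pedigrees = {
        fid: Pedigree(members, lenient=lenient) for fid, members in fam_members.items()
    }
    gm = GenotypeMatrix(samples, markers, calls)
    return pedigrees, gm


def write_ped_map(
    pedigrees: Mapping[str, Pedigree], gm: GenotypeMatrix, ped_path, map_path
) -> None:
    """Write PED/MAP in the dialect accepted by :func:`read_ped_map`."""
    with open(map_path, "w") as fh:
        for _, r in gm.markers.iterrows():
            fh.write(f"{r['chrom']}\t{r['marker_id']}\t{r['cm']:.6g}\t{int(r['bp'])}\n")
    allele_codes = gm.markers[["allele1", "allele2"]].to_numpy(str)
    with open(ped_path, "w") as fh:
        for fid, ped in pedigrees.items():
            for ind in ped.members:
                row = gm.calls[gm.sample_index(fid, ind.iid)]
                fields = [
                    fid,
                    ind.iid,
                    ind.father or MISSING,
                    ind.mother or MISSING,
                    _CODE_FROM_SEX[ind.sex],
                    "-9",
                ]
                for mi in range(gm.n_markers):
                    for slot in range(2):
                        a = row[mi, slot]
                        fields.append(MISSING if a < 0 else allele_codes[mi, a])
                fh.write(" ".join(fields) + "\n")


def read_fam(fam_path, *, lenient: bool = False) -> dict[str, Pedigree]:
    """Read family structure from a 6-column FAM (PED without genotypes)."""
    fam_members: dict[str, list[Individual]] = {}
    with open(fam_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 5:
                raise PedigreeError(f"{fam_path}: line {lineno}: too few fields")
            fid, iid, fat, mot, sex_code = parts[:5]
            fam_members.setdefault(fid, []).append(
                Individual(
                    iid=iid,
                    fid=fid,
                    father=None if fat == MISSING else fat,
                    mother=None if mot == MISSING else mot,
                    sex=_SEX_FROM_CODE.get(sex_code, "unknown"),
                )
            )
    return {f: Pedigree(m, lenient=lenient) for f, m in fam_members.items()}


def read_vcf(
    vcf_path, pedigrees: Mapping[str, Pedigree]
) -> GenotypeMatrix:
    """Read biallelic sites from a VCF into the PED/MAP representation.

    VCF sample names must match individual ids, which must be unique across
    families. Genetic positions are taken from the INFO field ``CM`` when
    present, else set to bp/1e6 (1 cM/Mb). Multi-allelic sites are skipped
    with a log entry.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(vcf_path))
    iid_to_fid = {
        ind.iid: fid for fid, ped in pedigrees.items() for ind in ped.members
    }
    samples = []
    for name in vcf.samples:
        if name not in iid_to_fid:
            raise PedigreeError(f"VCF sample {name!r} absent from pedigrees")
        samples.append((iid_to_fid[name], name))
    rows, calls = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.info("skipping multi-allelic site %s", var.ID or var.POS)
            continue
        cm = var.INFO.get("CM")
        rows.append(
            (
                var.ID or f"{var.CHROM}:{var.POS}",
                str(var.CHROM),
                int(var.POS),
                float(cm) if cm is not None else var.POS / 1e6,
                var.REF,
                var.ALT[0],
            )
        )
        site = np.full((len(samples), 2), -1, dtype=np.int8)
        gts = var.genotype.array()
        site[:, 0] = np.where(gts[:, 0] < 0, -1, np.minimum(gts[:, 0], 1))
        site[:, 1] = np.where(gts[:, 1] < 0, -1, np.minimum(gts[:, 1], 1))
        calls.append(site)
    markers = pd.DataFrame(
        rows, columns=["marker_id", "chrom", "bp", "cm", "allele1", "allele2"]
    )
    arr = (
        np.stack(calls, axis=1)
        if calls
        else np.empty((len(samples), 0, 2), dtype=np.int8)
    )
    return GenotypeMatrix(samples, markers, arr)


def read_phenotypes(path) -> pd.DataFrame:
    """Read the phenotype/covariate TSV (one row per individual).

    Requires ``family_id`` and ``individual_id`` columns; everything else
    (sbp, dbp, med, sex, age, bmi, pc1, ...) is passed through untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "individual_id": str})
    for col in ("family_id", "individual_id"):
        if col not in df.columns:
            raise ValueError(f"phenotype table lacks column {col!r}")
    return df


# ------------------------------------------------------------------ checks


def check_mendelian(
    pedigrees: Mapping[str, Pedigree], gm: GenotypeMatrix
) -> pd.DataFrame:
    """Report Mendelian-inconsistent trios (report-only, never raises).

    A child call is consistent if its two alleles can be assigned one from
    each parent's genotype; missing calls are unconstrained. Returns one
    row per (marker, trio) violation.
    """
    records = []
    calls = gm.calls
    for fid, ped in pedigrees.items():
        for ind in ped.members:
            if ind.is_founder:
                continue
            try:
                ci = gm.sample_index(fid, ind.iid)
                pi = gm.sample_index(fid, ind.father)
                mi = gm.sample_index(fid, ind.mother)
            except KeyError:
                continue
            child, fat, mot = calls[ci], calls[pi], calls[mi]
            bad = ~_trio_consistent(child, fat, mot)
            for mk in np.flatnonzero(bad):
                records.append(
                    {
                        "family_id": fid,
                        "child_id": ind.iid,
                        "marker_id": gm.markers["marker_id"].iloc[mk],
                        "child_gt": tuple(child[mk]),
                        "father_gt": tuple(fat[mk]),
                        "mother_gt": tuple(mot[mk]),
                    }
                )
    return pd.DataFrame(
        records,
        columns=["family_id", "child_id", "marker_id", "child_gt", "father_gt", "mother_gt"],
    )


def _trio_consistent(child: np.ndarray, fat: np.ndarray, mot: np.ndarray) -> np.ndarray:
    """Vectorized per-marker trio consistency for biallelic unordered calls."""

    def carries(par: np.ndarray, allele: np.ndarray) -> np.ndarray:
        # parent can transmit `allele` (missing parent call => anything)
        anymiss = (par < 0).any(axis=1)
        return anymiss | (par[:, 0] == allele) | (par[:, 1] == allele)

    c0, c1 = child[:, 0], child[:, 1]
    miss_child = (child < 0).any(axis=1)
    ok_a = carries(fat, c0) & carries(mot, c1)
    ok_b = carries(fat, c1) & carries(mot, c0)
    return miss_child | ok_a | ok_b


def ibs_relatedness_report(
    pedigrees: Mapping[str, Pedigree], gm: GenotypeMatrix
) -> pd.DataFrame:
    """Sanity report: mean identity-by-state sharing per within-family pair.

    A coarse screen for sample mix-ups: pairs whose pedigree kinship is
    high but whose IBS is at the unrelated background (or vice versa)
    deserve inspection. This is a descriptive report, not a formal
    relatedness inference.
    """
    kin = compute_kinship(pedigrees)
    dose = gm.dosage()
    rows = []
    for fid, ped in pedigrees.items():
        ids = ped.ids
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                i = gm.sample_index(fid, ids[a])
                j = gm.sample_index(fid, ids[b])
                di, dj = dose[i], dose[j]
                ok = ~np.isnan(di) & ~np.isnan(dj)
                ibs = np.nan
                if ok.sum():
                    ibs = float(np.mean(2.0 - np.abs(di[ok] - dj[ok])) / 2.0)
                rows.append(
                    {
                        "family_id": fid,
                        "id1": ids[a],
                        "id2": ids[b],
                        "kinship": kin.phi[kin.index(fid, ids[a]), kin.index(fid, ids[b])],
                        "mean_ibs": ibs,
                        "n_markers": int(ok.sum()),
                    }
                )
    return pd.DataFrame(rows)
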