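"""PLINK text PED/MAP input/output and the in-memory genotype matrix.

Genotype calls are coded per locus against the lexicographically smaller
observed allele ("allele 1"): 0 = homozygous allele-1, 1 = heterozygous,
2 = homozygous allele-2, -1 = missing.  PED carries no ref/alt notion, so
a deterministic coding rule is required for reproducibility.

Coordinates are 1-based inclusive physical positions (MAP convention);
all downstream segment bounds inherit this.  The MAP cM column is read
and ignored: the pipeline is physical-distance based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import DOG_AUTOSOMES, chrom_sort_key

#: Sentinel for a missing genotype call.
MISSING: int = -1

_SEX_FROM_PED = {"1": "male", "2": "female"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}


class PedMapFormatError(ValueError):
    """Malformed PED/MAP content (column counts, coordinates, alleles)."""


@dataclass(frozen=True)
class SnpLocus:
    """One array SNP: identifier, chromosome label and 1-based position."""
    snp_id: str
    chrom: str
    position_bp: int


@dataclass(frozen=True)
class Individual:
    sample_id: str
    sex: str = "unknown"          # "female" | "male" | "unknown"
    family_id: str | None = None
    phenotype: str = "-9"

    @property
    def fid(self) -> str:
        return self.family_id if self.family_id is not None else self.sample_id


@dataclass
class GenotypeMatrix:
    """Individuals x loci genotype calls with per-locus allele symbols.

    ``calls`` is an ``int8`` array of shape (n_individuals, n_loci) coded
    0/1/2/``MISSING``.  ``alleles`` is an (n_loci, 2) array of allele
    symbols; ``alleles[j, 1]`` is ``""`` when only one allele was observed
    at locus j (monomorphic).
    """

    individuals: list[Individual]
    snp_ids: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    alleles: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_i, n_l = self.calls.shape if self.calls.ndim == 2 else (0, 0)
        if self.calls.ndim != 2 or n_i != len(self.individuals) \
                or n_l != len(self.snp_ids):
            raise ValueError("call grid shape must be n_individuals x n_loci")
        if len(self.snp_ids) and self.positions.min() < 1:
            raise PedMapFormatError("positions must be >= 1")
        ids = pd.Index(self.snp_ids)
        if ids.has_duplicates:
            dup = ids[ids.duplicated()][0]
            raise PedMapFormatError(f"duplicate snp_id {dup!r}")
        sids = [ind.sample_id for ind in self.individuals]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate sample_id")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.snp_ids)

    @property
    def sample_ids(self) -> list[str]:
        return [ind.sample_id for ind in self.individuals]

    def loci(self) -> list[SnpLocus]:
        return [SnpLocus(s, c, int(p))
                for s, c, p in zip(self.snp_ids, self.chroms, self.positions)]

    def chrom_index(self, chrom: str) -> np.ndarray:
        """Column indices of the loci on one chromosome (position order)."""
        return np.flatnonzero(self.chroms == chrom)

    def chromosome_labels(self) -> list[str]:
        seen = dict.fromkeys(self.chroms.tolist())
        return sorted(seen, key=chrom_sort_key)

    def subset_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.individuals, self.snp_ids[idx],
                              self.chroms[idx], self.positions[idx],
                              self.alleles[idx], self.calls[:, idx])

    def subset_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        keep = [self.individuals[i] for i in np.atleast_1d(idx)]
        return GenotypeMatrix(keep, self.snp_ids, self.chroms, self.positions,
                              self.alleles, self.calls[np.atleast_1d(idx), :])

    def snp_spans_bp(self) -> dict[str, int]:
        """Per chromosome, the span covered by SNPs: last bp - first bp."""
        out: dict[str, int] = {}
        for c in self.chromosome_labels():
            pos = self.positions[self.chrom_index(c)]
            out[c] = int(pos.max() - pos.min())
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.individuals == other.individuals
                and np.array_equal(self.snp_ids, other.snp_ids)
                and np.array_equal(self.chroms, other.chroms)
                and np.array_equal(self.positions, other.positions)
                and np.array_equal(self.alleles, other.alleles)
                and np.array_equal(self.calls, other.calls))


def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PedMapFormatError(
                    f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, snp_id, _cm, bp = parts
            rows.append((chrom, snp_id, int(bp)))
    return pd.DataFrame(rows, columns=["chrom", "snp_id", "bp"])


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Load a PLINK text fileset into a :class:`GenotypeMatrix`.

    Loci are sorted by (chromosome, position) regardless of MAP order;
    individuals keep file order.  Allele "0" denotes missing; a locus
    showing more than two distinct non-missing alleles is rejected.
    """
    mp = _read_map(map_path)
    m = len(mp)

    individuals: list[Individual] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PedMapFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns "
                    f"for {m} MAP loci, got {len(parts)}")
            fid, iid, _pat, _mat, sex, pheno = parts[:6]
            individuals.append(Individual(
                sample_id=iid, sex=_SEX_FROM_PED.get(sex, "unknown"),
                family_id=fid, phenotype=pheno))
            allele_rows.append(np.array(parts[6:], dtype=object))

    n = len(individuals)
    if n:
        raw = np.vstack(allele_rows)            # (n, 2m)
        x1, x2 = raw[:, 0::2], raw[:, 1::2]     # each (n, m)
    else:
        x1 = x2 = np.empty((0, m), dtype=object)

    alleles = np.full((m, 2), "", dtype=object)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    if n and m:
        stacked = np.vstack([x1, x2]).astype(str)       # (2n, m)
        srt = np.sort(stacked, axis=0)
        is_new = np.ones_like(srt, dtype=bool)
        is_new[1:] = srt[1:] != srt[:-1]
        nz = is_new & (srt != "0")
        n_distinct = nz.sum(axis=0)
        bad = np.flatnonzero(n_distinct > 2)
        if bad.size:
            raise PedMapFormatError(
                f"locus {mp['snp_id'].iloc[bad[0]]!r} has more than two alleles")
        rank = np.cumsum(nz, axis=0)
        r1, c1 = np.nonzero(nz & (rank == 1))
        alleles[c1, 0] = srt[r1, c1]
        r2, c2 = np.nonzero(nz & (rank == 2))
        alleles[c2, 1] = srt[r2, c2]

        a2 = alleles[:, 1][None, :]
        miss = (x1 == "0") | (x2 == "0")
        counts = (x1 == a2).astype(np.int8) + (x2 == a2).astype(np.int8)
        calls = np.where(miss, np.int8(MISSING), counts).astype(np.int8)

    order = sorted(range(m), key=lambda j: (chrom_sort_key(mp["chrom"].iloc[j]),
                                            mp["bp"].iloc[j]))
    order = np.asarray(order, dtype=np.intp)
    chroms = mp["chrom"].to_numpy(dtype=object)[order]
    positions = mp["bp"].to_numpy(dtype=np.int64)[order]
    for j in range(1, m):
        if chroms[j] == chroms[j - 1] and positions[j] <= positions[j - 1]:
            raise PedMapFormatError(
                f"duplicate position {positions[j]} on chromosome {chroms[j]}")
    return GenotypeMatrix(
        individuals=individuals,
        snp_ids=mp["snp_id"].to_numpy(dtype=object)[order],
        chroms=chroms, positions=positions,
        alleles=alleles[order], calls=calls[:, order])


def write_ped_map(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write a PLINK text fileset; re-readable losslessly by
    :func:`read_ped_map` (MISSING written as ``0 0``)."""
    with open(map_path, "w") as fh:
        for snp_id, chrom, bp in zip(gm.snp_ids, gm.chroms, gm.positions):
            fh.write(f"{chrom}\t{snp_id}\t0\t{bp}\n")

    m = gm.n_loci
    a1 = gm.alleles[:, 0].astype(str)
    a2 = gm.alleles[:, 1].astype(str)
    if m and np.any((gm.calls > 0) & (a2 == "")[None, :]):
        raise ValueError("het/hom-2 call at a locus with a single allele")
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(gm.individuals):
            g = gm.calls[i]
            first = np.choose(np.clip(g, 0, 2), [a1, a1, a2])
            second = np.choose(np.clip(g, 0, 2), [a1, a2, a2])
            missing = g == MISSING
            first = np.where(missing, "0", first)
            second = np.where(missing, "0", second)
            geno = np.empty(2 * m, dtype=object)
            geno[0::2], geno[1::2] = first, second
            lead = [ind.fid, ind.sample_id, "0", "0",
                    _SEX_TO_PED[ind.sex], ind.phenotype]
            fh.write(" ".join(lead + geno.tolist()) + "\n")
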