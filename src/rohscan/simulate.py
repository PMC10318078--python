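"""Synthetic SNP-array genotype generator with planted autozygosity.

The generator emulates a small purebred-dog cohort genotyped on a dense
array: ~39 individuals, 38 autosomes totalling 2396.86 Mb, mean inter-SNP
spacing ~15 kb (~160k SNPs).  Outside planted tracts genotypes are drawn
under Hardy-Weinberg equilibrium from per-locus allele frequencies; a
planted autozygous tract makes the individual homozygous across its
extent (the homozygous allele drawn by frequency per locus), with a small
heterozygote-error rate emulating genotyping error, and uniform
missingness genome-wide.  One shared region carried by a configurable
fraction of individuals creates an extreme-ROH island.

Loci are independent (no background LD): window-based ROH detection does
not rely on LD, and the emulated protocol applies no LD pruning — this is
the generator's main realism gap.

A single :class:`numpy.random.Generator` keyed by the config seed drives
every draw, so identical configs yield byte-identical PED/MAP output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .detect import ROHSegment
from .genome import default_autosome_lengths_bp
from .io import MISSING, GenotypeMatrix, Individual, write_ped_map

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SharedIsland:
    """One region planted in a fixed fraction of individuals."""
    chrom: str = "18"
    start_bp: int = 3_000_000
    length_bp: int = 1_500_000
    carrier_fraction: float = 0.6


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; defaults emulate the study-scale cohort."""
    n_dogs: int = 39
    chromosomes: dict[str, int] = field(
        default_factory=default_autosome_lengths_bp)
    snp_spacing_bp: float = 15_000.0      # mean of exponential spacing
    maf_low: float = 0.05
    maf_high: float = 0.5
    segments_per_dog: int = 12
    seg_len_low_bp: float = 1e6           # log-uniform tract lengths
    seg_len_high_bp: float = 40e6
    shared_island: SharedIsland | None = field(default_factory=SharedIsland)
    het_error_rate: float = 0.005         # het calls inside planted tracts
    missing_rate: float = 0.02            # genome-wide missingness
    female_fraction: float = 25 / 39
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_error_rate", "missing_rate", "female_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.seg_len_low_bp > self.seg_len_high_bp:
            raise ValueError("seg_len_low_bp > seg_len_high_bp")
        isl = self.shared_island
        if isl is not None:
            if isl.chrom not in self.chromosomes:
                raise ValueError(f"island chromosome {isl.chrom!r} not in "
                                 "config")
            if isl.start_bp + isl.length_bp - 1 > self.chromosomes[isl.chrom]:
                raise ValueError("shared island exceeds chromosome length")
            if not 0.0 <= isl.carrier_fraction <= 1.0:
                raise ValueError("carrier_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """The simulator's record of what it planted."""
    tracts: dict[str, list[tuple[str, int, int]]]   # sample -> (chrom, s, e)
    island_carriers: list[str]
    island: SharedIsland | None
    freqs: np.ndarray                               # per-locus allele-2 freq

    def tract_frame(self) -> pd.DataFrame:
        rows = [(sid, c, s, e) for sid, lst in self.tracts.items()
                for (c, s, e) in lst]
        return pd.DataFrame(rows, columns=["IID", "chrom", "start_bp",
                                           "end_bp"])


def _simulate_map(cfg: SimConfig, rng: np.random.Generator):
    chroms, positions = [], []
    for label, length in cfg.chromosomes.items():
        # cumulative exponential spacings until past the chromosome end
        n_guess = int(length / cfg.snp_spacing_bp * 1.5) + 10
        gaps = rng.exponential(cfg.snp_spacing_bp, size=n_guess)
        pos = np.unique(np.cumsum(gaps).astype(np.int64) + 1)
        pos = pos[pos <= length]
        chroms.extend([label] * len(pos))
        positions.append(pos)
    return (np.array(chroms, dtype=object),
            np.concatenate(positions) if positions else
            np.empty(0, dtype=np.int64))


def _place_tracts(cfg: SimConfig, rng: np.random.Generator) -> dict:
    """Non-overlapping tract placement per dog, chromosomes drawn with
    probability proportional to length."""
    labels = list(cfg.chromosomes)
    lens = np.array([cfg.chromosomes[c] for c in labels], dtype=float)
    pchrom = lens / lens.sum()
    out: dict[str, list[tuple[str, int, int]]] = {}
    for d in range(cfg.n_dogs):
        placed: list[tuple[str, int, int]] = []
        for _ in range(cfg.segments_per_dog):
            for _attempt in range(50):
                ci = rng.choice(len(labels), p=pchrom)
                L = int(np.exp(rng.uniform(np.log(cfg.seg_len_low_bp),
                                           np.log(cfg.seg_len_high_bp))))
                if L >= lens[ci]:
                    continue
                start = int(rng.integers(1, int(lens[ci]) - L))
                end = start + L - 1
                if any(c == labels[ci] and s <= end and e >= start
                       for (c, s, e) in placed):
                    continue
                placed.append((labels[ci], start, end))
                break
        out[f"D{d + 1:03d}"] = sorted(placed)
    return out


def simulate(cfg: SimConfig, ped_path=None, map_path=None
             ) -> tuple[GenotypeMatrix, GroundTruth]:
    """Generate genotypes and ground truth; optionally write PED/MAP."""
    rng = np.random.default_rng(cfg.seed)
    chroms, positions = _simulate_map(cfg, rng)
    m = len(positions)

    snp_ids = np.array([f"snp_{c}_{p}" for c, p in zip(chroms, positions)],
                       dtype=object)
    # two distinct bases per locus; allele-1 is the lexicographically
    # smaller, and the allele-2 frequency is the (possibly flipped) MAF
    base_idx = np.array([rng.choice(4, size=2, replace=False)
                         for _ in range(m)]) if m else np.empty((0, 2), int)
    pair = np.sort(_BASES[base_idx], axis=1) if m else np.empty((0, 2))
    maf = rng.uniform(cfg.maf_low, cfg.maf_high, size=m)
    p2 = np.where(rng.random(m) < 0.5, maf, 1.0 - maf)  # freq of allele-2

    sex = np.where(rng.random(cfg.n_dogs) < cfg.female_fraction,
                   "female", "male")
    individuals = [Individual(sample_id=f"D{i + 1:03d}", sex=str(sex[i]),
                              family_id="SIM") for i in range(cfg.n_dogs)]
    sample_ids = [ind.sample_id for ind in individuals]

    # background: HWE as two independent allele draws per genotype
    u1 = rng.random((cfg.n_dogs, m))
    u2 = rng.random((cfg.n_dogs, m))
    calls = ((u1 < p2).astype(np.int8) + (u2 < p2).astype(np.int8))

    tracts = _place_tracts(cfg, rng)
    carriers: list[str] = []
    if cfg.shared_island is not None:
        isl = cfg.shared_island
        n_car = round(isl.carrier_fraction * cfg.n_dogs)
        carriers = sorted(rng.choice(sample_ids, size=n_car, replace=False))
        iv = (isl.chrom, isl.start_bp, isl.start_bp + isl.length_bp - 1)
        for sid in carriers:
            # drop planted tracts that collide with the island region
            tracts[sid] = [t for t in tracts[sid]
                           if not (t[0] == iv[0] and t[1] <= iv[2]
                                   and t[2] >= iv[1])] + [iv]
            tracts[sid].sort()

    # overwrite planted tracts with homozygous calls (+ het error)
    for i, sid in enumerate(sample_ids):
        for (c, s, e) in tracts[sid]:
            idx = np.flatnonzero(chroms == c)
            pos = positions[idx]
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, e, side="right")
            cols = idx[lo:hi]
            hom = np.where(rng.random(len(cols)) < p2[cols], 2, 0)
            err = rng.random(len(cols)) < cfg.het_error_rate
            calls[i, cols] = np.where(err, 1, hom).astype(np.int8)

    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    # allele symbols: report only what is observed so PED round-trips
    alleles = np.empty((m, 2), dtype=object)
    seen1 = (calls == 0).any(axis=0) | (calls == 1).any(axis=0)
    seen2 = (calls == 2).any(axis=0) | (calls == 1).any(axis=0)
    for j in range(m):
        if seen1[j] and seen2[j]:
            alleles[j] = pair[j]
        elif seen2[j]:
            alleles[j] = (pair[j][1], "")
            calls[:, j] = np.where(calls[:, j] == 2, 0, calls[:, j])
        else:
            alleles[j] = (pair[j][0], "")

    gm = GenotypeMatrix(individuals=individuals, snp_ids=snp_ids,
                        chroms=chroms, positions=positions,
                        alleles=alleles, calls=calls)
    truth = GroundTruth(tracts=tracts, island_carriers=carriers,
                        island=cfg.shared_island, freqs=p2)
    if ped_path is not None and map_path is not None:
        write_ped_map(gm, ped_path, map_path)
    return gm, truth


# ---------------------------------------------------------------------------
# small pedigree simulators for relatedness validation

def hwe_cohort(freqs: np.ndarray, n: int, rng: np.random.Generator
               ) -> np.ndarray:
    """n unrelated individuals at the given allele-2 frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    return ((rng.random((n, len(freqs))) < freqs).astype(np.int8)
            + (rng.random((n, len(freqs))) < freqs).astype(np.int8))


def _gamete(genotype: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele (0/1 copies of allele-2) per locus."""
    g = np.asarray(genotype)
    toss = (rng.random(g.shape) < 0.5).astype(np.int8)
    return np.where(g == 1, toss, (g // 2).astype(np.int8))


def simulate_pair(freqs: np.ndarray, relationship: str,
                  rng: np.random.Generator) -> np.ndarray:
    """Two individuals with a known relationship, as a (2, m) call array.

    ``relationship``: "unrelated", "duplicate", "parent_offspring" (one
    gamete from the parent, one from the population) or "full_sibs"
    (both individuals are children of the same two unrelated parents).
    """
    freqs = np.asarray(freqs, dtype=float)
    m = len(freqs)
    draw = lambda: (rng.random(m) < freqs).astype(np.int8)
    if relationship == "unrelated":
        return hwe_cohort(freqs, 2, rng)
    if relationship == "duplicate":
        a = hwe_cohort(freqs, 1, rng)[0]
        return np.stack([a, a.copy()])
    if relationship == "parent_offspring":
        parent = hwe_cohort(freqs, 1, rng)[0]
        child = _gamete(parent, rng) + draw()
        return np.stack([parent, child])
    if relationship == "full_sibs":
        pa, mo = hwe_cohort(freqs, 2, rng)
        s1 = _gamete(pa, rng) + _gamete(mo, rng)
        s2 = _gamete(pa, rng) + _gamete(mo, rng)
        return np.stack([s1, s2])
    raise ValueError(f"unknown relationship {relationship!r}")


def calls_to_matrix(calls: np.ndarray, chrom: str = "1",
                    spacing_bp: int = 10_000,
                    sample_ids: list[str] | None = None) -> GenotypeMatrix:
    """Wrap a raw (n, m) call array as a single-chromosome matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    alleles = np.empty((m, 2), dtype=object)
    alleles[:] = ("A", "B")
    return GenotypeMatrix(
        individuals=[Individual(sample_id=s) for s in sample_ids],
        snp_ids=np.array([f"s{j}" for j in range(m)], dtype=object),
        chroms=np.array([chrom] * m, dtype=object),
        positions=np.arange(1, m + 1, dtype=np.int64) * spacing_bp,
        alleles=alleles, calls=calls)


# ---------------------------------------------------------------------------
# recovery scoring

@dataclass(frozen=True)
class RecoveryScore:
    bp_precision: float
    bp_recall: float
    seg_precision: float
    seg_recall: float


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total, i, j = 0, 0, 0
    a, b = _merge(a), _merge(b)
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            total += hi - lo + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def score_recovery(called: list[ROHSegment], truth: GroundTruth,
                   min_overlap: float = 0.5,
                   min_truth_bp: float = 1e6) -> RecoveryScore:
    """Base-pair and segment-level precision/recall of called segments
    against planted tracts.

    Recall considers only tracts of at least ``min_truth_bp`` (shorter
    tracts are below the detector's minimum length by design).  A called
    segment counts as a true positive when at least ``min_overlap`` of
    its bp lie inside truth; a tract counts as recovered when at least
    ``min_overlap`` of its bp are called.  With no called segments the
    bp precision is reported as 1.0 (empty-denominator convention).
    """
    called_by: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for s in called:
        called_by.setdefault((s.sample_id, s.chrom), []).append(
            (s.start_bp, s.end_bp))
    truth_by: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for sid, lst in truth.tracts.items():
        for (c, s, e) in lst:
            truth_by.setdefault((sid, c), []).append((s, e))

    called_bp = overlap_bp = truth_bp = truth_cov = 0
    seg_tp = seg_n = tract_rec = tract_n = 0
    for key, ivs in called_by.items():
        t = truth_by.get(key, [])
        for s, e in ivs:
            L = e - s + 1
            ov = _overlap_bp([(s, e)], t)
            called_bp += L
            overlap_bp += ov
            seg_n += 1
            seg_tp += ov >= min_overlap * L
    for key, ivs in truth_by.items():
        c = called_by.get(key, [])
        for s, e in ivs:
            L = e - s + 1
            if L < min_truth_bp:
                continue
            ov = _overlap_bp([(s, e)], c)
            truth_bp += L
            truth_cov += ov
            tract_n += 1
            tract_rec += ov >= min_overlap * L
    return RecoveryScore(
        bp_precision=overlap_bp / called_bp if called_bp else 1.0,
        bp_recall=truth_cov / truth_bp if truth_bp else 0.0,
        seg_precision=seg_tp / seg_n if seg_n else 1.0,
        seg_recall=tract_rec / tract_n if tract_n else 0.0)
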