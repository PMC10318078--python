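"""Sliding-window runs-of-homozygosity detection.

The caller follows the overlapping-window algorithm popularised by PLINK
``--homozyg``: a fixed-size window slides one SNP at a time along each
chromosome; a window is "homozygous" when it contains at most a small
number of heterozygous and missing calls; each SNP receives the fraction
of homozygous windows among the windows that contain it; SNPs whose
fraction reaches a threshold are marked, and maximal runs of marked SNPs
become candidate segments.  Candidates are split at large inter-SNP
gaps, trimmed so they start and end on a homozygous non-missing call,
and kept only if they satisfy minimum-SNP, minimum-length and SNP
density constraints.

The minimum SNP count per run is usually not fixed by hand but computed
from the data so that the expected number of chance runs stays below a
false-positive rate alpha (the Lencz/Purfield "L parameter"):

    L = ln(alpha / (n_snps * n_individuals)) / ln(1 - mean_het)

where mean_het is the mean per-SNP heterozygote fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window scan settings (PLINK ``--homozyg-window-*``)."""
    window_snp: int = 50          # SNPs per window
    het_allow: int = 1            # max heterozygous calls per window
    missing_allow: int = 1        # max missing calls per window
    threshold: float = 0.05       # min fraction of homozygous windows

    def __post_init__(self) -> None:
        if self.window_snp < 1:
            raise ValueError("window_snp must be >= 1")
        if self.het_allow < 0 or self.missing_allow < 0:
            raise ValueError("window allowances must be >= 0")
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")


@dataclass(frozen=True)
class SegmentParams:
    """Run-level constraints (PLINK ``--homozyg-snp/-kb/-gap/-density``)."""
    min_snp: int = 50             # minimum SNPs per segment (the L value)
    min_length_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    max_density_kb_per_snp: float = 50.0

    def __post_init__(self) -> None:
        if min(self.min_snp, self.min_length_kb, self.max_gap_kb,
               self.max_density_kb_per_snp) <= 0:
            raise ValueError("all segment parameters must be positive")


@dataclass(frozen=True)
class LParams:
    """Inputs to the minimum-SNP (L) formula."""
    n_snps: int
    n_individuals: int
    mean_het: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.mean_het < 1.0:
            raise ValueError("mean_het must be in [0, 1)")
        if self.n_snps < 1 or self.n_individuals < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class ROHSegment:
    """One contiguous autozygous run for one individual.

    Bounds are the 1-based positions of the first and last SNP in the
    run (inclusive); ``length_bp = end_bp - start_bp + 1``.
    """
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snp: int
    n_het: int = 0
    n_missing: int = 0
    snp_first: str = ""
    snp_last: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6

    @property
    def kb(self) -> float:
        return self.length_bp / 1e3

    @property
    def density_kb_per_snp(self) -> float:
        return self.length_bp / 1e3 / self.n_snp


def mean_heterozygosity(gm: GenotypeMatrix) -> float:
    """Mean over loci of the observed heterozygote fraction (h-bar in the
    L formula), ignoring missing calls; loci with no observed calls are
    skipped."""
    obs = gm.calls != MISSING
    n_obs = obs.sum(axis=0)
    ok = n_obs > 0
    if not ok.any():
        raise ValueError("no observed genotype calls")
    het = (gm.calls == 1).sum(axis=0)
    return float((het[ok] / n_obs[ok]).mean())


def compute_min_snp(lp: LParams) -> int:
    """Minimum SNPs per ROH: floor of the L formula, clamped to >= 1."""
    if lp.mean_het == 0.0:
        raise ValueError("mean_het = 0: L formula undefined")
    L = math.log(lp.alpha / (lp.n_snps * lp.n_individuals)) \
        / math.log(1.0 - lp.mean_het)
    return max(1, math.floor(L))


def window_hit_fractions(calls: np.ndarray, positions: np.ndarray,
                         wp: WindowParams = WindowParams()) -> np.ndarray:
    """Per-SNP fraction of homozygous windows among windows containing it.

    ``calls`` and ``positions`` are one individual's data on one
    chromosome, position-sorted.  When the chromosome holds fewer SNPs
    than the window size no window fits and all fractions are zero.
    A SNP near a chromosome end lies in fewer windows; its denominator
    is the number of windows that actually contain it.
    """
    calls = np.asarray(calls)
    positions = np.asarray(positions)
    if calls.shape != positions.shape:
        raise ValueError("calls and positions must have equal length")
    n = len(calls)
    w = wp.window_snp
    if n < w:
        return np.zeros(n, dtype=float)

    het = (calls == 1).astype(np.int32)
    mis = (calls == MISSING).astype(np.int32)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    het_in_win = chet[w:] - chet[:-w]           # window start s = 0..n-w
    mis_in_win = cmis[w:] - cmis[:-w]
    hom_win = (het_in_win <= wp.het_allow) & (mis_in_win <= wp.missing_allow)

    cs = np.concatenate([[0], np.cumsum(hom_win)])
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)               # first window start holding j
    hi = np.minimum(j, n - w)                   # last window start holding j
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)


def _assemble_runs(calls: np.ndarray, positions: np.ndarray,
                   marked: np.ndarray, sp: SegmentParams):
    """Yield (start_idx, end_idx) index pairs of final segments on one
    chromosome for one individual, applying gap split, end trimming and
    the SNP/length/density filters."""
    max_gap_bp = sp.max_gap_kb * 1000.0
    min_len_bp = sp.min_length_kb * 1000.0
    n = len(calls)

    i = 0
    while i < n:
        if not marked[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and marked[j + 1]:
            j += 1
        # split run [i, j] at gaps larger than max_gap_bp
        starts = [i]
        pieces = []
        for k in range(i, j):
            if positions[k + 1] - positions[k] > max_gap_bp:
                pieces.append((starts[-1], k))
                starts.append(k + 1)
        pieces.append((starts[-1], j))
        for s, e in pieces:
            # trim to homozygous non-missing boundary calls
            while s <= e and calls[s] not in (0, 2):
                s += 1
            while e >= s and calls[e] not in (0, 2):
                e -= 1
            if s > e:
                continue
            n_snp = e - s + 1
            length = positions[e] - positions[s] + 1
            if n_snp < sp.min_snp or length < min_len_bp:
                continue
            if length / 1000.0 / n_snp > sp.max_density_kb_per_snp:
                continue
            yield s, e
        i = j + 1


def call_roh(gm: GenotypeMatrix, wp: WindowParams = WindowParams(),
             sp: SegmentParams = SegmentParams()) -> list[ROHSegment]:
    """Call ROH segments for every individual on every chromosome.

    Input should be autosomal and QC-filtered.  Output is sorted by
    (sample file order, chromosome, start position); segments of one
    individual on one chromosome are disjoint by construction.
    """
    segments: list[ROHSegment] = []
    for chrom in gm.chromosome_labels():
        idx = gm.chrom_index(chrom)
        pos = gm.positions[idx]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
        ids = gm.snp_ids[idx]
        for i, ind in enumerate(gm.individuals):
            calls = gm.calls[i, idx]
            frac = window_hit_fractions(calls, pos, wp)
            marked = frac >= wp.threshold
            for s, e in _assemble_runs(calls, pos, marked, sp):
                run = calls[s:e + 1]
                segments.append(ROHSegment(
                    sample_id=ind.sample_id, chrom=chrom,
                    start_bp=int(pos[s]), end_bp=int(pos[e]),
                    n_snp=e - s + 1,
                    n_het=int((run == 1).sum()),
                    n_missing=int((run == MISSING).sum()),
                    snp_first=str(ids[s]), snp_last=str(ids[e])))
    order = {ind.sample_id: i for i, ind in enumerate(gm.individuals)}
    segments.sort(key=lambda r: (order[r.sample_id], r.chrom, r.start_bp))
    return segments


HOM_COLUMNS = ["IID", "CHR", "SNP1", "SNP2", "POS1", "POS2",
               "KB", "NSNP", "DENSITY", "NHET", "NMISS"]


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """PLINK ``.hom``-style table of called segments."""
    rows = [(r.sample_id, r.chrom, r.snp_first, r.snp_last, r.start_bp,
             r.end_bp, round(r.kb, 3), r.n_snp,
             round(r.density_kb_per_snp, 3), r.n_het, r.n_missing)
            for r in segments]
    return pd.DataFrame(rows, columns=HOM_COLUMNS)


def frame_to_segments(df: pd.DataFrame) -> list[ROHSegment]:
    return [ROHSegment(sample_id=str(r.IID), chrom=str(r.CHR),
                       start_bp=int(r.POS1), end_bp=int(r.POS2),
                       n_snp=int(r.NSNP), n_het=int(r.NHET),
                       n_missing=int(r.NMISS), snp_first=str(r.SNP1),
                       snp_last=str(r.SNP2))
            for r in df.itertuples(index=False)]


def write_segments_tsv(segments: list[ROHSegment], path) -> None:
    segments_to_frame(segments).to_csv(path, sep="\t", index=False)


def read_segments_tsv(path) -> list[ROHSegment]:
    return frame_to_segments(pd.read_csv(path, sep="\t",
                                         dtype={"CHR": str, "IID": str}))
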