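"""ROH incidence tracks and extreme-ROH-island (eROHi) calling.

An island is a run of consecutive SNPs each covered by ROH in at least a
threshold fraction of individuals (e.g. 50% of the cohort); such shared
autozygosity is the classic signature of directional selection.  The
island span is reported as ``end_bp - start_bp`` (difference of the
first and last selected SNP positions, no +1), the convention used for
sizing selection-signature intervals.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import ROHSegment
from .genome import chrom_sort_key
from .io import GenotypeMatrix

TRACK_COLUMNS = ["chrom", "bp", "n_in_roh", "fraction"]


@dataclass(frozen=True)
class ERohIsland:
    """A merged run of consecutive high-incidence SNPs."""
    chrom: str
    start_bp: int
    end_bp: int
    n_snp: int
    n_dogs: int

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp


def island_span(island: ERohIsland) -> int:
    """Island size in bp: last selected SNP minus first selected SNP."""
    return island.span_bp


def min_carriers(n_individuals: int, fraction: float = 0.5) -> int:
    """Smallest carrier count satisfying "at least ``fraction`` of the
    sample": the ceiling of fraction * n (e.g. 20 of 39 at 50%)."""
    return math.ceil(fraction * n_individuals)


def snp_incidence(segments: list[ROHSegment], chroms: np.ndarray,
                  positions: np.ndarray, n_individuals: int) -> pd.DataFrame:
    """Per-SNP count and fraction of individuals whose ROH cover it.

    A locus counts for an individual iff one of that individual's
    segments on the same chromosome satisfies start <= position <= end;
    segments of one individual must be disjoint, so no double counting.
    Returns a position-sorted DataFrame (chrom, bp, n_in_roh, fraction).
    """
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    counts = np.zeros(len(positions), dtype=np.int32)
    idx_by_chrom = {c: np.flatnonzero(chroms == c)
                    for c in dict.fromkeys(chroms.tolist())}
    for s in segments:
        idx = idx_by_chrom.get(s.chrom)
        if idx is None:
            continue
        pos = positions[idx]
        lo = np.searchsorted(pos, s.start_bp, side="left")
        hi = np.searchsorted(pos, s.end_bp, side="right")
        counts[idx[lo:hi]] += 1
    frac = counts / n_individuals if n_individuals else counts.astype(float)
    df = pd.DataFrame({"chrom": chroms, "bp": positions,
                       "n_in_roh": counts, "fraction": frac})
    order = sorted(range(len(df)),
                   key=lambda i: (chrom_sort_key(chroms[i]), positions[i]))
    return df.iloc[order].reset_index(drop=True)


def incidence_from_matrix(segments: list[ROHSegment],
                          gm: GenotypeMatrix) -> pd.DataFrame:
    return snp_incidence(segments, gm.chroms, gm.positions, gm.n_individuals)


def _covering_dogs(segments_by_chrom: dict[str, list[ROHSegment]],
                   chrom: str, start: int, end: int, rule: str) -> int:
    ids = set()
    for s in segments_by_chrom.get(chrom, ()):
        if rule == "cover":
            if s.start_bp <= start and s.end_bp >= end:
                ids.add(s.sample_id)
        else:  # any overlap
            if s.start_bp <= end and s.end_bp >= start:
                ids.add(s.sample_id)
    return len(ids)


def call_islands(track: pd.DataFrame, threshold: float,
                 max_gap_kb: float = 1000.0,
                 segments: list[ROHSegment] | None = None,
                 ndog_rule: str = "cover") -> list[ERohIsland]:
    """Extract islands from an incidence track.

    SNPs with fraction >= ``threshold`` are selected; consecutive
    selected SNPs on one chromosome merge into an island, split where
    adjacent selected SNPs lie more than ``max_gap_kb`` apart.  ``n_dogs``
    counts individuals whose ROH cover the island (``ndog_rule="cover"``
    requires one segment spanning the whole extent; ``"overlap"`` accepts
    any overlap); it is 0 when ``segments`` is not provided.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if ndog_rule not in ("cover", "overlap"):
        raise ValueError("ndog_rule must be 'cover' or 'overlap'")
    max_gap_bp = max_gap_kb * 1000.0

    by_chrom: dict[str, list[ROHSegment]] = defaultdict(list)
    for s in segments or ():
        by_chrom[s.chrom].append(s)

    islands: list[ERohIsland] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sel = sub[sub["fraction"] >= threshold]
        if sel.empty:
            continue
        pos = sel["bp"].to_numpy(dtype=np.int64)
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for a, b in zip(starts, ends):
            start, end = int(pos[a]), int(pos[b])
            n_dogs = _covering_dogs(by_chrom, str(chrom), start, end,
                                    ndog_rule) if segments else 0
            islands.append(ERohIsland(chrom=str(chrom), start_bp=start,
                                      end_bp=end, n_snp=int(b - a + 1),
                                      n_dogs=n_dogs))
    islands.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start_bp))
    return islands


def islands_to_frame(islands: list[ERohIsland]) -> pd.DataFrame:
    """Island table (chrom, n_snp, from, to, size_bp, n_dogs)."""
    return pd.DataFrame(
        [(r.chrom, r.n_snp, r.start_bp, r.end_bp, r.span_bp, r.n_dogs)
         for r in islands],
        columns=["chrom", "n_snp", "from", "to", "size_bp", "n_dogs"])
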