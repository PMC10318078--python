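"""ROH summaries: length classes, genome coverage, per-dog statistics and
ROH-based inbreeding coefficients (F_ROH).

F_ROH for an individual is the summed length of its ROH divided by the
length of the genome (or of one chromosome) — the McQuillan genomic
inbreeding coefficient.  Two denominator conventions are supported and
must be chosen explicitly: the assembly length (the 2396.86 Mb dog
autosome total for genome-wide values) or the SNP-covered span (last SNP
bp minus first SNP bp per chromosome), which avoids counting assembly
sequence the array cannot interrogate.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import ROHSegment
from .genome import DOG_AUTOSOME_GENOME_MB, chrom_sort_key

#: Length-class bin edges in Mb; bins are [1,2), [2,4), [4,8), [8,16), [16,inf).
DEFAULT_CLASS_EDGES_MB: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)


def _class_labels(edges: tuple[float, ...]) -> list[str]:
    def fmt(x: float) -> str:
        return f"{x:g}"
    labels = [f"{fmt(a)}-{fmt(b)}" for a, b in zip(edges, edges[1:])]
    labels.append(f">{fmt(edges[-1])}")
    return labels


def _check_disjoint(segments: list[ROHSegment]) -> None:
    by_key: dict[tuple[str, str], list[ROHSegment]] = defaultdict(list)
    for s in segments:
        by_key[(s.sample_id, s.chrom)].append(s)
    for (sid, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda r: r.start_bp)
        for a, b in zip(segs, segs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(
                    f"overlapping segments for {sid} on chromosome {chrom}")


def class_genome_coverage(mean_count_per_animal: float, mean_length_mb: float,
                          genome_mb: float = DOG_AUTOSOME_GENOME_MB) -> float:
    """Percent of the genome covered by one ROH class:
    100 * mean_count * mean_length / genome size."""
    if genome_mb <= 0:
        raise ValueError("genome_mb must be positive")
    return 100.0 * mean_count_per_animal * mean_length_mb / genome_mb


def froh(segments: list[ROHSegment], denominator_bp: float) -> float:
    """Summed ROH length over a genome/chromosome length, for ONE
    individual.  Segments must be disjoint; a ratio above 1 signals a
    denominator mismatch and raises."""
    if denominator_bp <= 0:
        raise ValueError("denominator_bp must be positive")
    if not segments:
        return 0.0
    if len({s.sample_id for s in segments}) > 1:
        raise ValueError("froh expects segments of a single individual")
    _check_disjoint(segments)
    f = sum(s.length_bp for s in segments) / denominator_bp
    if f > 1.0:
        raise ValueError(f"F_ROH = {f:.3f} > 1; denominator too small")
    return f


def classify_roh(segments: list[ROHSegment],
                 edges_mb: tuple[float, ...] = DEFAULT_CLASS_EDGES_MB,
                 individuals: list[str] | None = None,
                 genome_mb: float = DOG_AUTOSOME_GENOME_MB) -> pd.DataFrame:
    """Per-length-class summary table.

    Each segment falls in exactly one left-closed bin by its length in
    Mb.  Per class: segment count, percent of all ROH, mean length,
    mean count per animal, genome coverage percent, and the mean/min/max
    of the per-individual class-restricted F_ROH (assembly denominator).
    ``individuals`` fixes the cohort (individuals with no ROH in a class
    contribute F_ROH = 0); default is the set of ids seen in ``segments``.

    Raises if any segment is shorter than the first bin edge: such
    segments violate the detector's minimum-length contract.
    """
    if individuals is None:
        individuals = sorted({s.sample_id for s in segments})
    n_ind = len(individuals)
    labels = _class_labels(edges_mb)
    edges = np.asarray(edges_mb, dtype=float)

    lengths = np.array([s.length_mb for s in segments], dtype=float)
    if lengths.size and lengths.min() < edges[0]:
        raise ValueError(f"segment shorter than {edges[0]} Mb present")
    # np.searchsorted with side='right' makes bins left-closed.
    bins = np.searchsorted(edges, lengths, side="right") - 1

    sample_idx = {sid: i for i, sid in enumerate(individuals)}
    froh_by_class = np.zeros((len(labels), n_ind), dtype=float)
    for s, b in zip(segments, bins):
        froh_by_class[b, sample_idx[s.sample_id]] += s.length_bp
    froh_by_class /= genome_mb * 1e6

    total = len(segments)
    rows = []
    for b, label in enumerate(labels):
        in_bin = bins == b
        count = int(in_bin.sum())
        mean_len = float(lengths[in_bin].mean()) if count else 0.0
        mean_cnt = count / n_ind if n_ind else 0.0
        cov = class_genome_coverage(mean_cnt, mean_len, genome_mb)
        fr = froh_by_class[b]
        rows.append({
            "length_class": label,
            "count": count,
            "percent": 100.0 * count / total if total else 0.0,
            "mean_length_mb": mean_len,
            "mean_count_per_animal": mean_cnt,
            "genome_coverage_pct": cov,
            "froh_mean": float(fr.mean()) if n_ind else 0.0,
            "froh_min": float(fr.min()) if n_ind else 0.0,
            "froh_max": float(fr.max()) if n_ind else 0.0,
        })
    return pd.DataFrame(rows)


def summarize_per_dog(segments: list[ROHSegment],
                      individuals: list[str] | None = None
                      ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-individual ROH count and total Mb, plus cohort mean +/- sd of
    the counts (sample sd, n-1; reported as 0.0 for a single individual)."""
    if individuals is None:
        individuals = sorted({s.sample_id for s in segments})
    counts = {sid: 0 for sid in individuals}
    total_bp = {sid: 0 for sid in individuals}
    for s in segments:
        counts[s.sample_id] += 1
        total_bp[s.sample_id] += s.length_bp
    table = pd.DataFrame({
        "IID": individuals,
        "n_roh": [counts[s] for s in individuals],
        "total_mb": [total_bp[s] / 1e6 for s in individuals],
    })
    n = len(individuals)
    mean = float(table["n_roh"].mean()) if n else 0.0
    sd = float(table["n_roh"].std(ddof=1)) if n > 1 else 0.0
    return table, {"mean_count": mean, "sd_count": sd, "n_individuals": n}


def froh_table(segments: list[ROHSegment], individuals: list[str],
               genome_bp: float,
               chrom_denominators_bp: dict[str, float] | None = None
               ) -> tuple[pd.Series, pd.DataFrame]:
    """Genome-wide F_ROH per individual and, when per-chromosome
    denominators are given, the (individual x chromosome) F_ROH matrix.

    ``chrom_denominators_bp`` maps chromosome label to its denominator —
    either assembly lengths or SNP-covered spans, per the chosen
    convention."""
    by_ind: dict[str, list[ROHSegment]] = {sid: [] for sid in individuals}
    for s in segments:
        by_ind[s.sample_id].append(s)
    genome = pd.Series({sid: froh(by_ind[sid], genome_bp)
                        for sid in individuals}, name="froh_genome")

    if chrom_denominators_bp is None:
        return genome, pd.DataFrame(index=individuals)
    chroms = sorted(chrom_denominators_bp, key=chrom_sort_key)
    mat = pd.DataFrame(0.0, index=individuals, columns=chroms)
    for sid in individuals:
        by_chrom: dict[str, list[ROHSegment]] = defaultdict(list)
        for s in by_ind[sid]:
            by_chrom[s.chrom].append(s)
        for c, segs in by_chrom.items():
            if c in chrom_denominators_bp:
                mat.loc[sid, c] = froh(segs, chrom_denominators_bp[c])
    return genome, mat


def generation_length_life_history(age_first_estrus_months: float = 9.0,
                                   estrus_interval_months: float = 9.0,
                                   gestation_months: float = 2.0) -> float:
    """Generation length in years by the life-history sum: average age at
    mating (age at first estrus plus one inter-estrus interval) plus
    gestation, converted from months and rounded to one decimal."""
    if min(age_first_estrus_months, estrus_interval_months,
           gestation_months) < 0:
        raise ValueError("durations must be non-negative")
    months = age_first_estrus_months + estrus_interval_months \
        + gestation_months
    return round(months / 12.0, 1)
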