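"""Genome constants for the domestic dog (Canis lupus familiaris).

The dog karyotype has 38 acrocentric autosomes plus X/Y/MT.  ROH analysis
is restricted to the autosomes; the total autosomal assembly size of
ROS_Cfam_1.0 (2396.86 Mb) is the default denominator for genome-wide
F_ROH and for genome-coverage percentages.
"""

from __future__ import annotations

import numpy as np

#: Autosome labels accepted for ROH analysis, in karyotype order.
DOG_AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 39))

#: Non-autosomal labels recognised on input and excluded by QC.
SEX_AND_MT: tuple[str, ...] = ("X", "Y", "MT")

#: Total autosomal length of the ROS_Cfam_1.0 assembly, in Mb.
DOG_AUTOSOME_GENOME_MB: float = 2396.86

_CHROM_RANK = {c: i for i, c in enumerate(DOG_AUTOSOMES)}
_CHROM_RANK.update({c: 100 + i for i, c in enumerate(SEX_AND_MT)})


def chrom_sort_key(label: str) -> tuple[int, str]:
    """Karyotype ordering: autosomes 1..38 numerically, then X, Y, MT,
    then anything else lexicographically."""
    return (_CHROM_RANK.get(label, 1000), label)


def default_autosome_lengths_bp(n: int = 38,
                                total_mb: float = DOG_AUTOSOME_GENOME_MB
                                ) -> dict[str, int]:
    """Synthetic per-autosome lengths for the simulator.

    The assembly total is fixed to ``total_mb`` and apportioned along a
    linearly decreasing profile (largest:smallest ~ 5:1), mimicking the
    real dog karyotype in which chromosome 1 is roughly five times the
    length of chromosome 38.  These are simulator defaults, not assembly
    coordinates.
    """
    raw = np.linspace(5.0, 1.0, n)
    lengths = raw / raw.sum() * total_mb * 1e6
    return {str(i + 1): int(round(l)) for i, l in enumerate(lengths)}
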