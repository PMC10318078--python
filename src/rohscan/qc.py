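"""Pre-ROH quality control: autosome restriction, call-rate filters and
pairwise relatedness screening.

Relatedness uses the Purcell method-of-moments IBD estimator: observed
identity-by-state (IBS) counts for each pair are inverted against
bias-corrected expected IBS proportions (computed from sample allele
frequencies) to yield P(IBD=0/1/2), and PI_HAT = P(IBD=2) + P(IBD=1)/2.
Flagged pairs are reported, never removed automatically: with a small
cohort, dropping one member of each related pair is a study decision.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genome import DOG_AUTOSOMES
from .io import MISSING, GenotypeMatrix

REPORT_COLUMNS = ["id1", "id2", "ibs0", "ibs1", "ibs2", "n_used",
                  "Z0", "Z1", "Z2", "PI_HAT"]


@dataclass(frozen=True)
class QcParams:
    """Call-rate and relatedness thresholds.

    Defaults follow the common SNP-array protocol: individuals with more
    than 10% missing genotypes are dropped, then SNPs missing in more
    than 5% of the remaining individuals; pairs with PI_HAT above 0.4
    are flagged as related.  ``apply_sample_filter=False`` skips the
    per-individual filter (useful for sparse datasets).
    """
    max_sample_missing: float = 0.10
    max_snp_missing: float = 0.05
    pi_hat_threshold: float = 0.4
    apply_sample_filter: bool = True

    def __post_init__(self) -> None:
        for name in ("max_sample_missing", "max_snp_missing",
                     "pi_hat_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def restrict_to_autosomes(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep loci on autosomes 1..38; X/Y/MT (and anything else) dropped."""
    keep = np.flatnonzero(np.isin(gm.chroms.astype(str), DOG_AUTOSOMES))
    return gm.subset_loci(keep)


def filter_by_call_rate(gm: GenotypeMatrix, params: QcParams = QcParams()
                        ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop high-missingness individuals, then high-missingness SNPs.

    The order matters and is fixed: sample filter first (if enabled),
    then the SNP filter evaluated on the remaining individuals.  Returns
    the filtered matrix and a removal log (kind, id, missing_fraction).
    """
    log_rows: list[tuple[str, str, float]] = []

    if params.apply_sample_filter and gm.n_loci:
        miss_frac = (gm.calls == MISSING).mean(axis=1)
        bad = miss_frac > params.max_sample_missing
        for i in np.flatnonzero(bad):
            log_rows.append(("sample", gm.individuals[i].sample_id,
                             float(miss_frac[i])))
        if bad.all() and gm.n_individuals:
            raise ValueError("all individuals removed by the sample "
                             "call-rate filter")
        gm = gm.subset_individuals(np.flatnonzero(~bad))

    if gm.n_individuals and gm.n_loci:
        snp_miss = (gm.calls == MISSING).mean(axis=0)
        bad = snp_miss > params.max_snp_missing
        for j in np.flatnonzero(bad):
            log_rows.append(("snp", str(gm.snp_ids[j]), float(snp_miss[j])))
        gm = gm.subset_loci(np.flatnonzero(~bad))

    log = pd.DataFrame(log_rows, columns=["kind", "id", "missing_fraction"])
    return gm, log


def allele2_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Per-locus frequency of allele-2 from non-missing calls; NaN where
    a locus has no observed calls."""
    calls = gm.calls.astype(float)
    obs = calls != MISSING
    with np.errstate(invalid="ignore"):
        return np.where(obs.any(axis=0),
                        np.where(obs, calls, 0.0).sum(axis=0)
                        / (2.0 * obs.sum(axis=0)), np.nan)


def _expected_ibs_terms(p: np.ndarray, n_alleles: np.ndarray
                        ) -> dict[str, np.ndarray]:
    """Per-locus expected IBS-state proportions conditional on IBD state,
    with the finite-sample bias correction for frequencies estimated from
    ``n_alleles`` observed alleles."""
    x, y = p, 1.0 - p
    Na = n_alleles.astype(float)
    c3 = ((Na - 1.0) / Na) * ((Na - 2.0) / Na) * ((Na - 3.0) / Na)
    c2 = ((Na - 1.0) / Na) * ((Na - 2.0) / Na)
    return {
        "e00": 2.0 * x * x * y * y * c3,
        "e10": (4.0 * x ** 3 * y + 4.0 * x * y ** 3) * c3,
        "e20": (x ** 4 + y ** 4 + 4.0 * x * x * y * y) * c3,
        "e11": (2.0 * x * x * y + 2.0 * x * y * y) * c2,
        "e21": (x ** 3 + y ** 3 + x * x * y + x * y * y) * c2,
    }


def estimate_relatedness(gm: GenotypeMatrix,
                         freqs: np.ndarray | None = None) -> pd.DataFrame:
    """Method-of-moments IBD estimates for every pair of individuals.

    Monomorphic loci (and loci with no observed calls) carry no IBD
    information and are excluded from both the IBS counts and the
    expectation terms.  ``freqs`` overrides the sample allele-2
    frequencies when they are known externally (e.g. simulations).

    Returns a DataFrame with one row per ordered pair (i < j):
    IBS state counts, P(IBD=0/1/2) as Z0/Z1/Z2, and PI_HAT.
    """
    n = gm.n_individuals
    if n < 2:
        raise ValueError("relatedness needs at least two individuals")

    p = allele2_frequencies(gm) if freqs is None else np.asarray(freqs, float)
    if p.shape != (gm.n_loci,):
        raise ValueError("freqs length must equal the locus count")
    obs_n = (gm.calls != MISSING).sum(axis=0)
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all loci monomorphic; IBS expectations undefined")

    calls = gm.calls[:, poly].astype(np.int16)
    # Allele count behind each frequency estimate; external freqs are
    # treated as population values (no finite-sample correction needed),
    # approximated by a large-Na limit.
    n_alleles = (2 * obs_n[poly]).astype(float) if freqs is None \
        else np.full(int(poly.sum()), 1e9)
    e = _expected_ibs_terms(p[poly], np.maximum(n_alleles, 4.0))

    rows = []
    nonmiss = calls != MISSING
    for i, j in combinations(range(n), 2):
        both = nonmiss[i] & nonmiss[j]
        m = int(both.sum())
        d = np.abs(calls[i, both] - calls[j, both])
        o0 = int((d == 2).sum())
        o1 = int((d == 1).sum())
        o2 = m - o0 - o1
        E00 = float(e["e00"][both].sum())
        E10 = float(e["e10"][both].sum())
        E20 = float(e["e20"][both].sum())
        E11 = float(e["e11"][both].sum())
        E21 = float(e["e21"][both].sum())

        z0 = o0 / E00 if E00 > 0 else 0.0
        z1 = (o1 - z0 * E10) / E11 if E11 > 0 else 0.0
        z2 = (o2 - z0 * E20 - z1 * E21) / m if m > 0 else 0.0
        z = np.clip([z0, z1, z2], 0.0, None)
        tot = z.sum()
        z = z / tot if tot > 0 else np.array([1.0, 0.0, 0.0])
        pi_hat = float(z[2] + 0.5 * z[1])
        rows.append((gm.individuals[i].sample_id, gm.individuals[j].sample_id,
                     o0, o1, o2, m, float(z[0]), float(z[1]), float(z[2]),
                     pi_hat))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def flag_related_pairs(report: pd.DataFrame, threshold: float = 0.4
                       ) -> pd.DataFrame:
    """Pairs with PI_HAT above ``threshold``, sorted by descending PI_HAT."""
    out = report[report["PI_HAT"] > threshold]
    return out.sort_values("PI_HAT", ascending=False).reset_index(drop=True)
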