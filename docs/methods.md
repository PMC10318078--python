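# Methods

This note documents the models and procedures implemented in `rohscan`,
the defaults and why they were chosen, what the simulator does and does
not emulate, and the numerical conventions that make results
reproducible bit-for-bit.

## Quality control

Input is PLINK text PED/MAP. Loci are re-sorted by (chromosome,
position); genotype calls are coded 0/1/2 as copies of "allele 2", where
allele 1 is the lexicographically smaller allele observed at the locus.
PED files carry no reference/alternate designation, so a deterministic
rule is required for the coding to be stable across runs and round
trips; the alphabetical rule is arbitrary but canonical.

Filters run in a fixed order: (1) drop non-autosomal loci (dog autosomes
are labels "1".."38"); (2) drop individuals with more than 10% missing
genotypes; (3) drop SNPs missing in more than 5% of the remaining
individuals. The order matters — a bad sample can push many SNPs over
the missingness limit — and sample-before-SNP matches standard
SNP-array practice. No minor-allele-frequency, Hardy–Weinberg or LD
pruning is applied: ROH detection deliberately uses the full marker
panel, since rare alleles and LD structure are part of the signal being
scanned.

### Relatedness

Pairwise relatedness uses the Purcell method-of-moments estimator.
For each pair, identity-by-state (IBS) states 0/1/2 are counted over
co-observed polymorphic autosomal SNPs. Expected IBS-state proportions
conditional on sharing 0, 1 or 2 alleles identical by descent (IBD) are
computed from allele frequencies with the finite-sample bias-correction
factors (products of `(N-1)/N`, `(N-2)/N`, `(N-3)/N` with `N` the number
of observed alleles behind each frequency estimate). Solving the moment
equations in order gives `P(IBD=0/1/2)`; negative estimates are clipped
to zero and the triple renormalised to sum to 1, and
`PI_HAT = P(IBD=2) + P(IBD=1)/2`. Monomorphic loci carry no information
and are excluded from counts and expectations alike. When true allele
frequencies are known (simulations), they can be passed explicitly; the
bias correction then degenerates to the population limit.

Pairs with `PI_HAT > 0.4` (roughly first-degree relatives and closer)
are *reported*, not removed: in a small cohort the choice of which
member of a related pair to drop is a study decision. The CLI offers
`--drop-related`, which keeps the member with the higher call rate.

## ROH detection

The detector follows the overlapping sliding-window algorithm of PLINK
`--homozyg`, restated here as an explicit rule list:

1. A window of 50 consecutive SNPs slides one SNP at a time along each
   chromosome. A window is *homozygous* if it contains at most 1
   heterozygous and at most 1 missing call.
2. Each SNP receives the fraction of homozygous windows among the
   windows that contain it. SNPs near chromosome ends belong to fewer
   windows; the denominator is the count of windows actually containing
   the SNP. A chromosome with fewer SNPs than the window yields all-zero
   fractions.
3. SNPs with fraction ≥ 0.05 are *marked*; maximal runs of consecutive
   marked SNPs are candidate segments.
4. A run is split wherever adjacent SNPs are more than 1000 kb apart.
5. Run ends are trimmed inward so the first and last SNP are homozygous
   non-missing calls (heterozygous/missing calls inside the run are
   tolerated via the window allowance, but a run never starts or ends on
   one).
6. A run is kept if it has at least `min_snp` SNPs, spans at least
   1000 kb (`length = end − start + 1`; the +1 is immaterial at Mb scale
   but fixed for determinism) and its density `length/1000/n_snp` is at
   most 50 kb per SNP. Density is evaluated per final segment, not per
   window.

`min_snp` defaults to the Lencz/Purfield *L* value,
`L = ln(alpha/(n_s·n_i)) / ln(1−h̄)` (floored, clamped to ≥1), with
`alpha = 0.05`, `n_s` the post-QC SNP count, `n_i` the cohort size and
`h̄` the mean per-SNP observed heterozygote fraction computed post-QC.
This bounds the expected number of chance all-homozygous runs across the
whole dataset by `alpha`. The realised value is echoed to the log;
`--min-snp` overrides it.

Only the window-level heterozygote cap is enforced; no additional limit
is placed on heterozygous calls inside a final segment. At the default
window threshold this admits roughly one tolerated heterozygous call per
50 SNPs, consistent with array error rates.

Marking is monotone in the threshold, every emitted segment satisfies
all constraints by construction, and the full caller is tested for exact
equivalence against a brute-force re-implementation that enumerates
every window and every candidate run.

### Known behaviour at the detection limit

Two intrinsic edge effects are worth knowing. First, a planted or true
autozygous tract barely above the 1 Mb minimum can be trimmed below it
(rules 5–6) and dropped entirely. Second, with a per-window missing
allowance of 1, a local cluster of two or more missing calls within ~50
SNPs defeats every window covering it, splitting long runs and shedding
sub-minimum fragments. The SNP call-rate filter removes precisely the
high-missingness SNPs responsible, which is why detection is specified
to run on QC'd data; recovery tests confirm ≥95% base-pair recall of
planted tracts ≥1 Mb through the QC + detection pipeline, versus ~91%
when QC is skipped.

## Summaries and F_ROH

ROH are classed by length into [1,2), [2,4), [4,8), [8,16) and [16,∞)
Mb — bins are left-closed because the conventional "1–2, 2–4, …"
labels do not state a boundary rule, and a 2.0 Mb segment must land in
exactly one bin. Genome coverage of a class is
`100 · mean_count_per_animal · mean_length_Mb / genome_Mb`; per-class
coverages sum to the pooled coverage by construction.

`F_ROH` is the McQuillan coefficient: summed ROH length divided by a
denominator. Two denominator conventions are supported and must be
chosen explicitly per call:

- **assembly length** — the dog autosomal total 2396.86 Mb (default for
  genome-wide values and the class table);
- **SNP-covered span** — last SNP bp − first SNP bp per chromosome,
  appropriate for per-chromosome values since an array cannot detect
  ROH outside its marker coverage.

Cohort count statistics use the sample standard deviation (n−1); for a
single individual the sd is reported as 0.0 by convention.

The generation-length utility implements the life-history sum: age at
first estrus + one inter-estrus interval + gestation, in months,
divided by 12 and rounded to one decimal (9 + 9 + 2 months → 1.7
years). Pedigree-based generation length is not implemented: averaging
"lifespan over several generations" is not reproducible without the
underlying pedigrees.

## ROH islands

The incidence track counts, per SNP, the individuals whose ROH cover it
(interval containment, `start ≤ pos ≤ end`). Islands are runs of
consecutive SNPs with incidence fraction ≥ a threshold (0.5 by
default — "at least half the cohort", i.e. ⌈0.5·n⌉ carriers under the
ceiling convention), split where adjacent selected SNPs lie more than
1000 kb apart. The merge gap reuses the ROH gap parameter because no
separate convention exists; it is exposed as a flag.

Island size is reported as `end − start` in bp (no +1), the convention
used for sizing selection-signature intervals. The per-island carrier
count `n_dogs` defaults to individuals with a single ROH spanning the
entire island extent; a looser any-overlap rule is available
(`ndog_rule="overlap"`), since "occurring in" an island is ambiguous.

## Simulator

The generator emulates a dense SNP-array panel on a small purebred
cohort. Defaults (all overridable):

| parameter | default | rationale |
|---|---|---|
| n_dogs | 39 | small national-breed cohort scale |
| autosomes | 38, totalling 2396.86 Mb | dog karyotype; linear 5:1 length profile apportioning the assembly total |
| SNP spacing | exponential, mean 15 kb | ~160k markers genome-wide, array density |
| MAF | uniform(0.05, 0.5) | broad array site-frequency spectrum |
| planted tracts | 12 per dog, log-uniform 1–40 Mb | yields mean F_ROH ≈ 0.05, the level typical of managed but not closed breeds |
| shared island | 1.5 Mb, carrier fraction 0.6 | one selection-signature-like region above the 0.5 calling threshold |
| het error in tracts | 0.005 | array genotyping error |
| missingness | 0.02 genome-wide | array no-call rate |

Background genotypes are two independent allele draws per locus
(exact Hardy–Weinberg). Inside a planted tract the individual is
homozygous, the allele drawn by frequency per locus, each call flipped
to heterozygous with the error rate; missingness is applied uniformly
afterwards. Shared-island carriers are a random subset of
`round(c·n)` dogs; a carrier's colliding private tract is replaced by
the island tract so ground truth stays disjoint per individual. A
single `numpy` Generator keyed by the config seed drives every draw, so
identical configs produce byte-identical PED/MAP files.

**What the simulator does not emulate:** background linkage
disequilibrium (loci are independent), allele-frequency correlation
along the chromosome, array clustering artefacts, and the X chromosome
(ROH analysis excludes it; arbitrary labels such as "X" can still be
configured to exercise the autosome filter). Window-based detection
does not rely on LD, so passing recovery tests demonstrates correctness
of the scan and its thresholds — not robustness to LD-driven
allozygous runs, which in real data are suppressed by the minimum
length rather than by the simulator's design.

Recovery scoring is interval arithmetic per (individual, chromosome):
base-pair precision = overlap/called, recall = overlap/planted
(restricted to tracts at or above the detector's minimum length);
segment-level scores use a 50% overlap criterion. With no calls,
precision is reported as 1.0 (empty denominator convention).

## Problem sizes used in the checked examples

Desk-scale tests use 2–10 dogs on 1–3 chromosomes (~5k SNPs);
recovery and island-threshold tests use 39-dog cohorts at the full
38-autosome, ~160k-SNP scale (a few seconds each); the brute-force
equivalence suite runs 100 randomised instances of up to 500 SNPs;
relatedness checks use 50k independent loci per pair.
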