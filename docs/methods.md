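# Methods

This note documents the models, conventions, and design choices behind
`gliopanel`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Panel model

The panel is represented as a manifest (target, chromosome, amplicon
count, covered bases, overall coverage, exon count) plus a 6-column BED of
amplicons (chrom, start, end, id, primer pool, target) and a SNP-marker
table (id, arm, chrom, 1-based position). BED coordinates are 0-based
half-open; every position surfaced to users is 1-based; conversion happens
only at the I/O boundary. Validation is strict for gene targets (BED
amplicon counts must equal the manifest) and lenient for the SNP marker
groups, whose published amplicon counts (30 for 29 chr1 markers, 24 for
25 chr19 markers) cannot be reconciled with a one-to-one mapping; the
packaged design uses one synthetic amplicon per marker and logs the
discrepancy. The packaged manifest totals 440 amplicons; sources for this
panel also quote 441 and 442 in different places, so nothing in the code
hard-codes a total — everything is computed from the manifest. Marker
identities, marker positions, and per-amplicon coordinates are not
published; the packaged stand-ins are synthetic (so labelled), because
only counts, arms, and target labels matter to the analytics.

Coverage QC computes, over **all** panel amplicons, the percentage at or
above each cutoff (defaults 100× and 500×), the mean depth, and the list
below the lowest cutoff. Missing depth entries count as zero with a
warning; negative depths are errors. Percentages are monotone
non-increasing in the cutoff and equal 100% at cutoff 0 by construction.

## Variant filter chain

`apply_filter_chain` mirrors a caller-level chain of seven pure,
conjunctive predicates per record:

(a) filtered coverage ≥ 100; (b) 50 ≤ allele reads ≤ 100,000; (c) location
∈ {exonic, intronic, upstream, splicesite_5, splicesite_3}; (d) VAF ≥
0.05; (e) effect in the allowed class list; (f) population MAF ≤ 0.5;
(g) SIFT < 0.05 **or** PolyPhen-2 > 0.85.

Conventions, each deliberately fixed:

* Coverage/allele-read/VAF/MAF bounds are closed as printed; the SIFT and
  PolyPhen gates are strict as printed.
* Rule (g) applies only to missense records carrying at least one score:
  the scores are undefined for truncating or non-coding changes, and
  penalizing score-free records would silently discard nonsense and
  frameshift variants that are plainly reportable.
* A missing MAF is treated as 0: absence from population databases is
  evidence of novelty, not commonness.
* The allowed-effect default includes `synonymous`. The caller-level
  effect list this chain mirrors omits it, but the downstream triage in
  the same workflow explicitly retains somatic synonymous variants as
  functionally cancer-associated, so a chain default that removed them
  would contradict the pipeline's own reported output; the list is
  configurable for users who want the narrower behaviour.
* Manual database review (ExAC/ClinVar/gnomAD) is modeled as the static
  `maf`/`clin_sig` annotation columns, keeping runs deterministic and
  offline.

Because the chain is a pure conjunction, the kept set is order-independent
and the operation is idempotent; the trace records every rule outcome and
attributes each removal to the first failing rule in (a)–(g) order, so
attrition counts sum exactly to the number removed.

`prioritize` is a second, separate stage (the chain intentionally still
admits intronic/upstream records, as the caller settings do): it removes
intronic and upstream records and buckets the remainder as exonic
(including synonymous), splicesite, or utr. `classify_clinical` partitions
on the annotation label, checking "conflicting"/"benign" before
"pathogenic" so that "conflicting interpretations of pathogenicity" is not
misread as pathogenic. The oncoplot matrix is gene × sample with
`multi_hit` collapsing and marginal counts.

## 1p/19q LOH calling

A germline-heterozygous SNP reads AF ≈ 0.5. Hemizygous loss of one arm in
a tumor of fraction f leaves one allele at dose 1 and the other at 1 − f
out of a total 2 − f, so the retained allele reads AF(f) = 1/(2 − f) and
the lost one 1 − 1/(2 − f). The caller does not estimate f; it classes
each adequately covered marker (≥ 250 reads; the AF of shallower markers
is too noisy and they are excluded) into fixed bands:

* homozygous: AF ∈ [0, 0.10] ∪ [0.90, 1.00] — closed, uninformative;
* heterozygous: AF ∈ [0.40, 0.60] — closed;
* imbalance: the open remainder (0.10, 0.40) ∪ (0.60, 0.90).

The printed band edges overlap at 10/40/60/90; here the named bands own
their edges and imbalance is the residual open set, which makes the three
classes an exact partition of [0, 1] (property-tested on a 10⁻³ grid).
The bands are symmetric under AF ↦ 1 − AF, so whether AF is oriented to
the reference or the alternate base is immaterial.

Arm rule: any heterozygous marker ⇒ `retained`; otherwise LOH requires at
least `min_informative_per_arm` (default 3 — one imbalanced marker is
fragile evidence, three is the smallest majority-robust count) informative
markers, all imbalanced; anything weaker is `non_informative`. "All
informative markers imbalanced" is the strict reading of the published
rule; since informative = heterozygous ∪ imbalance and a single
heterozygous marker already forces `retained`, the "all" and "majority"
readings coincide under this veto — the flag
`require_all_informative_imbalanced` exists to make the choice explicit.
Codeletion is `yes` only when both arms are LOH, `no` as soon as either
arm is retained, `non_informative` otherwise. Sample QC tiers: `optimal`
with zero low-depth markers; `non_informative` when an arm has fewer than
3 adequate markers or more than half of all markers are low-depth (these
fractions are not quantified in the source workflow and are configurable);
`suboptimal` between.

Benchmarking tallies calls against an orthogonal reference: single-arm
(partial) deletions in the truth count as codeletion-negative;
non-informative calls score conservatively (FN if truth-positive, TN if
truth-negative) by default, with an `exclude` policy available.

## Diagnostic metrics

Accuracy, sensitivity, and specificity are held as exact `Fraction`s;
the integer-percent display truncates toward zero. Truncation (not
half-up rounding) is the convention that prints 6/7 as 85% and 33/34 as
97%, and display is a pure formatting layer over the exact values.
Zero-denominator metrics are reported as undefined, never as 0.

## Limit of detection

The dilution engine mixes a mutant sample of base VAF v with wild-type
DNA at fraction φ: expected VAF = φ·v. Per replicate, alternate reads are
binomial over the configured depth (a beta-binomial overdispersion option
exists, default off — real amplicon chemistry is noisier than binomial,
and the binomial result is therefore a best case); a replicate detects
when it has ≥ 50 alt reads **and** observed VAF ≥ 2%, and the LOD is the
lowest expected VAF whose detection rate reaches 95%. These LOD-mode
floors are deliberately separate from the reporting chain's 5% VAF
threshold: sensitivity validation probes below the clinical reporting
line. In no-noise mode the LOD is the analytic floor
max(0.02, 50/depth) — 2.5% at 2000×. Acceptance runs use an expected-VAF
grid spanning 1–10% at 2000× with 500 replicates per dilution.

The copy-number detection limit is analytic: a deletion becomes visible
when AF(f) = 1/(2 − f) leaves the heterozygous band, at
f\* = 2 − 1/0.60 = 1/3, and saturates into the homozygous band at
f = 2 − 1/0.90 ≈ 0.89, beyond which deleted-arm markers read homozygous
and the arm turns non-informative — an intrinsic ceiling of AF-band LOH
calling. The "detected up to a 25% dilution" phrasing of wet-lab CNA
experiments is ambiguous between 25% tumor and 25% admixed normal; the
boundary operation therefore reports the full window (1/3, 0.89) and
evaluates any supplied fraction list (0.25 → AF 0.571, inside the
heterozygous band, not detected; 0.75 → AF 0.800, detected) rather than
asserting either reading.

## Synthetic data generator

The generator emulates the validation-study conditions, and its defaults
are fixed to them: 34 samples per cohort — 7 with full 1p/19q codeletion
(6 of which also carry IDH1 p.R132H, as in the clinical cohort), 2
1p-only and 2 19q-only partials (codeletion-negative), 2 TERT-promoter
mutants — at 1000× target depth and tumor purity uniform on (0.6, 0.85).
The purity ceiling stays below the ≈ 0.89 band-saturation point discussed
above. Per-amplicon depths are Poisson around the target (optional
log-normal efficiency emulates chronic low performers, default off).
Somatic variants assume copy-neutral heterozygous clonality: expected
observed VAF = purity × in-tumor VAF, alt reads binomial. Each panel
marker is germline-heterozygous with probability 0.4 (true per-marker
heterozygosities are unpublished; 0.4 is typical of assay SNPs chosen to
be informative); homozygous markers read 0/1 up to a 0.002 base-error
rate. Regeneration with the same seed and truth is bit-identical.

What the simulations do **not** model: FFPE deamination artifacts,
flow-space/homopolymer caller errors, amplicon GC bias, subclonal
architecture, and contaminating germline CNVs. Passing recovery tests
therefore demonstrate the correctness and calibration of the decision
rules under the stated read model, not the wet-lab error profile of a
sequencer.

The packaged clinical truth table reproduces the validation cohort's
molecular columns. Its one reference-discordant sample (ID233,
reference-positive for codeletion but not called) has no published AF
profile; the packaged benchmark scenario emulates it as a low-tumor-
fraction specimen (f = 0.2, below the analytic boundary f\* = 1/3), which
mechanistically yields the published confusion tally (6 TP, 27 TN, 1 FN,
0 FP → 97/85/100) rather than asserting it.

## Determinism and problem sizes

Every stochastic path takes a seed or `numpy.random.Generator`; a
stochastic dilution run without either is an error. The pipeline embeds a
SHA-256 hash of the resolved configuration in every report, so any
threshold change is visible in the output. Default suite and acceptance
sizes — 500 dilution replicates, 500-replicate VAF-recovery checks,
10⁴-instance oracle comparisons, 20-seed cohort recovery — were chosen as
the smallest sizes at which Monte-Carlo error is comfortably below the
asserted tolerances.

## Known limitations

* Tumor-only design: no matched-normal subtraction; germline variants are
  handled only through the MAF rule and annotation columns.
* The LOH caller is band-based, not a segmentation/BAF-model caller; it
  cannot separate copy-neutral LOH from deletion, nor call f outside the
  (1/3, 0.89) window.
* The filter chain consumes annotations as given; effect prediction and
  database lookup are upstream concerns.
* Coverage QC operates on per-amplicon mean depths, not per-base depths.
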