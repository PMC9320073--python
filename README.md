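# gliopanel

Analytics for targeted next-generation sequencing (tNGS) genotyping of
gliomas. A small amplicon panel — the coding regions of 13 glioma genes
(*ACVR1, ATRX, BRAF, CDKN2A, EGFR, H3F3A, HIST1H3B, HIST1H3C, IDH1, IDH2,
TP53, PDGFRA, PTEN*), a 125 bp stretch of the *TERT* promoter, and 54 SNPs
along chromosome arms 1p and 19q — can, in one sequencing workflow, report
the point mutations and the 1p/19q codeletion status that the current WHO
classification requires for diffuse gliomas. This package implements the
downstream analytics of such a workflow for neuropathology/bioinformatics
users who consume variant-caller output (not raw reads):

* the **somatic variant filter chain** — seven conjunctive rules on
  coverage (≥ 100×), allele read count (50–100,000), genomic location,
  variant allele frequency (VAF ≥ 0.05), effect class, population minor
  allele frequency (MAF ≤ 0.5), and in-silico deleteriousness (SIFT < 0.05
  or PolyPhen-2 > 0.85) — followed by triage into exonic / splice-site /
  UTR reportable alterations and a clinical-significance partition;
* the **1p/19q LOH caller**: each panel SNP with ≥ 250 reads is classed by
  its allelic frequency AF into homozygous ([0, 0.10] ∪ [0.90, 1]),
  heterozygous ([0.40, 0.60]), or allelic imbalance (the open remainder);
  an arm is LOH when it has no heterozygous marker and ≥ 3 informative
  markers, all imbalanced, and codeletion requires LOH on both arms —
  one heterozygous marker anywhere vetoes it;
* **amplicon coverage QC** against the panel manifest (% amplicons ≥ 100×
  / ≥ 500×, low-coverage lists);
* **diagnostic performance metrics** against an orthogonal reference
  method — accuracy (TP+TN)/total, sensitivity TP/(TP+FN), specificity
  TN/(TN+FP) — exact rationals with truncated integer-percent display;
* an **in-silico dilution engine** for the VAF limit of detection
  (binomial reads at fixed depth, detection floors of 50 alt reads and 2%
  VAF) and the analytic arm-deletion detection boundary from the mixture
  curve AF(f) = 1/(2 − f) at tumor fraction f;
* a **synthetic sample generator** producing variant tables, SNP AF
  profiles, amplicon depths, cohorts, and dilution series with known
  ground truth, so every stage is testable without sequencing data.

## Worked example

Generate a synthetic 34-sample cohort, filter one sample, and call its
1p/19q status:

```bash
gliopanel simulate cohort --n-samples 34 --seed 2 --out-dir simout
gliopanel filter --variants-tsv simout/SYN001.variants.tsv --out-prefix SYN001
gliopanel loh --snp-table simout/SYN001.snps.tsv --truth simout/truth.tsv --out-prefix SYN001
gliopanel metrics --tp 6 --tn 27 --fp 0 --fn 1
```

prints

```
1 raw -> 1 kept -> 1 prioritized (1 pathogenic-like)
called 1 samples
TP=1 TN=0 FP=0 FN=0 accuracy=100% sensitivity=100% specificity=None%
{"accuracy": 97, "sensitivity": 85, "specificity": 100}
```

SYN001 is a codeleted, IDH1 p.R132H-mutant sample: its one somatic variant
survives the whole chain and is pathogenic-like, and its SNP profile is
called codeleted (a true positive against the truth table; specificity is
`None` because a single positive sample gives no negatives to get right).
The final line shows the metric conventions on a confusion tally of 34
samples with one false negative: 33/34 truncates to 97% accuracy and 6/7
to 85% sensitivity.

The same library surface is importable (`gliopanel.apply_filter_chain`,
`gliopanel.call_sample`, `gliopanel.simulate_cohort`, ...); see
`docs/methods.md` for the models and conventions.

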