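# skipquant

Junction-read quantification of exon-skipping isoforms from bulk RNA-seq,
built around the BAX exon-2 event: the canonical Baxα transcript versus the
Bax∆2 variant, which lacks exon 2, fails to target mitochondria, and forms
cytosolic aggregates. The package measures, per sample, how much of the BAX
junction evidence supports the exon-skipped form, and compares that quantity
between diagnosis groups (e.g. Alzheimer's disease vs. no cognitive
impairment) the way splicing case-control studies do.

It is written for transcriptomics researchers who want a self-contained,
auditable version of this analysis: because the real cohort data are
controlled-access, the package ships a calibrated simulator that generates
whole mock cohorts with known ground truth, so every stage is testable end
to end.

## The statistic

The two isoforms differ only by the skipped exon, so the only informative
reads are those whose alignment crosses the diagnostic junction window
(bases 30–40 on both references for BAX). Each read is aligned competitively
against both transcripts and called

* `ALPHA` — crosses the canonical exon-1/exon-2 junction,
* `DELTA2` — crosses the skip exon-1/exon-3 junction,
* `AMBIGUOUS` — both references satisfy the junction rule with equal score,
* `NON_JUNCTION` — everything else (shared-exon reads, off-window reads).

A reference satisfies the junction rule when its primary alignment covers
the whole window, is gapless inside it, has ≥ `min_anchor` aligned bases on
each side of the junction (default 5), and has ≤ `max_mismatch_in_window`
mismatches inside the window (default 1). Per sample,

```
pct_skipped = 100 · n_DELTA2 / (n_ALPHA + n_DELTA2)        (PSI of the skip form)
has_splicing = (n_DELTA2 ≥ min_skip_reads)                 (default 1)
```

with `NA` (never 0) when a sample has no junction reads. Cohort tables are
de-identified before release — sample IDs replaced by unlinked shuffled
numbers, sequence columns masked with equal-length runs of `N` — and the
statistics layer reports per-group prevalence of `has_splicing`, a two-sided
Mann–Whitney rank-sum test on `pct_skipped` (case vs. control, and
stratified by sex), and a one-way ANOVA across APOE genotypes.

Pre-computed alignments are also accepted: SAM/BAM against the two
references is ingested keeping only mapped primary records (the
`samtools view -F 256` convention), with window mismatches recomputed
against the reference sequence.

## Worked example

Simulate a 60+60 mock cohort and run the whole pipeline (no reference files
needed — a synthetic six-exon BAX-like pair is built in; pass `--fasta` and
`--exons` to use your own):

```bash
skipquant simulate --out-dir cohort --n-per-group 60 --n-reads 1200 --seed 11
skipquant run --manifest cohort/metadata.tsv --out-dir out --seed 11
```

The run writes `out/summary.tsv` (the de-identified per-sample table),
`out/counts.tsv`, `out/id_map.tsv` and `out/stats.tsv`, and prints:

```
           contrast statistic_name  group_sizes   statistic      p_value sidedness                             note  p_bonferroni
     prevalence[AD] prevalence_pct           60   83.333333          NaN two_sided percent of samples with splicing           NaN
    prevalence[NCI] prevalence_pct           60   35.000000          NaN two_sided percent of samples with splicing           NaN
          AD_vs_NCI mann_whitney_U        60/60 2948.000000 4.407619e-10 two_sided                       asymptotic  1.763048e-09
   AD_vs_NCI[sex=F] mann_whitney_U        43/40 1453.000000 2.922009e-08 two_sided                       asymptotic  1.168803e-07
   AD_vs_NCI[sex=M] mann_whitney_U        17/20  260.000000 3.741207e-03 two_sided                       asymptotic  1.496483e-02
pct_skipped_by_apoe        anova_F 27/2/66/22/3    1.135359 3.434381e-01 two_sided                                   1.000000e+00
```

Reading this: 83% of the simulated AD samples and 35% of the NCI samples
carried any skip-junction evidence (this cohort's generating draw realized
37% nonzero NCI fractions, so the pipeline's detection error is under two
points); the rank-sum test strongly separates the groups on `pct_skipped`;
the APOE ANOVA is null, as designed — the simulator assigns genotypes
independently of splicing.

The same stages are importable as a library (`skipquant.simulate_cohort`,
`skipquant.classify_sample`, `skipquant.compute_ratio`,
`skipquant.cohort_report`, `skipquant.run_pipeline`).

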