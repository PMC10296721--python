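# Methods

## The event and its measurement model

An exon-skipping event with two isoforms — a canonical transcript and the
same transcript minus one internal exon — is fully determined by the
canonical sequence, the exon intervals, and the index of the skipped exon.
For the BAX case, skipping exon 2 produces the Bax∆2 variant; both the
canonical E1|E2 junction and the skip E1|E3 junction sit at the end of
exon 1, so a single transcript interval (the diagnostic window, bases 30–40
by default, 1-based inclusive) brackets the informative junction on both
references. Internally all coordinates are 0-based half-open; everything a
user sees is 1-based inclusive.

The skipped isoform is derived from the canonical model rather than loaded
independently, which guarantees the pair differs by exactly the skipped
exon; a second FASTA, when supplied, is validated against the derivation.
`N` bases are legal in references but never score as matches.

The per-sample quantity is the junction-read share of the skip form,
`pct_skipped = 100·n_DELTA2/(n_ALPHA + n_DELTA2)`. No length normalization
is applied because the diagnostic window has identical width on both
references by construction; reads that never cross the window (shared
exons) carry no isoform information and are excluded from the denominator.
This estimates the *junction-read* mixture share, not the molecule
fraction: when the two transcripts differ in length, a uniform-coverage
library yields junction reads from the shorter (skipped) isoform at a
higher per-molecule rate, so the junction share overstates the molecule
fraction by a known geometric factor. All simulation-recovery checks
therefore compare against the realized junction-level truth. A sample with
zero junction reads is `NA`, never silently 0; `NA` samples are excluded
from rank tests but retained in prevalence denominators (they were
sequenced and showed no skip evidence).

## Junction rule and competitive assignment

A read supports a reference when its primary alignment (i) covers the whole
diagnostic window (`full_window`, the default — "any overlap" would admit
reads touching the window edge without crossing the junction; the looser
`any_overlap` mode is retained as an option), (ii) is gapless inside the
window, (iii) has at least `min_anchor` aligned bases on each side of that
reference's junction, and (iv) has at most `max_mismatch_in_window`
mismatches inside the window. Among supporting references the strictly
higher alignment score wins; an exact tie is `AMBIGUOUS`, never broken
arbitrarily; no supporting reference is `NON_JUNCTION`.

Defaults `min_anchor = 5`, `max_mismatch_in_window = 1` are chosen so that
a single sequencing error cannot move a read between isoform classes:
flipping a call would require matching the other junction's k-mer, at least
`min_anchor` substitutions away. Paired mates are classified independently
and merged per fragment; conflicting mate calls become `AMBIGUOUS`.

## Alignment

Internal alignment is optimal affine-gap local alignment (match +2,
mismatch −3, gap open −5, gap extend −2; `N` never matches) via Biopython's
`PairwiseAligner`, taking the first co-optimal traceback in its canonical
enumeration order — a deterministic tie-break; scores are unaffected by
which co-optimal path is reported. Both orientations are tried and the
better kept (forward wins ties).

Two exact short-cuts keep whole-cohort runs fast without changing results:

* a read occurring verbatim in a reference is its own optimal alignment
  (among multiple occurrences, a window-covering one is preferred);
* a vectorized scan over all gapless placements (prefix-sum maximum
  subarray per offset, optimal end-clipping) gives the best gapless local
  alignment; any alignment containing a gap scores at most
  `match·L + gap_open`, so a gapless optimum at or above that bound is the
  global optimum. Below the bound, or when the outcome could still depend
  on a gapped alignment of the other reference, the dynamic program runs.
  The skip condition is score-dominance: if the other reference already
  supports the junction rule with a certain score strictly above the gap
  bound, no gapped alignment can win or tie. The margin field of an audit
  call may then reflect the gapless (lower-bound) score of the losing
  reference.

Tests assert that the fast path and the pure dynamic-programming path
produce identical sample counts, including under sequencing errors and
reverse-complemented reads.

SAM/BAM ingestion (pysam) keeps mapped primary records only — FLAG bits
0x4 and 0x100 unset, the `samtools view -F 256` convention. Mismatch
positions are always recomputed by comparing the aligned query to the
in-memory reference rather than trusting `NM` (which counts indels) or
parsing `MD`; scores are re-derived under the internal scoring scheme so
externally and internally aligned reads are comparable.

## Simulator

The simulator emulates only what the statistic needs. Per read: source
isoform ~ Bernoulli(true fraction skipped), start uniform over placements
that fit the transcript, independent per-base substitutions to a uniformly
chosen different base, constant quality `I`; optional reverse-complement
flipping and a basic paired mode (mate = reverse complement of the same
fragment). Truth (source isoform, start, substitution count, window
coverage) lives only in a separate table, and read IDs are opaque serial
numbers, so the classifier cannot cheat. Everything is deterministic given
the seed; per-sample streams are spawned from one root `SeedSequence`, so
cohorts are byte-identical across reruns.

Per-sample skipping fractions follow a zero-inflated Beta: a point mass at
zero (samples with no skipped transcripts) plus a Beta tail. The default
cohort design uses zero-inflation 0.15 for AD and 0.52 for NCI — matching
the published splicing prevalences of 85% and 48% — with Beta(2, 8) and
Beta(1.5, 12) tails (the case group both more often spliced and more
heavily spliced; the per-sample distribution is not published, so the tail
shapes are package choices and fully configurable). Sex frequencies follow
the published per-group counts (AD 210 F / 78 M, NCI 209 F / 117 M), APOE
genotype frequencies the published genotype panel, and age a truncated
normal (mean 85, sd 6, clipped to 70–100) matching an elderly cohort.
Genotype and sex are assigned independently of the skipping fraction, so
APOE contrasts are null by design.

What the simulator does *not* model: realistic error profiles (indels,
quality-dependent errors), positional coverage bias, PCR duplicates,
insert-size distributions, or expression of other genes. Passing recovery
tests therefore certify the classifier and statistics under the stated
generative model, not robustness to every artefact of real libraries; the
SAM route exists precisely so externally mapped real data can be ingested.

The synthetic BAX-like reference pair is a six-exon transcript
(exon lengths 34/50/46/30/30/30, 220 nt total) with a deterministic random
sequence — a synthetic stand-in, not BAX sequence, but structurally
faithful: exon 1 ends at base 34 so the default 30–40 window brackets both
junctions. The 220 nt desk scale keeps junction coverage per read high
(~20–30% of uniform 75-mers cross the window), which is what makes the
recovery suites fast at ≥500 junction reads per sample.

## Statistics

All tests are two-sided. Mann–Whitney uses midranks; the p-value is exact
by enumeration for tie-free pooled samples of ≤ 12 values, otherwise the
normal approximation with tie-corrected variance and continuity correction
(at cohort scale, ties at zero are ubiquitous, so the approximation is the
operative branch). Fully tied inputs return `U = n_a·n_b/2`, `p = 1`.
One-way ANOVA degenerates as follows: zero within-group variance with
separation gives `F = +∞, p = 0`; no variance anywhere gives `p = NA`.
Strata with fewer than 3 non-NA values per arm are reported as skipped
rather than dropped. No multiple-testing correction is applied across
panels (matching per-panel reporting); a Bonferroni column is emitted for
transparency. All statistics are invariant to input row order.

## De-identification and provenance

Released tables replace sample IDs with the integers `1..n` assigned in a
seeded random order; the original→new map is written only to a separate
optional file. Any designated sequence column is masked with an equal-length
run of `N`. Every TSV carries a provenance header (`#` comments: pipeline
version, references, window, thresholds, seed, NA policy). Cohort metadata
references FASTQs by file name relative to the cohort directory so reruns
into different locations remain byte-identical.

## Validation design and known limitations

The recovery suite checks, under fixed seeds: 100% agreement between the
classifier and an independent junction k-mer substring oracle on 10,000
error-free reads; mixture recovery within three binomial standard
deviations of the realized junction share at 0.5% substitution error
(exactly 0% at true fraction 0); null calibration of the rank-sum test
(rejection rate ≤ 6% at α = 0.05 over 2000 null replicates); and byte-level
determinism of all outputs.

Cohort-level prevalence recovery is split into two statistically separable
claims. At 60 samples per group the generator's own binomial noise around
the design expectation (sd ≈ 6.5 points for a 48% prevalence) exceeds the
pipeline's detection error by an order of magnitude, so a single-cohort
comparison against the design value mostly measures the random draw. The
suite therefore asserts (a) that the full read-level pipeline reproduces
the prevalence realized in the cohort it was given to within 8 points
(detection error is typically < 2 points), and (b) that prevalence averaged
over 100 independent design draws recovers the 85%/48% generating
expectations. Rank-sum power under the generating effect is ≥ 95% at 60+60.

Known limitations: no spliced/genome alignment (transcript references
only); multi-mapping resolution is delegated to the upstream aligner's
primary flag; base qualities are ignored in scoring; single two-isoform
events only (no multi-exon skips, no >2 isoforms per event); abundance
estimation (TPM/EM) is out of scope.
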