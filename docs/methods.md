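# Methods

This note documents the statistical model, the scoring conventions, the
synthetic-data generator and the numerical choices behind `mirmech`, in the
spirit of a package methods appendix. Everything quantitative below is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external data.

## Correlation model and significance

All expression is analysed on the log₂ scale. Protein spectral counts are
first normalized so every run's column total equals the largest observed
total (total-spectral-count normalization), then transformed as
`log2(x + 1)`; the pseudocount of 1 keeps zero counts at 0 and is the
standard choice for count data. When several proteins map to one gene, the
protein with the largest interquartile range (linear-interpolation
quartiles, ties to the lexicographically smallest protein id) represents
the gene — the IQR criterion favours the form that is both abundant and
variable across conditions, and the winning row is copied verbatim, never
blended. Replicates are averaged per cell line *after* these per-run steps,
and ratios (log₂ protein − log₂ mRNA) are computed after averaging.
miRNAs whose across-sample variance (unbiased, n−1 denominator) is ≤ 1 are
removed before correlation: such miRNAs carry too little signal for a
9-point correlation and would only add tests.

For each miRNA–gene pair and each layer (mRNA, protein, ratio) the Pearson
(optionally Spearman) correlation `r` across the n cell lines is converted
to a one-sided, negative-tail p-value via `t = r√(n−2)/√(1−r²)` on n−2
degrees of freedom. Sidedness is a deliberate choice: repression is a
directional hypothesis, and at n = 9 the joint threshold r < −0.8 with
p < 0.005 is coherent only one-sided (the one-sided p at exactly r = −0.8
is ≈ 0.0048; two-sided it would be ≈ 0.0096). Both inequalities are strict.
Pairs with an undefined layer (zero variance, missing data) are excluded
from classification and counted in the run log — never coerced to r = 0.
A first-order partial correlation (miRNA–protein given mRNA) is provided
as an alternative translational-repression statistic; it is not part of
the default pipeline.

## Classification

An interaction requires at least one significant inverse layer *and* at
least one supporting binding tool; tool identities are opaque labels joined
by a union rule. The significance pattern then maps to the six categories
through a fixed truth table (see README). The (S, NS, S) pattern —
significant decay and repression with no protein signal — cannot occur
under the model's own logic, so records showing it are retained and
flagged `anomalous` (they are diagnostic of miscalibration) but excluded
from category counts and shares. Shares are reported as exact fractions
and whole-percent roundings of: transcriptomics-only (RD + RD_o + B_s),
proteomics-benefit (B_w + TR + TR_o), TR-major (TR + TR_o), concordant
(B_s + B_w) and TR-involved (TR + TR_o + B_s + B_w).

Per-miRNA mechanism preference uses a 2×2 Fisher exact test (one-sided,
enrichment) of [TR-major vs other] × [this miRNA vs all others] over
miRNAs with ≥ 5 targets, with Benjamini–Hochberg correction across tested
miRNAs; a symmetric decay-preference test is reported alongside. The
contingency construction is one of several defensible choices; it
conditions on the pooled background including the tested miRNA's
complement, which is the usual enrichment formulation.

## Sequence features

Seed sites are reverse-complement matches to miRNA positions 2–7, reported
once per locus at the strongest compatible type
(8mer > 7mer-m8 > 7mer-A1 > 6mer), so overlapping calls never double-count
a locus. Only Watson–Crick pairs count anywhere; G:U wobbles never score.
DNA input is converted to RNA on read; coordinates are 0-based half-open
internally and 1-based inclusive in written reports. When several
transcripts map to a gene, each region independently takes its longest
candidate (ties to the first transcript id).

*Local AU context.* The k-th nucleotide from either site boundary
(k = 1..30) carries weight 1/k — "inversely proportional to distance" —
and the score is the weighted fraction of A/U among available positions,
so truncation at sequence ends renormalizes rather than penalizes.

*3′ supplementary pairing.* Candidate duplexes are single contiguous
Watson–Crick runs between miRNA positions 9..L and the 16 nt of message
immediately 5′ of the seed core, over placement offsets −8..+8. A run
scores 1 per paired nucleotide within miRNA 13–16 and 0.5 elsewhere, minus
0.5 per offset nucleotide beyond 2; the reported score is the maximum over
offsets and runs, floored at 0. The window size, offset range and
single-duplex rule are recorded conventions: they keep exhaustive
enumeration tractable, and the implementation is verified against a
brute-force maximizer over all offsets and all contiguous duplexes on
1000 random instances.

## Feature efficacy

Gene sets are pooled over (miRNA, gene) pairs — each miRNA contributes its
own sets — and compared with a one-sided two-sample KS test:
`D = sup_x (F_a − F_b)`, large when set *a* is shifted toward more negative
correlations, with the one-sided asymptotic p `exp(−2D²mn/(m+n))` clamped
to (0, 1]. A minimum set size (default 10) guards the asymptotic
approximation; undersized sets are flagged and omitted without touching
other sets. Site-type and region comparisons use a no-site reference
(pairs whose gene has no site of any kind for that miRNA). AU-content and
3′-pairing comparisons are restricted to genes with exactly one 3′UTR 8mer
site; AU quartiles have size floor(n/4) with ties broken by gene id, and
pairing classes are strict (> 4 good, < 1 poor; boundary scores in
neither). The paired t-test compares mean 3′-pairing scores between
decay-detected (r_mRNA < −0.8) and repression-detected (r_ratio < −0.8)
target sets across (miRNA, site-type) combinations; a zero-variance
difference vector is reported as degenerate (p → 0 when nonzero) rather
than hidden.

## Differential expression

Two-condition spectral counts are modelled per gene as Poisson with
`log μ = β₀ + β₁·group + log(total spectral count)`; the offset makes the
depth cancel exactly. β₁ is tested by Wald z and reported as
`log2FC = β₁/ln 2` with BH correction across genes. No overdispersion term
is fitted — a known simplification of the plain Poisson model; tests
verify the fit against the closed-form two-group MLE. Decoy-based FDR is
`min(1, 2R/(F+R))`, clamped because it estimates a proportion.

## Synthetic data generator

The generator emulates the assumed study design: 9 cell lines × 3
replicates, log₂ miRNA abundance varying across lines
(default SD 2.0 log₂ units, chosen so that simulated miRNAs realistically
clear the variance-≤1 filter the way the retained miRNAs of such a study
do), mRNA and protein responding linearly in log space through planted
mechanism slopes (strong effects −1.5, weak −0.05, compensation +1.5,
residual replicate noise 0.15 log₂ units), and protein observed as Poisson
spectral counts with per-run expectations proportional to linear abundance
scaled to a total depth of 2×10⁵. Replicates redraw noise and counts
independently; counts are generated per run and averaged downstream,
matching the pipeline's replicate-averaging order. One integer seed fixes
everything.

Two modelling choices deserve note:

* **Anchored repression.** Responses are anchored at the panel-minimum
  miRNA level: a target sits at its free baseline where its miRNA is
  lowest and is repressed as the miRNA rises, never exceeding baseline.
  With a symmetric (centred) response, strongly de-repressed genes would
  reach unrealistic abundances and, under a fixed per-run count budget,
  crush every other gene's counts — a compositional artifact no real
  proteome of thousands of genes exhibits. Anchoring caps single-gene
  count shares at ~1–3 % and preserves the correlation structure (Pearson
  r is invariant to the affine shift).
* **Compensation semantics.** `decay_compensated` couples a strong decay
  slope with an equal positive slope at the translation layer (protein
  buffered → pattern S, NS, NS), and `translation_compensated` is the
  mirror image; this reproduces the positive distribution shifts expected
  for the compensated categories.

Sequences: synthetic miRNAs are 22 nt with a unique mixed-composition seed
(so a pure A/U or pure G/C flank cannot contain an accidental seed
complement) and an all-A 3′ half. Sites are planted with controlled type,
region, AU level (30-nt flanks drawn from {A,U} or {G,C}) and pairing
level: the 16-nt upstream pairing window is filled with a base that cannot
Watson–Crick-pair the all-A 3′ half (A, or C in GC-rich context), giving
"poor" sites a score of exactly 0, while "good" sites overwrite the
canonical complement of miRNA 13–18 for a score of 5. Combining a "low AU"
flank with "good" pairing would violate the ≥90 % G/C flank guarantee (the
insert is A/U-rich) and is not used by the default configurations.
Accidental seed complements of any simulated miRNA are scrubbed from
backgrounds, and explicit negative context keeps a planted 6mer/7mer from
upgrading by chance — so the detected site table equals the planted truth,
which is what round-trip tests require. Real 3′UTRs, of course, contain
incidental sites; this generator trades that realism for exact ground
truth.

What passing recovery tests show — and what they do not: the pipeline
recovers planted decay-only and translation-only mechanisms (≥ 80 %
required, typically ~100 %) under linear log-scale responses with modest
i.i.d. noise and exact binding evidence. They do not show robustness to
nonlinear responses, confounded co-expression, batch structure, or binding
tables with realistic false-negative rates. Occasionally a simulated
miRNA's realized variance falls below the variance filter and its planted
targets become unrecoverable; this is faithful to the filter's behaviour
on real data and is visible in the confusion matrix's `unassigned` column.
`both_weak` effects (−0.05) sit deliberately at the single-layer detection
limit, so their recovery is intrinsically partial, and strong dual
repression can be read as `RD` when the protein count floor truncates the
ratio signal — a detection-limit artifact the category system shares with
the real experiment.

## Degenerate inputs and edge rules

Zero-variance vectors raise rather than return r = 0; empty KS samples,
empty pairing classes, fewer than 2 paired combinations, all-zero genes in
the Poisson model, and zero-total count columns all raise with specific
messages. The FDR formula clamps at 1. Boundary conventions: variance
exactly 1 is filtered; r exactly −0.8 is not significant; pairing score
exactly 4 or 1 belongs to neither class; protein filters are inclusive
(≥ 2 peptides, ≥ 10 spectra).

## Problem sizes

The reference synthetic study uses 10 miRNAs, 200 genes (100 planted
interactions across six mechanisms, 100 background), 9 samples × 3
replicates, and 600-nt 3′UTRs — sizes chosen so a full pipeline run takes
a couple of seconds while every feature class (site types, regions, AU
levels, pairing classes) remains populated. Oracle-equivalence tests run
300–1000 random instances per scorer.
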