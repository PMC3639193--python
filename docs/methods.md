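# Methods

This note documents the models and procedures implemented in `riscprof`, the
parameters that matter, the design choices made where the method was
genuinely open, and what the synthetic validation does and does not show.

## Experimental design assumed

The pipeline models an Ago HITS-CLIP study of a synchronized proliferation
time course: four time points (0 h quiescent/G₀, 1 h/G₁, 36 h/S, 48 h/M) with
two biological replicates each. Three libraries exist per condition: the
Ago-short miRNA fraction, Ago-bound mRNA fragments (consumed as transcript-
space intervals), and total RNA-seq. All coordinates are transcript-space,
0-based half-open; fragments are assumed already aligned to sense-strand
transcript models, so no genome liftover or strand logic exists anywhere.

## miRNA RISC loading

Loading is RPM within each replicate's Ago-short library. Thresholds
(`PipelineConfig`): `rpm_detect = 100` (detection, inclusive),
`rpm_differential = 1000` (differential testing floor, inclusive),
`fdr_loading = 0.20`. Detection uses the replicate-*mean* RPM at ≥ 1 time
point; the "cut-off" thresholds are read as ≥ and the boundary behaviour is
unit-tested explicitly.

Global normalization: each library is rescaled so that the median log-ratio
of its RPM to the quiescent replicate-mean RPM — over miRNAs whose quiescent
mean is ≥ 1000 RPM — is zero, and the quiescent libraries' scale factors are
geometric-mean-centered to 1. This is a robust median-of-ratios scheme
appropriate when the bulk of high-abundance miRNAs is not expected to change.
With fewer than 5 usable miRNAs the step degrades to a no-op with a warning.
A pseudocount of 0.5 reads (converted to RPM) is applied as a *floor* inside
log computations only, so observed ratios are untouched and zeros never
produce −∞; reported RPM never includes a pseudocount.

The differential test is deliberately simple for n = 2 replicates: a
two-sided z-test on log₂ normalized RPM whose replicate variance is pooled
across all miRNA × condition cells with mean normalized RPM ≥ 100 (low-count
cells are excluded because their Poisson component would inflate the pooled
estimate). P-values are BH-adjusted per time point over the miRNAs passing
the 1000 RPM floor at the tested or reference time point. The 100-repetition
null simulation in the test suite shows the realized false-call rate is
conservative (≪ 0.20), which is the intended failure direction for a
screening call.

## Footprint calling

The caller works on the vector of fragment 5′-end counts per transcript and
condition. Greedy rule: take the position with the maximal remaining count
(leftmost on ties, for determinism); stop when it is below `min_reads = 5`;
assign all starts within ± `assign_window = 10` nt to the footprint; emit the
interval `[anchor, anchor + footprint_len)` with `footprint_len = 50` nt
(clipped at the transcript end); zero the consumed window and repeat.
`footprint_len = 50` comfortably contains the downstream 5–43 nt confirmation
window; `min_reads` and `assign_window` are depth/geometry conventions, all
configurable. The caller is verified against an independent plain-Python
re-scan reference on 1,000+ random vectors (exact equality of anchors,
intervals and read counts) and by planted-anchor recovery.

Footprint strength is `RPM_footprint / RPKM_transcript` in the matching
condition. Transcripts below `rpkm_floor_strength = 0.1` RPKM give unstable
ratios; their footprints are flagged `strength_defined = False` and excluded
downstream rather than reported with huge strengths.

Merging (used by the ceRNA stage): footprints on one transcript/condition
whose intervals are within 20 nt are unioned transitively; reads, RPM and
strength are summed; the merged anchor is the strongest constituent's anchor.

## Total regulatory load

TRL per transcript = Σ footprint strengths, summed per replicate and averaged
across replicates per time point; absent replicates contribute 0. Matrices:
log₂(value + 0.1) per replicate library, quantile normalization (rank-mean,
average ties) across all 8 libraries, then replicate averaging. Row floors
are applied to the pre-normalization replicate means at ≥ 1 time point: TRL
strictly > 1 (so TRL = 1.0 is excluded), RPKM ≥ 2 (so 2.0 is included) —
the two rules are worded differently and implemented literally. The log
pseudocount 0.1 keeps zero entries finite while preserving order. k-means
runs on row-mean-centered profiles (centering removes expression level,
preserving the *shape* that defines a recruitment pattern) with a fixed seed
and multiple restarts; the inertia curve over a k range supports choosing k.

## MRE prediction and confirmation

The internal scanner reports perfect Watson–Crick complements of miRNA seed
classes on all transcript regions (5′UTR, CDS and 3′UTR alike): 8mer,
7mer-m8, 7mer-A1, 6mer, ranked in that order, one report per occurrence with
its best class; the default minimum reportable class is 7mer-m8. RNA/DNA
alphabets are bridged by U≡T. The scanner is a documented stand-in for an
external aligner-based predictor (e.g. miRanda, whose tabular output can be
imported instead and is defensively re-filtered at score ≥ 140,
energy ≤ −10 kcal/mol); it implements no alignment score or thermodynamics,
because the pipeline's contribution — footprint confirmation — is independent
of where raw candidates come from.

Confirmation, per replicate and time point: miRNA RPM ≥ 100 in that
replicate (raw RPM, not normalized — the criterion is about physical
presence in the library), and the site's 5′ coordinate lies 5–43 nt
downstream (3′ direction) of the anchor of a footprint with strength ≥ 0.31.
All three bounds are inclusive ("minimum of", "at least", "within 5 to 43").
The "start of a footprint" is its anchor — the only position the calling
procedure distinguishes. The confirmed set is the union over conditions,
with supporting (time point, replicate, footprint) evidence retained.

## Overlap statistics

One-sided Fisher exact p = upper hypergeometric tail P(X ≥ k) for an overlap
of k between an m-gene target set and an n-gene regulated set in an N-gene
universe (scipy's `hypergeom.sf`, verified against exact rational
enumeration for all tables with N ≤ 25); BH step-up for FDR. Genes, not
transcripts, are the testing unit: a gene is a target if any transcript
carries a confirmed pair. The default universe is caller-supplied; for
pipeline use the expressed-gene set is the defensible choice.

## ceRNA networks

Per time point, on replicate-pooled data (footprints re-called on summed
fragment starts, strengths from the pooled CLIP library size and
replicate-mean RPKM, loading as replicate-mean RPM — the dominance rules are
per-time-point statements, so replicates are combined first): an mRNA joins
a network when (1) its second strongest merged footprint is *strictly* less
than 25 % of the strongest (single-footprint mRNAs pass vacuously), and
(2) the most loaded miRNA with a confirmed element in that footprint is at
least 10× (inclusive) the second most loaded (single-miRNA footprints pass
vacuously). Rule 1 is strict and rule 2 inclusive because the first wording
is unambiguous ("less than 25 %") while "10× higher" is not; both boundaries
are unit-tested. Only *confirmed* miRNAs compete in rule 2. Summary networks
are the union of per-time-point edges keyed by (hub miRNA, transcript), with
supporting time points recorded per edge; merging is idempotent and
order-independent.

## Synthetic data

`SyntheticConfig` defaults define the simulated study: 60 transcripts of
0.8–3 kb (10 %/50 %/40 % UTR-CDS-UTR split), 30 miRNAs of 22 nt, true
loading log-uniform over 10–10⁵ RPM with 5 dynamically recruited miRNAs at
5-fold, true expression log-uniform over 0.1–10³ RPKM with mild temporal
wobble, 50 planted footprints with strengths log-uniform over 0.5–5
RPM/RPKM (a third given a 5-fold time profile), fragment starts jittered
around anchors with sd 2 nt over a uniform background of 2×10⁻⁴
fragments/nt/library (foreground:background far above 10:1), fragment
lengths uniform on [25, 50] nt, negative-binomial count noise with
dispersion 0.05 (var = μ + 0.05 μ²) for all libraries (CLIP 2×10⁶, miRNA
10⁶, RNA-seq 10⁷ reads). Planted footprints are restricted to transcripts
with true RPKM ≥ 10 so their expected read depth (strength × RPKM ×
library/10⁶) is above the caller's floor — the detectability condition,
recorded in the truth either way. Each footprint gets its miRNA's 7mer seed
complement written 5–43 nt downstream of the anchor; 25 decoy seed matches
are planted > 150 nt from every anchor. An optional planted ceRNA hub makes
the most loaded miRNA the sole regulator of five single-footprint
transcripts, each sharing its footprint with a weakly loaded decoy miRNA so
the 10× rule is exercised non-vacuously.

Two deliberate departures from "pure randomness": hub transcripts receive no
other planted footprints, and chance seed-core matches falling inside any
planted footprint's confirmation window are disrupted by a single base
change (about one such collision is expected per study per miRNA). Both keep
the recorded truth exhaustive — without them, recovery scores would be
polluted by accidental, unrecorded true positives.

What the simulation does **not** model: sequencing error, adapter/UMI
artefacts, crosslinking sequence bias, partial-complementarity (non-seed)
binding, genome-scale transcript numbers, and footprint width variation.
Passing recovery tests therefore demonstrates the correctness of the
*computational procedure* under its stated assumptions, not the biological
error rate on real libraries.

## Problem sizes and determinism

Default analysis scale (60 transcripts × 8 libraries, ~4×10⁵ CLIP reads)
runs the full pipeline in under a second; the validation suite uses 1,000
random vectors for the caller oracle, all hypergeometric tables with N ≤ 25,
and 100 repetitions of the 500-miRNA null loading study. All randomness
flows from explicit `numpy.random.default_rng` seeds; identical seeds give
identical studies, assignments and calls.

## Known limitations

* The greedy caller has no background model beyond the depth floor; on real
  data `min_reads` should be set against library depth.
* With n = 2 replicates the pooled-variance z-test borrows strength across
  miRNAs and assumes roughly homogeneous log-scale dispersion; strongly
  miRNA-specific dispersion would miscalibrate it.
* Quantile normalization with heavy ties (many zero TRLs) makes "identical
  sorted columns" only approximate within tied blocks.
* Imported predictor hits are trusted for their coordinates; the 5′-most
  alignment coordinate is assumed to be the reported position.
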