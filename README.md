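# riscprof

**Expression-weighted Ago HITS-CLIP profiling of microRNA regulation.**

`riscprof` re-implements, as a reusable Python pipeline, an analysis strategy
for Argonaute (Ago) HITS-CLIP experiments in a synchronously proliferating
tissue (quiescence plus 1 h, 36 h and 48 h into a regeneration time course,
two biological replicates each). It is aimed at computational biologists who
have (i) an Ago-short miRNA fraction, (ii) Ago-bound mRNA fragments aligned to
transcript models, and (iii) matched RNA-seq, and who want to know *which
miRNAs are actively engaged in the RISC, where they sit on mRNAs, and how
strongly each mRNA is regulated* — rather than relying on miRNA expression or
sequence-based target prediction alone.

## The method

* **RISC loading.** miRNA engagement is quantified as reads per million (RPM)
  in each replicate's Ago-short library: `RPM = count / library_size × 10⁶`.
  A miRNA is *detected* in the RISC when its replicate-mean RPM reaches
  100 at some time point. Differential loading vs the quiescent reference
  uses a stricter 1000 RPM floor, global median-of-log-ratio normalization,
  a pooled-variance z-test on log₂ normalized RPM and Benjamini–Hochberg
  control at FDR ≤ 20 %.
* **Footprints.** Fragment 5′-end positions are catalogued per transcript and
  coalesced greedily into footprints anchored at the locally strongest start
  accumulation. Footprint *strength* is its CLIP RPM divided by the
  transcript's RNA-seq RPKM — RISC occupancy weighted by mRNA abundance.
* **Total regulatory load (TRL).** `TRL(mRNA) = Σ footprint strengths`,
  replicate-averaged per time point. mRNAs with TRL > 1 enter a quantile-
  normalized log₂ time-course matrix that is clustered by k-means alongside
  the RPKM matrix of mRNAs expressed at ≥ 2 RPKM.
* **MRE confirmation.** Candidate miRNA regulatory elements (seed matches to
  miRNA nt 2–8, or imported miRanda-style hits filtered at score ≥ 140 and
  energy ≤ −10 kcal/mol) are *confirmed* when the miRNA is loaded at ≥ 100
  RPM and the site lies 5–43 nt downstream of the anchor of a footprint with
  strength ≥ 0.31 RPM/RPKM, checked separately per replicate and time point.
* **Overlap statistics.** Confirmed target sets are tested against regulated-
  gene sets with the one-sided Fisher exact test (hypergeometric upper tail)
  and BH correction.
* **ceRNA networks.** mRNAs whose second strongest merged footprint (20 nt
  merge) is < 25 % of the strongest, and whose top confirmed miRNA is ≥ 10×
  more loaded than the second, join that miRNA's competing-endogenous-RNA
  network; per-time-point networks are merged into summary networks.

A synthetic-study generator (`riscprof.synthetic_data`) emulates the full
design — planted footprints, planted and decoy seed-match MREs, dynamically
recruited miRNAs, negative-binomial replicate noise — and records the ground
truth, so every stage can be validated by recovery.

## Worked example

```bash
riscprof simulate --out-dir study --seed 5 --n-transcripts 30 \
    --n-mirnas 15 --n-footprints 20
riscprof run --study-dir study --out-dir results
```

prints (numbers from this exact invocation):

```
detected miRNAs: 15
differential loading calls: 7
footprints: 160
raw pairs: 90  confirmed: 20  refinement: 4.5x
ceRNA summary edges: 6
```

Read: all 15 simulated miRNAs are RISC-detected at ≥ 100 RPM (few miRNAs
share a million-read library, so each is abundant); 7 miRNA × time-point
combinations change loading significantly vs quiescence; 160 footprints are
called across the 8 libraries (20 planted sites × 8, essentially no
background calls); footprint confirmation shrinks 90 sequence-predicted
miRNA–mRNA pairs to 20 high-confidence ones (4.5-fold
refinement at this small scale); and 6 mRNAs are dominated by a single
footprint and a single miRNA, forming ceRNA network edges. Full tables land
in `results/` (`loading.tsv`, `footprints.tsv`/`.bed`, `trl.tsv`,
`mre_pairs.tsv`, `cerna_summary.tsv`, GraphML).

The same stages are importable as a library:

```python
from riscprof import SyntheticConfig, generate_study
from riscprof.pipeline import run_pipeline

study = generate_study(SyntheticConfig(seed=5))
res = run_pipeline(*study[:5])
res["refinement"]       # {'n_raw_pairs': ..., 'n_confirmed_pairs': ..., ...}
res["trl"].head()       # per-transcript TRL per time point, min/max/FC
```

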