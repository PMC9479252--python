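# Methods

`tfregulon` infers *regulated target genes* of a transcription factor (TF):
genes that the TF both binds (ChIP-seq peaks near the gene) and regulates
(expression change after induction of the TF), with the expected proportion
of false positives (EPFP) among the called genes controlled at a nominal
level. This note describes the model, the tunable parameters, the synthetic
study generator used for validation, and the numerical and design choices
made where the design was genuinely open.

## Pipeline

For one TF, one ChIP-seq experiment and one induction expression profile,
the stages run in order:

1. **Peak preparation.** Peaks separated by a boundary gap of < 500 bp are
   combined (the merged interval spans the members; its score is the sum of
   member scores, preserving total binding evidence). At most 25,000 peaks
   are analysed per data set; when more are present the highest-scoring are
   kept, with ties resolved in genome order. As a quality check, the
   histogram of signed peak-centre-to-nearest-TSS distances should peak
   within ±5 kb of the TSS; a displaced or flat mode usually indicates a
   genome-build mismatch.
2. **Peak-to-gene association.** Each peak is associated with at most 3
   genes whose (nearest) TSS lies within 100 kb of the peak centre, scored
   `Q·S / max(d_kb, 1)` where `Q` is the symbol quality (1 for "weak"
   symbols — names with four consecutive digits or containing FAM, MIR, MRP
   or orf — and 3 otherwise), `S` is the peak binding score, and `d_kb` the
   centre-to-TSS distance in kb floored at 1. Candidates scoring below 20%
   of the peak's best candidate are dropped (before the top-3 cut).
   Associations at d ≤ 500 bp are *promoter* binding; 0.5–100 kb are
   *enhancer* binding (a distal site, not a curated enhancer).
3. **Target sets.** Per-gene scores are built separately for promoter and
   enhancer associations by summation (method 1, the default), by maximum
   (method 2), or by summation over both region classes combined
   (method 3). Sets are capped at 5,000 genes (top-scoring kept).
4. **Enrichment gate (PAGE).** The PAGE statistic
   `z = (x_set − x_all)·√n_set / SD_all` tests whether target genes are
   enriched among the strongest responders, where `x` is per-gene log2 fold
   change. The direction-specific variant applies the statistic to the top
   quarter of genes by `x` (upregulation) or the bottom quarter
   (downregulation); `x_set`/`n_set` are the mean and count of target genes
   inside that quarter. By default `x_all`/`SD_all` are also computed
   within the quarter: set members inside the quarter are, under a
   random-target null, a uniform draw from it, so within-subset moments
   keep the null centred (measured type-I error at |z| ≥ 2 is ~2% over
   1,000 null draws). The classical all-gene-moments variant is available
   via `subset_moments=False`; with it, any random set appears "enriched"
   in both tails whenever the profile mean is displaced, which is why it is
   not the default. The target set is swept over decile thresholds of its
   binding scores and the maximal z is reported with the attaining
   threshold (the lowest threshold reproduces the unswept test, so the
   maximum can never fall below the baseline). The gate is p ≤ 0.05 with z
   > 0 in the tested direction; no multiple-testing correction is applied
   across the sweep.
5. **EPFP calling.** For each target gene (at the best sweep threshold)
   with a direction-consistent linear fold change ≥ 1.5,
   `EPFP(g) = p_c / p_r(g)`: `p_c` is the proportion of targets among
   "control" genes (absolute fold < 1.2, two-sided), `p_r(g)` the
   proportion of targets among all genes responding in that direction at
   least as strongly as g (weak inequality, so a candidate belongs to its
   own responder set and `p_r > 0`). Raw values (not clipped at 1) are
   adjusted by a running maximum from the strongest responder down, making
   EPFP non-decreasing with decreasing response; genes with adjusted EPFP
   ≤ 0.3 are called.
6. **Atlas assembly.** Calls are merged per (gene, direction) across a
   TF's experiments: minimum adjusted EPFP kept, support counted as
   distinct experiments (promoter and enhancer calls from one experiment
   count once for support but both inform the region category:
   promoter-only / enhancer-only / both). Entries supported by a single
   experiment are dropped when ≥ 2 experiments yielded calls; when only one
   experiment succeeded its calls are kept. Entries supported only by
   surrogate (indirect) ChIP-seq are flagged, and direct and indirect calls
   pool for the support rule with the flag preserved.
7. **TF characterisation.** With `q = n_up/(n_up+n_down)` over atlas
   entries: strong activator at q ≥ 0.8, strong repressor at q ≤ 0.2,
   moderate activator at 0.5 ≤ q < 0.8, moderate repressor otherwise;
   unclassified below 10 entries. Region usage and the fraction of
   ≥ 2-fold responders explained as regulated targets are computed in the
   dominant direction (up iff q ≥ 0.5). Scoring methods are compared by a
   1-df goodness-of-fit chi-square of two call counts against an equal
   split.
8. **Set overlap.** Similarity of two target sets in a universe of N genes
   is the normal-approximation hypergeometric z (`μ = nK/N`,
   `σ² = nK(N−n)(N−K)/(N²(N−1))`; z defined as 0 when σ = 0). In the
   pairwise matrix, down-vs-down comparisons are multiplied by −1 as a
   display convention; mixed pairs keep the positive sign. The universe is
   all genes with expression measurements. For N ≤ 200 the approximation's
   significance calls (|z| ≥ 2) agree with the exact hypergeometric test
   (doubled smaller tail, p ≤ 0.045) on ≥ 90% of random configurations.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| merge gap | 500 bp | peaks closer than this are combined |
| peak cap | 25,000 | max peaks analysed per data set |
| association window | 100 kb | max peak-centre-to-TSS distance |
| genes per peak | 3 | strongest-scoring candidates kept |
| relative score floor | 0.2 | candidates below 20% of the peak's best are dropped |
| promoter boundary | 500 bp | d ≤ 500 is promoter, else enhancer (inclusive boundary; the narrative "< 500 bp" and "−500 to +500" conventions differ by one basepair) |
| target-set cap | 5,000 genes | larger sets dilute enrichment |
| PAGE quarter | 0.25 | fraction of genes in the tested subset |
| gate alpha | 0.05 | enrichment significance level |
| candidate fold | 1.5 | minimum direction-consistent linear fold |
| control fold | 1.2 | below this absolute fold a gene is a control |
| EPFP level | 0.3 | acceptance level for calls |
| min targets | 10 | below this a TF is unclassified |
| rank-plot window | 300 genes | sliding window for enrichment curves |

## Synthetic studies

The generator (`synthetic_data`) emulates the joint structure of the real
inputs with planted ground truth. Defaults describe one desk-scale study:

- 2,000 genes on a single 300-Mb synthetic chromosome (one gene per
  150 kb, matching human gene density; minimum TSS spacing 10 kb); 5% of
  symbols are constructed "weak" (quality 1). Multi-chromosome layouts are
  a config change away (`chrom_name` per study), not a separate code path.
- 200 planted true targets; each is assigned a binding geometry — promoter
  (30%), enhancer (60%), or both, an enhancer-promoter "loop" (10%) — and
  a response direction (all up by default; `down` and `mixed` available).
- Per experiment (2 replicates by default), each true target receives one
  peak per assigned region — promoter peaks centred within ±300 bp of the
  TSS, enhancer peaks at 2–30 kb (distal regulatory contacts decay with
  distance, so distal binding concentrates within tens of kb) — with
  exponential scores (mean 20) over 150 uniform background peaks
  (exponential, mean 5). Background peaks avoid ±1.5 kb of planted-target
  TSSs so the planted region assignments remain truthful; replicates
  redraw positions and scores from experiment-specific seed streams.
- Expression: log2 fold change ~ Normal(0, 0.4) for non-targets and
  Normal(±1.5, 0.4) for targets; the ≥ 2-fold responder flag is granted
  deterministically from the fold change (the differential-expression
  significance machinery of the induction compendium is out of scope).

All randomness derives from one seed through named `SeedSequence` child
streams; identical configs produce byte-identical output files.

What the generator does **not** emulate: read-level noise and peak-calling
artifacts, sequence and motif content, correlated binding across unrelated
TFs, gene-density heterogeneity, expression-noise heteroscedasticity, and
replicate variance in the differential-expression call. Passing tests
therefore demonstrate the statistical machinery's correctness and
calibration under a clean generative model, not performance on real GEO
data.

Measured on this model (seeds 1–50, defaults): the mean realized
false-discovery proportion among called targets is ~0.01–0.03, comfortably
below the nominal 0.30 — the replication requirement (support ≥ 2) makes
the procedure conservative, as background binding rarely reproduces across
experiments near the same responsive gene. Mean sensitivity is ~0.8;
occasional studies lose most enhancer-channel calls when the single
strongest candidate happens to carry a raw EPFP above 0.3, which the
running-maximum adjustment then propagates to all weaker candidates. This
top-of-ranking instability is inherent to the adjustment as defined.

Two validation scenarios deviate from defaults for cause:

- *Method comparison* (sum vs max scoring) uses 4 peaks per target with
  per-peak score mean 3 (below the background mean 5) over 800 background
  peaks: only summation across sites separates true targets there, which
  is the regime the comparison is about. Under light background both
  methods saturate and differ by ±1 gene of noise.
- *Loop-geometry recovery* runs without background peaks, so the recovered
  promoter/enhancer/both fractions reflect the planted geometry; with
  background, promoter-assigned targets pick up spurious distal support
  (~+0.05 on the both-fraction).

## Numerical choices

- Ties in expression are broken by gene symbol everywhere a ranking is
  formed, making all outputs deterministic.
- `SD_all` uses the sample standard deviation (ddof = 1).
- The sweep uses `score ≥ threshold` so the 0th-percentile threshold
  retains the full set (with a strict inequality, uniform scores would
  empty the set).
- Degenerate inputs: zero-variance profiles, empty target sets, and
  empty-in-subset sets yield a flagged not-computable result (never a
  silent z of 0); a profile with no control genes is an error; the
  hypergeometric z is 0 by convention when its variance is 0.
- EPFP with `p_c = 0` (no target among controls) is 0; calls then reduce
  to the fold and significance gates.
- The peak cap keeps the highest-scoring peaks (the alternative — first in
  file order — would make results depend on input ordering); merged-peak
  scores are summed rather than maxed to preserve total evidence,
  consistent with method-1 summation downstream.

## Known limitations

- The calibration claim is a mean over replicated studies; individual
  studies can fall anywhere below (or occasionally above) the level.
- The PAGE normal approximation is optimistic for very small `n_set`; the
  gate requires only one target inside the tested quarter.
- Surrogate-TF mapping (which indirect ChIP-seq stands in for which
  induced TF) is consumed as metadata, not inferred.
- Genome-build conversion is out of scope: peak and gene coordinates must
  already share an assembly.
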