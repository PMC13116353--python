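# Methods

## Model and procedure

A candidate chromatin loop is an ordered pair of same-chromosome anchors
(0-based half-open intervals; left anchor precedes right). All coordinates
in the package are BED-convention 0-based half-open; conversion happens
only at file boundaries. Loop *distance* is the midpoint-to-midpoint
separation in bp — invariant to anchor width, which matters because loop
callers emit fixed 5 kb anchors.

Prediction is staged:

1. **Methylation module.** Each anchor is divided into 10 equal-width bins
   (bin width `floor(len/10)`; remainder bp extend the last bin so counts
   are conserved) and CpG sites with called methylation probability ≥ τ are
   counted per bin. The Pearson correlation of the two 10-bin count vectors
   (n = 10) summarizes anchor–anchor methylation coordination; a
   zero-variance vector yields r = 0 by convention ("no evidence of
   coordination" — keeps the feature finite and symmetric). A binary
   gradient-boosted tree ensemble maps the 21 inputs to a probability; the
   21 inputs plus that probability form the 22-D methylation block.
2. **Sequence module.** Anchor windows of length `l_anchor` centered on the
   anchor midpoint (clipped at chromosome ends and N-padded) are taken
   forward and reverse-complemented for both anchors — four sequences per
   loop. One-hot encoding uses rows A, C, G, T with N as an all-zero column
   (contributes nothing to convolutions). Windows of 1000 bp with 500 bp
   overlap feed the extractor: conv1d → ReLU → maxpool → dropout, twice,
   then conv1d → ReLU → dropout, then a learnable (channel × position)
   weight matrix that contracts the position axis per channel, then tanh.
   This is the smallest structure that compresses the convolutional feature
   map with weights adjusted by backpropagation; the third conv's channel
   count therefore equals the 128-D output. A sequence embedding is the
   mean over its windows (length- and order-invariant). The extractor is
   trained under a temporary 512→1 logistic head with binary cross-entropy
   and Adam (lr 1e-3, batch 32), early-stopped on validation loss with
   patience 5; the head is discarded and the weights frozen (verified by
   checksum before/after stage 3).
3. **Fusion.** The 535-vector — 20 counts, r, stage-1 probability, 4 × 128
   sequence values, distance in raw bp — feeds a second gradient-boosted
   ensemble whose output is the loop probability. Distance is passed
   untransformed: tree ensembles are monotone-invariant. The dimension
   chain 21 → 22, 4×128 = 512, 22+512+1 = 535 is asserted at runtime.

The convolutional extractor is implemented directly in numpy (im2col
convolutions, explicit backward passes, Adam); at fixture scale it trains
in seconds on one CPU and its gradients are validated against central
differences in the development history of the test suite.

### Tree-stage early stopping

Both tree stages use 500 rounds, learning rate 0.1, depth 6, with early
stopping on **validation log-loss** (20 rounds patience). A rank metric
such as auPRC saturates at the first boosting round on well-separated data,
which would freeze a one-tree model with probabilities compressed around
0.5; the perturbation analysis depends on calibrated probabilities (its
groups are defined by absolute thresholds 0.7/0.3), so the calibration-aware
metric is used.

### Stage-2 training classes

The staged-training description of the sequence module is ambiguous about
whether the temporary head sees positives only; a discriminative head needs
both classes, so it is trained on positives and the synthesized negatives.
Likewise "reverse sequences" is implemented as reverse complement, the
standard strand augmentation.

## Sampling

Negative anchors tile each chromosome with non-overlapping windows at the
anchor resolution (5 kb; non-overlapping stride maximizes anchor
independence) and are discarded if they come within 500 bp of any positive
anchor — positive anchors are excluded from negative pairing entirely.
Negative loops are random same-chromosome anchor pairs accepted until their
distance histogram equals the positives' over 20 log-spaced bins
(log-spacing reflects the heavy right tail of loop distances); the draw
budget is 1000 × the required count, after which a shortfall is logged
rather than looping forever. The result is a ~1:1 class balance whose
distance distribution cannot be exploited by the classifier. Splits are
purely chromosomal (train 4/7/8/11, validation 5/14, test the complement;
"chr" prefixes are normalized away), so no information leaks across splits
through genomic proximity.

## Analyses

* **Methylation swap** — among scored loops, equal-sized groups with
  probability ≥ 0.7 and ≤ 0.3 are formed (larger group subsampled); each
  low-group loop receives the full 22-D methylation block of one
  seeded-random high-group donor (donors paired randomly, not by rank) and
  is re-scored with sequence and distance untouched.
* **Clustering** — per-loop 20-D or per-anchor 10-D count vectors are
  z-scored per feature, X′ = (X − μ)/σ (zero-variance features left at 0),
  and clustered with K-means, k = 4, 10 seeded restarts keeping the best
  inertia. Labels are canonicalized by ascending mean raw count so repeated
  runs are comparable; the SSE elbow over a k-range shares seeding.
* **Loop typing** — an anchor is E/P if it overlaps ≥ 1 enhancer/promoter
  interval; an anchor overlapping both counts as promoter (promoter
  precedence: the stronger functional label). Pattern combinations are
  unordered (i ≤ j).
* **Signal aggregation** — length-weighted mean of bedGraph values over a
  region's bp, uncovered bp contributing 0 (raw means, no background
  normalization); a loop's value is the mean of its two anchors.
* **Genome-bin enrichment** — 100 equal bins per chromosome; an interval is
  assigned to the bin of its midpoint.
* **Canyon calling** — a deliberate threshold surrogate, not a hidden
  Markov model: 1000 bp tiles with mean CpG probability ≤ 0.1 (tiles with
  no CpGs ignored) are merged across gaps ≤ 1000 bp and kept if longer
  than 7300 bp. Window, ceiling, gap and minimum length are exposed in the
  CLI and function signature.
* **Long-range evaluation** — long-range means distance > 2 Mb; recall(τ)
  is the fraction of positives scoring ≥ τ; distance histograms are
  right-open with the final bin right-closed and out-of-range values
  clipped into the terminal bins so totals are conserved.

## Synthetic data

The generator plants exactly the structure the model claims to exploit, so
recovery is a meaningful check:

* **Labels.** Candidate anchor pairs on the 5 kb grid are positive with
  probability σ(β₀ + β₁e^{−d/s} + β₂r + β₃m): β₀ = −3, β₁ = 2 (distance
  decay, s = 200 kb), β₂ = 6 acting on r = ρ for coordinated pairs, β₃ = 2
  for motif-bearing pairs. A logistic labelling function was chosen for
  controllable effect sizes; it is the test harness's generative model, not
  a biological claim.
* **Methylation.** Background CpG probabilities draw from Beta(2, 5) (most
  mass below 0.6, as observed in real anchor methylomes). Coordinated
  pairs share a latent per-bin level u ~ N(0.5, 0.15²) with independent
  per-anchor noise of variance 0.15²(1−ρ)/ρ, so the 10-bin qualifying-count
  correlation has expectation ρ (default 0.7; the realized mean is ≈ 0.67
  after rounding/clipping attenuation, verified per seed). Positive anchors
  carry a fixed per-bin CpG complement (CpG-island-like spacing, 0.03/bp vs
  0.01/bp background) — fixed counts avoid Poisson attenuation of the
  planted correlation and make positive anchors CpG-richer than negatives.
* **Genome.** Uniform random nucleotides; a fixed 12-mer planted at
  motif-bearing anchor midpoints with probability 0.9; "CG" dinucleotides
  injected at the chosen CpG sites. Background CG dinucleotides arising by
  chance are simply uncalled sites (callers do not reach every CpG either).
* **Canyons** are planted in anchor-free regions with Beta(1, 30)
  probabilities. They are deliberately kept away from loop anchors: a
  canyon anchor has ~zero counts in every bin, hence zero variance and
  r = 0, which would destroy the coordination signal that carries
  long-range positives. The canyon/long-range association is exercised by
  the analysis operations, not baked into the label model.
* **Imprinting toggle** emits two haplotype methylomes identical except at
  one designated DMR anchor (hypo- vs hyper-methylated).
* **Profiles.** `tiny` (three chromosomes of 0.4–0.6 Mb, 48 positives,
  trains end-to-end in seconds) and `default` (chr4 5 Mb train / chr5
  2.5 Mb validation / chr1 5 Mb test, 180 short-range + 30 long-range
  positives). The default simulation-config chromosome set is two 1 Mb
  chromosomes; the bundled profiles use three, and larger ones where
  long-range (> 2 Mb) loops must exist, because chromosome-partitioned
  splits need train/validation/test chromosomes and a > 2 Mb loop needs a
  host chromosome longer than that. `clustering-blobs` emits four 10-D
  count blobs with centers 3/9/15/22 and unit spread — ≥ 6σ separation, so
  exact recovery (adjusted Rand index 1) is the correct expectation.

What the generator does **not** emulate: realistic genome composition
(repeats, GC structure, real CpG islands), read-level noise, shared anchors
between loops, TAD structure, or any coupling between canyons and anchors.
Passing tests therefore demonstrate that the implementation recovers the
signals it models, under clean conditions — not field performance on real
nanopore/Hi-C data.

## Problem sizes and numerical choices

The suite and the example configurations train with `l_anchor` = 1000 (one
window per sequence) and a 16/32/128-filter extractor over the bundled
profiles; the feature-module default remains `l_anchor` = 5000 (nine
1000/500 windows), matching the 5 kb anchor resolution, and is what a real
run would use. Tree stages are single-threaded with fixed seeds;
`tree_method="hist"` is deterministic, and all package randomness flows
from one root seed through spawned generators, so identical configurations
reproduce bit-identical metrics. Probabilities are compared at printed
precision; the Pearson and auPRC primitives are validated against
brute-force oracles at 1e-12 / 1e-9.

Degenerate inputs are defined, not crashed on: all-N sequences embed like
any other window (zero one-hot columns), anchors without CpGs give zero
count vectors and r = 0, empty bedGraph coverage contributes 0 signal, and
an infeasible distance-matching bin ends in a logged shortfall.

## Known limitations

* The canyon caller is a windowed threshold rule; boundary placement is
  quantized to the window size and it will merge canyons separated by gaps
  just under `merge_gap`.
* The loop-type annotator is O(anchors × annotations); adequate at fixture
  scale, an interval tree would be the next step for genome-scale tracks.
* `l_anchor` is fixed per model; anchors of heterogeneous widths are
  re-windowed around their midpoints rather than resized adaptively.
* Stage-2 training at real-genome scale (hundreds of thousands of windows)
  would want a compiled backend; the numpy implementation targets the
  fixture scale this package ships with.
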