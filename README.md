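# nanoloop

Chromatin loops bring distant genomic loci — enhancers, promoters,
insulators — into physical contact and are central to 3D genome
organization. Loop callers applied to Hi-C contact maps report loops as
pairs of ~5 kb *anchors*, but predicting which candidate anchor pairs loop
from primary data remains hard, and sequence-only predictors miss loops
whose formation is governed by epigenetic state. Nanopore sequencing reads
out DNA sequence and CpG methylation simultaneously, which makes a
dual-modality predictor natural: this package implements one, for
computational epigenomics researchers who have per-CpG methylation calls, a
genome, and a training set of loops in BEDPE form.

## The model

For a candidate loop with anchors $L$ and $R$ on one chromosome:

**Methylation block (22-D).** Each anchor is split into 10 equal-width bins
and $X_i$ (resp. $Y_i$) counts the CpG sites with methylation probability
$\ge \tau$ (default 0.5) in bin $i$. The coordination feature is the Pearson
correlation

$$r = \frac{\sum_{i=1}^{n}(X_i-\bar X)(Y_i-\bar Y)}
           {\sqrt{\sum_i (X_i-\bar X)^2}\sqrt{\sum_i (Y_i-\bar Y)^2}},\qquad n=10 .$$

A gradient-boosted tree classifier (stage 1) maps the 21 inputs
$(X_{1..10}, Y_{1..10}, r)$ to a loop probability; input and output are
concatenated into the 22-D methylation block.

**Sequence block (512-D).** Each anchor contributes its forward window and
its reverse complement (4 sequences per loop). Sequences are one-hot
encoded (4×L, N → zero column), cut into 1000 bp windows overlapping by
500 bp, and passed through a 1-D CNN: two conv/ReLU/maxpool/dropout blocks,
a third conv, a learnable per-channel position-weighted sum, and tanh,
giving 128 values per window; a sequence embedding is the mean over its
windows. The extractor is trained (stage 2) under a temporary logistic head
and then frozen. 4 × 128 = 512 values per loop.

**Fusion (stage 3).** The 535-vector — 22 methylation + 512 sequence + 1
anchor midpoint distance in bp — feeds a second gradient-boosted ensemble
that emits the final loop probability in [0, 1].

Training data come from a positive BEDPE plus synthesized negatives:
5 kb windows tiled over the genome, kept only if ≥ 500 bp clear of every
positive anchor, then paired at random so the negative distance histogram
matches the positives bin-for-bin (1:1 class balance). Splits are
chromosome-partitioned (train: chr4/7/8/11, validation: chr5/14, test: the
rest). Downstream analyses cover methylation-swap perturbation, k = 4
K-means anchor-pattern clustering, E-E/E-P/P-P loop typing, genome-bin
enrichment, a threshold methylation-canyon caller (> 7.3 kb, mean
probability ≤ 0.1) and long-range (> 2 Mb) recall evaluation. A seeded
synthetic-data generator emulates all planted structure, so the whole
pipeline runs without downloads.

## Worked example

Everything below is driven by the `nanoloop` CLI against a simulated
fixture; the library functions behind each subcommand are importable from
`nanoloop`.

```sh
nanoloop simulate --profile tiny --seed 0 --out fixture
nanoloop sample --loops fixture/loops_positive.bedpe \
                --chrom-sizes fixture/chrom.sizes --out samples --seed 1
# -> 48 positives, 48 negatives

cat > config.yaml <<EOF
output_dir: run
seed: 0
simulate: {profile: tiny}
features: {l_anchor: 1000, window: 1000, step: 500}
extractor: {filters1: 16, filters2: 32}
trees: {n_estimators: 200}
training: {max_epochs: 6, patience: 3}
EOF
nanoloop run --config config.yaml
cat run/metrics.json
```

```json
{
  "n_train": 33,
  "n_val": 34,
  "n_test": 29,
  "n_positives": 48,
  "n_negatives": 48,
  "negative_positive_ratio": 1.0,
  "test_prevalence": 0.5517241379310345,
  "test_auprc": 0.915948275862069
}
```

The held-out test chromosome is scored at auPRC 0.916 against a 0.55
prevalence baseline — the model has recovered the planted methylation and
motif signal. The downstream analyses run off the same artifacts:

```sh
nanoloop swap --bundle run/bundle --genome run/fixture/genome.fa \
              --meth run/fixture/methylation.tsv \
              --loops run/samples/positives.bedpe --out swap.tsv --seed 0
# -> mean before 0.0616 -> after 0.9343
nanoloop canyons --meth fixture/methylation.tsv \
                 --chrom-sizes fixture/chrom.sizes --out canyons.bed
# -> 3 canyons  (the three planted >7.3 kb low-methylation regions)
```

The swap line says: positive loops that happened to score ≤ 0.3 jump to a
mean probability of 0.93 once their 22-D methylation block is replaced by a
high-probability donor's, sequence and distance untouched — methylation
state alone moves the prediction.

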