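"""Methylation and sequence feature construction for loop prediction.

Methylation features: each ~5 kb anchor is split into 10 equal-width bins and
the CpG sites with methylation probability >= tau (default 0.5) are counted
per bin, giving a 10-D count vector per anchor; the Pearson correlation of the
left and right anchor vectors (n = 10) is the coordination feature.

Sequence features: the anchor window is taken as the forward strand plus its
reverse complement for both anchors (four sequences per loop), one-hot encoded
(4 x L, N as an all-zero column) and cut into 1000 bp windows overlapping by
500 bp for the convolutional extractor.

The fused representation is a fixed-order 535-vector:
20 bin counts + Pearson r + methylation-module probability (22)
+ 4 x 128 sequence embeddings (512) + anchor distance in bp (1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import GenomicInterval, LoopPair, MethylationIndex

N_BINS = 10
DEFAULT_TAU = 0.5
DEFAULT_L_ANCHOR = 5000
DEFAULT_WINDOW = 1000
DEFAULT_STEP = 500
SEQ_EMBED_DIM = 128
N_SEQUENCES = 4
SEQ_BLOCK_DIM = SEQ_EMBED_DIM * N_SEQUENCES  # 512
FEATURE_DIM = 2 * N_BINS + 1 + 1 + SEQ_BLOCK_DIM + 1  # 535

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class AnchorMethylationProfile:
    """Per-bin qualifying-CpG counts for one anchor."""

    anchor: GenomicInterval
    counts: tuple[int, ...]
    tau: float

    def __post_init__(self) -> None:
        if len(self.counts) != N_BINS:
            raise ValueError(f"expected {N_BINS} bins, got {len(self.counts)}")


@dataclass(frozen=True)
class LoopMethylationFeatures:
    """The 21 stage-1 inputs: two 10-bin count vectors plus their Pearson r."""

    left_counts: tuple[int, ...]
    right_counts: tuple[int, ...]
    correlation: float

    def as_array(self) -> np.ndarray:
        return np.concatenate(
            [self.left_counts, self.right_counts, [self.correlation]]
        ).astype(float)


@dataclass(frozen=True)
class SequenceSet:
    """Left/right anchor forward sequences and their reverse complements."""

    left_forward: str
    left_reverse: str
    right_forward: str
    right_reverse: str

    def __post_init__(self) -> None:
        seqs = self.as_tuple()
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("the four sequences must have equal length")
        for s in seqs:
            if set(s) - set("ACGTN"):
                raise ValueError("sequence alphabet must be ACGTN")

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (
            self.left_forward,
            self.left_reverse,
            self.right_forward,
            self.right_reverse,
        )


@dataclass(frozen=True)
class LoopFeatureVector:
    """The fused 535-D representation of one candidate loop."""

    methylation_block: np.ndarray  # 22: counts(20) + r + stage-1 probability
    sequence_block: np.ndarray  # 512: four concatenated 128-D embeddings
    distance: float

    def __post_init__(self) -> None:
        if self.methylation_block.shape != (2 * N_BINS + 2,):
            raise ValueError("methylation block must have 22 values")
        if self.sequence_block.shape != (SEQ_BLOCK_DIM,):
            raise ValueError("sequence block must have 512 values")

    def as_array(self) -> np.ndarray:
        vec = np.concatenate(
            [self.methylation_block, self.sequence_block, [self.distance]]
        )
        assert vec.shape == (FEATURE_DIM,)
        return vec


def feature_names() -> list[str]:
    """Names of the 535 fused features, in assembly order."""
    names = [f"meth_count_left_{b}" for b in range(N_BINS)]
    names += [f"meth_count_right_{b}" for b in range(N_BINS)]
    names += ["meth_correlation", "meth_module_prob"]
    for tag in ("left_fwd", "left_rev", "right_fwd", "right_rev"):
        names += [f"seq_{tag}_{i}" for i in range(SEQ_EMBED_DIM)]
    names.append("distance")
    assert len(names) == FEATURE_DIM
    return names


# ---------------------------------------------------------------------------
# Methylation block


def bin_cpg_counts(
    anchor: GenomicInterval,
    meth: MethylationIndex,
    n_bins: int = N_BINS,
    tau: float = DEFAULT_TAU,
) -> AnchorMethylationProfile:
    """Count CpGs with probability >= tau in n_bins equal-width anchor bins.

    Bin width is floor(len/n_bins); any remainder bp extend the last bin, so
    the bins exactly tile the anchor and the counts conserve the total number
    of qualifying CpGs inside it.
    """
    if len(anchor) < n_bins:
        raise ValueError(f"anchor shorter than {n_bins} bp cannot be binned")
    positions, probs = meth.query(anchor)
    qualifying = positions[probs >= tau]
    width = len(anchor) // n_bins
    # offsets beyond the last regular bin fall into bin n_bins-1
    bins = np.minimum((qualifying - anchor.start) // width, n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    return AnchorMethylationProfile(anchor, tuple(int(c) for c in counts), tau)


def methylation_correlation(x, y) -> float:
    """Pearson product-moment correlation of two 10-bin count vectors.

    A zero-variance vector carries no coordination evidence; the correlation
    is defined as 0.0 in that degenerate case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must have equal length")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0.0:
        return 0.0
    return float(np.clip((dx * dy).sum() / denom, -1.0, 1.0))


def loop_methylation_features(
    loop: LoopPair,
    meth: MethylationIndex,
    tau: float = DEFAULT_TAU,
) -> LoopMethylationFeatures:
    left = bin_cpg_counts(loop.left, meth, tau=tau)
    right = bin_cpg_counts(loop.right, meth, tau=tau)
    r = methylation_correlation(left.counts, right.counts)
    return LoopMethylationFeatures(left.counts, right.counts, r)


# ---------------------------------------------------------------------------
# Sequence block


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def standardize_anchor_window(
    anchor: GenomicInterval,
    genome: dict[str, str],
    l_anchor: int = DEFAULT_L_ANCHOR,
) -> str:
    """The L_anchor window centered on the anchor midpoint, N-padded at ends."""
    if anchor.chrom not in genome:
        raise KeyError(f"chromosome {anchor.chrom!r} not in genome")
    chrom_seq = genome[anchor.chrom]
    mid = anchor.midpoint
    start = mid - l_anchor // 2
    end = start + l_anchor
    left_pad = max(0, -start)
    right_pad = max(0, end - len(chrom_seq))
    seq = chrom_seq[max(0, start) : min(len(chrom_seq), end)]
    return "N" * left_pad + seq + "N" * right_pad


def build_sequence_sets(
    loop: LoopPair,
    genome: dict[str, str],
    l_anchor: int = DEFAULT_L_ANCHOR,
) -> SequenceSet:
    lf = standardize_anchor_window(loop.left, genome, l_anchor)
    rf = standardize_anchor_window(loop.right, genome, l_anchor)
    return SequenceSet(lf, reverse_complement(lf), rf, reverse_complement(rf))


def one_hot(seq: str) -> np.ndarray:
    """4 x len indicator matrix (rows A,C,G,T); N gives an all-zero column."""
    mat = np.zeros((4, len(seq)), dtype=np.float32)
    for i, ch in enumerate(seq):
        row = _BASE_INDEX.get(ch)
        if row is not None:
            mat[row, i] = 1.0
    return mat


def split_windows(
    matrix: np.ndarray, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
) -> np.ndarray:
    """Cut a 4 x L one-hot matrix into overlapping windows.

    Returns an array of shape (n_windows, 4, window) where
    n_windows = (L - window) / step + 1; L must satisfy that exactly
    (guaranteed by standardize_anchor_window defaults).
    """
    length = matrix.shape[1]
    if length < window:
        raise ValueError(f"sequence length {length} shorter than window {window}")
    if (length - window) % step != 0:
        raise ValueError(
            f"(L - window) = {length - window} not divisible by step {step}"
        )
    n = (length - window) // step + 1
    out = np.empty((n, 4, window), dtype=matrix.dtype)
    for k in range(n):
        out[k] = matrix[:, k * step : k * step + window]
    return out


def assemble_feature_vector(
    meth: LoopMethylationFeatures,
    meth_prob: float,
    seq_features: np.ndarray,
    distance: float,
) -> LoopFeatureVector:
    """Concatenate blocks in the fixed order: 20 counts, r, stage-1 prob,
    512 sequence values, distance."""
    seq_features = np.asarray(seq_features, dtype=float)
    if seq_features.shape != (SEQ_BLOCK_DIM,):
        raise ValueError(
            f"sequence block must have {SEQ_BLOCK_DIM} values, "
            f"got {seq_features.shape}"
        )
    if not 0.0 <= meth_prob <= 1.0:
        raise ValueError("methylation-module probability must be in [0,1]")
    block22 = np.concatenate([meth.as_array(), [meth_prob]])
    return LoopFeatureVector(block22, seq_features, float(distance))


def stage1_feature_matrix(
    loops: list[LoopPair], meth: MethylationIndex, tau: float = DEFAULT_TAU
) -> np.ndarray:
    """n x 21 matrix of methylation-module inputs, one row per loop."""
    return np.array(
        [loop_methylation_features(lp, meth, tau=tau).as_array() for lp in loops]
    ).reshape(len(loops), 2 * N_BINS + 1)
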