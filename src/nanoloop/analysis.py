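"""Downstream analyses: perturbation, clustering, annotation, canyons.

Covers the interpretive workflow around the predictor: the methylation-swap
experiment (does grafting a high-probability loop's methylation onto a
low-probability loop raise its score?), K-means clustering of anchor/loop
methylation patterns with z-score standardization, pattern-combination and
loop-type summaries, genome-bin enrichment, length-weighted signal
aggregation, a threshold-based methylation-canyon caller, and the long-range
loop evaluation helpers (recall vs threshold, distance histogram, canyon
overlap classes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core_io import ChromSizes, GenomicInterval, LoopPair, MethylationIndex, SignalTrack
from .model import DISTANCE_COL, METH_BLOCK, ModelBundle

log = logging.getLogger("nanoloop")

DEFAULT_K = 4
CANYON_MIN_LENGTH = 7300  # bp; canyons are defined as longer than this


# ---------------------------------------------------------------------------
# Methylation swap


@dataclass
class SwapExperiment:
    """Before/after probabilities of low-probability loops whose 22-D
    methylation block was replaced by a randomly paired high-probability donor's
    (sequence and distance blocks untouched)."""

    low_indices: np.ndarray
    high_indices: np.ndarray
    donor_for_low: np.ndarray
    before: np.ndarray
    after: np.ndarray
    p_hi: float
    p_lo: float
    seed: int


def methylation_swap(
    bundle: ModelBundle,
    frame: pd.DataFrame,
    probabilities: np.ndarray,
    p_hi: float = 0.7,
    p_lo: float = 0.3,
    seed: int = 0,
) -> SwapExperiment:
    """Replace low-group methylation blocks with high-group donors and re-score.

    Groups are defined by predicted probability (>= p_hi, <= p_lo) and
    subsampled to equal size; each low loop receives the full 22-D block
    (20 counts, Pearson r, stage-1 probability) of one seeded-random donor.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    high = np.flatnonzero(probabilities >= p_hi)
    low = np.flatnonzero(probabilities <= p_lo)
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both probability groups must be non-empty")
    rng = np.random.default_rng(seed)
    n = min(len(high), len(low))
    high = rng.choice(high, size=n, replace=False)
    low = rng.choice(low, size=n, replace=False)
    donors = rng.choice(high, size=n, replace=True)

    swapped = frame.iloc[low].copy()
    meth_cols = frame.columns[METH_BLOCK]
    swapped.loc[:, meth_cols] = frame.iloc[donors][meth_cols].to_numpy()
    after = bundle.score_matrix(swapped)
    return SwapExperiment(
        low_indices=low,
        high_indices=high,
        donor_for_low=donors,
        before=probabilities[low],
        after=after,
        p_hi=p_hi,
        p_lo=p_lo,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Clustering (z-score standardization, then K-means, labels canonicalized)


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # in standardized space, relabeled
    mean: np.ndarray
    std: np.ndarray
    labels: np.ndarray
    inertia: float


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score per feature; zero-variance features are left at 0."""
    mu = x.mean(axis=0)
    sigma = x.std(axis=0)
    z = np.where(sigma > 0, (x - mu) / np.where(sigma > 0, sigma, 1.0), 0.0)
    return z, mu, sigma


def _cluster(x: np.ndarray, k: int, seed: int) -> ClusterModel:
    x = np.asarray(x, dtype=float)
    if len(x) < k:
        raise ValueError(f"need at least k={k} samples, got {len(x)}")
    z, mu, sigma = _standardize(x)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw_labels = km.fit_predict(z)
    # canonical order: ascending mean raw methylation count per cluster
    means = np.array([x[raw_labels == c].mean() for c in range(k)])
    order = np.argsort(means, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_[order],
        mean=mu,
        std=sigma,
        labels=relabel[raw_labels],
        inertia=float(km.inertia_),
    )


def cluster_loops(loop_counts: np.ndarray, k: int = DEFAULT_K, seed: int = 0) -> ClusterModel:
    """K-means over per-loop 20-D CpG count vectors (left + right anchors)."""
    loop_counts = np.asarray(loop_counts, dtype=float)
    if loop_counts.ndim != 2 or loop_counts.shape[1] != 20:
        raise ValueError("loop clustering expects an n x 20 count matrix")
    return _cluster(loop_counts, k, seed)


def cluster_anchors(anchor_counts: np.ndarray, k: int = DEFAULT_K, seed: int = 0) -> ClusterModel:
    """K-means over per-anchor 10-D CpG count vectors (two samples per loop)."""
    anchor_counts = np.asarray(anchor_counts, dtype=float)
    if anchor_counts.ndim != 2 or anchor_counts.shape[1] != 10:
        raise ValueError("anchor clustering expects an n x 10 count matrix")
    return _cluster(anchor_counts, k, seed)


def sse_elbow(
    features: np.ndarray, k_range: range, seed: int = 0
) -> list[tuple[int, float]]:
    """Within-cluster sum of squared errors for each candidate k."""
    features = np.asarray(features, dtype=float)
    ks = list(k_range)
    if not ks or min(ks) < 1 or max(ks) > len(features):
        raise ValueError("invalid k range")
    z, _, _ = _standardize(features)
    out = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        km.fit(z)
        out.append((k, float(km.inertia_)))
    return out


def pattern_combinations(
    left_labels: np.ndarray, right_labels: np.ndarray, k: int = DEFAULT_K
) -> np.ndarray:
    """k x k unordered-pair frequency matrix of anchor cluster combinations.

    Cell (i, j) with i <= j counts loops whose anchors fall in clusters i and
    j (order ignored); the lower triangle stays 0; the total equals the loop
    count.
    """
    left_labels = np.asarray(left_labels, dtype=int)
    right_labels = np.asarray(right_labels, dtype=int)
    if left_labels.shape != right_labels.shape:
        raise ValueError("every loop needs both anchor labels")
    mat = np.zeros((k, k), dtype=int)
    for a, b in zip(left_labels, right_labels):
        i, j = (a, b) if a <= b else (b, a)
        mat[i, j] += 1
    return mat


# ---------------------------------------------------------------------------
# Annotation and signal


def _overlaps_any(anchor: GenomicInterval, intervals: list[GenomicInterval]) -> bool:
    return any(anchor.overlaps(iv) for iv in intervals)


def annotate_loop_types(
    loops: list[LoopPair],
    enhancers: list[GenomicInterval],
    promoters: list[GenomicInterval],
) -> list[str]:
    """Classify loops as E-E / E-P / P-P / other from anchor overlaps.

    An anchor overlapping both annotation kinds counts as promoter
    (promoter precedence)."""

    def mark(anchor: GenomicInterval) -> str:
        if _overlaps_any(anchor, promoters):
            return "P"
        if _overlaps_any(anchor, enhancers):
            return "E"
        return "."

    classes = []
    for lp in loops:
        marks = sorted((mark(lp.left), mark(lp.right)))
        if marks == ["E", "E"]:
            classes.append("E-E")
        elif marks == ["E", "P"]:
            classes.append("E-P")
        elif marks == ["P", "P"]:
            classes.append("P-P")
        else:
            classes.append("other")
    return classes


def signal_enrichment(
    regions: list[GenomicInterval] | list[LoopPair], track: SignalTrack
) -> np.ndarray:
    """Length-weighted mean track value per region; uncovered bp contribute 0.

    A loop's value is the mean of its two anchors' values."""

    def interval_mean(iv: GenomicInterval) -> float:
        spans = track.intervals.get(iv.chrom)
        if spans is None or len(spans) == 0:
            return 0.0
        values = track.values[iv.chrom]
        overlap = np.minimum(spans[:, 1], iv.end) - np.maximum(spans[:, 0], iv.start)
        overlap = np.clip(overlap, 0, None)
        return float((overlap * values).sum() / len(iv))

    out = []
    for region in regions:
        if isinstance(region, LoopPair):
            out.append(
                0.5 * (interval_mean(region.left) + interval_mean(region.right))
            )
        else:
            out.append(interval_mean(region))
    return np.array(out, dtype=float)


def genome_bin_enrichment(
    intervals: list[GenomicInterval],
    chrom_sizes: ChromSizes,
    n_bins: int = 100,
) -> dict[str, np.ndarray]:
    """Per-chromosome counts of intervals over n_bins equal bins (by midpoint)."""
    counts = {chrom: np.zeros(n_bins, dtype=int) for chrom in chrom_sizes}
    for iv in intervals:
        length = chrom_sizes.get(iv.chrom)
        if length is None:
            raise ValueError(f"unknown chromosome {iv.chrom}")
        mid = iv.midpoint
        if mid >= length:
            raise ValueError(
                f"interval midpoint {mid} beyond {iv.chrom} length {length}"
            )
        b = min(int(mid / length * n_bins), n_bins - 1)
        counts[iv.chrom][b] += 1
    return counts


# ---------------------------------------------------------------------------
# Methylation canyons (threshold caller)


@dataclass
class CanyonSet:
    intervals: list[GenomicInterval] = field(default_factory=list)
    min_length: int = CANYON_MIN_LENGTH
    ceiling: float = 0.1


def call_canyons(
    meth: MethylationIndex,
    chrom_sizes: ChromSizes,
    window: int = 1000,
    ceiling: float = 0.1,
    min_length: int = CANYON_MIN_LENGTH,
    merge_gap: int = 1000,
) -> CanyonSet:
    """Threshold caller for large low-methylation regions.

    The genome is tiled in fixed windows; a window whose mean CpG probability
    is <= ceiling (windows without CpGs are ignored) is low. Low windows
    within merge_gap bp of each other are merged, and merged runs longer than
    min_length are reported as canyons.
    """
    canyons: list[GenomicInterval] = []
    for chrom, length in chrom_sizes.items():
        low_runs: list[list[int]] = []  # [start, end] of merged low stretches
        for start in range(0, length, window):
            end = min(start + window, length)
            _, probs = meth.query(GenomicInterval(chrom, start, end))
            if len(probs) == 0 or probs.mean() > ceiling:
                continue
            if low_runs and start - low_runs[-1][1] <= merge_gap:
                low_runs[-1][1] = end
            else:
                low_runs.append([start, end])
        for start, end in low_runs:
            if end - start > min_length:
                canyons.append(GenomicInterval(chrom, start, end))
    return CanyonSet(canyons, min_length=min_length, ceiling=ceiling)


def canyon_overlap_classes(
    loops: list[LoopPair], canyons: CanyonSet
) -> dict[str, float]:
    """Proportions of loops with both / one / neither anchor in a canyon."""
    counts = {"both": 0, "one": 0, "neither": 0}
    for lp in loops:
        n = sum(
            _overlaps_any(anchor, canyons.intervals)
            for anchor in (lp.left, lp.right)
        )
        counts[("neither", "one", "both")[n]] += 1
    total = max(len(loops), 1)
    return {key: val / total for key, val in counts.items()}


# ---------------------------------------------------------------------------
# Long-range evaluation


def recall_at_thresholds(
    probabilities: np.ndarray, labels: np.ndarray, thresholds
) -> np.ndarray:
    """recall(t) = fraction of positive loops scoring >= t, per threshold."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = probabilities[labels == 1]
    if len(pos) == 0:
        raise ValueError("recall needs at least one positive")
    return np.array([float(np.mean(pos >= t)) for t in thresholds])


def distance_histogram(loops: list[LoopPair], bin_edges_mb) -> np.ndarray:
    """Loop counts per distance bin; bins right-open, final bin right-closed.

    Out-of-range distances are clipped into the first/last bin so the counts
    always conserve the total loop count.
    """
    edges = np.asarray(bin_edges_mb, dtype=float) * 1e6
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly ascending")
    dists = np.array([lp.distance for lp in loops], dtype=float)
    if len(dists):
        dists = np.clip(dists, edges[0], edges[-1])
    counts, _ = np.histogram(dists, bins=edges)
    return counts
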