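"""Training-set construction: distance-matched negatives and chromosome splits.

Negatives are synthesized by tiling each chromosome with fixed-width windows
(the HiCCUPS anchor resolution, 5 kb), discarding any window that comes within
``min_gap`` bp of a positive anchor, and then pairing the surviving anchors at
random so that the negative loop distances reproduce the positive distance
histogram bin-for-bin (20 log-spaced bins), targeting a 1:1 class balance.

Splits are chromosome-partitioned: chromosomes 4, 7, 8 and 11 train,
5 and 14 validate, everything else tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    NEGATIVE,
    ChromSizes,
    GenomicInterval,
    LoopPair,
    MethylationIndex,
    make_loop,
    read_bedpe,
    write_bedpe,
)
from .features import bin_cpg_counts

log = logging.getLogger("nanoloop")

DEFAULT_WINDOW = 5000
DEFAULT_MIN_GAP = 500
DEFAULT_N_DISTANCE_BINS = 20
DRAW_BUDGET_FACTOR = 1000

TRAIN_CHROMS = frozenset({"4", "7", "8", "11"})
VAL_CHROMS = frozenset({"5", "14"})


def normalize_chrom(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


@dataclass
class SampleManifest:
    """Positives, synthesized negatives, and the chromosome-partitioned split."""

    positives: list[LoopPair]
    negatives: list[LoopPair]
    splits: dict[str, str] = field(default_factory=dict)  # loop key -> split
    seed: int = 0
    parameters: dict = field(default_factory=dict)

    @staticmethod
    def loop_key(lp: LoopPair) -> str:
        return (
            f"{lp.left.chrom}:{lp.left.start}-{lp.left.end}|"
            f"{lp.right.chrom}:{lp.right.start}-{lp.right.end}"
        )

    def split_of(self, lp: LoopPair) -> str:
        return self.splits[self.loop_key(lp)]

    def subset(self, split: str) -> tuple[list[LoopPair], np.ndarray]:
        """Loops of one split with their binary labels (positive=1)."""
        loops, labels = [], []
        for lab, group in ((1, self.positives), (0, self.negatives)):
            for lp in group:
                if self.split_of(lp) == split:
                    loops.append(lp)
                    labels.append(lab)
        return loops, np.array(labels, dtype=int)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_bedpe(self.positives, out_dir / "positives.bedpe")
        write_bedpe(self.negatives, out_dir / "negatives.bedpe")
        with open(out_dir / "splits.tsv", "w") as fh:
            for key, split in self.splits.items():
                fh.write(f"{key}\t{split}\n")
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(
                {"seed": self.seed, "parameters": self.parameters}, fh, indent=2
            )

    @classmethod
    def load(cls, out_dir: str | Path) -> "SampleManifest":
        out_dir = Path(out_dir)
        positives = read_bedpe(out_dir / "positives.bedpe", label="positive")
        negatives = read_bedpe(out_dir / "negatives.bedpe", label="negative")
        splits = {}
        with open(out_dir / "splits.tsv") as fh:
            for line in fh:
                key, split = line.strip().split("\t")
                splits[key] = split
        with open(out_dir / "manifest.json") as fh:
            meta = json.load(fh)
        return cls(positives, negatives, splits, meta["seed"], meta["parameters"])


def generate_negative_anchors(
    chrom_sizes: ChromSizes,
    positive_anchors: list[GenomicInterval],
    window: int = DEFAULT_WINDOW,
    min_gap: int = DEFAULT_MIN_GAP,
) -> list[GenomicInterval]:
    """Tile each chromosome with non-overlapping ``window`` bp anchors and
    keep those that stay at least ``min_gap`` bp clear of every positive anchor.
    """
    pos_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in positive_anchors:
        pos_by_chrom.setdefault(iv.chrom, []).append(iv)
        if iv.chrom not in chrom_sizes:
            raise ValueError(f"positive anchor on unknown chromosome {iv.chrom}")

    kept: list[GenomicInterval] = []
    for chrom, length in chrom_sizes.items():
        positives = pos_by_chrom.get(chrom, [])
        starts = np.array([iv.start for iv in positives], dtype=np.int64)
        ends = np.array([iv.end for iv in positives], dtype=np.int64)
        n_kept_before = len(kept)
        for start in range(0, length - window + 1, window):
            end = start + window
            # overlap test against the candidate expanded by min_gap
            if len(starts) and np.any(
                (starts < end + min_gap) & (ends > start - min_gap)
            ):
                continue
            kept.append(GenomicInterval(chrom, start, end))
        if len(kept) == n_kept_before:
            log.warning(
                "no negative anchor candidates survived on %s; skipping", chrom
            )
    return kept


def _distance_bins(
    positive_distances: np.ndarray, n_bins: int = DEFAULT_N_DISTANCE_BINS
) -> np.ndarray:
    """Log-spaced bin edges spanning the positive distance range."""
    lo, hi = positive_distances.min(), positive_distances.max()
    if lo == hi:
        return np.array([lo, hi + 1], dtype=float)
    edges = np.geomspace(lo, hi, n_bins + 1)
    edges[-1] = hi + 1  # right-open bins must cover the max
    return edges


def pair_and_match_distance(
    negative_anchors: list[GenomicInterval],
    positive_loops: list[LoopPair],
    seed: int = 0,
    n_bins: int = DEFAULT_N_DISTANCE_BINS,
) -> list[LoopPair]:
    """Randomly pair negative anchors so their distance histogram matches the
    positives' (same log-spaced bins, same per-bin counts), giving ~1:1 balance.

    Infeasible bins are reported as a logged shortfall after a bounded number
    of draws; the function never loops forever.
    """
    if not positive_loops:
        return []
    rng = np.random.default_rng(seed)
    pos_d = np.array([lp.distance for lp in positive_loops], dtype=float)
    edges = _distance_bins(pos_d, n_bins)
    quota, _ = np.histogram(pos_d, bins=edges)

    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in negative_anchors:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    chroms = [c for c, ivs in by_chrom.items() if len(ivs) >= 2]
    if not chroms:
        log.warning("no chromosome holds >= 2 negative anchors; 0 negatives")
        return []
    weights = np.array([len(by_chrom[c]) for c in chroms], dtype=float)
    weights /= weights.sum()

    needed = int(quota.sum())
    budget = DRAW_BUDGET_FACTOR * needed
    remaining = quota.copy()
    negatives: list[LoopPair] = []
    used: set[tuple] = set()
    draws = 0
    while remaining.sum() > 0 and draws < budget:
        draws += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        anchors = by_chrom[chrom]
        i, j = rng.choice(len(anchors), size=2, replace=False)
        loop = make_loop(anchors[i], anchors[j], NEGATIVE)
        b = int(np.searchsorted(edges, loop.distance, side="right")) - 1
        if b < 0 or b >= len(remaining) or remaining[b] == 0:
            continue
        key = SampleManifest.loop_key(loop)
        if key in used:
            continue
        used.add(key)
        remaining[b] -= 1
        negatives.append(loop)
    shortfall = int(remaining.sum())
    if shortfall:
        log.warning(
            "distance matching shortfall: %d of %d negatives not generated",
            shortfall,
            needed,
        )
    return negatives


def split_by_chromosome(
    loops: list[LoopPair],
    train_chroms: frozenset[str] = TRAIN_CHROMS,
    val_chroms: frozenset[str] = VAL_CHROMS,
) -> dict[str, str]:
    """Assign each loop to train/val/test purely by its chromosome name."""
    splits: dict[str, str] = {}
    for lp in loops:
        chrom = normalize_chrom(lp.left.chrom)
        if chrom in train_chroms:
            split = "train"
        elif chrom in val_chroms:
            split = "val"
        else:
            split = "test"
        splits[SampleManifest.loop_key(lp)] = split
    return splits


def build_manifest(
    positive_loops: list[LoopPair],
    chrom_sizes: ChromSizes,
    seed: int = 0,
    window: int = DEFAULT_WINDOW,
    min_gap: int = DEFAULT_MIN_GAP,
    train_chroms: frozenset[str] = TRAIN_CHROMS,
    val_chroms: frozenset[str] = VAL_CHROMS,
) -> SampleManifest:
    """Full sampling workflow: negatives, distance matching, chromosome split."""
    pos_anchors = [lp.left for lp in positive_loops] + [
        lp.right for lp in positive_loops
    ]
    neg_anchors = generate_negative_anchors(
        chrom_sizes, pos_anchors, window=window, min_gap=min_gap
    )
    negatives = pair_and_match_distance(neg_anchors, positive_loops, seed=seed)
    splits = split_by_chromosome(
        positive_loops + negatives, train_chroms, val_chroms
    )
    return SampleManifest(
        positives=list(positive_loops),
        negatives=negatives,
        splits=splits,
        seed=seed,
        parameters={"window": window, "min_gap": min_gap},
    )


def mean_anchor_cpg_content(
    loops: list[LoopPair],
    labels: np.ndarray,
    meth: MethylationIndex,
    tau: float = 0.5,
) -> dict[str, float]:
    """Mean qualifying-CpG count per anchor, separately for each label class."""
    sums = {0: [], 1: []}
    for lp, lab in zip(loops, labels, strict=True):
        for anchor in (lp.left, lp.right):
            sums[int(lab)].append(sum(bin_cpg_counts(anchor, meth, tau=tau).counts))
    return {
        "positive": float(np.mean(sums[1])) if sums[1] else 0.0,
        "negative": float(np.mean(sums[0])) if sums[0] else 0.0,
    }
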