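"""Seeded simulator of genomes, methylomes and loop sets.

The generator emits data with the statistical structure the predictor
assumes, so every training stage and analysis runs without external
downloads:

* candidate anchor pairs on a 5 kb grid whose positive/negative status is a
  logistic function of anchor distance, anchor-anchor methylation
  coordination, and a planted sequence motif;
* a genome of uniform random nucleotides with the motif planted at
  motif-bearing anchors and CpG sites placed at a configurable density
  (enriched at true-loop anchors, where callers see CpG-island-like spacing);
* a per-CpG methylome in which coordinated anchor pairs share a latent
  per-bin methylation level, giving their 10-bin qualifying-CpG counts an
  expected Pearson correlation of rho; background CpGs draw from Beta(2,5)
  (most mass below 0.6), canyon CpGs from near zero;
* large low-methylation canyons planted away from anchors;
* optionally two haplotype methylomes differing only at one DMR anchor
  (the imprinting-switch scenario);
* a "clustering-blobs" fixture of four well-separated 10-bin count patterns
  for cluster-recovery tests.

One seed fixes every draw; identical seeds give byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    POSITIVE,
    GenomicInterval,
    LoopPair,
    MethylationRecord,
    write_bed,
    write_bedpe,
    write_chrom_sizes,
    write_fasta,
    write_methylation_tsv,
)

LONG_RANGE_BP = 2_000_000


def _sigmoid(z: float) -> float:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class SimulationConfig:
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr4": 1_000_000, "chr5": 1_000_000}
    )
    anchor_width: int = 5000
    cpg_density: float = 0.01  # background CpG sites per bp
    anchor_cpg_density: float = 0.03  # at true-loop anchors
    motif: str = "CCACCAGGTGGC"  # fixed 12-mer planted at motif-bearing anchors
    motif_plant_prob: float = 0.9
    background_beta: tuple[float, float] = (2.0, 5.0)
    rho: float = 0.7  # target anchor-anchor count correlation
    latent_sd: float = 0.15  # spread of the shared per-bin latent level
    distance_scale: float = 200_000.0  # decay scale of the distance term (bp)
    min_distance: int = 20_000
    n_positive_per_chrom: int = 30
    n_long_range_per_chrom: int = 0
    n_canyons_per_chrom: int = 2
    canyon_length: int = 10_000
    coordination_prob: float = 0.5
    motif_pair_prob: float = 0.5
    beta0: float = -3.0
    beta1: float = 2.0
    beta2: float = 6.0
    beta3: float = 2.0
    imprinting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.motif_plant_prob,
            self.coordination_prob,
            self.motif_pair_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0,1)")
        if len(self.motif) > self.anchor_width:
            raise ValueError("motif longer than anchor")


@dataclass(frozen=True)
class CandidateLoop:
    loop: LoopPair
    generative_probability: float
    label: int
    coordinated: bool
    has_motif: bool

    @property
    def is_long_range(self) -> bool:
        return self.loop.distance > LONG_RANGE_BP


@dataclass
class GroundTruth:
    candidates: list[CandidateLoop]
    canyons: list[GenomicInterval]
    dmr: GenomicInterval | None
    config: SimulationConfig

    @property
    def positives(self) -> list[LoopPair]:
        return [c.loop for c in self.candidates if c.label == 1]

    @property
    def decoys(self) -> list[LoopPair]:
        return [c.loop for c in self.candidates if c.label == 0]


@dataclass
class SimulatedDataset:
    genome: dict[str, str]
    methylation: list[MethylationRecord]
    haplotype_methylomes: tuple[list[MethylationRecord], list[MethylationRecord]] | None
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Loop placement and labelling


def simulate_loops(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    """Place anchors on the 5 kb grid and label candidate pairs.

    Each candidate's generative probability is
    sigmoid(beta0 + beta1*exp(-d/scale) + beta2*r + beta3*motif),
    where r is rho for coordinated pairs and 0 otherwise. Long-range
    candidates (> 2 Mb) are always coordinated and motif-free, so their
    positivity is carried by the methylation term alone.
    """
    w = config.anchor_width
    candidates: list[CandidateLoop] = []
    canyons: list[GenomicInterval] = []

    for chrom, length in config.chrom_sizes.items():
        n_cells = length // w
        if n_cells < 10:
            raise ValueError(f"{chrom} too short for anchor placement")
        occupied: set[int] = set()

        def place_pair(d_cells: int) -> tuple[GenomicInterval, GenomicInterval] | None:
            if d_cells + 2 >= n_cells:
                return None
            left_cell = int(rng.integers(1, n_cells - d_cells - 1))
            right_cell = left_cell + d_cells
            if left_cell in occupied or right_cell in occupied:
                return None
            occupied.add(left_cell)
            occupied.add(right_cell)
            return (
                GenomicInterval(chrom, left_cell * w, (left_cell + 1) * w),
                GenomicInterval(chrom, right_cell * w, (right_cell + 1) * w),
            )

        def sample_candidate(long_range: bool) -> CandidateLoop | None:
            if long_range:
                max_d = min(length - 3 * w, 4_000_000)
                if max_d <= LONG_RANGE_BP + 3 * w:
                    raise ValueError(
                        f"{chrom} ({length} bp) cannot host >2 Mb loops"
                    )
                d_bp = rng.uniform(LONG_RANGE_BP + 2 * w, max_d)
                coordinated, has_motif = True, False
            else:
                max_d = length // 2
                d_bp = min(
                    config.min_distance + rng.exponential(config.distance_scale),
                    max_d,
                )
                coordinated = rng.random() < config.coordination_prob
                has_motif = rng.random() < config.motif_pair_prob
            d_cells = max(int(round(d_bp / w)), 3)
            pair = place_pair(d_cells)
            if pair is None:
                return None
            left, right = pair
            d = right.midpoint - left.midpoint
            r = config.rho if coordinated else 0.0
            z = (
                config.beta0
                + config.beta1 * np.exp(-d / config.distance_scale)
                + config.beta2 * r
                + config.beta3 * float(has_motif)
            )
            p = _sigmoid(z)
            label = int(rng.random() < p)
            return CandidateLoop(
                LoopPair(left, right, POSITIVE if label else "negative"),
                float(p),
                label,
                coordinated,
                has_motif,
            )

        for quota, long_range in (
            (config.n_positive_per_chrom, False),
            (config.n_long_range_per_chrom, True),
        ):
            got, attempts = 0, 0
            budget = 500 * max(quota, 1)
            while got < quota and attempts < budget:
                attempts += 1
                cand = sample_candidate(long_range)
                if cand is None:
                    continue
                candidates.append(cand)
                got += cand.label
            if got < quota:
                raise ValueError(
                    f"quota infeasible on {chrom}: placed {got}/{quota} "
                    f"{'long-range ' if long_range else ''}positives"
                )

        # canyons occupy anchor-free grid stretches (a canyon anchor would
        # have zero-variance bin counts, killing the coordination signal)
        span = config.canyon_length // w + 1
        for _ in range(config.n_canyons_per_chrom):
            for _attempt in range(200):
                start_cell = int(rng.integers(1, n_cells - span - 1))
                cells = range(start_cell, start_cell + span)
                if any(c in occupied for c in cells):
                    continue
                occupied.update(cells)
                canyons.append(
                    GenomicInterval(
                        chrom,
                        start_cell * w,
                        start_cell * w + config.canyon_length,
                    )
                )
                break

    dmr = None
    if config.imprinting:
        for cand in candidates:
            if cand.label == 1 and cand.coordinated:
                dmr = cand.loop.left
                break
    return GroundTruth(candidates, canyons, dmr, config)


# ---------------------------------------------------------------------------
# Genome


def _choose_cpg_positions(
    config: SimulationConfig, truth: GroundTruth, chrom: str, length: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[tuple[int, int], np.ndarray]]:
    """Background + canyon CpGs at cpg_density; positive anchors get a fixed
    per-bin complement at anchor_cpg_density. Returns all positions plus the
    per-anchor, per-bin position lists for coordinated-methylation writing.
    """
    w = config.anchor_width
    n_bins = 10
    bin_width = w // n_bins
    per_bin = max(int(round(config.anchor_cpg_density * bin_width)), 1)

    anchor_positions: dict[tuple[int, int], np.ndarray] = {}
    pos_anchor_spans = []
    for cand in truth.candidates:
        if cand.label != 1 or cand.loop.chrom != chrom:
            continue
        for anchor in (cand.loop.left, cand.loop.right):
            key = (anchor.start, anchor.end)
            if key in anchor_positions:
                continue
            bins = []
            for b in range(n_bins):
                lo = anchor.start + b * bin_width
                offsets = rng.choice(bin_width - 2, size=per_bin, replace=False)
                bins.append(np.sort(lo + offsets))
            anchor_positions[key] = np.concatenate(bins)
            pos_anchor_spans.append((anchor.start, anchor.end))

    n_background = int(config.cpg_density * length)
    background = rng.choice(length - 2, size=n_background, replace=False)
    # drop background sites inside positive anchors (those have fixed sites)
    if pos_anchor_spans:
        spans = np.array(pos_anchor_spans)
        inside = np.zeros(len(background), dtype=bool)
        for s, e in spans:
            inside |= (background >= s) & (background < e)
        background = background[~inside]

    all_pos = np.unique(
        np.concatenate([background] + list(anchor_positions.values()))
    )
    # enforce >= 2 bp spacing so injected "CG" dinucleotides cannot collide
    keep = np.r_[True, np.diff(all_pos) >= 2]
    all_pos = all_pos[keep]
    anchor_positions = {
        key: vals[np.isin(vals, all_pos)] for key, vals in anchor_positions.items()
    }
    return all_pos, anchor_positions


def simulate_genome(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, np.ndarray], dict[str, dict]]:
    """Uniform random genome with planted motifs and injected CpG sites.

    Returns the genome, the per-chromosome CpG position arrays, and the
    per-chromosome {anchor span: bin-structured CpG positions} maps consumed
    by the methylome simulator.
    """
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    motif = np.frombuffer(config.motif.encode(), dtype=np.uint8)
    genome: dict[str, str] = {}
    cpg_positions: dict[str, np.ndarray] = {}
    anchor_maps: dict[str, dict] = {}

    for chrom, length in config.chrom_sizes.items():
        seq = rng.choice(bases, size=length)
        positions, anchor_pos = _choose_cpg_positions(
            config, truth, chrom, length, rng
        )
        seq[positions] = ord("C")
        seq[positions + 1] = ord("G")
        # plant the motif at motif-bearing true-anchor midpoints
        for cand in truth.candidates:
            if cand.loop.chrom != chrom or not cand.has_motif:
                continue
            for anchor in (cand.loop.left, cand.loop.right):
                if rng.random() < config.motif_plant_prob:
                    mid = anchor.midpoint
                    seq[mid : mid + len(motif)] = motif
        genome[chrom] = seq.tobytes().decode("ascii")
        cpg_positions[chrom] = positions
        anchor_maps[chrom] = anchor_pos
    return genome, cpg_positions, anchor_maps


# ---------------------------------------------------------------------------
# Methylome


def sample_coordinated_bin_fractions(
    rng: np.random.Generator,
    n_pairs: int,
    rho: float,
    latent_sd: float = 0.15,
    n_bins: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired per-bin methylated fractions with Pearson expectation rho.

    Both anchors share a latent bin level u ~ N(0.5, latent_sd^2); each adds
    independent noise of variance latent_sd^2 * (1 - rho)/rho, so
    corr(u + eps_L, u + eps_R) = rho before clipping to [0.02, 0.98].
    With rho = 0 the two fraction vectors are drawn independently.
    """
    if rho <= 0.0:
        f_left = rng.normal(0.5, latent_sd, size=(n_pairs, n_bins))
        f_right = rng.normal(0.5, latent_sd, size=(n_pairs, n_bins))
    else:
        u = rng.normal(0.5, latent_sd, size=(n_pairs, n_bins))
        noise_sd = latent_sd * np.sqrt((1.0 - rho) / rho)
        f_left = u + rng.normal(0.0, noise_sd, size=(n_pairs, n_bins))
        f_right = u + rng.normal(0.0, noise_sd, size=(n_pairs, n_bins))
    return np.clip(f_left, 0.02, 0.98), np.clip(f_right, 0.02, 0.98)


def simulate_methylome(
    config: SimulationConfig,
    cpg_positions: dict[str, np.ndarray],
    anchor_maps: dict[str, dict],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[
    list[MethylationRecord],
    tuple[list[MethylationRecord], list[MethylationRecord]] | None,
]:
    """Per-CpG methylation probabilities.

    Background CpGs draw from Beta(a, b); canyon CpGs from near zero;
    coordinated positive anchor pairs write bin-level fractions sharing a
    latent level (expected count correlation rho). With the imprinting toggle,
    two haplotype methylomes are also returned, identical everywhere except
    the DMR anchor (hypo- vs hyper-methylated).
    """
    a, b = config.background_beta
    n_bins = 10
    prob_by_site: dict[str, np.ndarray] = {}

    for chrom, positions in cpg_positions.items():
        probs = rng.beta(a, b, size=len(positions))
        prob_by_site[chrom] = probs

    # canyons: near-zero methylation
    for canyon in truth.canyons:
        positions = cpg_positions[canyon.chrom]
        mask = (positions >= canyon.start) & (positions < canyon.end)
        prob_by_site[canyon.chrom][mask] = rng.beta(1.0, 30.0, size=mask.sum())

    # coordinated pairs: shared latent bin levels
    for cand in truth.candidates:
        if cand.label != 1 or not cand.coordinated:
            continue
        f_left, f_right = sample_coordinated_bin_fractions(
            rng, 1, config.rho, config.latent_sd, n_bins
        )
        for anchor, fractions in (
            (cand.loop.left, f_left[0]),
            (cand.loop.right, f_right[0]),
        ):
            _write_anchor_bins(
                config, anchor, fractions, cpg_positions, anchor_maps,
                prob_by_site, rng,
            )

    def to_records(probs: dict[str, np.ndarray]) -> list[MethylationRecord]:
        records = []
        for chrom in sorted(cpg_positions):
            for pos, p in zip(cpg_positions[chrom], probs[chrom]):
                records.append(MethylationRecord(chrom, int(pos), float(round(p, 4))))
        return records

    base = to_records(prob_by_site)
    haplotypes = None
    if config.imprinting and truth.dmr is not None:
        dmr = truth.dmr
        positions = cpg_positions[dmr.chrom]
        mask = (positions >= dmr.start) & (positions < dmr.end)
        hypo = {c: p.copy() for c, p in prob_by_site.items()}
        hyper = {c: p.copy() for c, p in prob_by_site.items()}
        hypo[dmr.chrom][mask] = rng.uniform(0.0, 0.2, size=mask.sum())
        hyper[dmr.chrom][mask] = rng.uniform(0.8, 1.0, size=mask.sum())
        haplotypes = (to_records(hypo), to_records(hyper))
    return base, haplotypes


def _write_anchor_bins(
    config, anchor, fractions, cpg_positions, anchor_maps, prob_by_site, rng
) -> None:
    """Set each bin's CpGs so that round(fraction * n_bin) sites are >= 0.5."""
    key = (anchor.start, anchor.end)
    sites = anchor_maps[anchor.chrom].get(key)
    if sites is None:
        return
    positions = cpg_positions[anchor.chrom]
    n_bins = 10
    bin_width = len(anchor) // n_bins
    for bin_i in range(n_bins):
        lo = anchor.start + bin_i * bin_width
        hi = anchor.end if bin_i == n_bins - 1 else lo + bin_width
        bin_sites = sites[(sites >= lo) & (sites < hi)]
        if len(bin_sites) == 0:
            continue
        n_high = int(round(fractions[bin_i] * len(bin_sites)))
        chosen = rng.choice(len(bin_sites), size=n_high, replace=False)
        high = np.zeros(len(bin_sites), dtype=bool)
        high[chosen] = True
        idx = np.searchsorted(positions, bin_sites)
        prob_by_site[anchor.chrom][idx[high]] = rng.uniform(0.6, 1.0, size=high.sum())
        prob_by_site[anchor.chrom][idx[~high]] = rng.uniform(
            0.0, 0.4, size=(~high).sum()
        )


# ---------------------------------------------------------------------------
# Orchestration and fixtures


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run loop placement, genome and methylome simulation under one seed."""
    root = np.random.SeedSequence(config.seed)
    rng_loops, rng_genome, rng_meth = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    truth = simulate_loops(config, rng_loops)
    genome, cpg_positions, anchor_maps = simulate_genome(config, truth, rng_genome)
    methylation, haplotypes = simulate_methylome(
        config, cpg_positions, anchor_maps, truth, rng_meth
    )
    return SimulatedDataset(genome, methylation, haplotypes, truth)


def make_cluster_blobs(
    n_per_cluster: int = 100,
    centers: tuple[float, ...] = (3.0, 9.0, 15.0, 22.0),
    sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Four well-separated 10-bin count blobs with their planted labels."""
    rng = np.random.default_rng(seed)
    counts, labels = [], []
    for label, center in enumerate(centers):
        block = rng.normal(center, sd, size=(n_per_cluster, 10))
        counts.append(np.clip(np.round(block), 0, None))
        labels.extend([label] * n_per_cluster)
    return np.vstack(counts), np.array(labels, dtype=int)


PROFILES = {
    "tiny": dict(
        chrom_sizes={"chr4": 600_000, "chr5": 400_000, "chr1": 500_000},
        n_positive_per_chrom=16,
        n_long_range_per_chrom=0,
        n_canyons_per_chrom=1,
        distance_scale=60_000.0,
        imprinting=True,
    ),
    "default": dict(
        chrom_sizes={"chr4": 5_000_000, "chr5": 2_500_000, "chr1": 5_000_000},
        n_positive_per_chrom=60,
        n_long_range_per_chrom=10,
        n_canyons_per_chrom=2,
        imprinting=True,
    ),
}


def _annotation_beds(
    truth: GroundTruth, rng: np.random.Generator
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Enhancer/promoter marks planted at positive-loop anchors."""
    enhancers, promoters = [], []
    for cand in truth.candidates:
        if cand.label != 1:
            continue
        for anchor in (cand.loop.left, cand.loop.right):
            roll = rng.random()
            mark = GenomicInterval(
                anchor.chrom, anchor.midpoint - 250, anchor.midpoint + 250
            )
            if roll < 0.4:
                enhancers.append(mark)
            elif roll < 0.8:
                promoters.append(mark)
    return enhancers, promoters


def make_fixture(
    profile: str, seed: int, out_dir: str | Path
) -> Path:
    """Write a complete text fixture directory for the named profile."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if profile == "clustering-blobs":
        counts, labels = make_cluster_blobs(seed=seed)
        np.savetxt(out_dir / "blobs.tsv", counts, fmt="%d", delimiter="\t")
        np.savetxt(out_dir / "blob_labels.tsv", labels, fmt="%d")
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump({"profile": profile, "seed": seed}, fh, indent=2)
        return out_dir

    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    config = SimulationConfig(seed=seed, **PROFILES[profile])
    data = simulate_dataset(config)
    truth = data.truth

    write_fasta(data.genome, out_dir / "genome.fa")
    write_chrom_sizes(config.chrom_sizes, out_dir / "chrom.sizes")
    write_methylation_tsv(data.methylation, out_dir / "methylation.tsv")
    if data.haplotype_methylomes is not None:
        hypo, hyper = data.haplotype_methylomes
        write_methylation_tsv(hypo, out_dir / "methylation_hap1.tsv")
        write_methylation_tsv(hyper, out_dir / "methylation_hap2.tsv")
    write_bedpe(truth.positives, out_dir / "loops_positive.bedpe")
    write_bedpe(truth.decoys, out_dir / "decoys.bedpe")
    write_bed(truth.canyons, out_dir / "canyons.bed")
    rng_annot = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    enhancers, promoters = _annotation_beds(truth, rng_annot)
    write_bed(enhancers, out_dir / "enhancers.bed")
    write_bed(promoters, out_dir / "promoters.bed")

    ground_truth = {
        "dmr": None
        if truth.dmr is None
        else [truth.dmr.chrom, truth.dmr.start, truth.dmr.end],
        "candidates": [
            {
                "chrom": c.loop.chrom,
                "left": [c.loop.left.start, c.loop.left.end],
                "right": [c.loop.right.start, c.loop.right.end],
                "label": c.label,
                "generative_probability": round(c.generative_probability, 6),
                "coordinated": c.coordinated,
                "has_motif": c.has_motif,
                "long_range": c.is_long_range,
            }
            for c in truth.candidates
        ],
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(ground_truth, fh, indent=2)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(
            {"profile": profile, "seed": seed, "config": asdict(config)},
            fh,
            indent=2,
        )
    return out_dir
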