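"""Run orchestration: structured config, staged execution, reproducible runs.

A run is described by one RunConfig (YAML on disk, strict schema: unknown
keys are rejected, values validated before any stage executes). All
randomness derives from the single root seed, expanded per stage, so two runs
with the same config produce identical manifests, bundles and metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import core_io, sampling
from .core_io import MethylationIndex, read_bedpe, read_chrom_sizes, read_fasta
from .features import feature_names
from .model import (
    ModelBundle,
    NanoLoopConfig,
    SequenceExtractorConfig,
    TrainParams,
    TreeParams,
    evaluate_auprc,
    train_nanoloop,
)
from .synthetic import make_fixture

log = logging.getLogger("nanoloop")


class ConfigError(ValueError):
    """Invalid run configuration (reported before any stage executes)."""


def _strict(cls, raw: dict, context: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown {context} keys: {sorted(unknown)}")
    try:
        return cls(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context} config: {exc}") from exc


@dataclass(frozen=True)
class PathsConfig:
    genome: str | None = None
    methylation: str | None = None
    loops: str | None = None
    chrom_sizes: str | None = None
    enhancers: str | None = None
    promoters: str | None = None


@dataclass(frozen=True)
class SimulateConfig:
    profile: str | None = None  # when set, inputs are generated into the run dir


@dataclass(frozen=True)
class FeatureConfig:
    l_anchor: int = 5000
    window: int = 1000
    step: int = 500
    tau: float = 0.5
    n_bins: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must lie in [0,1], got {self.tau}")
        if self.n_bins != 10:
            raise ValueError("the methylation block is defined over 10 bins")
        if (self.l_anchor - self.window) % self.step != 0:
            raise ValueError("(l_anchor - window) must be divisible by step")


@dataclass(frozen=True)
class SamplingConfig:
    window: int = 5000
    min_gap: int = 500
    train_chroms: tuple[str, ...] = ("4", "7", "8", "11")
    val_chroms: tuple[str, ...] = ("5", "14")


@dataclass(frozen=True)
class RunConfig:
    output_dir: str = "nanoloop_run"
    seed: int = 0
    log_level: str = "INFO"
    paths: PathsConfig = field(default_factory=PathsConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    extractor: dict = field(default_factory=dict)
    trees: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sub = {}
        for key, sub_cls in (
            ("paths", PathsConfig),
            ("simulate", SimulateConfig),
            ("features", FeatureConfig),
            ("sampling", SamplingConfig),
        ):
            if key in raw:
                value = raw.pop(key)
                if key == "sampling":
                    for ck in ("train_chroms", "val_chroms"):
                        if ck in value:
                            value[ck] = tuple(str(c) for c in value[ck])
                sub[key] = _strict(sub_cls, value, key)
        for key in ("extractor", "trees", "training"):
            if key in raw:
                sub[key] = dict(raw.pop(key))
        try:
            cfg = cls(**raw, **sub)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        cfg.model_config()  # validate nested model parameters eagerly
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def model_config(self) -> NanoLoopConfig:
        try:
            extractor = _strict(
                SequenceExtractorConfig,
                {
                    "window": self.features.window,
                    "step": self.features.step,
                    **self.extractor,
                },
                "extractor",
            )
            return NanoLoopConfig(
                l_anchor=self.features.l_anchor,
                tau=self.features.tau,
                extractor=extractor,
                trees=_strict(TreeParams, self.trees, "trees"),
                training=_strict(TrainParams, self.training, "training"),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """simulate (optional) -> sample -> train -> predict -> evaluate.

    Writes, under output_dir: the sample manifest, the trained bundle,
    test-set predictions, metrics.json, and run_manifest.json listing every
    input and output file with its checksum.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        root = np.random.SeedSequence(config.seed)
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(3)]
        inputs: dict[str, Path] = {}

        stage = "simulate"
        paths = config.paths
        if config.simulate.profile is not None:
            fixture = out / "fixture"
            make_fixture(config.simulate.profile, seeds[0], fixture)
            paths = PathsConfig(
                genome=str(fixture / "genome.fa"),
                methylation=str(fixture / "methylation.tsv"),
                loops=str(fixture / "loops_positive.bedpe"),
                chrom_sizes=str(fixture / "chrom.sizes"),
            )
        for name in ("genome", "methylation", "loops", "chrom_sizes"):
            value = getattr(paths, name)
            if value is None:
                raise ConfigError(f"paths.{name} is required (or set simulate.profile)")
            inputs[name] = Path(value)

        stage = "load"
        genome = read_fasta(inputs["genome"])
        meth = MethylationIndex(core_io.read_methylation_tsv(inputs["methylation"]))
        positives = read_bedpe(inputs["loops"], label="positive")
        chrom_sizes = read_chrom_sizes(inputs["chrom_sizes"])

        stage = "sample"
        manifest = sampling.build_manifest(
            positives,
            chrom_sizes,
            seed=seeds[1],
            window=config.sampling.window,
            min_gap=config.sampling.min_gap,
            train_chroms=frozenset(config.sampling.train_chroms),
            val_chroms=frozenset(config.sampling.val_chroms),
        )
        manifest.save(out / "samples")

        stage = "train"
        train_loops, train_labels = manifest.subset("train")
        val_loops, val_labels = manifest.subset("val")
        test_loops, test_labels = manifest.subset("test")
        if not train_loops or not val_loops:
            raise ValueError("empty train or validation split")
        bundle = train_nanoloop(
            train_loops,
            train_labels,
            val_loops,
            val_labels,
            genome,
            meth,
            config=config.model_config(),
            seed=seeds[2],
        )
        bundle.save(out / "bundle")

        stage = "predict"
        predictions = bundle.predict(test_loops, genome, meth)
        probs = np.array([p.probability for p in predictions])
        core_io.write_predictions_tsv(test_loops, probs, out / "predictions.tsv")

        stage = "evaluate"
        metrics = {
            "n_train": len(train_loops),
            "n_val": len(val_loops),
            "n_test": len(test_loops),
            "n_positives": len(manifest.positives),
            "n_negatives": len(manifest.negatives),
            "negative_positive_ratio": len(manifest.negatives)
            / max(len(manifest.positives), 1),
            "test_prevalence": float(np.mean(test_labels)) if len(test_loops) else None,
            "test_auprc": float(evaluate_auprc(probs, test_labels))
            if len(set(test_labels)) == 2
            else None,
        }
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2)

        stage = "manifest"
        files = sorted(
            str(p.relative_to(out))
            for p in out.rglob("*")
            if p.is_file() and p.name != "run_manifest.json"
        )
        run_manifest = {
            "seed": config.seed,
            "stage_seeds": seeds,
            "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
            "outputs": {f: _sha256(out / f) for f in files},
            "feature_columns": feature_names(),
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(run_manifest, fh, indent=2)
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return out
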