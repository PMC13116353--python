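"""Shared fixtures: an in-memory tiny simulated world and a trained bundle.

Session-scoped so the expensive pieces (simulation, three-stage training)
run once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from nanoloop.core_io import MethylationIndex
from nanoloop.model import (
    NanoLoopConfig,
    SequenceExtractorConfig,
    TrainParams,
    TreeParams,
    train_nanoloop,
)
from nanoloop.sampling import build_manifest
from nanoloop.synthetic import PROFILES, SimulationConfig, simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def small_model_config() -> NanoLoopConfig:
    """A compact training configuration sized for fixture-scale data."""
    return NanoLoopConfig(
        l_anchor=1000,
        tau=0.5,
        extractor=SequenceExtractorConfig(
            filters1=16, filters2=32, filters3=128, window=1000, step=500
        ),
        trees=TreeParams(n_estimators=300),
        training=TrainParams(max_epochs=15, patience=4),
    )


@pytest.fixture(scope="session")
def tiny_world():
    """Tiny simulated dataset with its methylation index and sample manifest."""
    config = SimulationConfig(seed=0, **PROFILES["tiny"])
    data = simulate_dataset(config)
    meth = MethylationIndex(data.methylation)
    manifest = build_manifest(data.truth.positives, config.chrom_sizes, seed=1)
    return config, data, meth, manifest


@pytest.fixture(scope="session")
def tiny_bundle(tiny_world):
    """A bundle trained end-to-end on the tiny world."""
    _, data, meth, manifest = tiny_world
    train_loops, train_labels = manifest.subset("train")
    val_loops, val_labels = manifest.subset("val")
    return train_nanoloop(
        train_loops,
        train_labels,
        val_loops,
        val_labels,
        data.genome,
        meth,
        config=small_model_config(),
        seed=0,
    )


@pytest.fixture(scope="session")
def default_world():
    """The larger default fixture (long-range loops, stronger training set)."""
    config = SimulationConfig(seed=0, **PROFILES["default"])
    data = simulate_dataset(config)
    meth = MethylationIndex(data.methylation)
    manifest = build_manifest(data.truth.positives, config.chrom_sizes, seed=1)
    return config, data, meth, manifest
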