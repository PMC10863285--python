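"""Shared fixtures.

The session-scoped ``benchmark_run`` fixture builds the default synthetic
benchmark (2,000 planted sites, motif strength 1, balanced negatives) and
trains the reduced-depth model once; the end-to-end acceptance checks
(held-out AUROC, attribution motif recovery, completeness) all read from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ssbscan.datasets import DatasetConfig, SplitDataset
from ssbscan.network import ModelConfig, SSBModel, assemble_model, reduced_config
from ssbscan.seqcore import GenomeSequence
from ssbscan.simgen import BenchmarkBundle, SimConfig, generate_benchmark_bundle
from ssbscan.training import (
    EpochRecord,
    TrainConfig,
    stratified_validation_split,
    train_model,
)

BENCHMARK_SEED = 11


def tiny_model_config(**overrides) -> ModelConfig:
    """A minimal architecture for fast structural tests."""
    defaults = dict(blocks_per_stage=1, d_k=8, d_v=8, heads=2,
                    mlp_hidden=(8, 4), seed=0)
    defaults.update(overrides)
    return ModelConfig(**defaults)


@pytest.fixture
def tiny_model() -> SSBModel:
    return assemble_model(tiny_model_config())


@pytest.fixture
def small_genome() -> GenomeSequence:
    rng = np.random.default_rng(5)
    residues = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
    return GenomeSequence("chrT", residues)


@dataclass
class BenchmarkRun:
    bundle: BenchmarkBundle
    model: SSBModel
    history: list[EpochRecord]


@pytest.fixture(scope="session")
def benchmark_run() -> BenchmarkRun:
    """Default synthetic benchmark trained with the reduced-depth model."""
    bundle = generate_benchmark_bundle(
        SimConfig(seed=BENCHMARK_SEED),
        DatasetConfig(imbalance_ratio=1, seed=BENCHMARK_SEED),
    )
    model = assemble_model(reduced_config(4, seed=BENCHMARK_SEED))
    train_ex, val_ex = stratified_validation_split(bundle.split.train,
                                                   seed=BENCHMARK_SEED)
    model, history = train_model(
        model, train_ex, val_ex,
        TrainConfig(batch_size=64, max_epochs=4, early_stop_patience=3,
                    seed=BENCHMARK_SEED),
    )
    return BenchmarkRun(bundle, model, history)
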