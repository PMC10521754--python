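"""Shared fixtures: small synthetic cohorts and the seeded experiment sweep.

Heavy end-to-end artifacts (the 10-seed modality comparison and fine-tuning
protocol) are computed once per session and shared across the tests that
consume them.
"""

from __future__ import annotations

import numpy as np
import pytest

from mmil.pipeline import fine_tune_experiment, run_split_experiment
from mmil.synthetic import SyntheticConfig, generate_cohort

SWEEP_SEEDS = tuple(range(1, 11))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 12-patient cohort for structural tests."""
    cfg = SyntheticConfig(n_patients=12, tiles_per_bag=6, tile_size=32, seed=3)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def modality_sweep():
    """Held-out AUCs of the fused / image-only / biomarker-only models over
    ten seeded replicates of the default study conditions."""
    return {seed: run_split_experiment(seed) for seed in SWEEP_SEEDS}


@pytest.fixture(scope="session")
def finetune_sweep(modality_sweep):
    """Frozen vs fine-tuned AUC on a biomarker-shifted cohort, ten seeds."""
    return {
        seed: fine_tune_experiment(seed, base_experiment=modality_sweep[seed])
        for seed in SWEEP_SEEDS
    }


@pytest.fixture(scope="session")
def trained_experiment(modality_sweep):
    """One representative trained experiment (first sweep seed)."""
    return modality_sweep[SWEEP_SEEDS[0]]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
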