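"""Shared fixtures: a small, fast synthetic panel for unit tests and one
session-scoped full-scale (250-species) pipeline run reused by the
end-to-end tests."""

from __future__ import annotations

import numpy as np
import pytest

from cpgclock import (
    SimulationConfig,
    TrainingConfig,
    predict_lifespan,
    score_predictions,
    simulate_panel,
    train_clock,
)


@pytest.fixture()
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_species=16,
        class_proportions={"Mammalia": 0.5, "Aves": 0.25, "Fish": 0.25},
        n_causal_promoters=6,
        n_null_promoters=14,
        promoter_length=100,
        genome_length=7000,
        seed=11,
    )


@pytest.fixture()
def small_panel(small_config):
    return simulate_panel(small_config)


def run_pipeline(seed: int):
    """Simulate at study scale, train, and score the held-out test set."""
    panel = simulate_panel(SimulationConfig(seed=seed))
    model, train_ids, test_ids = train_clock(
        panel.density_matrix, panel.records, panel.tree, TrainingConfig(seed=seed)
    )
    classes = panel.classes
    preds = [
        predict_lifespan(model, panel.density_matrix.row(s), classes[s], species_id=s)
        for s in test_ids
    ]
    report = score_predictions({s: panel.lifespans[s] for s in test_ids}, preds)
    return {
        "panel": panel,
        "model": model,
        "train_ids": train_ids,
        "test_ids": test_ids,
        "report": report,
    }


@pytest.fixture(scope="session")
def pipeline_run():
    return run_pipeline(seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
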