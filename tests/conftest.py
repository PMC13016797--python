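"""Shared fixtures.

The negative-binomial GLMM calibration suites (null type-I error and
effect-size recovery at the study design size) each need hundreds of fits;
both unit and acceptance tests consume the same simulations, so the batches
are session-scoped and run once through a single R worker call.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from kinpref.inference import ModelSpec, fit_nb_glmm_batch
from kinpref.pipeline import Scenario
from kinpref.synthdata import BehaviorSimParams, simulate_behavior_counts, spawn_seeds

N_CALIBRATION_REPS = 200

CELL_SPEC = ModelSpec(
    response="count",
    family="negative-binomial",
    fixed_effects=("relatedness", "mating_status"),
    random_effects=("arena_id",),
    interactions=False,
    factor_levels={
        "relatedness": ("related", "unrelated"),
        "mating_status": ("experienced", "virgin"),
    },
)


def _batch(effect_relatedness: float, master_seed: int):
    seeds = spawn_seeds(master_seed, N_CALIBRATION_REPS)
    datasets = [
        simulate_behavior_counts(
            BehaviorSimParams(
                base_rate=10.0,
                effect_relatedness=effect_relatedness,
                effect_status=0.0,
                dispersion=2.0,
                arena_sd=0.3,
                n_arenas=12,
                seed=s,
            )
        )
        for s in seeds
    ]
    results = fit_nb_glmm_batch([CELL_SPEC] * len(datasets), datasets)
    return results


@pytest.fixture(scope="session")
def null_nb_fits():
    """200 NB-GLMM fits of null-effect counts at the study design size."""
    return _batch(effect_relatedness=0.0, master_seed=90210)


@pytest.fixture(scope="session")
def recovery_nb_fits():
    """200 NB-GLMM fits with a true unrelated:related rate ratio of 0.5."""
    return _batch(effect_relatedness=float(np.log(0.5)), master_seed=31415)


@pytest.fixture(scope="session")
def fast_scenario() -> Scenario:
    """Study-structure scenario with shortened recordings for quick runs."""
    return dataclasses.replace(
        Scenario(),
        exp1_trial_duration_s=300.0,
        exp1_frame_rate=5.0,
        arena_duration_s=240.0,
        arena_frame_rate=5.0,
    )


def relatedness_term(result):
    sub = result.terms[result.terms["term"] == "relatednessunrelated"]
    assert len(sub) == 1
    return sub.iloc[0]
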