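"""Shared fixtures: one model simulation and one scored synthetic cohort
per session, reused across the suite to keep runtime down."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cml_chronos as cc


@pytest.fixture(scope="session")
def default_params() -> cc.ModelParams:
    return cc.ModelParams()


@pytest.fixture(scope="session")
def default_traj(default_params) -> cc.TrajectorySeries:
    return cc.simulate_trajectories(default_params)


@pytest.fixture(scope="session")
def default_curve(default_traj) -> cc.SimulatedEntropyCurve:
    sgem = cc.generate_sgem(6384, rng_seed=11)
    return cc.simulated_entropy_curve(sgem, default_traj)


@pytest.fixture(scope="session")
def entropy_min_10(default_params, default_traj) -> cc.EntropyMinimum:
    """Seed-averaged entropy minimum (10 SGEM draws) shared by the
    acceptance-facing tests."""
    return cc.simulated_entropy_minimum(
        default_params, n_seeds=10, base_seed=1, trajectory=default_traj
    )


@pytest.fixture(scope="session")
def scored_cohort(default_params, default_traj):
    """One synthetic cohort (seed 0) taken through signature scoring,
    entropy and truth bookkeeping."""
    cfg = cc.SyntheticCohortConfig(rng_seed=0)
    expression, annotations, truth = cc.make_cohort(
        cfg, params=default_params, traj=default_traj
    )
    refs = list(annotations.index[annotations["is_cd34_reference"]])
    signature = cc.build_signature(expression, reference_samples=refs)
    scores = cc.score_cohort(expression, signature)
    entropies = pd.Series(
        cc.matrix_entropy(expression.T.to_numpy()),
        index=expression.columns,
        name="entropy",
    )
    patient_mask = ~annotations["is_cd34_reference"]
    cp_ids = [
        s for s in annotations.index
        if annotations.loc[s, "stage"] == "CP" and patient_mask[s]
    ]
    return {
        "config": cfg,
        "expression": expression,
        "annotations": annotations,
        "truth": truth,
        "signature": signature,
        "scores": scores,
        "entropies": entropies,
        "cp_ids": cp_ids,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
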