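"""End-to-end orchestration of the staging pipeline.

``run_pipeline`` wires the stages together: simulate the compartment
model, build the simulated entropy curve (seed-averaged minimum), score
the cohort against the CD34+ signature, compute per-sample entropies,
pin chronic-phase patients to disease time and split T1/T2, and run the
downstream statistics (V-shape, differential expression, stage-fraction
grid with permutation control).  Every run writes tidy TSV artifacts plus
a manifest recording the configuration hash, seeds and package version,
so a run is reproducible from its manifest alone.

All randomness is fanned out from a single top-level seed via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohortstats import (
    de_fraction_matrix,
    differential_expression,
    entropy_correlation_subsample,
    randomization_control,
    stage_fraction_grid,
    vshape_test,
)
from .entropy import (
    EntropyConfig,
    generate_sgem,
    matrix_entropy,
    simulated_entropy_curve,
    simulated_entropy_minimum,
)
from .io import prepare_cohort, write_expression
from .popmodel import ModelParams, simulate_trajectories
from .signatures import build_signature, score_cohort
from .synthetic_data import SyntheticCohortConfig, make_cohort
from .timemap import classify_T1_T2, pin_patients

__all__ = ["PipelineError", "run_pipeline", "stage_seeds"]

STAGE_NAMES = ("synthetic", "sgem", "subsample", "permutation")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage seeds derived from one top-level seed."""
    states = np.random.SeedSequence(seed).generate_state(len(STAGE_NAMES))
    return {name: int(s % (2**31)) for name, s in zip(STAGE_NAMES, states)}


def _config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    out_dir,
    seed: int = 0,
    model_params: ModelParams | None = None,
    cohort_config: SyntheticCohortConfig | None = None,
    entropy_config: EntropyConfig | None = None,
    n_sgem_seeds: int = 10,
    expression: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
    alpha: float = 0.05,
    n_permutations: int = 1000,
) -> dict:
    """Run the full staging pipeline and write artifacts to ``out_dir``.

    With no ``expression``/``annotations`` a synthetic cohort is
    generated (its ground truth is written alongside).  Returns a results
    bundle (dict of DataFrames / scalars) mirroring the written files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    params = model_params or ModelParams()
    ecfg = entropy_config or EntropyConfig()

    def fail(stage, exc):
        raise PipelineError(stage, str(exc)) from exc

    # --- model side -------------------------------------------------
    try:
        traj = simulate_trajectories(params)
        curve = simulated_entropy_curve(
            generate_sgem(6384, seeds["sgem"], n_rows=2 * params.n_compartments),
            traj, ecfg,
        )
        minimum = simulated_entropy_minimum(
            params, n_seeds=n_sgem_seeds, base_seed=seeds["sgem"],
            config=ecfg, trajectory=traj,
        )
    except Exception as exc:  # noqa: BLE001
        fail("model", exc)

    # --- cohort -----------------------------------------------------
    truth = None
    if expression is None or annotations is None:
        try:
            cohort_config = cohort_config or SyntheticCohortConfig(
                rng_seed=seeds["synthetic"]
            )
            expression, annotations, truth = make_cohort(
                cohort_config, params=params, traj=traj
            )
        except Exception as exc:  # noqa: BLE001
            fail("synthetic", exc)
    try:
        annotations = prepare_cohort(annotations)
        expression = expression[annotations.index]
    except Exception as exc:  # noqa: BLE001
        fail("prepare", exc)

    # --- scoring ----------------------------------------------------
    try:
        reference_ids = list(annotations.index[annotations["is_cd34_reference"]])
        signature = build_signature(
            expression, reference_samples=reference_ids or None
        )
        scores = score_cohort(expression, signature)
        entropies = pd.Series(
            matrix_entropy(expression.T.to_numpy(), ecfg),
            index=expression.columns, name="entropy",
        )
    except Exception as exc:  # noqa: BLE001
        fail("scoring", exc)

    # --- pinning ----------------------------------------------------
    try:
        patient_mask = ~annotations["is_cd34_reference"]
        cp_ids = annotations.index[(annotations["stage"] == "CP") & patient_mask]
        mapping = pin_patients(
            scores.loc[cp_ids, "score"].to_numpy(),
            entropies.loc[cp_ids].to_numpy(),
            curve, sample_ids=list(cp_ids),
        )
        mapping = classify_T1_T2(mapping, minimum.t_min)
    except Exception as exc:  # noqa: BLE001
        fail("pinning", exc)

    # --- statistics -------------------------------------------------
    try:
        cp_scores = scores.loc[cp_ids, "score"].to_numpy()
        vshape = vshape_test(entropies.loc[cp_ids].to_numpy(), cp_scores)
        t1_ids = list(mapping.index[mapping["phase_label"] == "T1"])
        t2_ids = list(mapping.index[mapping["phase_label"] == "T2"])
        groups = {"T1-CP": t1_ids, "T2-CP": t2_ids}
        for stage in ("AP", "APcyto", "BC"):
            ids = list(annotations.index[(annotations["stage"] == stage) & patient_mask])
            if ids:
                groups[stage] = ids
        de_t1_t2 = (
            differential_expression(expression, t1_ids, t2_ids, alpha=alpha,
                                    group_names=("T1-CP", "T2-CP"))
            if len(t1_ids) >= 2 and len(t2_ids) >= 2 else None
        )
        de_fractions = de_fraction_matrix(
            expression, {k: v for k, v in groups.items() if len(v) >= 2},
            alpha=alpha,
        )
        corr = entropy_correlation_subsample(
            entropies.loc[cp_ids].to_numpy(),
            mapping["matched_model_entropy"].to_numpy(),
            rng_seed=seeds["subsample"],
        )
        pat_ids = annotations.index[patient_mask]
        grid = stage_fraction_grid(
            scores.loc[pat_ids, "score"].to_numpy(),
            entropies.loc[pat_ids].to_numpy(),
            annotations.loc[pat_ids, "stage"],
        )
        null = randomization_control(
            annotations.loc[pat_ids, "stage"], grid.cell_of_sample,
            n_perm=n_permutations, rng_seed=seeds["permutation"],
        )
    except Exception as exc:  # noqa: BLE001
        fail("statistics", exc)

    # --- artifacts --------------------------------------------------
    config = {
        "seed": seed,
        "stage_seeds": seeds,
        "model_params": asdict(params),
        "entropy_config": {"n_bins": ecfg.n_bins, "log_base": str(ecfg.log_base)},
        "cohort_config": asdict(cohort_config) if cohort_config else None,
        "n_sgem_seeds": n_sgem_seeds,
        "alpha": alpha,
        "n_permutations": n_permutations,
    }
    manifest = {
        "version": __version__,
        "config": config,
        "config_hash": _config_hash(config),
        "entropy_minimum_days": minimum.t_min,
        "n_samples": int(annotations.shape[0]),
    }
    traj.to_frame().to_csv(out / "trajectories.tsv", sep="\t", index=False)
    curve.to_frame().to_csv(out / "simulated_curve.tsv", sep="\t", index=False)
    write_expression(expression, out / "expression.tsv")
    annotations.to_csv(out / "annotations.tsv", sep="\t")
    scores.join(entropies).to_csv(out / "scores.tsv", sep="\t")
    mapping.to_csv(out / "mapping.tsv", sep="\t")
    de_fractions.to_csv(out / "de_fractions.tsv", sep="\t")
    grid.table.to_csv(out / "stage_fraction_grid.tsv", sep="\t", index=False)
    null.to_csv(out / "randomization_control.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_csv(out / "ground_truth.tsv", sep="\t")
    summary = {
        "entropy_minimum_days": minimum.t_min,
        "boundary_time_days": minimum.t_min,
        "n_t1": len(t1_ids),
        "n_t2": len(t2_ids),
        "vshape_p_quadratic": vshape.p_quadratic,
        "vshape_vertex": vshape.vertex,
        "de_t1_t2_significant": de_t1_t2.n_significant if de_t1_t2 else None,
        "de_t1_t2_fraction_pct": (
            100.0 * de_t1_t2.fraction_significant if de_t1_t2 else None
        ),
        "entropy_correlation_p": corr["overall_p"],
        "entropy_correlation_pct_significant": corr["pct_significant"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return {
        "trajectory": traj,
        "curve": curve,
        "minimum": minimum,
        "expression": expression,
        "annotations": annotations,
        "truth": truth,
        "signature": signature,
        "scores": scores,
        "entropies": entropies,
        "mapping": mapping,
        "vshape": vshape,
        "de_t1_t2": de_t1_t2,
        "de_fractions": de_fractions,
        "correlation": corr,
        "grid": grid,
        "randomization": null,
        "manifest": manifest,
        "summary": summary,
    }
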