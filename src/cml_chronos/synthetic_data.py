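"""Synthetic CML cohorts with known ground truth.

Generates expression cohorts that emulate the published four-stage CML
microarray layout (42 CP / 9 AP / 8 APcyto / 28 BC plus flagged CD34+
reference samples) with the statistical structure the pipeline is built
to detect:

* every sample is a population-weighted mixture of per-compartment
  expression profiles (uniform-distributed, so the degree of population
  mixing genuinely reshapes the per-sample value distribution and yields
  the entropy V over chronic phase);
* CD34-signature genes carry a contrast that is linear in the normalized
  model CD34 ratio at the sample's true disease time -- the patient-side
  counterpart of the model's rising CD34 ratio;
* a disjoint block of progression genes carries stage-graded mean shifts,
  giving ordered differential-expression fractions (T1 < T2 < AP < BC);
* blast counts are stage-dependent with planted missingness.

Chronic-phase truth times are drawn uniformly on the *normalized CD34
ratio* axis and converted to days through the model curve.  (The ratio
curve is exponentially flat over early chronic phase, so patients placed
uniformly in time would be informationally indistinguishable there; a
diagnosed cohort spread across the similarity axis is both the realistic
and the testable condition.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popmodel import (
    ModelParams,
    TrajectorySeries,
    cd34_ratio,
    population_fraction_matrix,
    simulate_trajectories,
)

__all__ = [
    "SyntheticCohortConfig",
    "generate_compartment_profiles",
    "generate_cohort",
    "make_cohort",
]

SQRT3 = float(np.sqrt(3.0))


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions of the synthetic cohort.

    Stage counts follow the emulated cohort; expression is on a log-
    intensity-like scale where 1.0 is one unit of per-gene biological
    spread.  ``signature_effect_size`` is the half-range of the CD34-
    signature contrast in those units; ``stage_tau_ranges`` are the
    normalized-CD34-ratio coordinates at which each advanced stage sits
    (values above 1 extrapolate beyond the chronic-phase window).
    """

    n_cp: int = 42
    n_ap: int = 9
    n_apcyto: int = 8
    n_bc: int = 28
    n_reference: int = 6
    n_genes: int = 6384
    n_signature_genes: int = 320  # per direction (up and down)
    signature_effect_size: float = 0.45
    reference_effect_size: float = 3.0  # cell-intrinsic contrast in sorted refs
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 0.3
    profile_scale: float = 1.25
    lineage_coherence: float = 0.8  # share of profile variance common per lineage
    shift_gene_frac: float = 0.10
    stage_shift_sd: float = 0.6
    cp_time_range_days: tuple[float, float] = (0.0, 2200.0)
    cp_time_sampling: str = "uniform-ratio"  # or "uniform-time"
    stage_tau_ranges: dict = field(
        default_factory=lambda: {
            "AP": (0.75, 0.95), "APcyto": (0.55, 0.85), "BC": (0.95, 1.25)
        }
    )
    stage_dispersion: dict = field(
        default_factory=lambda: {"CP": 0.0, "AP": 0.4, "APcyto": 1.0, "BC": 0.6}
    )
    stage_shift_level: dict = field(
        default_factory=lambda: {"AP": 2.0, "APcyto": 1.7, "BC": 3.0}
    )
    missing_blast_fraction: float = 0.15
    boundary_days: float = 1476.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cp", "n_ap", "n_apcyto", "n_bc", "n_reference"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.signature_effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect size and noise must be >= 0")
        if 2 * self.n_signature_genes + int(
            round(self.shift_gene_frac * self.n_genes)
        ) > self.n_genes:
            raise ValueError("signature and shift gene blocks exceed n_genes")

    @property
    def stage_counts(self) -> dict:
        return {
            "CP": self.n_cp, "AP": self.n_ap,
            "APcyto": self.n_apcyto, "BC": self.n_bc,
        }


def generate_compartment_profiles(
    n_genes: int,
    signature_gene_ids,
    effect: float,
    rng: np.random.Generator,
    cd34_cutoff: int = 23,
    n_compartments: int = 32,
    scale: float = 1.0,
) -> pd.DataFrame:
    """Per-population base expression profiles (2K rows x genes).

    Baseline entries are i.i.d. uniform with zero mean and standard
    deviation ``scale`` (a flat per-population distribution, like the
    random matrix behind the simulated entropy curve).  Signature genes
    are shifted by ``+effect`` in CD34-positive populations (compartment
    <= cutoff, either lineage) and ``-effect`` elsewhere; when
    ``signature_gene_ids`` is an (up, down) pair the down genes get the
    opposite pattern.
    """
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    if isinstance(signature_gene_ids, tuple) and len(signature_gene_ids) == 2:
        up_ids, down_ids = signature_gene_ids
    else:
        up_ids, down_ids = list(signature_gene_ids), []
    missing = (set(up_ids) | set(down_ids)) - set(gene_ids)
    if missing:
        raise ValueError(f"signature genes outside the gene list: {sorted(missing)[:5]}")
    values = rng.uniform(-SQRT3 * scale, SQRT3 * scale,
                         size=(2 * n_compartments, n_genes))
    frame = pd.DataFrame(
        values,
        index=[f"{lin}_c{k:02d}" for lin in ("healthy", "cml")
               for k in range(1, n_compartments + 1)],
        columns=gene_ids,
    )
    compartment = np.tile(np.arange(1, n_compartments + 1), 2)
    cd34_pos = compartment <= cd34_cutoff
    sign_rows = np.where(cd34_pos, 1.0, -1.0)[:, None]
    if up_ids:
        frame.loc[:, up_ids] += effect * sign_rows
    if down_ids:
        frame.loc[:, down_ids] -= effect * sign_rows
    return frame


def _cp_truth_times(cfg: SyntheticCohortConfig, times, ratio_norm, rng):
    lo_t, hi_t = cfg.cp_time_range_days
    mask = (times >= lo_t) & (times <= hi_t)
    if not mask.any():
        raise ValueError("cp_time_range_days outside the simulated window")
    sub_times, sub_nr = times[mask], ratio_norm[mask]
    if cfg.cp_time_sampling == "uniform-time":
        t = rng.uniform(lo_t, hi_t, size=cfg.n_cp)
        idx = np.searchsorted(sub_times, t).clip(0, sub_times.size - 1)
    elif cfg.cp_time_sampling == "uniform-ratio":
        u = rng.uniform(sub_nr.min(), sub_nr.max(), size=cfg.n_cp)
        idx = np.array([np.argmin(np.abs(sub_nr - ui)) for ui in u])
    else:
        raise ValueError(f"unknown cp_time_sampling {cfg.cp_time_sampling!r}")
    return sub_times[idx], sub_nr[idx]


def generate_cohort(
    cfg: SyntheticCohortConfig,
    traj: TrajectorySeries,
    base_profiles: pd.DataFrame,
):
    """Build (expression, annotations, ground truth) for one cohort.

    Each chronic-phase sample at true time ``t`` is a population-weighted
    mixture of the base profiles plus the ratio-linear signature contrast,
    stage-graded progression shifts, and Gaussian noise; advanced-stage
    samples use the end-of-window weights with extra flat dispersion.
    Flagged CD34+ reference samples are pure CD34-positive mixtures.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    params = traj.params
    gene_ids = list(base_profiles.columns)
    if len(gene_ids) != cfg.n_genes:
        raise ValueError("base_profiles gene count does not match config")

    # gene roles (deterministic per seed): signature up/down + shift block
    perm = rng.permutation(cfg.n_genes)
    up_idx = perm[: cfg.n_signature_genes]
    down_idx = perm[cfg.n_signature_genes: 2 * cfg.n_signature_genes]
    n_shift = int(round(cfg.shift_gene_frac * cfg.n_genes))
    shift_idx = perm[2 * cfg.n_signature_genes: 2 * cfg.n_signature_genes + n_shift]
    # heterogeneous per-gene effect magnitudes (real marker genes differ in
    # fold change; also keeps the rank-sum score responsive at high contrast)
    sig_vector = np.zeros(cfg.n_genes)
    sig_vector[up_idx] = rng.uniform(0.3, 1.7, cfg.n_signature_genes)
    sig_vector[down_idx] = -rng.uniform(0.3, 1.7, cfg.n_signature_genes)
    shift_vector = np.zeros(cfg.n_genes)
    shift_vector[shift_idx] = rng.choice([-1.0, 1.0], size=n_shift) * cfg.stage_shift_sd

    baseline = cfg.baseline_mean + rng.normal(0.0, cfg.baseline_sd, cfg.n_genes)

    weights = population_fraction_matrix(traj)
    ratio = cd34_ratio(traj).ratio
    ratio_norm = (ratio - ratio.min()) / (ratio.max() - ratio.min())
    # signature genes follow the differentiation axis systematically, not the
    # random per-population texture: their compartment structure is carried by
    # the ratio-linear contrast below, so their random base rows are silenced
    base = base_profiles.to_numpy(float).copy()
    base[:, up_idx] = 0.0
    base[:, down_idx] = 0.0
    # Each sample mixes a healthy and a leukemic expression program in
    # proportion to its healthy cell-mass share; the program realizations are
    # drawn fresh per sample (transcriptional snapshot noise), so the
    # per-sample value distribution goes flat -> triangular -> flat as the
    # mass shifts from purely healthy through the mixed state to purely
    # leukemic -- the entropy V over chronic phase -- without planting
    # gene-level mean differences between patient groups.
    lam = cfg.lineage_coherence
    k = params.n_compartments

    def lineage_program(healthy_share):
        u = rng.uniform(-SQRT3 * cfg.profile_scale, SQRT3 * cfg.profile_scale,
                        (2, cfg.n_genes))
        u[:, up_idx] = 0.0  # signature genes carry the ratio-linear contrast
        u[:, down_idx] = 0.0
        return healthy_share * u[0] + (1.0 - healthy_share) * u[1]

    cp_times, cp_tau = _cp_truth_times(cfg, traj.times, ratio_norm, rng)
    order = np.argsort(cp_times)
    cp_times, cp_tau = cp_times[order], cp_tau[order]
    end_weights = weights[-1]

    columns, samples, truth_rows, annot_rows = [], [], [], []

    def emit(sample_id, stage, tau, w, dispersion, shift_level, true_time,
             is_ref=False):
        healthy_share = w[:k].sum()
        mix = lam * lineage_program(healthy_share) + (1.0 - lam) * (w @ base)
        amp = cfg.reference_effect_size if is_ref else cfg.signature_effect_size
        x = baseline + mix + amp * (2.0 * tau - 1.0) * sig_vector
        x = x + shift_level * shift_vector
        if dispersion > 0:
            x = x + rng.uniform(-SQRT3 * dispersion, SQRT3 * dispersion, cfg.n_genes)
        x = x + rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
        columns.append(sample_id)
        samples.append(x)
        truth_rows.append(
            {"sample_id": sample_id, "stage": stage,
             "true_time_days": true_time, "true_tau": tau,
             "true_phase": (
                 ("T1" if true_time < cfg.boundary_days else "T2")
                 if stage == "CP" and not is_ref and true_time is not None
                 else ""
             )}
        )
        annot_rows.append(
            {"sample_id": sample_id, "stage": stage,
             "is_cd34_reference": is_ref}
        )

    cp_weights = [weights[traj.time_index(t)] for t in cp_times]
    # the CD34+ reference differs from the average patient only along the
    # CD34 axis (cell-intrinsic signature contrast at full strength)
    mean_patient_w = np.mean(cp_weights + [end_weights] * (
        cfg.n_ap + cfg.n_apcyto + cfg.n_bc), axis=0) if (
        cp_weights or cfg.n_ap + cfg.n_apcyto + cfg.n_bc) else np.full(2 * k, 0.5 / k)
    for i in range(cfg.n_reference):
        emit(f"REF{i + 1:02d}", "CP", 1.0, mean_patient_w, 0.0, 0.0, None,
             is_ref=True)
    for i, (t, tau) in enumerate(zip(cp_times, cp_tau)):
        emit(f"CP{i + 1:02d}", "CP", tau, cp_weights[i],
             cfg.stage_dispersion["CP"], tau, t)
    for stage in ("AP", "APcyto", "BC"):
        lo, hi = cfg.stage_tau_ranges[stage]
        for i in range(cfg.stage_counts[stage]):
            tau = rng.uniform(lo, hi)
            emit(f"{stage}{i + 1:02d}", stage, tau, end_weights,
                 cfg.stage_dispersion[stage], cfg.stage_shift_level[stage], None)

    expression = pd.DataFrame(
        np.column_stack(samples), index=gene_ids, columns=columns
    )
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    annotations = pd.DataFrame(annot_rows).set_index("sample_id")

    # stage-dependent blast counts with planted missingness
    blast = pd.Series(np.nan, index=annotations.index)
    draws = {
        "CP": lambda n: rng.uniform(1, 9, n),
        "AP": lambda n: rng.uniform(10, 19, n),
        "APcyto": lambda n: rng.uniform(1, 9, n),
        "BC": lambda n: rng.uniform(20, 90, n),
    }
    for stage, fn in draws.items():
        mask = (annotations["stage"] == stage) & ~annotations["is_cd34_reference"]
        blast.loc[mask] = np.round(fn(int(mask.sum())), 1)
    blast.loc[annotations["is_cd34_reference"]] = 1.0
    for stage in ("CP", "BC"):
        mask = (annotations["stage"] == stage) & ~annotations["is_cd34_reference"]
        ids = annotations.index[mask]
        n_missing = int(round(cfg.missing_blast_fraction * len(ids)))
        if n_missing:
            drop = rng.choice(ids, size=n_missing, replace=False)
            blast.loc[drop] = np.nan
    annotations["blast_count"] = blast
    truth["blast_count"] = blast
    truth["blast_missing"] = blast.isna()

    expression.attrs["signature_up"] = [gene_ids[i] for i in np.sort(up_idx)]
    expression.attrs["signature_down"] = [gene_ids[i] for i in np.sort(down_idx)]
    return expression, annotations, truth


def make_cohort(
    cfg: SyntheticCohortConfig | None = None,
    params: ModelParams | None = None,
    traj: TrajectorySeries | None = None,
):
    """Convenience wrapper: simulate the model and generate one cohort."""
    cfg = cfg or SyntheticCohortConfig()
    params = params or ModelParams()
    traj = traj or simulate_trajectories(params)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.rng_seed).spawn(1)[0])
    base = generate_compartment_profiles(
        cfg.n_genes,
        signature_gene_ids=(),
        effect=0.0,
        rng=rng,
        cd34_cutoff=params.cd34_cutoff,
        n_compartments=params.n_compartments,
        scale=cfg.profile_scale,
    )
    return generate_cohort(cfg, traj, base)
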