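"""Cohort-level statistics downstream of scoring and pinning.

Covers the V-shape regression of entropy on CD34+ similarity within
chronic phase, per-gene differential expression with Benjamini-Hochberg
control and differential-expression fractions between patient groups,
robustness of the observed/simulated entropy correlation under random
sub-sampling, and the 8-subset stage-fraction grid (CD34 quarters x
entropy halves) with its label-permutation null control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VShapeResult",
    "DEResult",
    "StageFractionGrid",
    "vshape_test",
    "differential_expression",
    "de_fraction_matrix",
    "entropy_correlation_subsample",
    "stage_fraction_grid",
    "randomization_control",
]

STAGES = ("CP", "AP", "APcyto", "BC")


@dataclass
class VShapeResult:
    """Quadratic regression of entropy on CD34+ similarity."""

    coefficients: np.ndarray  # (intercept, linear, quadratic)
    p_quadratic: float
    vertex: float | None  # -b1/(2 b2) when the parabola opens upwards
    n: int


def vshape_test(entropy, cd34_scores) -> VShapeResult:
    """Test for a V-shape of entropy along the CD34+ similarity axis.

    Ordinary least squares of ``entropy ~ score + score**2``; the reported
    p-value is the two-sided t-test of the quadratic coefficient, and the
    vertex is the parabola minimum when the curvature is positive.
    """
    y = np.asarray(entropy, dtype=float)
    x = np.asarray(cd34_scores, dtype=float)
    if y.size != x.size:
        raise ValueError("entropy and scores must be aligned")
    if y.size < 5:
        raise ValueError("need at least 5 samples for the V-shape test")
    design = np.column_stack([np.ones_like(x), x, x**2])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("degenerate design (collinear scores)")
    fit = sm.OLS(y, design).fit()
    beta = fit.params
    vertex = float(-beta[1] / (2 * beta[2])) if beta[2] > 0 else None
    return VShapeResult(
        coefficients=np.asarray(beta), p_quadratic=float(fit.pvalues[2]),
        vertex=vertex, n=int(y.size),
    )


@dataclass
class DEResult:
    """Per-gene differential expression between two sample groups."""

    table: pd.DataFrame  # mean_diff, t, p, q, direction, degenerate
    n_tested: int
    n_significant: int
    alpha: float
    groups: tuple[str, str] = ("A", "B")

    @property
    def fraction_significant(self) -> float:
        """Share of tested genes passing the FDR cut, in [0, 1]."""
        return self.n_significant / self.n_tested if self.n_tested else 0.0


def differential_expression(
    matrix: pd.DataFrame,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    alpha: float = 0.05,
    equal_var: bool = True,
    group_names: tuple[str, str] = ("A", "B"),
) -> DEResult:
    """Two-sided two-sample t-test per gene with Benjamini-Hochberg FDR.

    ``direction`` is the sign of mean(A) - mean(B).  Genes with zero
    variance in both groups short-circuit to p = 1 when the group means
    agree and are flagged ``degenerate`` (and excluded from the FDR
    universe) when they differ.
    """
    a_ids, b_ids = list(group_a_ids), list(group_b_ids)
    if set(a_ids) & set(b_ids):
        raise ValueError("groups must be disjoint")
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("need at least 2 samples per group")
    a = matrix[a_ids].to_numpy(float)
    b = matrix[b_ids].to_numpy(float)
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = zero_var & (mean_diff == 0)
    degenerate = zero_var & (mean_diff != 0)
    p = np.where(equal_means, 1.0, p)
    t_stat = np.where(equal_means, 0.0, t_stat)
    q = np.full_like(p, np.nan)
    valid = ~degenerate & np.isfinite(p)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "t": t_stat,
            "p": p,
            "q": q,
            "direction": np.where(mean_diff >= 0, "up", "down"),
            "degenerate": degenerate,
        },
        index=matrix.index,
    )
    n_sig = int(np.sum(q[valid] < alpha))
    return DEResult(
        table=table, n_tested=int(valid.sum()), n_significant=n_sig,
        alpha=alpha, groups=group_names,
    )


def de_fraction_matrix(
    matrix: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Symmetric table of pairwise DE fractions (percent of tested genes)."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            res = differential_expression(
                matrix, groups[gi], groups[gj], alpha=alpha, equal_var=equal_var,
                group_names=(gi, gj),
            )
            pct = 100.0 * res.fraction_significant
            out.loc[gi, gj] = out.loc[gj, gi] = pct
    return out


def entropy_correlation_subsample(
    observed,
    simulated,
    n_iter: int = 1000,
    subsample_frac: float = 0.8,
    rng_seed: int = 0,
    method: str = "pearson",
    alpha: float = 0.05,
) -> dict:
    """Significance of the observed/simulated entropy correlation under
    random sub-sampling.

    Correlates the full pairing, then ``n_iter`` random subsamples
    (without replacement) of the given fraction, and reports the share of
    iterations with p below ``alpha``.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(simulated, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need paired vectors of length >= 5")
    k = int(round(subsample_frac * x.size))
    if k < 4:
        raise ValueError(f"subsample of {k} pairs is too small (< 4)")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    overall_r, overall_p = corr(x, y)
    rng = np.random.default_rng(rng_seed)
    p_values = np.empty(n_iter)
    for i in range(n_iter):
        idx = rng.choice(x.size, size=k, replace=False)
        if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
            p_values[i] = 1.0
            continue
        p_values[i] = corr(x[idx], y[idx])[1]
    return {
        "overall_r": float(overall_r),
        "overall_p": float(overall_p),
        "subsample_frac": subsample_frac,
        "n_iter": n_iter,
        "pct_significant": float(100.0 * np.mean(p_values < alpha)),
        "iteration_p_values": p_values,
    }


@dataclass
class StageFractionGrid:
    """Stage composition of the 4 CD34-quarters x 2 entropy-halves grid."""

    table: pd.DataFrame  # quarter, half, stage, count, fraction_pct
    cell_of_sample: pd.Series  # sample -> "Q<q>/<low|high>"
    n_total: int
    score_edges: np.ndarray = field(default=None)
    entropy_edges: np.ndarray = field(default=None)


def _bin_half_open(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Assign values to (e_i, e_{i+1}] cells: a value sitting exactly on an
    internal boundary joins the lower cell; the global minimum joins the
    first cell (documented half-open binning rule)."""
    idx = np.searchsorted(edges, values, side="left") - 1
    return np.clip(idx, 0, len(edges) - 2)


def stage_fraction_grid(scores, entropies, stages) -> StageFractionGrid:
    """Partition the cohort into 8 rectangular score/entropy subsets.

    The CD34+ similarity range is split into observed-range quarters and
    the entropy range into halves; per cell and disease stage the patient
    count and its fraction of the *total* cohort are reported.
    """
    s = np.asarray(scores, dtype=float)
    h = np.asarray(entropies, dtype=float)
    stages = pd.Series(list(stages))
    if not (s.size == h.size == stages.size):
        raise ValueError("scores, entropies and stages must be aligned")
    if s.size == 0:
        raise ValueError("empty cohort")
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage labels: {sorted(unknown)}")
    score_edges = np.linspace(s.min(), s.max(), 5)
    entropy_edges = np.linspace(h.min(), h.max(), 3)
    quarter = _bin_half_open(s, score_edges)
    half = _bin_half_open(h, entropy_edges)
    cell = pd.Series(
        [f"Q{q + 1}/{'low' if e == 0 else 'high'}" for q, e in zip(quarter, half)],
        index=stages.index,
    )
    n_total = s.size
    rows = []
    for q in range(4):
        for e, ename in ((0, "low"), (1, "high")):
            in_cell = (quarter == q) & (half == e)
            for stage in STAGES:
                count = int(np.sum(in_cell & (stages == stage).to_numpy()))
                rows.append(
                    {
                        "quarter": q + 1,
                        "entropy_half": ename,
                        "stage": stage,
                        "count": count,
                        "fraction_pct": 100.0 * count / n_total,
                    }
                )
    return StageFractionGrid(
        table=pd.DataFrame(rows), cell_of_sample=cell, n_total=n_total,
        score_edges=score_edges, entropy_edges=entropy_edges,
    )


def randomization_control(
    stages,
    cell_assignments,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Stage-label permutation null for the stage-fraction grid.

    Stage labels are randomly re-assigned ``n_perm`` times over the fixed
    sample positions (overall stage composition preserved exactly); for
    every (cell, stage) the null mean/sd of the stage fraction -- both as
    a share of the whole cohort and as a share of the cell's occupancy --
    and the empirical two-sided exceedance probability of the observed
    fraction are returned.  ``DataFrame.attrs["null_fractions"]`` holds
    the full null histograms (cohort-share scale), shaped (n_perm,) per
    (cell, stage).
    """
    stages = pd.Series(list(stages)).reset_index(drop=True)
    cells = pd.Series(list(cell_assignments)).reset_index(drop=True)
    if stages.size != cells.size:
        raise ValueError("stages and cell assignments must be aligned")
    n = stages.size
    rng = np.random.default_rng(rng_seed)
    cell_names = sorted(cells.unique())
    cell_masks = {c: (cells == c).to_numpy() for c in cell_names}
    cell_sizes = {c: int(m.sum()) for c, m in cell_masks.items()}
    stage_arr = stages.to_numpy()
    observed = {
        (c, st): 100.0 * np.sum(cell_masks[c] & (stage_arr == st)) / n
        for c in cell_names
        for st in STAGES
    }
    null = {key: np.empty(n_perm) for key in observed}
    for i in range(n_perm):
        perm = stage_arr[rng.permutation(n)]
        for c in cell_names:
            sub = perm[cell_masks[c]]
            for st in STAGES:
                null[(c, st)][i] = 100.0 * np.sum(sub == st) / n
    rows = []
    for (c, st), draws in null.items():
        obs = observed[(c, st)]
        exceed = np.mean(np.abs(draws - draws.mean()) >= abs(obs - draws.mean()))
        occupancy = cell_sizes[c]
        scale = n / occupancy if occupancy else np.nan  # cohort- -> cell-share
        rows.append(
            {
                "cell": c,
                "stage": st,
                "cell_size": occupancy,
                "observed_fraction_pct": obs,
                "null_mean_pct": float(draws.mean()),
                "null_sd_pct": float(draws.std()),
                "observed_within_cell_pct": obs * scale,
                "null_mean_within_cell_pct": float(draws.mean() * scale),
                "p_two_sided": float(exceed),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["null_fractions"] = null
    return out
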