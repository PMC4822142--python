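"""Pinning chronic-phase patients onto disease-evolutionary time.

The compartment model provides, per simulated day, a CD34 ratio and a
simulated entropy; a patient biopsy provides a CD34+ similarity score and
an observed expression entropy.  Because the patient score and the model
ratio are independently min-max normalized to [0, 1] and assumed linearly
related, each chronic-phase (CP) patient can be matched to the day whose
normalized CD34 ratio is nearest to the patient's normalized score
(step 1); the match is then refined inside a CD34 neighbourhood by
nearest *entropy* distance, after shifting the observed-entropy V minimum
onto the simulated-entropy minimum so both entropy axes are aligned
("pinning", step 2).  Patients matched before the simulated-entropy
minimum are labelled T1 ("early CP"), the rest T2 ("late CP").

A scikit-learn style :class:`DiseaseTimeMapper` wraps the procedure:
``fit`` ingests the simulated curve, ``predict`` maps a cohort of
(score, entropy) pairs to disease times and T1/T2 labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .entropy import SimulatedEntropyCurve, find_entropy_minimum

__all__ = [
    "NormalizationRecord",
    "normalize_unit_interval",
    "pin_patients",
    "classify_T1_T2",
    "DiseaseTimeMapper",
]


@dataclass(frozen=True)
class NormalizationRecord:
    """Affine record of a min-max normalization, for inverse mapping."""

    minimum: float
    value_range: float

    def inverse(self, normalized: np.ndarray) -> np.ndarray:
        return np.asarray(normalized) * self.value_range + self.minimum


def normalize_unit_interval(values) -> tuple[np.ndarray, NormalizationRecord]:
    """Min-max normalize ``values`` to [0, 1].

    Raises on fewer than 2 distinct values (zero range).
    """
    x = np.asarray(values, dtype=float)
    lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
    if not np.isfinite(lo) or not np.isfinite(hi) or hi == lo:
        raise ValueError("cannot normalize: values span zero range")
    return (x - lo) / (hi - lo), NormalizationRecord(minimum=lo, value_range=hi - lo)


def _observed_vertex(scores_norm: np.ndarray, entropies: np.ndarray) -> float:
    """Normalized-score coordinate of the observed-entropy V minimum.

    Quadratic OLS vertex (robust to single-sample noise); raises if the
    fit is degenerate or opens downwards.
    """
    from .cohortstats import vshape_test

    res = vshape_test(entropies, scores_norm)
    if res.vertex is None:
        raise ValueError("observed entropy has no upward-opening V vertex")
    return float(res.vertex)


def pin_patients(
    cp_scores,
    cp_entropies,
    curve: SimulatedEntropyCurve,
    neighborhood: float = 0.05,
    match: str = "two-step",
    align_minima: bool = True,
    smoothing_window: int = 11,
    sample_ids=None,
    enforce_monotone: bool = True,
    max_alignment_shift: float = 0.25,
) -> pd.DataFrame:
    """Map each CP patient to a day of the simulated disease window.

    Parameters
    ----------
    cp_scores, cp_entropies:
        CD34+ similarity scores and observed entropies of the CP samples
        (aligned sequences).
    curve:
        Simulated entropy curve with CD34 ratio over the full window.
    neighborhood:
        Half-width of the CD34 neighbourhood searched in the entropy
        refinement step, as a fraction of the normalized CD34 axis.
    match:
        ``"two-step"`` (nearest CD34, then nearest entropy nearby) or
        ``"joint"`` (2-D Euclidean nearest neighbour in the normalized
        score/entropy plane).
    align_minima:
        Shift the observed-entropy V vertex onto the simulated-entropy
        minimum along the CD34/score axis before the entropy step.  Falls
        back to no shift (with ``aligned=False`` flags) when the V fit is
        degenerate.
    enforce_monotone:
        Process patients in score order and forbid time reversals, making
        matched times nondecreasing in normalized score.

    Returns
    -------
    DataFrame with one row per patient: ``normalized_cd34``,
    ``matched_time_days``, ``matched_model_entropy``, ``observed_entropy``
    and bookkeeping flags.
    """
    scores = np.asarray(cp_scores, dtype=float)
    entropies = np.asarray(cp_entropies, dtype=float)
    if scores.size != entropies.size:
        raise ValueError("scores and entropies must be aligned")
    if scores.size < 2:
        raise ValueError("need at least 2 CP patients to normalize")
    if sample_ids is None:
        sample_ids = [f"CP{i + 1:02d}" for i in range(scores.size)]

    scores_norm, _ = normalize_unit_interval(scores)
    ratio_norm = curve.normalized_cd34()
    sim_entropy_norm = curve.normalized_entropy()
    obs_entropy_norm, _ = normalize_unit_interval(entropies)

    sim_min = find_entropy_minimum(curve, smoothing_window=smoothing_window)
    sim_min_idx = int(np.argmin(np.abs(curve.times - sim_min.t_min)))

    shift, aligned = 0.0, False
    if align_minima:
        try:
            vertex = _observed_vertex(scores_norm, entropies)
            shift = float(ratio_norm[sim_min_idx]) - vertex
            if abs(shift) > max_alignment_shift:
                warnings.warn(
                    f"V-minimum alignment shift {shift:+.2f} exceeds "
                    f"{max_alignment_shift}; treating the V fit as unreliable "
                    "and skipping the shift",
                    UserWarning, stacklevel=2,
                )
                shift = 0.0
            else:
                aligned = True
        except ValueError as exc:
            warnings.warn(
                f"V-minimum alignment skipped: {exc}", UserWarning, stacklevel=2
            )
    effective = scores_norm + shift

    order = np.argsort(effective, kind="mergesort")
    matched_idx = np.empty(scores.size, dtype=int)
    floor_idx = 0
    for pos in order:
        target = effective[pos]
        lo_idx = floor_idx if enforce_monotone else 0
        cd34_dist = np.abs(ratio_norm[lo_idx:] - target)
        if match == "two-step":
            cand = int(np.argmin(cd34_dist)) + lo_idx
            near = (
                np.abs(ratio_norm[lo_idx:] - ratio_norm[cand]) <= neighborhood
            )
            if not near.any():
                raise ValueError("empty CD34 neighbourhood around candidate")
            pool = np.flatnonzero(near) + lo_idx
            best = pool[
                np.argmin(np.abs(sim_entropy_norm[pool] - obs_entropy_norm[pos]))
            ]
        elif match == "joint":
            d2 = cd34_dist**2 + (
                sim_entropy_norm[lo_idx:] - obs_entropy_norm[pos]
            ) ** 2
            best = int(np.argmin(d2)) + lo_idx
        else:
            raise ValueError(f"unknown match mode {match!r}")
        matched_idx[pos] = best
        if enforce_monotone:
            floor_idx = best
    result = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "normalized_cd34": scores_norm,
            "matched_time_days": curve.times[matched_idx],
            "matched_model_entropy": curve.entropy[matched_idx],
            "observed_entropy": entropies,
            "aligned": aligned,
        }
    ).set_index("sample_id")
    result.attrs["simulated_entropy_min_days"] = sim_min.t_min
    result.attrs["alignment_shift"] = shift
    return result


def classify_T1_T2(mapping: pd.DataFrame, boundary_time: float) -> pd.DataFrame:
    """Label patients T1 (matched before the boundary) or T2.

    A matched time exactly equal to the boundary is assigned T2 (the
    boundary is the entry into the late, higher-risk phase).
    """
    out = mapping.copy()
    out["phase_label"] = np.where(
        out["matched_time_days"] < boundary_time, "T1", "T2"
    )
    out.attrs.update(mapping.attrs)
    out.attrs["boundary_time_days"] = float(boundary_time)
    return out


class DiseaseTimeMapper(BaseEstimator):
    """Map (CD34 similarity, entropy) pairs to disease time and phase.

    Parameters mirror :func:`pin_patients`; ``boundary_time=None`` uses
    the simulated-entropy minimum of the fitted curve.

    Attributes
    ----------
    curve_ : SimulatedEntropyCurve
        The fitted model curve.
    boundary_time_ : float
        T1/T2 boundary in days.
    """

    def __init__(self, neighborhood: float = 0.05, match: str = "two-step",
                 align_minima: bool = True, boundary_time: float | None = None,
                 smoothing_window: int = 11):
        self.neighborhood = neighborhood
        self.match = match
        self.align_minima = align_minima
        self.boundary_time = boundary_time
        self.smoothing_window = smoothing_window

    def fit(self, curve: SimulatedEntropyCurve, y=None):
        self.curve_ = curve
        if self.boundary_time is not None:
            self.boundary_time_ = float(self.boundary_time)
        else:
            self.boundary_time_ = find_entropy_minimum(
                curve, smoothing_window=self.smoothing_window
            ).t_min
        return self

    def predict(self, X) -> np.ndarray:
        """Matched disease times (days) for an (n, 2) array-like of
        (score, entropy) pairs or a DataFrame with those columns."""
        return self.map_cohort(X)["matched_time_days"].to_numpy()

    def map_cohort(self, X) -> pd.DataFrame:
        check_is_fitted(self, "curve_")
        if isinstance(X, pd.DataFrame):
            scores = X["score"].to_numpy()
            entropies = X["entropy"].to_numpy()
            ids = list(X.index)
        else:
            arr = np.asarray(X, dtype=float)
            scores, entropies = arr[:, 0], arr[:, 1]
            ids = None
        mapping = pin_patients(
            scores, entropies, self.curve_,
            neighborhood=self.neighborhood, match=self.match,
            align_minima=self.align_minima,
            smoothing_window=self.smoothing_window, sample_ids=ids,
        )
        return classify_T1_T2(mapping, self.boundary_time_)
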