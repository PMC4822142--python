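"""CD34+ signature construction and signed rank-sum similarity scoring.

A CD34+ reference profile is assembled by averaging expression over the
flagged CD34+ reference samples; the top 5% most up- and down-regulated
genes of that profile form the signature.  A sample's CD34+ similarity is
then the signed log10 p-value of a two-sided Wilcoxon rank-sum test
between its expression values on the up-set and the down-set: a strongly
positive score means the sample's transcriptome looks like immature,
CD34-positive stem/progenitor cells, which in CML indicates advanced
disease history.

Expression matrices are gene x sample :class:`pandas.DataFrame` objects
on a log-intensity scale.  By default every gene is centered by its
cohort mean before both signature construction and scoring, which removes
probe-level baseline differences (``centering="none"`` preserves the raw
reading).  A :class:`CD34SimilarityScorer` estimator wraps the same logic
in scikit-learn fit/transform form (samples x genes orientation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "Signature",
    "SimilarityScore",
    "build_signature",
    "similarity_score",
    "score_cohort",
    "CD34SimilarityScorer",
]

_P_FLOOR = np.nextafter(0.0, 1.0)  # keep signed log10 finite
EXACT_MAX_SET_SIZE = 25  # exact rank-sum distribution up to this per-set size


@dataclass(frozen=True)
class Signature:
    """Ordered up-/down-regulated gene sets of a reference state."""

    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    reference_label: str = ""

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down gene sets overlap")
        if not self.up_genes or not self.down_genes:
            raise ValueError("signature gene sets must be nonempty")


@dataclass(frozen=True)
class SimilarityScore:
    """Signed log10 rank-sum p-value of one sample."""

    sample_id: str
    score: float
    p_value: float
    direction: int
    n_up: int = 0
    n_down: int = 0
    ok: bool = True
    note: str = ""


def _cohort_means(matrix: pd.DataFrame) -> pd.Series:
    return matrix.mean(axis=1)


def build_signature(
    matrix: pd.DataFrame,
    reference_samples: Sequence[str] | None = None,
    top_frac: float = 0.05,
    centering: str = "cohort-mean",
    reference_label: str = "CD34+",
) -> Signature:
    """Extract the top-``top_frac`` up/down genes of the reference profile.

    Parameters
    ----------
    matrix:
        Gene x sample expression table for the whole cohort (used for
        per-gene centering).
    reference_samples:
        Column names of the reference samples; all columns when ``None``.
    top_frac:
        Fraction of genes per direction; set sizes are
        ``max(1, floor(top_frac * n_genes))``.
    centering:
        ``"cohort-mean"`` (default) or ``"none"``.

    Ties in the reference profile are broken by gene-identifier order, so
    the signature is deterministic.
    """
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique()[:5]
        raise ValueError(f"duplicated gene identifiers, e.g. {list(dupes)}")
    if not 0 < top_frac < 0.5:
        raise ValueError("top_frac must lie in (0, 0.5)")
    n_top = max(1, int(np.floor(top_frac * matrix.shape[0])))
    if matrix.shape[0] < 2 * n_top:
        raise ValueError(
            f"too few genes ({matrix.shape[0]}) for disjoint top-{top_frac:.0%} "
            "up and down sets"
        )
    ref = matrix if reference_samples is None else matrix[list(reference_samples)]
    if ref.shape[1] < 1:
        raise ValueError("need at least one reference sample")
    profile = ref.mean(axis=1)
    if centering == "cohort-mean":
        profile = profile - _cohort_means(matrix)
    elif centering != "none":
        raise ValueError(f"unknown centering mode {centering!r}")
    # sort descending by value with gene-id tiebreak: stable sort on id first
    ordered = profile.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort"
    )
    up = tuple(ordered.index[:n_top])
    down = tuple(ordered.index[-n_top:][::-1])
    return Signature(up_genes=up, down_genes=down, reference_label=reference_label)


def _ranksum_pvalue(up_values: np.ndarray, down_values: np.ndarray) -> float:
    """Two-sided rank-sum p: exact for small tie-free sets, else normal
    approximation with continuity correction."""
    n, m = up_values.size, down_values.size
    pooled = np.concatenate([up_values, down_values])
    has_ties = np.unique(pooled).size < pooled.size
    small = n <= EXACT_MAX_SET_SIZE and m <= EXACT_MAX_SET_SIZE
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        up_values, down_values, alternative="two-sided", method=method,
        use_continuity=True,
    )
    return float(res.pvalue)


def similarity_score(
    sample_values: pd.Series,
    signature: Signature,
    sample_id: str = "",
    min_coverage: float = 0.8,
    centering_means: pd.Series | None = None,
) -> SimilarityScore:
    """Signed log10 rank-sum p-value of one sample against a signature.

    Missing signature genes are dropped pairwise; each gene set must keep
    at least ``min_coverage`` of its members.  The sign is positive when
    the up-set median exceeds the down-set median (more CD34+-like).
    """
    values = sample_values.dropna()
    if centering_means is not None:
        values = values - centering_means.reindex(values.index)
        values = values.dropna()
    up = values.reindex(list(signature.up_genes)).dropna()
    down = values.reindex(list(signature.down_genes)).dropna()
    if up.empty or down.empty:
        raise ValueError(
            f"sample {sample_id!r} has no overlap with the "
            f"{'up' if up.empty else 'down'} gene set"
        )
    cov_up = len(up) / len(signature.up_genes)
    cov_down = len(down) / len(signature.down_genes)
    if min(cov_up, cov_down) < min_coverage:
        return SimilarityScore(
            sample_id=sample_id, score=np.nan, p_value=np.nan, direction=0,
            n_up=len(up), n_down=len(down), ok=False,
            note=f"signature coverage {min(cov_up, cov_down):.0%} below "
                 f"{min_coverage:.0%}",
        )
    p = max(_ranksum_pvalue(up.to_numpy(), down.to_numpy()), _P_FLOOR)
    med_diff = float(np.median(up) - np.median(down))
    direction = 0 if med_diff == 0 else int(np.sign(med_diff))
    score = -direction * np.log10(p)
    return SimilarityScore(
        sample_id=sample_id, score=float(score), p_value=p, direction=direction,
        n_up=len(up), n_down=len(down),
    )


def score_cohort(
    matrix: pd.DataFrame,
    signature: Signature,
    min_coverage: float = 0.8,
    centering: str = "cohort-mean",
) -> pd.DataFrame:
    """Score every sample (column) of a cohort matrix.

    Returns a DataFrame indexed by sample id with columns
    ``score, p_value, direction, n_up, n_down, ok, note``; per-sample
    coverage failures are flagged rather than raised.
    """
    means = _cohort_means(matrix) if centering == "cohort-mean" else None
    records = []
    for sample_id in matrix.columns:
        try:
            s = similarity_score(
                matrix[sample_id], signature, sample_id=sample_id,
                min_coverage=min_coverage, centering_means=means,
            )
        except ValueError as exc:
            s = SimilarityScore(
                sample_id=sample_id, score=np.nan, p_value=np.nan,
                direction=0, ok=False, note=str(exc),
            )
        records.append(s.__dict__)
    return pd.DataFrame(records).set_index("sample_id")


class CD34SimilarityScorer(TransformerMixin, BaseEstimator):
    """Scikit-learn style CD34+ similarity scorer.

    ``fit(X, reference_mask=...)`` builds the signature from the reference
    rows of a samples x genes DataFrame (all rows when no mask is given)
    and stores the cohort centering means; ``transform`` maps samples to
    their signed log10 rank-sum similarity scores (an ``(n_samples, 1)``
    array, or a DataFrame via :meth:`score_frame`).

    Parameters
    ----------
    top_frac : float, default 0.05
        Fraction of genes per signature direction.
    centering : {"cohort-mean", "none"}
        Per-gene centering applied before ranking and scoring.
    min_coverage : float, default 0.8
        Minimum fraction of each gene set a sample must cover.
    """

    def __init__(self, top_frac: float = 0.05, centering: str = "cohort-mean",
                 min_coverage: float = 0.8):
        self.top_frac = top_frac
        self.centering = centering
        self.min_coverage = min_coverage

    def fit(self, X: pd.DataFrame, y=None, reference_mask=None):
        X = self._as_frame(X)
        matrix = X.T  # genes x samples
        if reference_mask is not None:
            reference = list(X.index[np.asarray(reference_mask, bool)])
        else:
            reference = None
        self.gene_means_ = _cohort_means(matrix)
        self.signature_ = build_signature(
            matrix, reference_samples=reference, top_frac=self.top_frac,
            centering=self.centering,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "signature_")
        return self.score_frame(X)[["score"]].to_numpy()

    def score_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Full per-sample score table (see :func:`score_cohort`)."""
        check_is_fitted(self, "signature_")
        X = self._as_frame(X)
        means = self.gene_means_ if self.centering == "cohort-mean" else None
        records = []
        for sample_id, row in X.iterrows():
            try:
                s = similarity_score(
                    row, self.signature_, sample_id=str(sample_id),
                    min_coverage=self.min_coverage, centering_means=means,
                )
            except ValueError as exc:
                s = SimilarityScore(
                    sample_id=str(sample_id), score=np.nan, p_value=np.nan,
                    direction=0, ok=False, note=str(exc),
                )
            records.append(s.__dict__)
        return pd.DataFrame(records).set_index("sample_id")

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X)
        return pd.DataFrame(
            X,
            index=[f"S{i}" for i in range(X.shape[0])],
            columns=[f"G{j + 1:05d}" for j in range(X.shape[1])],
        )
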