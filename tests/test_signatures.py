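"""Signature construction and signed rank-sum scoring, checked against an
exact enumeration oracle of the rank-sum distribution."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

import cml_chronos as cc
from cml_chronos.signatures import _ranksum_pvalue


def exact_ranksum_two_sided_p(up, down):
    """Independent oracle: enumerate all C(n+m, n) rank assignments of the
    pooled values and compute the two-sided tail of the Mann-Whitney U."""
    up, down = np.asarray(up, float), np.asarray(down, float)
    n, m = len(up), len(down)
    u_obs = sum(1 for a in up for b in down if a > b)
    pooled = np.concatenate([up, down])
    total = comb(n + m, n)
    count_le = count_ge = 0
    for idx in combinations(range(n + m), n):
        mask = np.zeros(n + m, bool)
        mask[list(idx)] = True
        u = sum(1 for a in pooled[mask] for b in pooled[~mask] if a > b)
        count_le += u <= u_obs
        count_ge += u >= u_obs
    return min(1.0, 2.0 * min(count_le, count_ge) / total)


def random_matrix(n_genes, n_samples, rng, prefix="G"):
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"{prefix}{i:05d}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )


class TestBuildSignature:
    @pytest.mark.parametrize("n_genes,expected", [(20, 1), (100, 5), (4309, 215)])
    def test_set_sizes_follow_floor_rule(self, n_genes, expected, rng):
        sig = cc.build_signature(random_matrix(n_genes, 3, rng))
        assert len(sig.up_genes) == len(sig.down_genes) == expected
        assert not set(sig.up_genes) & set(sig.down_genes)

    def test_ties_broken_by_gene_identifier(self, rng):
        matrix = random_matrix(40, 2, rng)
        matrix.iloc[:, :] = 1.0  # fully tied reference profile
        first = cc.build_signature(matrix, centering="none")
        second = cc.build_signature(matrix, centering="none")
        assert first == second
        assert list(first.up_genes) == sorted(matrix.index)[:2]

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError, match="too few genes"):
            cc.build_signature(random_matrix(1, 2, rng))

    def test_duplicate_gene_ids_rejected(self, rng):
        matrix = random_matrix(30, 2, rng)
        matrix.index = ["G1"] * 30
        with pytest.raises(ValueError, match="duplicated"):
            cc.build_signature(matrix)


class TestSimilarityScore:
    def test_identical_value_multisets_score_zero(self):
        sig = cc.Signature(up_genes=("u1", "u2", "u3"), down_genes=("d1", "d2", "d3"))
        values = pd.Series(
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            index=["u1", "u2", "u3", "d1", "d2", "d3"],
        )
        score = cc.similarity_score(values, sig)
        assert score.p_value == pytest.approx(1.0)
        assert score.score == 0.0
        assert score.direction == 0

    def test_fully_separated_sets_match_exact_enumeration(self):
        """5 up-genes all above 5 down-genes: two-sided p = 2/252."""
        sig = cc.Signature(
            up_genes=tuple(f"u{i}" for i in range(5)),
            down_genes=tuple(f"d{i}" for i in range(5)),
        )
        values = pd.Series(
            np.r_[np.arange(10.0, 15.0), np.arange(5)],
            index=list(sig.up_genes) + list(sig.down_genes),
        )
        score = cc.similarity_score(values, sig)
        assert score.p_value == pytest.approx(2.0 / 252.0)
        assert score.score == pytest.approx(-np.log10(2.0 / 252.0))
        assert score.score == pytest.approx(2.10, abs=0.01)
        swapped = cc.Signature(up_genes=sig.down_genes, down_genes=sig.up_genes)
        assert cc.similarity_score(values, swapped).score == pytest.approx(
            -score.score
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        up=st.lists(st.integers(0, 10_000), min_size=2, max_size=7, unique=True),
        down=st.lists(st.integers(10_001, 20_000), min_size=2, max_size=7,
                      unique=True),
        data=st.randoms(use_true_random=False),
    )
    def test_small_set_pvalues_match_enumeration_oracle(self, up, down, data):
        """The implementation agrees with brute-force enumeration of every
        rank configuration for tie-free sets of size <= 8."""
        values = np.array(up + down, dtype=float)
        data.shuffle(values)  # decouple magnitudes from set membership
        u_vals, d_vals = values[: len(up)], values[len(up):]
        if np.intersect1d(u_vals, d_vals).size:
            return
        assert _ranksum_pvalue(u_vals, d_vals) == pytest.approx(
            exact_ranksum_two_sided_p(u_vals, d_vals), rel=1e-12
        )

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=12, max_size=12, unique=True))
    def test_antisymmetry_under_set_swap(self, values):
        sig = cc.Signature(
            up_genes=tuple(f"u{i}" for i in range(6)),
            down_genes=tuple(f"d{i}" for i in range(6)),
        )
        series = pd.Series(values, index=list(sig.up_genes) + list(sig.down_genes))
        swapped = cc.Signature(up_genes=sig.down_genes, down_genes=sig.up_genes)
        a = cc.similarity_score(series, sig).score
        b = cc.similarity_score(series, swapped).score
        assert a == pytest.approx(-b)

    def test_score_monotone_in_up_set_shift(self, rng):
        sig = cc.Signature(
            up_genes=tuple(f"u{i}" for i in range(20)),
            down_genes=tuple(f"d{i}" for i in range(20)),
        )
        base = pd.Series(
            rng.normal(size=40), index=list(sig.up_genes) + list(sig.down_genes)
        )
        scores = []
        for delta in [0.0, 0.5, 1.0, 2.0, 4.0]:
            shifted = base.copy()
            shifted.loc[list(sig.up_genes)] += delta
            scores.append(cc.similarity_score(shifted, sig).score)
        assert np.all(np.diff(scores) >= 0)

    def test_empty_overlap_is_an_error(self):
        sig = cc.Signature(up_genes=("u1",), down_genes=("d1",))
        with pytest.raises(ValueError, match="no overlap"):
            cc.similarity_score(pd.Series({"x": 1.0}), sig)


class TestScoreCohort:
    def test_matches_single_sample_scoring(self, rng):
        matrix = random_matrix(200, 4, rng)
        sig = cc.build_signature(matrix, centering="none")
        cohort = cc.score_cohort(matrix, sig, centering="none")
        single = cc.similarity_score(matrix["S0"], sig, sample_id="S0")
        assert cohort.loc["S0", "score"] == pytest.approx(single.score)
        assert list(cohort.index) == list(matrix.columns)

    def test_sample_below_coverage_is_flagged_not_fatal(self, rng):
        matrix = random_matrix(200, 3, rng)
        sig = cc.build_signature(matrix, centering="none")
        broken = matrix.copy()
        broken.loc[list(sig.up_genes), "S1"] = np.nan
        cohort = cc.score_cohort(broken, sig, centering="none")
        assert not cohort.loc["S1", "ok"]
        assert cohort.loc[["S0", "S2"], "ok"].all()

    def test_scores_track_disease_time_on_synthetic_cohort(self, scored_cohort):
        """CD34+ similarity rank-correlates with true generation time."""
        truth = scored_cohort["truth"]
        cp = scored_cohort["cp_ids"]
        rho = spearmanr(
            truth.loc[cp, "true_time_days"].astype(float),
            scored_cohort["scores"].loc[cp, "score"],
        ).statistic
        assert rho > 0.9


class TestEstimator:
    def test_fit_transform_matches_function_surface(self, rng):
        matrix = random_matrix(200, 6, rng)  # genes x samples
        X = matrix.T
        est = cc.CD34SimilarityScorer().fit(X, reference_mask=[True] * 3 + [False] * 3)
        sig = cc.build_signature(matrix, reference_samples=["S0", "S1", "S2"])
        assert est.signature_ == sig
        transformed = est.transform(X)
        cohort = cc.score_cohort(matrix, sig)
        np.testing.assert_allclose(
            transformed.ravel(), cohort["score"].to_numpy()
        )

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = cc.CD34SimilarityScorer(top_frac=0.1)
        assert clone(est).get_params()["top_frac"] == 0.1
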