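"""V-shape regression, differential expression with BH control,
entropy-correlation sub-sampling and the stage-fraction grid."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cml_chronos as cc
from cml_chronos.cohortstats import DEResult


def bh_stepup_oracle(p_values):
    """Independently coded Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p_values, float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def random_matrix(n_genes, n_samples, rng):
    return pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"G{i:05d}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )


class TestVShape:
    def test_noiseless_parabola_recovers_vertex(self):
        x = np.linspace(0.0, 1.0, 42)
        y = 3.0 + 5.0 * (x - 0.4) ** 2
        res = cc.vshape_test(y, x)
        assert res.vertex == pytest.approx(0.4, abs=1e-9)
        assert res.p_quadratic < 1e-12

    def test_downward_parabola_has_no_vertex(self):
        x = np.linspace(0.0, 1.0, 30)
        res = cc.vshape_test(-((x - 0.5) ** 2), x)
        assert res.vertex is None

    def test_collinear_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cc.vshape_test(np.arange(6.0), np.ones(6))

    def test_type_one_error_rate_under_linear_truth(self):
        """Under a straight-line truth the quadratic term rejects at the
        nominal rate: over 1,000 simulated cohorts of n=42, the alpha=0.05
        rejection rate lies in [0.03, 0.07]."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = rng.uniform(0, 1, 42)
            y = 1.0 + 2.0 * x + rng.normal(0, 0.3, 42)
            rejections += cc.vshape_test(y, x).p_quadratic < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_significant_on_synthetic_chronic_phase(self, scored_cohort):
        """The generated cohort reproduces the entropy V over CP."""
        cp = scored_cohort["cp_ids"]
        res = cc.vshape_test(
            scored_cohort["entropies"].loc[cp].to_numpy(),
            scored_cohort["scores"].loc[cp, "score"].to_numpy(),
        )
        assert res.p_quadratic < 0.05
        assert res.vertex is not None


class TestDifferentialExpression:
    def test_identical_groups_yield_no_discoveries(self, rng):
        matrix = random_matrix(300, 8, rng)
        res = cc.differential_expression(
            matrix, ["S0", "S1", "S2", "S3"], ["S4", "S5", "S6", "S7"]
        )
        # same-distribution split: nothing should survive the FDR cut
        assert res.n_significant == 0
        assert res.n_tested == 300

    def test_q_never_below_p(self, rng):
        matrix = random_matrix(200, 10, rng)
        res = cc.differential_expression(
            matrix, [f"S{i}" for i in range(5)], [f"S{i}" for i in range(5, 10)]
        )
        ok = res.table["q"].notna()
        assert (res.table.loc[ok, "q"] >= res.table.loc[ok, "p"] - 1e-12).all()

    def test_direction_follows_mean_difference(self, rng):
        matrix = random_matrix(50, 6, rng)
        matrix.iloc[0, :3] += 10.0
        res = cc.differential_expression(
            matrix, ["S0", "S1", "S2"], ["S3", "S4", "S5"]
        )
        assert res.table.iloc[0]["direction"] == "up"

    def test_zero_variance_short_circuit(self):
        matrix = pd.DataFrame(
            {"S0": [1.0, 1.0], "S1": [1.0, 1.0], "S2": [1.0, 2.0],
             "S3": [1.0, 2.0]},
            index=["G1", "G2"],
        )
        res = cc.differential_expression(matrix, ["S0", "S1"], ["S2", "S3"])
        assert res.table.loc["G1", "p"] == 1.0
        assert bool(res.table.loc["G2", "degenerate"])
        assert res.n_tested == 1

    def test_overlapping_groups_rejected(self, rng):
        matrix = random_matrix(20, 4, rng)
        with pytest.raises(ValueError, match="disjoint"):
            cc.differential_expression(matrix, ["S0", "S1"], ["S1", "S2"])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=20))
    def test_bh_adjustment_matches_stepup_oracle(self, p_values):
        from statsmodels.stats.multitest import multipletests

        ours = multipletests(p_values, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, bh_stepup_oracle(p_values), atol=1e-12)


class TestDEFractions:
    def test_fraction_arithmetic(self):
        table = pd.DataFrame({"q": []})
        res = DEResult(table=table, n_tested=4309, n_significant=411, alpha=0.05)
        assert 100 * res.fraction_significant == pytest.approx(9.538, abs=0.01)

    def test_identical_groups_give_zero_percent(self, rng):
        matrix = random_matrix(100, 8, rng)
        groups = {
            "A": ["S0", "S1", "S2", "S3"],
            "B": ["S4", "S5", "S6", "S7"],
        }
        table = cc.de_fraction_matrix(matrix, groups)
        assert table.loc["A", "B"] == 0.0
        assert table.loc["A", "B"] == table.loc["B", "A"]

    def test_planted_separation_orders_fractions(self, scored_cohort):
        """Graded planted shifts reproduce the ordering
        T1-vs-BC > T1-vs-AP > T1-vs-T2."""
        annot = scored_cohort["annotations"]
        truth = scored_cohort["truth"]
        cp = scored_cohort["cp_ids"]
        t1 = [s for s in cp if truth.loc[s, "true_phase"] == "T1"]
        t2 = [s for s in cp if truth.loc[s, "true_phase"] == "T2"]
        groups = {"T1": t1, "T2": t2}
        for stage in ("AP", "BC"):
            groups[stage] = [
                s for s in annot.index
                if annot.loc[s, "stage"] == stage
                and not annot.loc[s, "is_cd34_reference"]
            ]
        table = cc.de_fraction_matrix(scored_cohort["expression"], groups)
        assert table.loc["T1", "BC"] > table.loc["T1", "AP"] > table.loc["T1", "T2"]


class TestEntropyCorrelation:
    def test_perfect_correlation_always_significant(self, rng):
        x = rng.normal(size=42)
        res = cc.entropy_correlation_subsample(x, x, n_iter=100, rng_seed=0)
        assert res["pct_significant"] == 100.0

    def test_null_pairs_significant_at_nominal_rate(self):
        """Averaged over many independent null cohorts the sub-sampling
        procedure flags ~5% of iterations."""
        rng = np.random.default_rng(7)
        fracs = []
        for _ in range(150):
            x, y = rng.normal(size=(2, 42))
            res = cc.entropy_correlation_subsample(x, y, n_iter=40, rng_seed=1)
            fracs.append(res["pct_significant"])
        assert np.mean(fracs) == pytest.approx(5.0, abs=2.5)

    def test_tiny_subsample_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            cc.entropy_correlation_subsample(
                np.arange(5.0), np.arange(5.0), subsample_frac=0.5
            )


class TestStageGrid:
    def test_hand_placed_cohort_matches_enumeration(self):
        """One patient per cell: the grid equals the hand enumeration."""
        scores = np.array([0.0, 0.3, 0.6, 1.0, 0.05, 0.35, 0.65, 0.95])
        entropies = np.array([0.0] * 4 + [1.0] * 4)
        stages = ["CP", "AP", "APcyto", "BC"] * 2
        grid = cc.stage_fraction_grid(scores, entropies, stages)
        occupied = grid.table[grid.table["count"] > 0]
        assert occupied.shape[0] == 8
        assert (occupied["count"] == 1).all()
        np.testing.assert_allclose(occupied["fraction_pct"].to_numpy(), 12.5)
        low = grid.table[grid.table["entropy_half"] == "low"]
        assert list(low[low["count"] > 0]["stage"]) == ["CP", "AP", "APcyto", "BC"]

    def test_single_stage_fractions_sum_to_hundred(self, rng):
        scores = rng.uniform(0, 1, 30)
        entropies = rng.uniform(0, 1, 30)
        grid = cc.stage_fraction_grid(scores, entropies, ["CP"] * 30)
        cp_rows = grid.table[grid.table["stage"] == "CP"]
        assert cp_rows["fraction_pct"].sum() == pytest.approx(100.0)
        assert grid.table["count"].sum() == 30

    def test_boundary_values_join_lower_cell(self):
        """A score on an internal quarter edge belongs to the lower quarter."""
        scores = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        entropies = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        grid = cc.stage_fraction_grid(scores, entropies, ["CP"] * 5)
        quarters = grid.cell_of_sample.str.extract(r"Q(\d)")[0].astype(int)
        assert list(quarters) == [1, 1, 2, 3, 4]

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown stage"):
            cc.stage_fraction_grid([0, 1], [0, 1], ["CP", "XX"])


class TestRandomizationControl:
    @staticmethod
    def cohort_labels():
        return ["CP"] * 42 + ["AP"] * 9 + ["APcyto"] * 8 + ["BC"] * 28

    def test_permutations_preserve_composition_and_mean_fraction(self):
        """Labels are only shuffled, and the expected AP share inside any
        fixed subset equals the cohort-wide AP proportion (~10%)."""
        stages = self.cohort_labels()
        n = len(stages)
        cells = ["inside"] * 22 + ["outside"] * (n - 22)
        table = cc.randomization_control(stages, cells, n_perm=1000, rng_seed=3)
        null = table.attrs["null_fractions"]
        # composition: per permutation the two cells' AP counts sum to 9
        total_ap = (null[("inside", "AP")] + null[("outside", "AP")]) * n / 100
        np.testing.assert_allclose(total_ap, 9.0, atol=1e-9)
        row = table.set_index(["cell", "stage"]).loc[("inside", "AP")]
        expected = 100.0 * 9 / 87
        mc_se = row["null_sd_pct"] * (n / 22) / np.sqrt(1000)
        assert row["null_mean_within_cell_pct"] == pytest.approx(
            expected, abs=3 * mc_se + 0.2
        )

    def test_seeded_runs_are_identical(self):
        stages = self.cohort_labels()
        cells = (["a"] * 40 + ["b"] * 47)
        t1 = cc.randomization_control(stages, cells, n_perm=50, rng_seed=9)
        t2 = cc.randomization_control(stages, cells, n_perm=50, rng_seed=9)
        for key in t1.attrs["null_fractions"]:
            np.testing.assert_array_equal(
                t1.attrs["null_fractions"][key], t2.attrs["null_fractions"][key]
            )

    def test_null_mean_matches_cohort_proportion_per_cell(self):
        """Law of total probability: under label permutation every cell's
        expected stage share (of cohort) is cell_size/n * stage share."""
        stages = self.cohort_labels()
        rng = np.random.default_rng(0)
        cells = rng.choice(["q1", "q2", "q3", "q4"], size=len(stages))
        table = cc.randomization_control(stages, cells, n_perm=1000, rng_seed=5)
        n = len(stages)
        for _, row in table.iterrows():
            expected = 100.0 * row["cell_size"] / n * (
                stages.count(row["stage"]) / n
            )
            se = row["null_sd_pct"] / np.sqrt(1000)
            assert row["null_mean_pct"] == pytest.approx(
                expected, abs=3 * se + 1e-9
            )
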