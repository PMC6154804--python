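"""Differential modification/expression rules and diurnal classification."""

import numpy as np
import pandas as pd
import pytest

from acylscape.differential import (
    changed_set_overlap,
    diff_expression,
    diff_modification,
    diurnal_classification,
)


def _tpm(*cols):
    idx = pd.Index([f"g{i}" for i in range(len(cols[0]))], name="gene_id")
    return pd.DataFrame({f"r{j+1}": c for j, c in enumerate(cols)}, index=idx)


class TestDiffModification:
    def test_consistent_increase_is_up(self):
        res = diff_modification(_tpm([10.0], [10.0]), _tpm([20.0], [22.0]), epsilon=0.1)
        assert res["call"].iloc[0] == "up"
        assert res["fc_rep1"].iloc[0] == pytest.approx(20.1 / 10.1)

    def test_one_replicate_below_threshold_is_unchanged(self):
        res = diff_modification(_tpm([10.0], [10.0]), _tpm([14.0], [20.0]), epsilon=0.1)
        assert res["call"].iloc[0] == "unchanged"

    def test_pseudocount_bounds_fold_change_on_empty_genes(self):
        res = diff_modification(_tpm([0.0], [0.0]), _tpm([5.0], [5.0]), epsilon=1.0)
        assert res["fc_rep1"].iloc[0] == pytest.approx(6.0)
        assert res["call"].iloc[0] == "up"

    def test_swapping_conditions_mirrors_calls(self):
        rng = np.random.default_rng(2)
        a = _tpm(rng.gamma(2, 10, 200), rng.gamma(2, 10, 200))
        b = _tpm(rng.gamma(2, 10, 200), rng.gamma(2, 10, 200))
        fwd = diff_modification(a, b)
        rev = diff_modification(b, a)
        assert ((fwd["call"] == "up") == (rev["call"] == "down")).all()
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"])

    def test_replicate_count_and_epsilon_validated(self):
        with pytest.raises(ValueError, match="2 replicates"):
            diff_modification(_tpm([1.0]), _tpm([1.0], [1.0]))
        with pytest.raises(ValueError, match="epsilon"):
            diff_modification(_tpm([1.0], [1.0]), _tpm([1.0], [1.0]), epsilon=0.0)


def _counts(matrix):
    arr = np.asarray(matrix, dtype=float)
    idx = pd.Index([f"g{i}" for i in range(arr.shape[0])], name="gene_id")
    return pd.DataFrame(arr, index=idx, columns=[f"r{j}" for j in range(arr.shape[1])])


class TestDiffExpression:
    def test_identical_groups_are_unchanged(self):
        rng = np.random.default_rng(1)
        m = _counts(rng.poisson(100, size=(50, 3)))
        res = diff_expression(m, m.copy())
        assert (res["call"] == "unchanged").all()
        assert (res["log2fc"] == 0).all()

    def test_strong_but_small_fold_change_fails_fc_gate(self):
        """FC 3 with overwhelming significance still does not satisfy FC > 4."""
        rng = np.random.default_rng(6)
        base = rng.poisson(1000, size=(400, 3)).astype(float)
        treated = base.copy()
        treated[0] = rng.poisson(3000, 3)  # 3-fold, trivially significant
        res = diff_expression(_counts(base), _counts(treated))
        assert res["fdr"].iloc[0] < 1e-4
        assert res["call"].iloc[0] == "unchanged"

    def test_planted_eightfold_gene_called_up(self):
        rng = np.random.default_rng(8)
        base = rng.poisson(300, size=(500, 3)).astype(float)
        treated = base.copy()
        treated[3] = rng.poisson(2400, 3)
        res = diff_expression(_counts(base), _counts(treated))
        assert res["call"].iloc[3] == "up"

    def test_precomputed_pvalues_are_respected(self):
        m = _counts([[10, 10, 10], [10, 10, 10]])
        t = _counts([[100, 100, 100], [100, 100, 100]])
        p = pd.Series([1.0, 1e-9], index=m.index)
        res = diff_expression(m, t, pvalues=p)
        assert res["call"].tolist() == ["unchanged", "up"]

    def test_welch_method_available(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(200, size=(100, 4)).astype(float)
        res = diff_expression(_counts(base), _counts(base * 10), method="welch")
        assert (res["log2fc"] > 3).mean() > 0.9

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            diff_expression(_counts([[1], [2]]), _counts([[1, 2], [3, 4]]))


def _timepoints(rows_by_tp, reps=3, seed=0):
    rng = np.random.default_rng(seed)
    out = {}
    for tp, means in rows_by_tp.items():
        mu = np.asarray(means, dtype=float)
        out[tp] = _counts(rng.poisson(mu[:, None], size=(mu.size, reps)))
    return out


class TestDiurnal:
    def test_constant_gene_never_significant(self):
        tps = _timepoints({t: [500] * 30 for t in "ABCD"}, seed=3)
        call = diurnal_classification(tps)
        assert (call.table["n_significant"] == 0).all()
        assert not call.table["diurnal"].any()

    def test_two_significant_comparisons_is_not_diurnal(self):
        """'More than two of six' is strict: a gene whose only >2-fold
        contrasts are A-vs-C and A-vs-D (A/B and B/C stay at 1.8x) has
        exactly 2 significant comparisons and is not called diurnal."""
        base = [1600] * 40
        tps = _timepoints(
            {"A": [5200] + base, "B": [2888] + base, "C": [1600] + base, "D": [1600] + base},
            seed=5,
        )
        call = diurnal_classification(tps)
        assert call.table["n_significant"].iloc[0] == 2
        assert not call.table["diurnal"].iloc[0]

    def test_spike_at_one_time_point_is_diurnal(self):
        base = [400] * 40
        tps = _timepoints(
            {"A": [6000] + base, "B": [500] + base, "C": [500] + base, "D": [500] + base},
            seed=7,
        )
        call = diurnal_classification(tps)
        assert call.table["n_significant"].iloc[0] == 3
        assert call.table["diurnal"].iloc[0]

    def test_planted_sinusoid_recovered_under_generator_defaults(self, sim_small):
        _, _, truth, _, expr = sim_small
        call = diurnal_classification(expr.timepoint_counts)
        planted = truth.df.index[truth.df["diurnal"]]
        nulls = truth.df.index[~truth.df["diurnal"]]
        assert call.table.loc[planted, "diurnal"].mean() > 0.7
        assert call.table.loc[nulls, "diurnal"].mean() <= 0.01

    def test_invariant_under_cyclic_relabelling(self):
        tps = _timepoints(
            {"A": [500, 900], "B": [100, 900], "C": [500, 900], "D": [2000, 900]},
            seed=9,
        )
        rotated = {k: tps[k] for k in ["C", "D", "A", "B"]}
        c1 = diurnal_classification(tps)
        c2 = diurnal_classification(rotated)
        pd.testing.assert_series_equal(
            c1.table["n_significant"], c2.table["n_significant"]
        )

    def test_wrong_number_of_time_points_rejected(self):
        tps = _timepoints({t: [10] * 5 for t in "ABC"})
        with pytest.raises(ValueError, match="4 time points"):
            diurnal_classification(tps)


class TestChangedSetOverlap:
    def test_disjoint_and_identical_sets(self):
        res = changed_set_overlap({"a": {"g1", "g2"}, "b": {"g3"}})
        assert res.loc["a&b", "n"] == 0
        res = changed_set_overlap({"a": {"g1", "g2"}, "b": {"g1", "g2"}})
        assert res.loc["a&b", "n"] == 2
        assert res.loc["a&b", "pct_of_first"] == 100.0

    def test_random_sets_match_hypergeometric_expectation(self):
        rng = np.random.default_rng(11)
        universe = np.array([f"g{i}" for i in range(5000)])
        inters = []
        for _ in range(50):
            a = set(rng.choice(universe, 400, replace=False))
            b = set(rng.choice(universe, 600, replace=False))
            inters.append(changed_set_overlap({"a": a, "b": b}).loc["a&b", "n"])
        expected = 400 * 600 / 5000
        assert abs(np.mean(inters) - expected) < 4 * np.sqrt(expected / 50) + 1

    def test_triple_intersection_reported(self):
        res = changed_set_overlap(
            {"a": {"g1", "g2"}, "b": {"g1", "g3"}, "c": {"g1"}}
        )
        assert res.loc["a&b&c", "n"] == 1
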