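import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aspasia.analysis import AnalysisError, ResponseTable, efast_indices, local_curves, prcc
from aspasia.sampling import efast_sample, lhs_sample, local_sweep
from aspasia.settings import ParameterRange


def _table(y):
    return ResponseTable(pd.DataFrame({"y": y}))


def unit_ranges(k):
    return [ParameterRange(f"p{j}", 0.0, 1.0, baseline=0.5) for j in range(k)]


def prcc_oracle(X, y):
    """Independent oracle: partial rank correlation via inversion of the
    rank correlation matrix (precision-matrix identity), not residualisation."""
    R = np.column_stack([stats.rankdata(c) for c in X.T] + [stats.rankdata(y)])
    C = np.corrcoef(R, rowvar=False)
    P = np.linalg.inv(C)
    k = X.shape[1]
    return np.array([-P[j, k] / np.sqrt(P[j, j] * P[k, k]) for j in range(k)])


class TestPRCC:
    def test_strong_monotone_dependence(self):
        design = lhs_sample(unit_ranges(4), n=100, seed=0)
        rng = np.random.default_rng(0)
        y = 3.0 * design.rows[:, 0] + 0.01 * rng.normal(size=100)
        res = prcc(design, _table(y), "y")
        t = res.table.set_index("target")
        assert t.loc["p0", "prcc"] >= 0.95
        assert (t.drop("p0")["prcc"].abs() <= 0.3).all()
        assert t.loc["p0", "p_value"] < 1e-6

    def test_rank_invariance(self):
        design = lhs_sample(unit_ranges(3), n=50, seed=1)
        y = design.rows[:, 0] - 0.5 * design.rows[:, 2]
        r1 = prcc(design, _table(y), "y").table["prcc"]
        r2 = prcc(design, _table(np.exp(y)), "y").table["prcc"]
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_matrix_oracle_small(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 10, 3
        design = lhs_sample(unit_ranges(k), n=n, seed=seed)
        y = rng.normal(size=n)
        got = prcc(design, _table(y), "y").table["prcc"].to_numpy()
        np.testing.assert_allclose(got, prcc_oracle(design.rows, y), atol=1e-10)

    def test_joint_permutation_invariance(self):
        design = lhs_sample(unit_ranges(3), n=40, seed=2)
        noise_rng = np.random.default_rng(7)
        y = design.rows[:, 1] ** 2 + 0.2 * noise_rng.normal(size=40)
        perm = np.random.default_rng(0).permutation(40)
        from dataclasses import replace
        shuffled = replace(design, rows=design.rows[perm])
        r1 = prcc(design, _table(y), "y").table["prcc"]
        r2 = prcc(shuffled, _table(y[perm]), "y").table["prcc"]
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_constant_column_flagged(self):
        design = lhs_sample(unit_ranges(3), n=20, seed=3)
        from dataclasses import replace
        rows = design.rows.copy()
        rows[:, 1] = 0.5
        design = replace(design, rows=rows)
        res = prcc(design, _table(rows[:, 0]), "y")
        t = res.table.set_index("target")
        assert np.isnan(t.loc["p1", "prcc"])
        assert "constant" in t.loc["p1", "note"]

    def test_requires_lhs(self):
        design = local_sweep(unit_ranges(2), increments=5)
        with pytest.raises(AnalysisError, match="LHS"):
            prcc(design, _table(np.zeros(10)), "y")

    def test_needs_enough_rows(self):
        design = lhs_sample(unit_ranges(4), n=5, seed=0)
        with pytest.raises(AnalysisError, match="n >="):
            prcc(design, _table(np.zeros(5)), "y")

    def test_bounds(self):
        design = lhs_sample(unit_ranges(2), n=30, seed=5)
        y = design.rows[:, 0]
        res = prcc(design, _table(y), "y")
        assert (res.table["prcc"].abs() <= 1.0).all()


class TestEfastIndices:
    def test_single_factor_dominates(self):
        design = efast_sample(unit_ranges(3), 129, 3, seed=0)
        y = design.rows[:, 0] ** 2
        res = efast_indices(design, _table(y), "y")
        t = res.table.set_index("target")
        assert t.loc["p0", "Si"] >= 0.9
        assert t.loc["_dummy_", "STi"] <= 0.1
        assert t.loc["p0", "p_vs_dummy"] < 0.05

    def test_si_at_most_sti(self):
        design = efast_sample(unit_ranges(3), 129, 3, seed=1)
        rng = np.random.default_rng(1)
        y = (design.rows[:, 0] + 0.5 * design.rows[:, 1] * design.rows[:, 2]
             + 0.05 * rng.normal(size=design.n_rows))
        res = efast_indices(design, _table(y), "y")
        for _, row in res.table.iterrows():
            assert row["Si"] <= row["STi"] + 0.05
            assert -0.05 <= row["Si"] <= 1.05

    def test_additive_sum_bounded(self):
        design = efast_sample(unit_ranges(3), 257, 3, seed=2)
        y = design.rows[:, 0] + 2 * design.rows[:, 1] + 3 * design.rows[:, 2]
        res = efast_indices(design, _table(y), "y")
        real = res.table[~res.table["is_dummy"]]
        assert real["Si"].sum() <= 1.05

    def test_constant_response_flagged(self):
        design = efast_sample(unit_ranges(2), 65, 2, seed=3)
        res = efast_indices(design, _table(np.zeros(design.n_rows)), "y")
        assert "degenerate_blocks" in res.notes
        assert res.table["Si"].isna().all()

    def test_requires_efast_design(self):
        design = lhs_sample(unit_ranges(2), n=10, seed=0)
        with pytest.raises(AnalysisError):
            efast_indices(design, _table(np.zeros(10)), "y")


class TestLocalCurves:
    def test_flat_response(self):
        design = local_sweep(unit_ranges(2), increments=5)
        res = local_curves(design, _table(np.full(10, 7.0)), "y")
        for frame in res.values():
            assert (frame["abs_deviation"] == 0).all()

    def test_hand_computed_five_point(self):
        design = local_sweep([ParameterRange("a", 0.0, 1.0, baseline=0.5)],
                             increments=5)
        y = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        res = local_curves(design, _table(y), "y", baseline_response=4.0)
        np.testing.assert_allclose(res["a"]["abs_deviation"], [3, 2, 0, 4, 12])

    def test_monotone_deviations_for_linear_response(self):
        design = local_sweep([ParameterRange("a", 0.0, 1.0, baseline=0.5)],
                             increments=9)
        y = 2.0 * design.rows[:, 0]
        res = local_curves(design, _table(y), "y", baseline_response=1.0)
        dev = res["a"]["abs_deviation"].to_numpy()
        assert np.all(np.diff(dev[:5]) <= 0) and np.all(np.diff(dev[4:]) >= 0)

    def test_missing_response_column(self):
        design = local_sweep(unit_ranges(1), increments=3)
        with pytest.raises(AnalysisError, match="not found"):
            local_curves(design, _table(np.zeros(3)), "z")
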