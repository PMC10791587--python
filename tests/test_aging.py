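"""Spearman aging classification and fold-change deregulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ncaging import (Thresholds, classify_aging, deregulated_counts,
                     foldchange_table, spearman_age, ttest_bh)
from ncaging._stats import spearman_p_from_rho, spearman_rho_matrix

from conftest import make_cm


def rank_pearson_oracle(x, y):
    """Independent oracle: mid-rank then plain Pearson."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        rho, p = spearman_age([1, 2, 5, 9, 20], [1, 3, 6, 9, 12])
        assert rho == pytest.approx(1.0) and p < 0.05

    def test_reversed_ages_is_minus_one(self):
        ages = np.array([1, 3, 6, 9, 12, 15.0])
        rho, _ = spearman_age(ages[::-1], ages)
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_rank_displacement(self):
        # ranks (2,1,4,3,6,5) against 1..6: rho = 1 - 6*6/(6*35) = 0.8286
        rho, _ = spearman_age([2, 1, 4, 3, 6, 5], [1, 2, 3, 4, 5, 6])
        assert rho == pytest.approx(1 - 36 / 210, abs=1e-12)

    def test_constant_vector_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_age([5, 5, 5, 5], [1, 2, 3, 4])
        assert np.isnan(rho)

    def test_matches_rank_pearson_oracle_fuzzed(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(10, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.5:     # inject ties
                x = np.round(x)
                y = np.round(y, 1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = spearman_age(x, y)
            assert rho == pytest.approx(rank_pearson_oracle(x, y),
                                        abs=1e-12)
            sp = stats.spearmanr(x, y)
            assert rho == pytest.approx(sp.statistic, abs=1e-12)
            assert p == pytest.approx(sp.pvalue, rel=1e-9)

    def test_exact_permutation_p_small_n(self):
        """For n <= 9 without ties, p is the exact permutation tail."""
        x = [3, 1, 4, 2, 5]
        y = [1, 2, 3, 4, 5]
        rho, p = spearman_age(x, y)
        from itertools import permutations
        rhos = [rank_pearson_oracle(perm, y)
                for perm in permutations(range(5))]
        exact = np.mean([abs(r) >= abs(rho) - 1e-12 for r in rhos])
        assert p == pytest.approx(exact)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 25))
        ages = rng.integers(1, 28, 25).astype(float)
        rho = spearman_rho_matrix(x, ages[None, :])[:, 0]
        p = spearman_p_from_rho(rho, 25)
        for i in range(8):
            r_i, p_i = spearman_age(x[i], ages)
            assert rho[i] == pytest.approx(r_i, abs=1e-12)
            assert p[i] == pytest.approx(p_i, rel=1e-9)


class TestClassify:
    def _rho(self, rows):
        return pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))],
                            columns=[f"t{j}" for j in
                                     range(len(rows[0]))])

    def test_global_needs_more_than_five_same_sign_tissues(self):
        rho = self._rho([[0.6] * 6, [0.6] * 5 + [0.0],
                         [-0.6] * 6, [0.6] * 3 + [-0.6] * 3])
        calls = classify_aging(rho)
        assert list(calls["label"]) == ["global_pos", "local", "global_neg",
                                        "local"]

    def test_single_tissue_local(self):
        rho = self._rho([[0.6, 0.1, -0.2, 0.0, 0.3, 0.4]])
        calls = classify_aging(rho)
        assert calls["label"].iloc[0] == "local"
        assert calls["local_tissue"].iloc[0] == "t0"

    def test_boundary_rho_is_strict(self):
        rho = self._rho([[0.5] * 6])
        assert classify_aging(rho)["label"].iloc[0] == "none"


class TestFoldChange:
    def _cm(self):
        # liver: 3m mean 20, 12m mean 30 (f1) / 40 (f2); f3 zero baseline
        counts = {"a3_0": [20, 20, 0], "a3_1": [20, 20, 0],
                  "a3_2": [20, 20, 0],
                  "a12_0": [30, 40, 5], "a12_1": [30, 40, 5],
                  "a12_2": [30, 40, 5]}
        cm = make_cm(counts, ["f1", "f2", "f3"],
                     ages=[3, 3, 3, 12, 12, 12])
        # use raw counts as expression: equal library sizes
        cm.normalized = cm.counts.astype(float)
        return cm

    def test_boundary_three_halves_not_deregulated(self):
        fc = foldchange_table(self._cm(), "liver")
        row = fc[fc["feature_id"] == "f1"].iloc[0]
        assert row["fc"] == pytest.approx(1.5) and not row["deregulated"]

    def test_twofold_is_deregulated(self):
        fc = foldchange_table(self._cm(), "liver")
        row = fc[fc["feature_id"] == "f2"].iloc[0]
        assert row["fc"] == pytest.approx(2.0) and row["deregulated"]

    def test_zero_baseline_excluded(self):
        fc = foldchange_table(self._cm(), "liver")
        assert "f3" not in set(fc["feature_id"])

    def test_no_later_timepoints_empty(self):
        cm = make_cm({"s1": [1], "s2": [2]}, ["f1"], ages=[3, 3]).normalize()
        assert foldchange_table(cm, "liver").empty


class TestTTestBH:
    def test_bh_step_up_hand_example(self):
        # four features with p = .01,.02,.03,.04 -> all adjusted to .04
        rng = np.random.default_rng(0)
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    def test_identical_groups_p_near_one(self):
        counts = {f"s{j}": [10] for j in range(6)}
        cm = make_cm(counts, ["f1"], ages=[3, 3, 3, 12, 12, 12])
        cm.normalized = cm.counts.astype(float)
        out = ttest_bh(cm, "liver", 12.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_small_groups_give_no_p(self):
        counts = {f"s{j}": [j] for j in range(4)}
        cm = make_cm(counts, ["f1"], ages=[3, 3, 12, 12]).normalize()
        out = ttest_bh(cm, "liver", 12.0)
        assert out["p"].isna().all()

    def test_bh_is_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        counts = {f"s{j}": rng.integers(1, 1000, 50).tolist()
                  for j in range(8)}
        cm = make_cm(counts, [f"f{i}" for i in range(50)],
                     ages=[3] * 4 + [12] * 4).normalize()
        out = ttest_bh(cm, "liver", 12.0).dropna()
        srt = out.sort_values("p")
        assert (srt["p_adj"].diff().dropna() >= -1e-12).all()
        assert (out["p_adj"] <= 1.0 + 1e-12).all()
        assert (out["p_adj"] >= out["p"] - 1e-12).all()


class TestDeregulatedCounts:
    def _records(self, n_dereg):
        rows = [{"feature_id": f"f{i}", "tissue": "liver",
                 "timepoint": 12.0, "deregulated": i < n_dereg}
                for i in range(max(n_dereg, 1) + 5)]
        return pd.DataFrame(rows)

    def test_no_deregulated_all_zero(self):
        table = deregulated_counts(self._records(0))
        assert (table.to_numpy() == 0).all()

    def test_cap_mode(self):
        table = deregulated_counts(self._records(150), cap=100)
        assert table.loc["liver", 12.0] == 100

    def test_uncapped_equals_record_count(self):
        table = deregulated_counts(self._records(150))
        assert table.loc["liver", 12.0] == 150


class TestPlantedRecovery:
    def test_global_features_recovered_in_default_cohort(self, default_cohort,
                                                         thresholds):
        from ncaging import aging_correlations
        cm = default_cohort.cm
        rho = aging_correlations(cm)
        calls = classify_aging(rho, thresholds)
        truth = default_cohort.truth
        g_true = set(truth.index[truth["label"] == "global"])
        g_called = set(calls.index[calls["label"].str.startswith("global")])
        assert len(g_true & g_called) / len(g_true) >= 0.95
        nulls = set(truth.index[truth["label"] == "none"])
        assert len(g_called & nulls) <= max(1, 0.001 * len(nulls))
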