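"""Inverse-correlation target calling, enrichment and set overlaps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ncaging import (BindingSite, CountMatrix, Thresholds, call_targets,
                     circulating_features, circulating_intersection,
                     control_targets, enrichment_fold, site_enrichment,
                     target_set_overlaps)

from conftest import make_cm


def _paired_matrices(gene_fn, n_tissues=3, n=20, seed=0):
    """miRNA matrix with one miRNA; genes built from it by gene_fn."""
    rng = np.random.default_rng(seed)
    sids, tissues, mi_col, gene_cols = [], [], [], {}
    for t in range(n_tissues):
        for j in range(n):
            sids.append(f"t{t}_s{j}")
            tissues.append(f"t{t}")
    mi_vals = rng.uniform(10, 100, len(sids))
    genes = gene_fn(mi_vals, rng)
    mi_cm = make_cm({s: [int(v)] for s, v in zip(sids, mi_vals)},
                    ["mir-1"], tissues=tissues)
    mi_cm.normalized = mi_cm.counts.astype(float)
    g_cm = make_cm({s: [int(genes[k][i]) for k in sorted(genes)]
                    for i, s in enumerate(sids)}, sorted(genes),
                   tissues=tissues)
    g_cm.normalized = g_cm.counts.astype(float)
    return mi_cm, g_cm


class TestCallTargets:
    def test_planted_anticorrelation_found_in_three_tissues(self):
        mi, g = _paired_matrices(
            lambda v, rng: {"gene-anti": 200 - v + rng.normal(0, 1, len(v))})
        pairs = call_targets(mi, g, ["mir-1"])
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row["gene"] == "gene-anti" and row["n_support_tissues"] == 3

    def test_single_tissue_support_excluded(self):
        def gene_fn(v, rng):
            out = v.copy()
            out[:20] = 200 - v[:20]                   # anti only in tissue 0
            out[20:] = rng.uniform(10, 100, len(v) - 20)
            return {"gene-local": out}
        mi, g = _paired_matrices(gene_fn)
        assert call_targets(mi, g, ["mir-1"]).empty

    def test_positive_control_mirrors_inverse(self):
        mi, g = _paired_matrices(
            lambda v, rng: {"gene-pos": v + rng.normal(0, 1, len(v)),
                            "gene-anti": 200 - v})
        ctrl = control_targets(mi, g, ["mir-1"])
        assert set(ctrl["gene"]) == {"gene-pos"}

    def test_no_shared_samples_is_error(self):
        mi = make_cm({"a": [1]}, ["mir-1"]).normalize()
        g = make_cm({"b": [1]}, ["g1"]).normalize()
        with pytest.raises(ValueError, match="shared"):
            call_targets(mi, g, ["mir-1"])

    def test_null_discovery_calibrated(self):
        """Independent genes: p < 0.05 at the nominal rate, and the full
        inverse criterion is rarer than the p cutoff."""
        rng = np.random.default_rng(123)
        n = 40
        n_pairs = 1000
        from ncaging._stats import spearman_p_from_rho, spearman_rho_matrix
        x = rng.normal(size=(n_pairs, n))
        y = rng.normal(size=(n_pairs, n))
        rho = np.array([spearman_rho_matrix(x[i:i + 1], y[i:i + 1])[0, 0]
                        for i in range(n_pairs)])
        p = spearman_p_from_rho(rho, n)
        rate_p = (p < 0.05).mean()
        ci = 3 * np.sqrt(0.05 * 0.95 / n_pairs)
        assert abs(rate_p - 0.05) < ci + 0.01
        rate_full = ((p < 0.05) & (rho < -0.4)).mean()
        assert rate_full <= 0.05


class TestEnrichment:
    def test_fold_from_printed_fraction_pairs(self):
        assert enrichment_fold(4.91, 0.78) == pytest.approx(6.3, abs=0.1)
        assert enrichment_fold(4.92, 1.30) == pytest.approx(3.8, abs=0.1)
        assert enrichment_fold(2.45, 0.27) == pytest.approx(9.0, abs=0.1)
        assert enrichment_fold(1.0, 0.0) == float("inf")

    def test_odds_ratio_hand_arithmetic(self):
        # 2x2 table (9, 113 | 120, 54872)
        odds, p = stats.fisher_exact([[9, 113], [120, 54872]])
        assert odds == pytest.approx(9 * 54872 / (113 * 120), rel=1e-12)
        assert odds == pytest.approx(36.42, abs=0.01)
        assert p < 0.01

    def _pairs(self, genes, mirna="m1"):
        return pd.DataFrame({"mirna": [mirna] * len(genes), "gene": genes,
                             "direction": "inverse",
                             "n_support_tissues": 2, "mean_rho": -0.5,
                             "tissues": "a,b"})

    def test_identical_fractions_fold_one_p_one(self):
        case = self._pairs([f"g{i}" for i in range(20)])
        ctrl = self._pairs([f"h{i}" for i in range(20)])
        sites = [BindingSite("m1", g, "8mer", True)
                 for g in ["g0", "g1", "h0", "h1"]]
        res = {e.site_type: e for e in site_enrichment(case, ctrl, sites)}
        assert res["8mer"].fold == pytest.approx(1.0)
        assert res["8mer"].p_fisher == pytest.approx(1.0)

    def test_zero_control_hits_gives_inf_fold(self):
        case = self._pairs(["g0", "g1"])
        ctrl = self._pairs(["h0", "h1"])
        sites = [BindingSite("m1", "g0", "8mer", True)]
        res = {e.site_type: e for e in site_enrichment(case, ctrl, sites)}
        assert res["8mer"].fold == float("inf")
        assert np.isfinite(res["8mer"].p_fisher)

    def test_pair_counted_once_despite_duplicate_sites(self):
        case = self._pairs(["g0"])
        ctrl = self._pairs(["h0"])
        sites = [BindingSite("m1", "g0", "8mer", True)] * 5
        res = {e.site_type: e for e in site_enrichment(case, ctrl, sites)}
        assert res["8mer"].k_case == 1

    def test_planted_enrichment_detected(self, default_cohort,
                                         default_design, thresholds):
        from ncaging import simulate_mrna_partner
        partner = simulate_mrna_partner(default_design, default_cohort)
        truth = default_cohort.truth
        gm = sorted(truth.index[truth["label"] == "global"])
        cm = default_cohort.cm
        case = call_targets(cm, partner.cm.normalize(), gm, thresholds)
        ctrl = control_targets(cm, partner.cm, gm, thresholds)
        planted = set(map(tuple, partner.truth[
            partner.truth["kind"] == "inverse"][["mirna", "gene"]].values))
        called = set(map(tuple, case[["mirna", "gene"]].values))
        assert len(planted & called) / len(planted) >= 0.9
        res = {e.site_type: e for e in
               site_enrichment(case, ctrl, partner.sites)}
        assert res["any"].fold > 1 and res["any"].p_fisher < 0.05


class TestOverlaps:
    def test_identical_sets_full_overlap(self):
        regions = target_set_overlaps({"a": {"g1", "g2"}, "b": {"g1", "g2"}})
        assert regions[("a", "b")] == 2
        assert regions[("a",)] == 0 and regions[("b",)] == 0

    def test_disjoint_sets(self):
        regions = target_set_overlaps({"a": {"g1"}, "b": {"g2"}})
        assert regions[("a", "b")] == 0
        assert regions[("a",)] == 1 and regions[("b",)] == 1

    def test_matches_powerset_oracle_on_random_sets(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(30)]
        sets = {m: {g for g in universe if rng.random() < 0.4}
                for m in ["a", "b", "c"]}
        regions = target_set_overlaps(sets)
        # oracle: per-gene exact membership pattern
        from collections import Counter
        oracle = Counter()
        for g in universe:
            members = tuple(sorted(m for m in sets if g in sets[m]))
            if members:
                oracle[members] += 1
        for subset, count in regions.items():
            assert count == oracle.get(subset, 0)

    def test_circulating_intersection_regions(self):
        regions = circulating_intersection({"a", "b"}, {"b", "c"},
                                           {"a", "b", "c", "d"})
        assert regions[("circulating", "global", "local")] == 1   # b
        assert regions[("circulating",)] == 1                     # d
        assert regions[("circulating", "local")] == 1             # a
        assert regions[("circulating", "global")] == 1            # c


class TestCirculatingRule:
    def test_strictly_more_than_ten_percent(self):
        # 10 samples, feature at 1 rpmm in exactly 1 -> 10% is NOT enough
        counts = {f"s{j}": [1_000_000 if j == 0 else 0, 1]
                  for j in range(10)}
        cm = make_cm(counts, ["edge", "anchor"])
        cm.normalized = pd.DataFrame(
            {s: [1.0 if j == 0 else 0.0, 2.0]
             for j, s in enumerate(counts)}, index=["edge", "anchor"])
        out = circulating_features(cm)
        assert "edge" not in out and "anchor" in out
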