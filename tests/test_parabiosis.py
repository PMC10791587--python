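"""Parabiosis REJ/ACC/AGE classification and reversal effect sizes."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ncaging import (SimDesign, Thresholds, assign_group, group_counts,
                     parabiosis_effects, reversal_summary,
                     simulate_aging_cohort, simulate_parabiosis)

from conftest import make_cm

# (fc, p) encodings of the three states of each contrast
STATES = {"up": (2.0, 0.01), "down": (0.5, 0.01), "flat": (1.0, 0.9)}


def truth_table_oracle(rej, acc, age):
    """Independent re-statement of the six-group definitions."""
    d = {k: s != "flat" for k, s in
         zip(("rej", "acc", "age"), (rej, acc, age))}
    if d["rej"] and d["age"] and rej == "up" and age == "down":
        return "REJ_up_AGE_down"
    if d["rej"] and d["age"] and rej == "down" and age == "up":
        return "REJ_down_AGE_up"
    if d["age"] and d["acc"] and age == "up" and acc == "up":
        return "AGE_ACC_up"
    if d["age"] and d["acc"] and age == "down" and acc == "down":
        return "AGE_ACC_down"
    if d["rej"] and not d["age"] and not d["acc"]:
        return "REJ_unique"
    if d["acc"] and not d["age"] and not d["rej"]:
        return "ACC_unique"
    return "none"


class TestGroupAssignment:
    def test_exhaustive_sign_significance_grid(self):
        for rej, acc, age in itertools.product(STATES, STATES, STATES):
            fc_r, p_r = STATES[rej]
            fc_a, p_a = STATES[acc]
            fc_g, p_g = STATES[age]
            assert assign_group(fc_r, p_r, fc_a, p_a, fc_g, p_g) == \
                truth_table_oracle(rej, acc, age), (rej, acc, age)

    def test_nonsignificant_fold_change_not_deregulated(self):
        # large FC but p above cutoff: conjunction rule
        assert assign_group(3.0, 0.2, 1.0, 0.9, 1.0, 0.9) == "none"

    def test_missing_age_p_never_deregulated(self):
        assert assign_group(2.0, 0.01, 1.0, 0.9, 2.0, float("nan")) == \
            "REJ_unique"

    def test_definitional_examples(self):
        assert assign_group(2.0, 0.01, 1.0, 0.9, 0.5, 0.01) == \
            "REJ_up_AGE_down"
        assert assign_group(2.0, 0.01, 1.0, 0.9, 1.0, 0.9) == "REJ_unique"
        assert assign_group(1.0, 0.9, 1.0, 0.9, 1.0, 0.9) == "none"


def _parab_cm(iy, hy, ha, ia, reps=4):
    counts, groups = {}, []
    for g, mean in (("IY", iy), ("HY", hy), ("HA", ha), ("IA", ia)):
        for r in range(reps):
            counts[f"{g}_{r}"] = [mean]
            groups.append(g)
    cm = make_cm(counts, ["f1"], cohort="parabiosis", groups=groups,
                 ages=[3 if g in ("IY", "HY") else 21 for g in groups])
    cm.normalized = cm.counts.astype(float)
    return cm


class TestReversalSummary:
    def test_ha_equals_ia_zero_rejuvenation(self):
        cm = _parab_cm(iy=10, hy=30, ha=50, ia=50)
        rs = reversal_summary(cm, "f1", "liver")
        assert rs.effect_rej == pytest.approx(0.0)

    def test_no_effects_ratio_undefined(self):
        cm = _parab_cm(iy=10, hy=10, ha=50, ia=50)
        rs = reversal_summary(cm, "f1", "liver")
        assert rs.effect_rej == 0 and np.isnan(rs.rej_to_acc_ratio)

    def test_noiseless_reversal_ratio_is_four(self):
        """Planted reversal 0.8 vs. acceleration 0.2 gives an exact 4:1
        rejuvenation-to-acceleration effect ratio."""
        design = SimDesign(seed=3, noise="none",
                           parabiosis_reversal_frac=0.8,
                           parabiosis_accel_frac=0.2)
        cohort = simulate_aging_cohort(design)
        parab = simulate_parabiosis(design, cohort)
        rev = parab.truth.index[parab.truth["reversible"]]
        rs = reversal_summary(parab.cm, rev[0], design.tissues[0])
        assert rs.rej_to_acc_ratio == pytest.approx(4.0, rel=1e-9)

    def test_zero_variance_feature_is_error(self):
        cm = _parab_cm(iy=5, hy=5, ha=5, ia=5)
        with pytest.raises(ValueError, match="zero variance"):
            reversal_summary(cm, "f1", "liver")


class TestSimulatedReversal:
    def test_reversal_frac_zero_rej_fold_near_one(self):
        design = SimDesign(seed=2, parabiosis_reversal_frac=0.0,
                           parabiosis_accel_frac=0.0)
        cohort = simulate_aging_cohort(design)
        parab = simulate_parabiosis(design, cohort)
        cm = parab.cm.normalize()
        recs = parabiosis_effects(cm, cohort.cm.normalize(),
                                  design.tissues[0])
        rev = recs[recs["feature_id"].isin(
            parab.truth.index[parab.truth["reversible"]])]
        assert np.nanmedian(np.abs(np.log2(rev["fc_rej"]))) < 0.15

    def test_full_reversal_noiseless_ha_equals_iy(self):
        design = SimDesign(seed=2, noise="none",
                           parabiosis_reversal_frac=1.0)
        cohort = simulate_aging_cohort(design)
        parab = simulate_parabiosis(design, cohort)
        cm = parab.cm
        groups = cm.samples["group"]
        rev = parab.truth.index[parab.truth["reversible"]]
        ha = cm.rpmm.loc[rev, groups[groups == "HA"].index].mean(axis=1)
        iy = cm.rpmm.loc[rev, groups[groups == "IY"].index].mean(axis=1)
        assert np.allclose(ha, iy)

    def test_planted_reversal_sensitivity_and_specificity(self, thresholds):
        design = SimDesign(seed=1)
        cohort = simulate_aging_cohort(design)
        parab = simulate_parabiosis(design, cohort)
        pcm = parab.cm.normalize()
        acm = cohort.cm.normalize()
        recs = pd.concat([parabiosis_effects(pcm, acm, t, thresholds)
                          for t in design.tissues], ignore_index=True)
        rev = set(parab.truth.index[parab.truth["reversible"]])
        rev_mask = recs["feature_id"].isin(rev)
        rev_groups = {"REJ_up_AGE_down", "REJ_down_AGE_up"}
        sens = recs[rev_mask]["group"].isin(rev_groups).mean()
        assert sens >= 0.9
        truth = cohort.truth
        aged_nonrev = set(truth.index[truth["label"] == "local"])
        nr = recs[recs["feature_id"].isin(aged_nonrev)]
        spec = (~nr["group"].isin(rev_groups)).mean()
        assert spec >= 0.95

    def test_missing_group_is_error(self):
        cm = _parab_cm(iy=10, hy=10, ha=10, ia=10)
        cm2 = cm.subset_samples([s for s in cm.sample_ids
                                 if not s.startswith("HA")])
        aging_cm = make_cm({"y": [10], "o": [20]}, ["f1"],
                           ages=[3, 21]).normalize()
        with pytest.raises(ValueError, match="HA"):
            parabiosis_effects(cm2, aging_cm, "liver")


class TestGroupCounts:
    def _records(self, n, group="REJ_unique"):
        return pd.DataFrame({"feature_id": [f"f{i}" for i in range(n)],
                             "tissue": "liver", "group": group})

    def test_empty_records_zero_table(self):
        assert group_counts(pd.DataFrame(
            columns=["feature_id", "tissue", "group"])).empty

    def test_cap_at_100(self):
        table = group_counts(self._records(120), cap=100)
        assert table.loc["liver", "REJ_unique"] == 100

    def test_uncapped_counts_equal_truth(self):
        table = group_counts(self._records(17))
        assert table.loc["liver", "REJ_unique"] == 17
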