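"""Rejuvenation and accelerated-aging effects from heterochronic parabiosis.

Four groups share the cohort: isochronic young (IY) and aged (IA) controls,
and heterochronic young (HY) and aged (HA) animals.  Three fold-change
contrasts quantify the intervention per feature and tissue:

* REJ  = mean(HA) / mean(IA) — rejuvenation (aged animal with young blood),
* ACC  = mean(HY) / mean(IY) — accelerated aging (young with aged blood),
* AGE  = mean(21 m) / mean(3 m) from the healthy-aging cohort.

A contrast is deregulated when its fold change leaves the (2/3, 3/2)
window AND its Welch t-test p is below the cutoff.  Features are assigned
to six mutually exclusive groups: reversal groups (REJ and AGE deregulated
in opposite directions), co-aging groups (AGE and ACC deregulated in the
same direction), and uniquely deregulated REJ or ACC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import welch_t_rows
from .config import Thresholds
from .io import CountMatrix

GROUPS = ("REJ_unique", "ACC_unique", "REJ_up_AGE_down", "REJ_down_AGE_up",
          "AGE_ACC_up", "AGE_ACC_down", "none")


@dataclass(frozen=True)
class ReversalSummary:
    feature_id: str
    tissue: str
    z_means: dict                 # group -> mean z-score
    effect_rej: float             # |z(IA) - z(HA)|
    effect_acc: float             # |z(HY) - z(IY)|
    rej_to_acc_ratio: float       # nan when effect_acc == 0


def assign_group(fc_rej: float, p_rej: float, fc_acc: float, p_acc: float,
                 fc_age: float, p_age: float,
                 th: Thresholds = Thresholds()) -> str:
    """Six-way classification from the three (fold change, p) pairs.

    Deregulation requires the fold change strictly outside [2/3, 3/2] and
    p < dereg_p_cut; a missing p (NaN) never counts as deregulated.
    Reversal groups (REJ vs. AGE in opposite directions) take precedence,
    then same-direction AGE+ACC groups, then unique deregulation.
    """
    def dereg(fc, p):
        return (fc < th.fc_low or fc > th.fc_high) and \
            (p is not None and not np.isnan(p) and p < th.dereg_p_cut)

    d_rej, d_acc, d_age = dereg(fc_rej, p_rej), dereg(fc_acc, p_acc), \
        dereg(fc_age, p_age)
    if d_rej and d_age and fc_rej > th.fc_high and fc_age < th.fc_low:
        return "REJ_up_AGE_down"
    if d_rej and d_age and fc_rej < th.fc_low and fc_age > th.fc_high:
        return "REJ_down_AGE_up"
    if d_age and d_acc and fc_age > th.fc_high and fc_acc > th.fc_high:
        return "AGE_ACC_up"
    if d_age and d_acc and fc_age < th.fc_low and fc_acc < th.fc_low:
        return "AGE_ACC_down"
    if d_rej and not d_age and not d_acc:
        return "REJ_unique"
    if d_acc and not d_age and not d_rej:
        return "ACC_unique"
    return "none"


def _group_cols(cm: CountMatrix, group: str) -> np.ndarray:
    cols = np.flatnonzero(cm.samples["group"].to_numpy() == group)
    if len(cols) == 0:
        raise ValueError(f"parabiosis group {group!r} missing")
    return cols


def parabiosis_effects(parab_cm: CountMatrix, aging_cm: CountMatrix,
                       tissue: str, th: Thresholds = Thresholds(),
                       young_age: float = 3.0, old_age: float = 21.0
                       ) -> pd.DataFrame:
    """Per-feature REJ/ACC/AGE fold changes, significance and group label
    for one tissue.

    All four parabiosis groups must be present in the tissue, and the aging
    cohort must contain the young/old baseline timepoints.  Features absent
    from the aging cohort keep dereg_age = False (AGE fold change NaN).
    """
    sub = parab_cm.tissue(tissue)
    rpmm = sub.rpmm
    x = rpmm.to_numpy(dtype=float)
    cols = {g: _group_cols(sub, g) for g in ("IY", "HY", "HA", "IA")}
    means = {g: x[:, cols[g]].mean(axis=1) for g in cols}

    with np.errstate(divide="ignore", invalid="ignore"):
        fc_rej = means["HA"] / means["IA"]
        fc_acc = means["HY"] / means["IY"]
    p_rej = welch_t_rows(x[:, cols["HA"]], x[:, cols["IA"]])
    p_acc = welch_t_rows(x[:, cols["HY"]], x[:, cols["IY"]])

    ag = aging_cm.tissue(tissue) if \
        (aging_cm.samples["tissue"] == tissue).any() else None
    fc_age = np.full(len(rpmm), np.nan)
    p_age = np.full(len(rpmm), np.nan)
    if ag is not None:
        ages = ag.samples["age_months"].to_numpy(dtype=float)
        young_cols = np.flatnonzero(ages == young_age)
        old_cols = np.flatnonzero(ages == old_age)
        if len(young_cols) == 0 or len(old_cols) == 0:
            raise ValueError(
                f"aging cohort lacks {young_age} m or {old_age} m samples "
                f"in {tissue!r}")
        shared = [f for f in rpmm.index if f in set(ag.rpmm.index)]
        ay = ag.rpmm.loc[shared].to_numpy(dtype=float)
        young_mean = ay[:, young_cols].mean(axis=1)
        old_mean = ay[:, old_cols].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc_shared = old_mean / young_mean
        p_shared = welch_t_rows(ay[:, old_cols], ay[:, young_cols])
        pos = {f: i for i, f in enumerate(rpmm.index)}
        for f, fcv, pv in zip(shared, fc_shared, p_shared):
            fc_age[pos[f]] = fcv
            p_age[pos[f]] = pv

    rows = []
    for i, fid in enumerate(rpmm.index):
        def _d(fc, p):
            return bool((fc < th.fc_low or fc > th.fc_high) and
                        not np.isnan(p) and p < th.dereg_p_cut) \
                if not np.isnan(fc) else False
        rows.append({
            "feature_id": fid, "tissue": tissue,
            "fc_rej": fc_rej[i], "fc_acc": fc_acc[i], "fc_age": fc_age[i],
            "p_rej": p_rej[i], "p_acc": p_acc[i], "p_age": p_age[i],
            "dereg_rej": _d(fc_rej[i], p_rej[i]),
            "dereg_acc": _d(fc_acc[i], p_acc[i]),
            "dereg_age": _d(fc_age[i], p_age[i]),
            "group": assign_group(fc_rej[i], p_rej[i], fc_acc[i], p_acc[i],
                                  np.nan_to_num(fc_age[i], nan=1.0),
                                  p_age[i], th)})
    return pd.DataFrame(rows)


def reversal_summary(parab_cm: CountMatrix, feature_id: str, tissue: str
                     ) -> ReversalSummary:
    """Group-mean z-scores and REJ/ACC effect sizes for one feature.

    z-scores are computed across all parabiosis samples of the tissue
    (ddof=1); a zero-variance feature is an error.  The ratio is NaN when
    the ACC effect is zero.
    """
    sub = parab_cm.tissue(tissue)
    vals = sub.rpmm.loc[feature_id].to_numpy(dtype=float)
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError(f"{feature_id}: zero variance in {tissue!r}")
    z = (vals - vals.mean()) / sd
    groups = sub.samples["group"].to_numpy()
    z_means = {g: float(z[groups == g].mean()) for g in ("IY", "HY", "HA",
                                                         "IA")}
    effect_rej = abs(z_means["IA"] - z_means["HA"])
    effect_acc = abs(z_means["HY"] - z_means["IY"])
    ratio = effect_rej / effect_acc if effect_acc > 0 else float("nan")
    return ReversalSummary(feature_id=feature_id, tissue=tissue,
                           z_means=z_means, effect_rej=effect_rej,
                           effect_acc=effect_acc, rej_to_acc_ratio=ratio)


def group_counts(records: pd.DataFrame, cap: int | None = None
                 ) -> pd.DataFrame:
    """Tissue x group counts of classified features (optionally capped)."""
    if records.empty:
        return pd.DataFrame(columns=[g for g in GROUPS if g != "none"])
    sub = records[records["group"] != "none"]
    table = sub.pivot_table(index="tissue", columns="group",
                            values="feature_id", aggfunc="count",
                            fill_value=0).astype(int)
    table = table.reindex(columns=[g for g in GROUPS if g != "none"],
                          fill_value=0)
    table = table.reindex(index=sorted(records["tissue"].unique()),
                          fill_value=0)
    if cap is not None:
        table = table.clip(upper=cap)
    return table
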