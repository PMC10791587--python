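"""Aging-correlation classification and fold-change deregulation analysis.

Two complementary views of expression change over the lifespan:

* *Linear*: Spearman rank correlation of each feature's rpmm with age, per
  tissue.  Features exceeding ``|rho| > 0.5`` with the same sign in more
  than five tissues are *global* aging features; features exceeding the
  cutoff in at least one tissue but not qualifying as global are *local*.

* *Nonlinear*: fold changes of every later timepoint against the 3-month
  baseline, flagged as deregulated outside the (2/3, 3/2) window, with
  Welch t-tests (groups of >= 3 samples) corrected by Benjamini-Hochberg
  within each (tissue, timepoint) stratum.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._stats import (spearman, spearman_p_from_rho, spearman_rho_matrix,
                     welch_t_rows)
from .config import Thresholds
from .io import CountMatrix

spearman_age = spearman
"""(expr, ages) -> (rho, p): Spearman correlation of expression with age."""


def spearman_age_matrix(cm: CountMatrix, tissue: str
                        ) -> tuple[pd.Series, pd.Series]:
    """Per-feature Spearman rho and p against age within one tissue."""
    sub = cm.tissue(tissue)
    ages = sub.samples["age_months"].to_numpy(dtype=float)
    x = sub.rpmm.to_numpy(dtype=float)
    rho = spearman_rho_matrix(x, ages[None, :])[:, 0]
    p = spearman_p_from_rho(rho, len(ages))
    idx = sub.rpmm.index
    return pd.Series(rho, index=idx, name="rho"), pd.Series(p, index=idx,
                                                            name="p")


def aging_correlations(cm: CountMatrix, tissues: Sequence[str] | None = None
                       ) -> pd.DataFrame:
    """Feature x tissue Spearman rho table (NaN where undefined)."""
    tissues = list(tissues) if tissues is not None else \
        sorted(cm.samples["tissue"].unique())
    cols = {}
    for t in tissues:
        rho, _ = spearman_age_matrix(cm, t)
        cols[t] = rho
    return pd.DataFrame(cols).reindex(cm.feature_ids)


def classify_aging(rho: pd.DataFrame, th: Thresholds = Thresholds()
                   ) -> pd.DataFrame:
    """Label features as global/local/non-aging from a feature x tissue
    rho table.

    A feature is ``global_pos`` (``global_neg``) when rho > rho_cut
    (rho < -rho_cut) in strictly more than ``n_tissues_global`` tissues —
    same sign required.  A feature exceeding the cutoff in at least one
    tissue without being global is ``local``; ``local_tissue`` names the
    tissue of largest |rho| among those exceeding, with every qualifying
    tissue kept in ``local_tissues``.
    """
    vals = rho.to_numpy(dtype=float)
    pos = np.nan_to_num(vals) > th.rho_cut
    neg = np.nan_to_num(vals) < -th.rho_cut
    n_pos = pos.sum(axis=1)
    n_neg = neg.sum(axis=1)

    labels = []
    local_tissue = []
    local_tissues = []
    tissues = np.array(rho.columns)
    for i in range(len(rho)):
        if n_pos[i] > th.n_tissues_global:
            labels.append("global_pos")
        elif n_neg[i] > th.n_tissues_global:
            labels.append("global_neg")
        elif n_pos[i] + n_neg[i] >= 1:
            labels.append("local")
        else:
            labels.append("none")
        exceed = pos[i] | neg[i]
        if labels[-1] == "local":
            hits = tissues[exceed]
            best = hits[np.argmax(np.abs(vals[i, exceed]))]
            local_tissue.append(best)
            local_tissues.append(",".join(hits))
        else:
            local_tissue.append(None)
            local_tissues.append(",".join(tissues[exceed]))
    return pd.DataFrame({
        "n_pos_tissues": n_pos, "n_neg_tissues": n_neg, "label": labels,
        "local_tissue": local_tissue, "local_tissues": local_tissues},
        index=rho.index)


def ttest_bh(cm: CountMatrix, tissue: str, timepoint: float,
             th: Thresholds = Thresholds(), baseline: float = 3.0
             ) -> pd.DataFrame:
    """Welch t-test of ``timepoint`` vs. the baseline per feature, with BH
    correction within this single (tissue, timepoint) stratum.

    p values are reported only when both groups have at least
    ``min_n_ttest`` samples; otherwise both columns are NaN.
    """
    sub = cm.tissue(tissue)
    ages = sub.samples["age_months"].to_numpy(dtype=float)
    a_cols = np.flatnonzero(ages == timepoint)
    b_cols = np.flatnonzero(ages == baseline)
    idx = sub.rpmm.index
    if len(a_cols) < th.min_n_ttest or len(b_cols) < th.min_n_ttest:
        nan = pd.Series(np.nan, index=idx)
        return pd.DataFrame({"p": nan, "p_adj": nan})
    x = sub.rpmm.to_numpy(dtype=float)
    p = welch_t_rows(x[:, a_cols], x[:, b_cols])
    ok = ~np.isnan(p)
    p_adj = np.full_like(p, np.nan)
    if ok.any():
        p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame({"p": p, "p_adj": p_adj}, index=idx)


def foldchange_table(cm: CountMatrix, tissue: str, baseline: float = 3.0,
                     th: Thresholds = Thresholds(),
                     timepoints: Sequence[float] | None = None
                     ) -> pd.DataFrame:
    """Fold changes of each later timepoint against the baseline, per feature.

    Features with zero mean at the baseline are excluded.  ``deregulated``
    reflects the fold-change rule alone (strict: fc < 2/3 or fc > 3/2);
    ``significant`` additionally requires ``p_adj < dereg_p_cut`` where a
    test was possible.  ``log2fc`` is NaN when fc = 0 (such records are
    dropped from volcano-style output by the caller).
    """
    sub = cm.tissue(tissue)
    ages = sub.samples["age_months"].to_numpy(dtype=float)
    later = sorted({a for a in ages if a > baseline}) if timepoints is None \
        else list(timepoints)
    if baseline not in ages:
        raise ValueError(f"no {baseline}-month baseline group in {tissue!r}")
    rpmm = sub.rpmm
    base_mean = rpmm.iloc[:, np.flatnonzero(ages == baseline)].mean(axis=1)
    keep = base_mean > 0

    rows = []
    for tp in later:
        tp_mean = rpmm.iloc[:, np.flatnonzero(ages == tp)].mean(axis=1)
        fc = (tp_mean[keep] / base_mean[keep]).astype(float)
        with np.errstate(divide="ignore"):
            log2fc = np.where(fc > 0, np.log2(np.where(fc > 0, fc, 1.0)),
                              np.nan)
        stats_df = ttest_bh(cm, tissue, tp, th, baseline).loc[fc.index]
        dereg = (fc < th.fc_low) | (fc > th.fc_high)
        signif = dereg & (stats_df["p_adj"] < th.dereg_p_cut)
        rows.append(pd.DataFrame({
            "feature_id": fc.index, "tissue": tissue, "timepoint": tp,
            "fc": fc.to_numpy(), "log2fc": log2fc,
            "p": stats_df["p"].to_numpy(),
            "p_adj": stats_df["p_adj"].to_numpy(),
            "deregulated": dereg.to_numpy(),
            "significant": signif.fillna(False).to_numpy()}))
    if not rows:
        return pd.DataFrame(columns=["feature_id", "tissue", "timepoint",
                                     "fc", "log2fc", "p", "p_adj",
                                     "deregulated", "significant"])
    return pd.concat(rows, ignore_index=True)


def deregulated_counts(records: pd.DataFrame, cap: int | None = None,
                       flag: str = "deregulated") -> pd.DataFrame:
    """Tissue x timepoint counts of deregulated features.

    ``cap`` truncates large counts for display (e.g. cap=100 sets every
    value above 100 to 100).
    """
    if records.empty:
        return pd.DataFrame()
    sub = records[records[flag].astype(bool)]
    table = sub.pivot_table(index="tissue", columns="timepoint",
                            values="feature_id", aggfunc="count",
                            fill_value=0).astype(int)
    all_tissues = records["tissue"].unique()
    all_tps = sorted(records["timepoint"].unique())
    table = table.reindex(index=sorted(all_tissues), columns=all_tps,
                          fill_value=0)
    if cap is not None:
        table = table.clip(upper=cap)
    return table
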