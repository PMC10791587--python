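"""Sample QC, abundance filtering and RNA-class composition summaries.

The filtering funnel mirrors a typical multi-tissue small-RNA study: drop
shallow samples, restrict piRNAs to prepachytene-cluster members (somatic
piRNA annotation is noisy), keep features reaching 1 rpmm in at least one
sample anywhere (global analyses) or in at least 10% of one tissue's
samples (local analyses).  rpmm values are computed before any feature
filtering and are never recomputed, so the filters commute and are
idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import Thresholds
from .io import CountMatrix, FeatureAnnotation


@dataclass(frozen=True)
class ClassComposition:
    """Per-tissue RNA-class composition summary."""

    tissue: str
    shares: pd.DataFrame          # timepoint x rna_class, percentages
    mean_variance: float          # mean over classes of temporal variance
    stability: str                # "stable" | "variable"


def qc_exclude_samples(cm: CountMatrix, th: Thresholds = Thresholds()
                       ) -> CountMatrix:
    """Drop samples with fewer than ``min_reads_sample`` aligned reads.

    The comparison is strict ("fewer than"), so a sample at exactly the
    threshold is retained.  Removing every sample is an error.
    """
    keep = cm.samples.index[
        cm.samples["total_aligned_reads"] >= th.min_reads_sample]
    if len(keep) == 0:
        raise ValueError("empty cohort: all samples fail the read-depth QC")
    return cm.subset_samples(list(keep))


def filter_pirna_prepachytene(cm: CountMatrix,
                              annotation: Mapping[str, FeatureAnnotation]
                              ) -> CountMatrix:
    """Keep only piRNAs annotated in prepachytene genomic clusters.

    Features of other RNA classes pass through untouched; piRNAs with a
    false or missing cluster flag are removed.
    """
    keep = []
    for fid in cm.feature_ids:
        ann = annotation.get(fid)
        if ann is not None and ann.rna_class == "piRNA":
            if ann.prepachytene_cluster is True:
                keep.append(fid)
        else:
            keep.append(fid)
    return cm.subset_features(keep)


def filter_abundant_global(cm: CountMatrix, th: Thresholds = Thresholds()
                           ) -> CountMatrix:
    """Keep features with >= ``rpmm_min`` rpmm in at least one sample."""
    rpmm = cm.rpmm
    keep = rpmm.index[(rpmm >= th.rpmm_min).any(axis=1)] if cm.n_samples \
        else rpmm.index[:0]
    return cm.subset_features(list(keep))


def filter_abundant_local(cm: CountMatrix, tissue: str,
                          th: Thresholds = Thresholds()) -> CountMatrix:
    """Keep features reaching ``rpmm_min`` in >= ``local_frac`` of one
    tissue's samples (exact fraction k/n >= local_frac, no rounding).

    Returns the matrix restricted to that tissue's samples and surviving
    features.
    """
    sub = cm.tissue(tissue)
    rpmm = sub.rpmm
    frac = (rpmm >= th.rpmm_min).sum(axis=1) / sub.n_samples
    keep = rpmm.index[frac >= th.local_frac]
    return sub.subset_features(list(keep))


def class_composition(cm: CountMatrix,
                      annotation: Mapping[str, FeatureAnnotation],
                      th: Thresholds = Thresholds()
                      ) -> tuple[pd.DataFrame, list[ClassComposition]]:
    """RNA-class count shares per (tissue, timepoint) and temporal stability.

    Per sample, share(class) = 100 * class counts / total counts; samples
    with zero total are excluded with a warning.  Per (tissue, timepoint)
    the shares are averaged over samples; per tissue, the temporal variance
    (sample variance, ddof=1, across timepoint means) is averaged over
    classes and compared against ``variance_cut`` (equality counts as
    stable).

    Returns a tidy table (tissue, timepoint, rna_class, share) plus one
    :class:`ClassComposition` per tissue.  Intended to run on the locally
    filtered matrix of each tissue concatenated back together, or per tissue.
    """
    classes = {fid: annotation[fid].rna_class for fid in cm.feature_ids
               if fid in annotation}
    unknown = [f for f in cm.feature_ids if f not in classes]
    if unknown:
        raise ValueError(f"features without annotation: {unknown[:5]}")
    class_series = pd.Series(classes).loc[cm.feature_ids]

    totals = cm.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        warnings.warn(f"excluding {len(zero)} sample(s) with zero total counts")
    use = [s for s in cm.sample_ids if s not in set(zero)]

    by_class = cm.counts[use].groupby(class_series, sort=True).sum()
    shares = by_class.div(by_class.sum(axis=0), axis=1) * 100.0  # class x sample

    meta = cm.samples.loc[use]
    tidy_rows = []
    summaries = []
    for tissue, tissue_meta in meta.groupby("tissue", sort=True):
        cols = list(tissue_meta.index)
        tp_means = shares[cols].T.groupby(
            tissue_meta["age_months"]).mean()          # timepoint x class
        for tp, row in tp_means.iterrows():
            for cls, share in row.items():
                tidy_rows.append({"tissue": tissue, "timepoint": tp,
                                  "rna_class": cls, "share": share})
        var = tp_means.var(axis=0, ddof=1)             # per class over time
        mean_var = float(var.mean())
        stability = "stable" if mean_var <= th.variance_cut else "variable"
        summaries.append(ClassComposition(
            tissue=tissue, shares=tp_means, mean_variance=mean_var,
            stability=stability))
    return pd.DataFrame(tidy_rows), summaries
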