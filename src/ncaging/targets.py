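"""miRNA-mRNA target calling by inverse expression correlation.

Targets are genes whose expression is significantly anti-correlated with a
miRNA (Spearman rho < -0.4, p < 0.05) in at least two tissues.  Pairs found
by *positive* correlation at the mirrored threshold serve as a control set:
if the anti-correlated pairs are real targets they should carry conserved
seed-match binding sites (8mer, 7mer-m8, 7mer-1a) more often than the
control, tested per site type with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import spearman_p_from_rho, spearman_rho_matrix
from .config import Thresholds
from .io import BindingSite, CountMatrix, SITE_TYPES


@dataclass(frozen=True)
class EnrichmentResult:
    """Conserved binding-site enrichment of case vs. control pairs."""

    site_type: str            # one of SITE_TYPES or "any"
    k_case: int
    n_case: int
    k_ctrl: int
    n_ctrl: int
    frac_case: float          # percent
    frac_ctrl: float          # percent
    fold: float               # frac_case / frac_ctrl (inf when k_ctrl = 0)
    odds_ratio: float
    p_fisher: float           # two-sided Fisher exact


def enrichment_fold(frac_case: float, frac_ctrl: float) -> float:
    """Fold enrichment from two fractions (same units); inf when ctrl = 0."""
    if frac_ctrl == 0:
        return float("inf")
    return frac_case / frac_ctrl


def _correlate_tissues(mirna_cm: CountMatrix, mrna_cm: CountMatrix,
                       mirnas: Sequence[str]
                       ) -> dict[str, tuple[np.ndarray, np.ndarray, int]]:
    """Per tissue: (rho, p) matrices of shape (mirnas x genes)."""
    shared = [s for s in mirna_cm.sample_ids if s in set(mrna_cm.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between miRNA and mRNA matrices")
    mi = mirna_cm.subset_samples(shared)
    mr = mrna_cm.subset_samples(shared)
    out = {}
    for tissue in sorted(mi.samples["tissue"].unique()):
        mi_t = mi.tissue(tissue)
        mr_t = mr.tissue(tissue)
        n = mi_t.n_samples
        if n < 3:
            continue
        x = mi_t.rpmm.loc[list(mirnas)].to_numpy(dtype=float)
        y = mr_t.rpmm.to_numpy(dtype=float)
        rho = spearman_rho_matrix(x, y)
        p = spearman_p_from_rho(rho, n)
        out[tissue] = (rho, p, n)
    return out


def _call(mirna_cm: CountMatrix, mrna_cm: CountMatrix,
          mirnas: Sequence[str], th: Thresholds, min_tissues: int,
          direction: str) -> pd.DataFrame:
    per_tissue = _correlate_tissues(mirna_cm, mrna_cm, mirnas)
    genes = mrna_cm.feature_ids
    support = np.zeros((len(mirnas), len(genes)), dtype=int)
    rho_sum = np.zeros_like(support, dtype=float)
    tissue_hits: dict[tuple[int, int], list[str]] = {}
    for tissue, (rho, p, _n) in per_tissue.items():
        if direction == "inverse":
            hit = (rho < -th.target_rho_cut) & (p < th.target_p_cut)
        else:
            hit = (rho > th.target_rho_cut) & (p < th.target_p_cut)
        hit &= ~np.isnan(rho)
        support += hit
        rho_sum += np.where(hit, np.nan_to_num(rho), 0.0)
        for i, j in zip(*np.nonzero(hit)):
            tissue_hits.setdefault((i, j), []).append(tissue)
    rows = []
    for i, j in zip(*np.nonzero(support >= min_tissues)):
        rows.append({
            "mirna": mirnas[i], "gene": genes[j], "direction": direction,
            "n_support_tissues": int(support[i, j]),
            "mean_rho": rho_sum[i, j] / support[i, j],
            "tissues": ",".join(tissue_hits[(i, j)])})
    cols = ["mirna", "gene", "direction", "n_support_tissues", "mean_rho",
            "tissues"]
    return pd.DataFrame(rows, columns=cols)


def call_targets(mirna_cm: CountMatrix, mrna_cm: CountMatrix,
                 mirnas: Sequence[str], th: Thresholds = Thresholds(),
                 min_tissues: int = 2) -> pd.DataFrame:
    """Inverse-correlation target pairs (rho < -0.4, p < 0.05 in >=
    ``min_tissues`` tissues), one row per (mirna, gene)."""
    return _call(mirna_cm, mrna_cm, list(mirnas), th, min_tissues, "inverse")


def control_targets(mirna_cm: CountMatrix, mrna_cm: CountMatrix,
                    mirnas: Sequence[str], th: Thresholds = Thresholds(),
                    min_tissues: int = 2) -> pd.DataFrame:
    """Positive-correlation control pairs at the mirrored threshold."""
    return _call(mirna_cm, mrna_cm, list(mirnas), th, min_tissues, "positive")


def _pairs_with_site(pairs: pd.DataFrame, site_index: set[tuple[str, str]]
                     ) -> int:
    uniq = {(m, g) for m, g in zip(pairs["mirna"], pairs["gene"])}
    return sum((m, g) in site_index for m, g in uniq)


def site_enrichment(case: pd.DataFrame, ctrl: pd.DataFrame,
                    sites: Iterable[BindingSite]
                    ) -> list[EnrichmentResult]:
    """Conserved-site enrichment of case vs. control pairs, per site type
    and pooled ("any").

    The unit is the unique (mirna, gene) pair: a pair counts once however
    many tissues support it and however many sites of a type it carries.
    """
    sites = list(sites)
    results = []
    for site_type in list(SITE_TYPES) + ["any"]:
        idx = {(s.mirna, s.gene) for s in sites
               if s.conserved and (site_type == "any" or
                                   s.site_type == site_type)}
        n_case = case[["mirna", "gene"]].drop_duplicates().shape[0]
        n_ctrl = ctrl[["mirna", "gene"]].drop_duplicates().shape[0]
        k_case = _pairs_with_site(case, idx)
        k_ctrl = _pairs_with_site(ctrl, idx)
        frac_case = 100.0 * k_case / n_case if n_case else 0.0
        frac_ctrl = 100.0 * k_ctrl / n_ctrl if n_ctrl else 0.0
        table = [[k_case, n_case - k_case], [k_ctrl, n_ctrl - k_ctrl]]
        if n_case and n_ctrl:
            odds, p = stats.fisher_exact(table, alternative="two-sided")
        else:
            odds, p = float("nan"), float("nan")
        results.append(EnrichmentResult(
            site_type=site_type, k_case=k_case, n_case=n_case,
            k_ctrl=k_ctrl, n_ctrl=n_ctrl, frac_case=frac_case,
            frac_ctrl=frac_ctrl, fold=enrichment_fold(frac_case, frac_ctrl),
            odds_ratio=float(odds), p_fisher=float(p)))
    return results


def target_set_overlaps(pairs_by_mirna: Mapping[str, set[str]]
                        ) -> dict[tuple[str, ...], int]:
    """Venn-region counts over the miRNA target sets.

    For every non-empty subset S of miRNAs, the returned count is the number
    of genes targeted by exactly the miRNAs in S (a disjoint partition, as
    drawn in a Venn diagram).
    """
    mirnas = sorted(pairs_by_mirna)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(mirnas) + 1):
        for subset in combinations(mirnas, r):
            inside = set.intersection(*(pairs_by_mirna[m] for m in subset))
            outside = set().union(*(pairs_by_mirna[m] for m in mirnas
                                    if m not in subset)) if len(subset) < \
                len(mirnas) else set()
            regions[subset] = len(inside - outside)
    return regions


def circulating_intersection(local_set: set[str], global_set: set[str],
                             circulating_set: set[str]
                             ) -> dict[tuple[str, ...], int]:
    """Counts of the 7 regions of the local / global / circulating Venn."""
    return target_set_overlaps({"local": set(local_set),
                                "global": set(global_set),
                                "circulating": set(circulating_set)})


def circulating_features(cm: CountMatrix, th: Thresholds = Thresholds()
                         ) -> set[str]:
    """Features detected at >= rpmm_min in strictly more than
    ``local_frac`` of the samples of at least one group.

    Note the strict ">" — this circulating-detection rule is deliberately
    different from the tissue abundance filter's inclusive ">=".
    Groups are the ``group`` column when informative, else the whole cohort.
    """
    rpmm = cm.rpmm
    groups = cm.samples["group"]
    if groups.nunique() <= 1:
        group_cols = {"all": list(cm.sample_ids)}
    else:
        group_cols = {g: list(cm.samples.index[groups == g])
                      for g in groups.unique()}
    out: set[str] = set()
    for cols in group_cols.values():
        frac = (rpmm[cols] >= th.rpmm_min).sum(axis=1) / len(cols)
        out |= set(rpmm.index[frac > th.local_frac])
    return out
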