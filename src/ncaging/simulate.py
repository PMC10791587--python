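"""Synthetic multi-organ aging and parabiosis cohorts with known ground truth.

The generator emulates a bulk small-RNA-seq study across several tissues
and the full mouse lifespan: negative-binomial counts with log-normal
library sizes, planted monotone "global aging" features shared with one
sign across all tissues, tissue-exclusive "local aging" features, a large
contingent of near-zero piRNAs (mimicking noisy somatic piRNA annotation),
planted inverse-correlated mRNA targets whose conserved binding sites are
enriched over random pairs, and a four-group parabiosis cohort (IY/HY/HA/IA)
in which planted reversible features are pulled back toward young levels.

Every generator is deterministic under the design seed, so downstream
stages can be scored against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (BindingSite, CountMatrix, FeatureAnnotation, RNA_CLASSES,
                 SITE_TYPES)

TISSUE_POOL = ("brain", "liver", "kidney", "BAT", "limb_muscle", "skin",
               "lung", "heart", "GAT", "MAT", "spleen", "marrow", "bone",
               "pancreas", "intestine", "SCAT")

_REF_LENGTHS = {"miRNA": 22, "piRNA": 28, "lncRNA": 1000, "snoRNA": 100,
                "snRNA": 150, "tRNA": 75, "rRNA": 1500, "scaRNA": 120}


@dataclass(frozen=True)
class SimDesign:
    """Study-design parameters of the synthetic cohorts.

    Defaults describe a desk-scale cohort: 6 tissues, the ten lifespan
    timepoints (months), 4 replicates per timepoint, planted global aging
    features monotone in every tissue with slope 1.5 log2 units across the
    lifespan.  A 16-tissue paper-scale layout is available by overriding
    ``n_tissues``.
    """

    n_tissues: int = 6
    timepoints: tuple[float, ...] = (1, 3, 6, 9, 12, 15, 18, 21, 24, 27)
    reps_per_tp: int = 4
    n_features_per_class: Mapping[str, int] = field(default_factory=lambda: {
        "miRNA": 300, "piRNA": 150, "lncRNA": 40, "snoRNA": 30, "snRNA": 20,
        "tRNA": 30, "rRNA": 10, "scaRNA": 10})
    n_global_aging: int = 20
    n_local_aging_per_tissue: int = 10
    effect_slope: float = 1.5          # log2 units across the lifespan
    nb_dispersion: float = 0.03
    libsize_lognorm: tuple[float, float] = (15.5, 0.15)   # ~5.4 M reads
    pirna_rare_frac: float = 0.95
    prepachytene_frac: float = 0.2
    # mRNA partner
    n_targets_per_global_mirna: int = 16
    n_null_genes: int = 150
    target_beta: float = 1.0
    conserved_enrichment: float = 5.0
    conserved_base_prob: float = 0.12
    # parabiosis
    parabiosis_reversal_frac: float = 0.8
    parabiosis_accel_frac: float = 0.2
    parabiosis_reps: int = 6
    parabiosis_nb_dispersion: float = 0.01
    noise: str = "nb"                  # "nb" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.parabiosis_reversal_frac <= 1.0:
            raise ValueError("parabiosis_reversal_frac must be in [0, 1]")
        if self.n_tissues < 2:
            raise ValueError("global aging features need >= 2 tissues")
        if self.n_tissues > len(TISSUE_POOL):
            raise ValueError(f"at most {len(TISSUE_POOL)} tissues supported")
        unknown = set(self.n_features_per_class) - set(RNA_CLASSES)
        if unknown:
            raise ValueError(f"unknown RNA classes {sorted(unknown)}")

    @property
    def tissues(self) -> tuple[str, ...]:
        return TISSUE_POOL[:self.n_tissues]


@dataclass
class CohortModel:
    """Deterministic expected-rpmm model shared by all generators."""

    design: SimDesign
    features: pd.DataFrame        # feature_id, rna_class, base_log2, sign...
    annotation: dict[str, FeatureAnnotation]
    offsets: np.ndarray           # features x tissues, log2

    def expected_rpmm(self, tissue_idx: int, age: float) -> np.ndarray:
        d = self.design
        t0, t1 = min(d.timepoints), max(d.timepoints)
        frac = (age - t0) / (t1 - t0)
        slope = self.features["slope_log2"].to_numpy()
        active = self.features["trend_tissues"].apply(
            lambda ts: tissue_idx in ts).to_numpy()
        log2mu = (self.features["base_log2"].to_numpy()
                  + self.offsets[:, tissue_idx]
                  + np.where(active, slope * frac, 0.0))
        return 2.0 ** log2mu


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def build_cohort_model(design: SimDesign) -> CohortModel:
    """Feature set, annotation and expected-expression model (seed-determined)."""
    rng = np.random.default_rng(design.seed)
    rows = []
    for cls in RNA_CLASSES:
        n = design.n_features_per_class.get(cls, 0)
        for i in range(n):
            rows.append({"feature_id": f"{cls}-{i:04d}", "rna_class": cls})
    feats = pd.DataFrame(rows)
    n_feat = len(feats)

    base = rng.uniform(3.0, 9.0, size=n_feat)
    is_pirna = (feats["rna_class"] == "piRNA").to_numpy()
    rare = is_pirna & (rng.random(n_feat) < design.pirna_rare_frac)
    base[rare] = rng.uniform(-7.0, -3.5, size=rare.sum())
    feats["base_log2"] = base
    feats["rare"] = rare

    # plant aging truth among miRNAs
    mirna_idx = np.flatnonzero((feats["rna_class"] == "miRNA").to_numpy())
    n_needed = design.n_global_aging + \
        design.n_local_aging_per_tissue * design.n_tissues
    if n_needed > len(mirna_idx):
        raise ValueError("not enough miRNA features to plant aging truth")
    planted = rng.choice(mirna_idx, size=n_needed, replace=False)
    global_idx = planted[:design.n_global_aging]
    local_idx = planted[design.n_global_aging:]

    labels = np.array(["none"] * n_feat, dtype=object)
    signs = np.zeros(n_feat)
    trend_tissues = [tuple() for _ in range(n_feat)]
    all_tissues = tuple(range(design.n_tissues))
    for j, fi in enumerate(global_idx):
        labels[fi] = "global"
        signs[fi] = 1.0 if j % 2 == 0 else -1.0
        trend_tissues[fi] = all_tissues
    for j, fi in enumerate(local_idx):
        labels[fi] = "local"
        signs[fi] = 1.0 if j % 2 == 0 else -1.0
        trend_tissues[fi] = (j % design.n_tissues,)
    feats["label"] = labels
    feats["sign"] = signs
    feats["trend_tissues"] = trend_tissues
    feats["slope_log2"] = signs * design.effect_slope
    feats["local_tissue"] = [
        design.tissues[ts[0]] if lab == "local" else None
        for lab, ts in zip(labels, trend_tissues)]

    offsets = rng.normal(0.0, 0.5, size=(n_feat, design.n_tissues))
    offsets[rare] = 0.0

    # rescale abundant features so intended rpmm totals ~1e6 and planted
    # rare piRNAs stay below the abundance cutoff in actual rpmm
    total = (2.0 ** feats.loc[~rare, "base_log2"]).sum()
    feats.loc[~rare, "base_log2"] += np.log2(1e6 / total)

    annotation = {}
    for i, row in feats.iterrows():
        length = _REF_LENGTHS[row.rna_class]
        length = int(length * rng.uniform(0.8, 1.2)) if length > 30 else length
        prep = None
        if row.rna_class == "piRNA":
            prep = bool(rng.random() < design.prepachytene_frac)
        seq = _random_rna(rng, length) if row.rna_class in ("miRNA", "piRNA") \
            else None
        annotation[row.feature_id] = FeatureAnnotation(
            feature_id=row.feature_id, rna_class=row.rna_class,
            reference_length=length, mature_sequence=seq,
            prepachytene_cluster=prep, is_first_paralog=True)
    return CohortModel(design=design, features=feats, annotation=annotation,
                       offsets=offsets)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float
               ) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _sample_sheet_row(sid, tissue, age, sex, cohort, group, total):
    return {"sample_id": sid, "tissue": tissue, "age_months": age,
            "sex": sex, "cohort": cohort, "group": group,
            "total_aligned_reads": total}


@dataclass
class AgingCohort:
    cm: CountMatrix
    annotation: dict[str, FeatureAnnotation]
    truth: pd.DataFrame
    model: CohortModel


def simulate_aging_cohort(design: SimDesign = SimDesign()) -> AgingCohort:
    """Generate the aging cohort with planted aging truth.

    Counts are negative binomial around library-size-scaled expected rpmm;
    planted aging features follow monotone log-linear trends (one sign per
    feature across its tissues).  The returned truth table carries the
    planted label, sign and tissues per feature.
    """
    model = build_cohort_model(design)
    rng = np.random.default_rng(design.seed + 1)
    mu_lib, sd_lib = design.libsize_lognorm

    counts_cols = {}
    meta_rows = []
    for ti, tissue in enumerate(design.tissues):
        for age in design.timepoints:
            expected = model.expected_rpmm(ti, age)
            for r in range(design.reps_per_tp):
                libsize = float(np.exp(rng.normal(mu_lib, sd_lib)))
                mean_counts = expected * libsize / 1e6
                if design.noise == "none":
                    col = np.rint(mean_counts).astype(np.int64)
                else:
                    col = _nb_counts(rng, mean_counts, design.nb_dispersion)
                sid = f"{tissue}_t{int(age):02d}_r{r}"
                counts_cols[sid] = col
                meta_rows.append(_sample_sheet_row(
                    sid, tissue, float(age), "M" if r % 2 == 0 else "F",
                    "aging", "none", int(libsize)))
    counts = pd.DataFrame(counts_cols,
                          index=model.features["feature_id"].to_numpy())
    samples = pd.DataFrame(meta_rows)
    cm = CountMatrix(counts=counts, samples=samples)

    truth = model.features[["feature_id", "rna_class", "label", "sign",
                            "local_tissue", "rare"]].copy()
    truth["tissues"] = [
        ",".join(design.tissues[t] for t in ts)
        for ts in model.features["trend_tissues"]]
    if design.noise == "none":
        cm.normalized = pd.DataFrame(
            {sid: model.expected_rpmm(design.tissues.index(row["tissue"]),
                                      row["age_months"])
             for sid, row in samples.set_index("sample_id").iterrows()},
            index=counts.index)
    return AgingCohort(cm=cm, annotation=model.annotation,
                       truth=truth.set_index("feature_id"), model=model)


@dataclass
class MrnaPartner:
    cm: CountMatrix
    sites: list[BindingSite]
    truth: pd.DataFrame           # mirna, gene, kind in {inverse, positive}


def simulate_mrna_partner(design: SimDesign, mirna_cohort: AgingCohort
                          ) -> MrnaPartner:
    """Paired mRNA matrix with planted inverse- and positive-correlated
    genes for each global aging miRNA, plus independent null genes.

    Planted target genes track the realized miRNA expression:
    log2 mean = baseline -/+ target_beta * centered log2 miRNA rpmm, so the
    inverse pairs are recoverable by rank correlation.  Conserved binding
    sites are assigned at ``conserved_base_prob`` for random pairs and at
    ``conserved_enrichment`` times that for true inverse-target pairs.
    """
    rng = np.random.default_rng(design.seed + 2)
    cm = mirna_cohort.cm.normalize()
    truth = mirna_cohort.truth
    global_mirnas = list(truth.index[truth["label"] == "global"])
    samples = cm.samples
    mu_lib, sd_lib = design.libsize_lognorm

    gene_rows = []        # (gene_id, mirna, kind, base_log2)
    g = 0
    for mirna in global_mirnas:
        for _ in range(design.n_targets_per_global_mirna):
            gene_rows.append((f"gene-{g:04d}", mirna, "inverse",
                              rng.uniform(4, 8)))
            g += 1
        for _ in range(design.n_targets_per_global_mirna):
            gene_rows.append((f"gene-{g:04d}", mirna, "positive",
                              rng.uniform(4, 8)))
            g += 1
    for _ in range(design.n_null_genes):
        gene_rows.append((f"gene-{g:04d}", None, "null", rng.uniform(4, 8)))
        g += 1

    log_mi = np.log2(cm.rpmm.loc[global_mirnas].to_numpy(dtype=float) + 0.5)
    # center per tissue so coupling does not shift overall abundance
    tissue_of = samples["tissue"].to_numpy()
    centered = log_mi.copy()
    for tissue in np.unique(tissue_of):
        cols = tissue_of == tissue
        centered[:, cols] -= centered[:, cols].mean(axis=1, keepdims=True)
    mi_pos = {m: i for i, m in enumerate(global_mirnas)}

    n_samp = cm.n_samples
    counts = np.zeros((len(gene_rows), n_samp), dtype=np.int64)
    libsizes = np.exp(rng.normal(mu_lib, sd_lib, size=n_samp))
    for gi, (gid, mirna, kind, base) in enumerate(gene_rows):
        log2mu = np.full(n_samp, base)
        if kind == "inverse":
            log2mu = base - design.target_beta * centered[mi_pos[mirna]]
        elif kind == "positive":
            log2mu = base + design.target_beta * centered[mi_pos[mirna]]
        mean_counts = (2.0 ** log2mu) * libsizes / 1e6
        counts[gi] = _nb_counts(rng, mean_counts, design.nb_dispersion)

    gene_ids = [r[0] for r in gene_rows]
    mrna_cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids,
                            columns=cm.sample_ids),
        samples=samples.copy())

    sites: list[BindingSite] = []
    inverse_pairs = {(m, gid) for gid, m, kind, _ in gene_rows
                     if kind == "inverse"}
    for mirna in global_mirnas:
        for gid in gene_ids:
            p_cons = design.conserved_base_prob
            if (mirna, gid) in inverse_pairs:
                p_cons = min(0.95, p_cons * design.conserved_enrichment)
            if rng.random() < p_cons:
                sites.append(BindingSite(
                    mirna=mirna, gene=gid,
                    site_type=SITE_TYPES[rng.integers(len(SITE_TYPES))],
                    conserved=True))
            if rng.random() < 0.15:     # non-conserved background sites
                sites.append(BindingSite(
                    mirna=mirna, gene=gid,
                    site_type=SITE_TYPES[rng.integers(len(SITE_TYPES))],
                    conserved=False))

    pair_truth = pd.DataFrame(
        [{"mirna": m, "gene": gid, "kind": kind}
         for gid, m, kind, _ in gene_rows if kind != "null"])
    return MrnaPartner(cm=mrna_cm, sites=sites, truth=pair_truth)


@dataclass
class ParabiosisCohort:
    cm: CountMatrix
    truth: pd.DataFrame           # feature_id -> reversible flag


def simulate_parabiosis(design: SimDesign, aging: AgingCohort,
                        young_age: float = 3.0, old_age: float = 21.0
                        ) -> ParabiosisCohort:
    """Four-group parabiosis cohort with planted partial reversal.

    IY/IA group means equal the aging model's young/aged expected rpmm.
    For reversible features (the planted global aging set), the HA mean is
    the IA mean shifted linearly toward IY by ``parabiosis_reversal_frac``
    and the HY mean is shifted toward IA by ``parabiosis_accel_frac``;
    other features keep their isochronic means.  With ``noise="none"`` the
    normalized matrix holds the exact planted rpmm means (counts are their
    rounded library-scaled versions), so effect-size identities hold
    exactly.
    """
    model = aging.model
    rng = np.random.default_rng(design.seed + 3)
    mu_lib, sd_lib = design.libsize_lognorm
    reversible = (model.features["label"] == "global").to_numpy()

    counts_cols = {}
    exact_cols = {}
    meta_rows = []
    for ti, tissue in enumerate(design.tissues):
        m_young = model.expected_rpmm(ti, young_age)
        m_aged = model.expected_rpmm(ti, old_age)
        group_means = {
            "IY": m_young,
            "IA": m_aged,
            "HA": np.where(reversible,
                           m_aged + design.parabiosis_reversal_frac *
                           (m_young - m_aged), m_aged),
            "HY": np.where(reversible,
                           m_young + design.parabiosis_accel_frac *
                           (m_aged - m_young), m_young),
        }
        ages = {"IY": young_age, "HY": young_age,
                "HA": old_age, "IA": old_age}
        for group in ("IY", "HY", "HA", "IA"):
            for r in range(design.parabiosis_reps):
                libsize = float(np.exp(rng.normal(mu_lib, sd_lib))) \
                    if design.noise != "none" else float(np.exp(mu_lib))
                mean_counts = group_means[group] * libsize / 1e6
                if design.noise == "none":
                    col = np.rint(mean_counts).astype(np.int64)
                else:
                    col = _nb_counts(rng, mean_counts,
                                     design.parabiosis_nb_dispersion)
                sid = f"{tissue}_{group}_r{r}"
                counts_cols[sid] = col
                exact_cols[sid] = group_means[group]
                meta_rows.append(_sample_sheet_row(
                    sid, tissue, ages[group], "M", "parabiosis", group,
                    int(libsize)))
    index = model.features["feature_id"].to_numpy()
    cm = CountMatrix(counts=pd.DataFrame(counts_cols, index=index),
                     samples=pd.DataFrame(meta_rows))
    if design.noise == "none":
        cm.normalized = pd.DataFrame(exact_cols, index=index)
    truth = pd.DataFrame({"feature_id": index, "reversible": reversible,
                          "sign": model.features["sign"].to_numpy()}
                         ).set_index("feature_id")
    return ParabiosisCohort(cm=cm, truth=truth)


def simulate_intervals(annotation: Mapping[str, FeatureAnnotation],
                       mean_frag_len: float = 30.0, depth: float = 20.0,
                       full_length_prob: float = 0.6, seed: int = 0
                       ) -> dict[str, list[tuple[int, int]]]:
    """Read-alignment intervals per feature for coverage statistics.

    Per feature the read count is Poisson(``depth``).  For miRNA/piRNA
    (read-length-scale references) each read covers the full reference with
    probability ``full_length_prob``; otherwise (and always for longer
    classes) a fragment of roughly ``mean_frag_len`` nt is placed uniformly.
    ``depth=0`` yields an empty map.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[tuple[int, int]]] = {}
    for fid, ann in annotation.items():
        n_reads = int(rng.poisson(depth))
        if n_reads == 0:
            continue
        length = ann.reference_length
        ivs = []
        for _ in range(n_reads):
            if ann.rna_class in ("miRNA", "piRNA") and \
                    rng.random() < full_length_prob:
                ivs.append((0, length))
                continue
            frag = int(np.clip(rng.normal(mean_frag_len, 8.0), 10, None))
            frag = min(frag, length)
            start = int(rng.integers(0, length - frag + 1))
            ivs.append((start, start + frag))
        out[fid] = ivs
    return out
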