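"""End-to-end orchestration of the aging and parabiosis analyses.

The aging pipeline runs QC -> piRNA prepachytene filter -> global abundance
filter -> per-tissue local filter -> class composition -> Spearman aging
classification -> fold-change deregulation -> trajectory clustering ->
(optional) target inference, writing one tidy TSV per stage plus a JSON
manifest with row counts, the seed and a config hash.  Feature-count deltas
are logged after every filter so the filtering funnel is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aging as aging_mod
from . import clustering, filtering, parabiosis, targets
from .config import Thresholds
from .io import CountMatrix, read_annotation, read_count_matrix
from .simulate import (AgingCohort, SimDesign, simulate_aging_cohort,
                       simulate_mrna_partner, simulate_parabiosis)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and stage toggles for a pipeline run."""

    out_dir: str = "ncaging_out"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    design: SimDesign | None = None       # simulate when no input paths
    counts_path: str | None = None
    sample_sheet_path: str | None = None
    annotation_path: str | None = None
    run_clustering: bool = True
    run_targets: bool = True
    c_range: tuple[int, int] = (2, 8)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "thresholds" in data:
            data["thresholds"] = Thresholds(**data["thresholds"])
        if "design" in data:
            data["design"] = SimDesign(**data["design"])
        if "c_range" in data:
            data["c_range"] = tuple(data["c_range"])
        return cls(**data)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)      # analysis params only
        blob = json.dumps(payload, default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_or_simulate(config: PipelineConfig) -> AgingCohort:
    if config.counts_path:
        if not (config.sample_sheet_path and config.annotation_path):
            raise ValueError("counts_path requires sample_sheet_path and "
                             "annotation_path")
        ann = read_annotation(config.annotation_path)
        cm = read_count_matrix(config.counts_path, config.sample_sheet_path,
                               annotation=ann)
        return AgingCohort(cm=cm, annotation=ann, truth=pd.DataFrame(),
                           model=None)
    design = config.design or SimDesign(seed=config.seed)
    if design.seed != config.seed:
        design = dataclasses.replace(design, seed=config.seed)
    return simulate_aging_cohort(design)


def _write(df: pd.DataFrame, path: Path, manifest: dict, name: str,
           **kwargs) -> None:
    df.to_csv(path, sep="\t", **kwargs)
    manifest["tables"][name] = {"path": str(path), "rows": int(len(df))}


def run_aging_pipeline(config: PipelineConfig) -> dict:
    """Run the aging analysis end to end; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    manifest: dict = {"pipeline": "aging", "seed": config.seed,
                      "config_hash": config.config_hash(), "tables": {},
                      "feature_funnel": {}}

    cohort = _load_or_simulate(config)
    cm = cohort.cm.normalize()
    manifest["feature_funnel"]["input"] = cm.n_features

    cm = filtering.qc_exclude_samples(cm, th)
    cm = filtering.filter_pirna_prepachytene(cm, cohort.annotation)
    manifest["feature_funnel"]["after_prepachytene"] = cm.n_features
    logger.info("prepachytene filter: %d features",
                manifest["feature_funnel"]["after_prepachytene"])
    cm = filtering.filter_abundant_global(cm, th)
    manifest["feature_funnel"]["after_global_filter"] = cm.n_features
    logger.info("global abundance filter: %d features", cm.n_features)

    tissues = sorted(cm.samples["tissue"].unique())
    local = {t: filtering.filter_abundant_local(cm, t, th) for t in tissues}
    manifest["feature_funnel"]["after_local_filter"] = {
        t: local[t].n_features for t in tissues}

    comp_rows = []
    for t in tissues:
        tidy, summaries = filtering.class_composition(local[t],
                                                      cohort.annotation, th)
        comp_rows.append(tidy)
    _write(pd.concat(comp_rows, ignore_index=True),
           out / "class_composition.tsv", manifest, "class_composition",
           index=False)

    # aging classification on the union of locally expressed features
    rho_cols = {}
    for t in tissues:
        rho, _ = aging_mod.spearman_age_matrix(cm.subset_features(
            local[t].feature_ids), t)
        rho_cols[t] = rho
    rho_df = pd.DataFrame(rho_cols)
    calls = aging_mod.classify_aging(rho_df, th)
    _write(calls, out / "aging_calls.tsv", manifest, "aging_calls",
           index_label="feature_id")

    fc_rows = []
    for t in tissues:
        fc_rows.append(aging_mod.foldchange_table(local[t], t, th=th))
    fc = pd.concat(fc_rows, ignore_index=True)
    _write(fc, out / "deregulation.tsv", manifest, "deregulation",
           index=False)
    _write(aging_mod.deregulated_counts(fc),
           out / "deregulated_counts.tsv", manifest, "deregulated_counts")

    if config.run_clustering:
        common = set(local[tissues[0]].feature_ids)
        for t in tissues[1:]:
            common &= set(local[t].feature_ids)
        ts = clustering.zscore_trajectories(cm, sorted(common), tissues)
        c_opt, curve = clustering.select_c(ts, config.c_range,
                                           seed=config.seed)
        fc_clust = clustering.fuzzy_cmeans(ts, c_opt, seed=config.seed)
        assign = pd.DataFrame({
            "feature_id": [k[0] for k in fc_clust.keys],
            "tissue": [k[1] for k in fc_clust.keys],
            "cluster": fc_clust.hard_labels,
            "membership": fc_clust.memberships.max(axis=1)})
        _write(assign, out / "clusters.tsv", manifest, "clusters",
               index=False)
        _write(pd.DataFrame(sorted(curve.items()),
                            columns=["c", "dmin"]),
               out / "dmin_curve.tsv", manifest, "dmin_curve", index=False)
        _write(clustering.tissue_specificity(fc_clust, th),
               out / "cluster_specificity.tsv", manifest,
               "cluster_specificity", index=False)
        manifest["c_opt"] = int(c_opt)

    if config.run_targets and cohort.model is not None:
        partner = simulate_mrna_partner(cohort.model.design, cohort)
        global_mirnas = sorted(calls.index[calls["label"]
                                           .str.startswith("global")])
        if global_mirnas:
            case = targets.call_targets(cm, partner.cm.normalize(),
                                        global_mirnas, th)
            ctrl = targets.control_targets(cm, partner.cm, global_mirnas, th)
            _write(case, out / "target_pairs.tsv", manifest, "target_pairs",
                   index=False)
            enr = targets.site_enrichment(case, ctrl, partner.sites)
            _write(pd.DataFrame([dataclasses.asdict(e) for e in enr]),
                   out / "site_enrichment.tsv", manifest, "site_enrichment",
                   index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_parabiosis_pipeline(config: PipelineConfig) -> dict:
    """Parabiosis analysis: same QC/filters, then REJ/ACC/AGE effects."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    manifest: dict = {"pipeline": "parabiosis", "seed": config.seed,
                      "config_hash": config.config_hash(), "tables": {}}

    design = config.design or SimDesign(seed=config.seed)
    if design.seed != config.seed:
        design = dataclasses.replace(design, seed=config.seed)
    aging_cohort = simulate_aging_cohort(design)
    parab = simulate_parabiosis(design, aging_cohort)

    aging_cm = aging_cohort.cm.normalize()
    parab_cm = parab.cm.normalize()
    parab_cm = filtering.qc_exclude_samples(parab_cm, th)
    parab_cm = filtering.filter_pirna_prepachytene(parab_cm,
                                                   aging_cohort.annotation)
    parab_cm = filtering.filter_abundant_global(parab_cm, th)
    manifest["n_features"] = parab_cm.n_features

    tissues = sorted(parab_cm.samples["tissue"].unique())
    records = pd.concat([parabiosis.parabiosis_effects(parab_cm, aging_cm,
                                                       t, th)
                         for t in tissues], ignore_index=True)
    _write(records, out / "parabiosis_records.tsv", manifest,
           "parabiosis_records", index=False)
    _write(parabiosis.group_counts(records), out / "parabiosis_groups.tsv",
           manifest, "parabiosis_groups")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
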