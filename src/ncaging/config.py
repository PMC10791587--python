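"""Threshold configuration shared by every pipeline stage.

All numeric cutoffs of the analysis live in a single :class:`Thresholds`
object so that a YAML config file maps 1:1 onto the parameters that decide
which features survive filtering, which correlations count as aging, and
which fold changes count as deregulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class Thresholds:
    """Numeric cutoffs of the aging / parabiosis analysis.

    Attributes
    ----------
    rho_cut:
        Absolute Spearman correlation with age above which a feature counts
        as aging in a tissue (strict: ``|rho| > rho_cut``).
    n_tissues_global:
        A feature is *globally* aging when it exceeds ``rho_cut`` with the
        same sign in strictly more than this many tissues.
    target_rho_cut, target_p_cut:
        Inverse-correlation target calling: ``rho < -target_rho_cut`` and
        ``p < target_p_cut`` (both strict).
    fc_low, fc_high:
        Fold-change deregulation window; a fold change strictly below
        ``fc_low`` (2/3) or strictly above ``fc_high`` (3/2) is deregulated.
    dereg_p_cut:
        Significance cutoff paired with the fold-change rule where a p value
        is required (parabiosis contrasts).
    rpmm_min:
        Abundance cutoff in reads per mapped million (inclusive).
    local_frac:
        Per-tissue abundance rule: a feature must reach ``rpmm_min`` in at
        least this fraction of the tissue's samples (inclusive).
    min_reads_sample:
        Samples with fewer aligned reads than this are excluded (strict).
    variance_cut:
        Mean temporal variance (percent^2 scale) splitting tissues into
        stable vs. variable RNA-class composition; equality counts as stable.
    tissue_specific_frac:
        A trajectory cluster is tissue-specific when at least this fraction
        of members comes from one tissue (inclusive).
    c_min, c_max:
        Range of candidate cluster numbers for fuzzy c-means selection.
    min_n_ttest:
        Minimum group size per side for a t test to be reported.
    """

    rho_cut: float = 0.5
    n_tissues_global: int = 5
    target_rho_cut: float = 0.4
    target_p_cut: float = 0.05
    fc_low: float = 2.0 / 3.0
    fc_high: float = 3.0 / 2.0
    dereg_p_cut: float = 0.05
    rpmm_min: float = 1.0
    local_frac: float = 0.10
    min_reads_sample: int = 2_000_000
    variance_cut: float = 4.5
    tissue_specific_frac: float = 0.30
    c_min: int = 2
    c_max: int = 20
    min_n_ttest: int = 3

    def __post_init__(self) -> None:
        if not (self.fc_low < 1.0 < self.fc_high):
            raise ValueError("fc_low < 1 < fc_high required")
        for name in ("rho_cut", "target_rho_cut", "target_p_cut", "dereg_p_cut",
                     "rpmm_min", "local_frac", "variance_cut",
                     "tissue_specific_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.c_min < 2 or self.c_max < self.c_min:
            raise ValueError("need 2 <= c_min <= c_max")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Thresholds":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
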