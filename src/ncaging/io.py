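"""Domain containers and readers/writers for the tabular formats of the pipeline.

Count matrices travel as features x samples integer tables (TSV or
MatrixMarket triplet) accompanied by a sample sheet; feature annotation,
binding-site tables and alignment intervals are plain TSV/BED.  All interval
coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

SAMPLE_COLUMNS = ["sample_id", "tissue", "age_months", "sex", "cohort",
                  "group", "total_aligned_reads"]
RNA_CLASSES = ("miRNA", "piRNA", "lncRNA", "snoRNA", "snRNA", "tRNA",
               "rRNA", "scaRNA")
PARABIOSIS_GROUPS = ("IY", "HY", "HA", "IA")
SITE_TYPES = ("8mer", "7mer-m8", "7mer-1a")
_SITE_ALIASES = {"8mer": "8mer", "7mer-m8": "7mer-m8", "7mer-8m": "7mer-m8",
                 "7mer-1a": "7mer-1a"}


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced sample."""

    sample_id: str
    tissue: str
    age_months: float
    sex: str                 # M / F
    cohort: str              # aging / parabiosis
    group: str = "none"      # IY / HY / HA / IA / none
    total_aligned_reads: int = 0

    def __post_init__(self) -> None:
        if self.age_months <= 0:
            raise ValueError(f"{self.sample_id}: age_months must be > 0")
        if self.sex not in ("M", "F"):
            raise ValueError(f"{self.sample_id}: sex must be M or F")
        if self.cohort not in ("aging", "parabiosis"):
            raise ValueError(f"{self.sample_id}: unknown cohort {self.cohort}")
        if (self.group == "none") != (self.cohort == "aging"):
            raise ValueError(
                f"{self.sample_id}: group must be none iff cohort is aging")
        if self.cohort == "parabiosis" and self.group not in PARABIOSIS_GROUPS:
            raise ValueError(f"{self.sample_id}: unknown group {self.group}")
        if self.total_aligned_reads < 0:
            raise ValueError(f"{self.sample_id}: negative total_aligned_reads")


@dataclass(frozen=True)
class FeatureAnnotation:
    """Reference annotation for one ncRNA (or mRNA) feature."""

    feature_id: str
    rna_class: str
    reference_length: int
    mature_sequence: str | None = None
    prepachytene_cluster: bool | None = None
    is_first_paralog: bool = True

    def __post_init__(self) -> None:
        if self.reference_length < 1:
            raise ValueError(f"{self.feature_id}: reference_length must be >= 1")
        if self.mature_sequence is not None:
            bad = set(self.mature_sequence.upper()) - set("ACGUN")
            if bad:
                raise ValueError(
                    f"{self.feature_id}: invalid sequence letters {sorted(bad)}")


@dataclass(frozen=True)
class BindingSite:
    """One conserved/non-conserved seed-match record (mirna, gene, type)."""

    mirna: str
    gene: str
    site_type: str
    conserved: bool


@dataclass
class CountMatrix:
    """Feature x sample count table with per-sample metadata.

    ``counts`` holds raw non-negative integer read counts (rows = features,
    columns = sample ids); ``samples`` is a DataFrame aligned with the
    columns; ``normalized``, when present, holds reads per mapped million
    (rpmm) computed ONCE from the in-matrix column totals.  Filters never
    re-normalize, so rpmm values are invariant under feature filtering.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.samples = self.samples.set_index(
            pd.Index(self.samples["sample_id"], name="sample_id"), drop=False) \
            if "sample_id" in self.samples.columns else self.samples
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count matrix columns do not match sample sheet")
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at feature {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}")

    # -- accessors -------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    # -- normalization ---------------------------------------------------
    def normalize(self) -> "CountMatrix":
        """Attach the rpmm matrix: counts * 1e6 / per-sample total.

        Columns with zero total stay all-zero.  Idempotent: an existing
        ``normalized`` table is kept as-is so downstream filtering can never
        change rpmm values.
        """
        if self.normalized is not None:
            return self
        totals = self.counts.sum(axis=0).astype(float)
        safe = totals.replace(0, np.nan)
        norm = self.counts.div(safe, axis=1) * 1e6
        self.normalized = norm.fillna(0.0)
        return self

    @property
    def rpmm(self) -> pd.DataFrame:
        if self.normalized is None:
            raise ValueError("call .normalize() before using rpmm")
        return self.normalized

    # -- subsetting ------------------------------------------------------
    def subset_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        return CountMatrix(
            counts=self.counts.loc[keep],
            samples=self.samples.copy(),
            normalized=None if self.normalized is None
            else self.normalized.loc[keep])

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return CountMatrix(
            counts=self.counts[keep],
            samples=self.samples.loc[keep].copy(),
            normalized=None if self.normalized is None
            else self.normalized[keep])

    def tissue(self, tissue: str) -> "CountMatrix":
        ids = self.samples.index[self.samples["tissue"] == tissue]
        if len(ids) == 0:
            raise ValueError(f"tissue {tissue!r} not present")
        return self.subset_samples(list(ids))


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(SAMPLE_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    for row in sheet.itertuples(index=False):
        SampleMeta(sample_id=row.sample_id, tissue=row.tissue,
                   age_months=float(row.age_months), sex=row.sex,
                   cohort=row.cohort, group=row.group,
                   total_aligned_reads=int(row.total_aligned_reads))
    return sheet.set_index(pd.Index(sheet["sample_id"], name="sample_id"),
                           drop=False)


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def _read_counts_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def _read_counts_mtx(path: Path) -> pd.DataFrame:
    mat = scipy.sparse.coo_matrix(scipy.io.mmread(path)).toarray()
    rows = Path(str(path) + ".features.txt").read_text().split()
    cols = Path(str(path) + ".samples.txt").read_text().split()
    return pd.DataFrame(mat, index=rows, columns=cols)


def read_count_matrix(path: str | Path, sample_sheet: str | Path,
                      annotation: Mapping[str, FeatureAnnotation] | None = None,
                      ) -> CountMatrix:
    """Load a feature x sample count matrix and attach sample metadata.

    ``path`` may be a TSV (feature ids in the first column, sample ids in the
    header) or a MatrixMarket file with ``<path>.features.txt`` and
    ``<path>.samples.txt`` sidecars.  Every matrix column must have a row in
    the sample sheet.  When an annotation map is given, features whose
    ``is_first_paralog`` flag is false are dropped at load so duplicate
    paralogs never enter the analysis.
    """
    path = Path(path)
    head = path.open().readline()
    df = _read_counts_mtx(path) if head.startswith("%%MatrixMarket") \
        else _read_counts_tsv(path)

    vals = df.to_numpy()
    if vals.size:
        frac, _ = np.modf(vals.astype(float))
        if frac.any():
            i, j = np.argwhere(frac != 0)[0]
            raise ValueError(
                f"non-integer count at feature {df.index[i]!r}, "
                f"sample {df.columns[j]!r}")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at feature {df.index[i]!r}, "
                f"sample {df.columns[j]!r}")
    df = df.astype(np.int64)

    sheet = read_sample_sheet(sample_sheet)
    missing = [s for s in df.columns if s not in sheet.index]
    if missing:
        raise ValueError(f"sample id(s) missing from sheet: {missing}")
    sheet = sheet.loc[list(df.columns)]

    if annotation is not None:
        keep = [f for f in df.index
                if f not in annotation or annotation[f].is_first_paralog]
        df = df.loc[keep]
    return CountMatrix(counts=df, samples=sheet)


def write_count_matrix(cm: CountMatrix, path: str | Path,
                       sample_sheet: str | Path | None = None) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="feature_id")
    if sample_sheet is not None:
        write_sample_sheet(cm.samples, sample_sheet)


# ---------------------------------------------------------------------------
# feature annotation
# ---------------------------------------------------------------------------

def _parse_bool(x) -> bool | None:
    if pd.isna(x) or x in (".", ""):
        return None
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {x!r}")


def read_annotation(path: str | Path) -> dict[str, FeatureAnnotation]:
    """Read the feature annotation TSV into a feature_id -> record map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"feature_id", "rna_class", "reference_length"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation needs columns {sorted(required)}")
    out: dict[str, FeatureAnnotation] = {}
    for row in df.itertuples(index=False):
        seq = getattr(row, "mature_sequence", None)
        seq = None if seq is None or pd.isna(seq) or seq == "." else seq
        prep = _parse_bool(getattr(row, "prepachytene_cluster", None))
        first = _parse_bool(getattr(row, "is_first_paralog", "true"))
        out[row.feature_id] = FeatureAnnotation(
            feature_id=row.feature_id, rna_class=row.rna_class,
            reference_length=int(row.reference_length), mature_sequence=seq,
            prepachytene_cluster=prep,
            is_first_paralog=True if first is None else first)
    return out


def write_annotation(ann: Mapping[str, FeatureAnnotation],
                     path: str | Path) -> None:
    rows = []
    for a in ann.values():
        rows.append({
            "feature_id": a.feature_id, "rna_class": a.rna_class,
            "reference_length": a.reference_length,
            "mature_sequence": a.mature_sequence or ".",
            "prepachytene_cluster": "." if a.prepachytene_cluster is None
            else str(a.prepachytene_cluster).lower(),
            "is_first_paralog": str(a.is_first_paralog).lower()})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intervals (BED-like, 0-based half-open)
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read 3-column BED-like intervals grouped by feature.

    Coordinates are 0-based half-open; an interval with end <= start is a
    hard error naming the offending line.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: need 3 columns")
            fid, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(
                    f"line {lineno}: empty or inverted interval "
                    f"[{start}, {end}) for {fid}")
            out.setdefault(fid, []).append((start, end))
    return out


def write_intervals(intervals: Mapping[str, Iterable[tuple[int, int]]],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        for fid, ivs in intervals.items():
            for start, end in ivs:
                fh.write(f"{fid}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# binding-site table
# ---------------------------------------------------------------------------

def normalize_site_type(site_type: str) -> str:
    canon = _SITE_ALIASES.get(site_type.strip().lower())
    if canon is None:
        raise ValueError(f"unknown binding-site type {site_type!r}")
    return canon


def read_site_table(path: str | Path) -> list[BindingSite]:
    """Read the (mirna, gene, site_type, conserved) TSV.

    Site types are normalized case-insensitively and the legacy alias
    ``7mer-8m`` is accepted for ``7mer-m8``.  Duplicate rows are retained:
    a gene can carry several sites of the same type.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"mirna", "gene", "site_type", "conserved"}
    if not required <= set(df.columns):
        raise ValueError(f"site table needs columns {sorted(required)}")
    sites = []
    for row in df.itertuples(index=False):
        sites.append(BindingSite(
            mirna=row.mirna, gene=row.gene,
            site_type=normalize_site_type(row.site_type),
            conserved=bool(_parse_bool(row.conserved))))
    return sites


def write_site_table(sites: Iterable[BindingSite], path: str | Path) -> None:
    pd.DataFrame([{"mirna": s.mirna, "gene": s.gene, "site_type": s.site_type,
                   "conserved": str(s.conserved).lower()}
                  for s in sites]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA (mature sequences)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
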