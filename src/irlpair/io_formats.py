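"""Readers, writers and validated containers for every table the pipeline touches.

All tabular I/O is TSV (tab-separated, UTF-8, header row). Gene annotation
additionally accepts Ensembl-dialect GTF, from which only the gene-level
attributes ``gene_id``, ``gene_name`` and ``gene_biotype`` are used —
coordinates and strand are irrelevant to a rank-based signature.

Expression values are kept on the linear scale (FPKM-like abundances);
log transforms happen inside the operations that need them. Because the
pair encoding is rank-based the actual unit never matters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NORMAL = "normal"

#: Biotype spellings collapsed onto the three classes the pipeline uses.
BIOTYPE_SYNONYMS = {
    "lncrna": "lncRNA",
    "lincrna": "lncRNA",
    "antisense": "lncRNA",
    "antisense_rna": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    "processed_transcript": "lncRNA",
    "3prime_overlapping_ncrna": "lncRNA",
    "macro_lncrna": "lncRNA",
    "bidirectional_promoter_lncrna": "lncRNA",
    "protein_coding": "protein_coding",
    "mrna": "protein_coding",
}


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class ExpressionMatrix:
    """Linear-scale gene-by-sample expression with tumor/normal labels.

    ``values`` is a genes x samples DataFrame of finite, non-negative
    reals; ``sample_group`` maps every sample id to ``"tumor"`` or
    ``"normal"``.
    """

    values: pd.DataFrame
    sample_group: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate gene identifiers: {dup[:5]}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample identifiers: {dup[:5]}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ParseError("expression values must be finite")
        if (arr < 0).any():
            bad = v.index[(arr < 0).any(axis=1)][0]
            raise ParseError(f"negative expression value in gene {bad!r}")
        self.sample_group = pd.Series(self.sample_group, dtype=object)
        missing = v.columns.difference(self.sample_group.index)
        if len(missing):
            raise ParseError(f"samples without group label: {list(missing)[:5]}")
        self.sample_group = self.sample_group.reindex(v.columns)
        bad_groups = set(self.sample_group.unique()) - {TUMOR, NORMAL}
        if bad_groups:
            raise ParseError(f"unknown sample groups: {sorted(bad_groups)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.sample_group.index[self.sample_group == group])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.sample_group)


@dataclass
class GeneAnnotation:
    """gene_id -> (gene_name, biotype) with biotypes normalised to
    {lncRNA, protein_coding, other}."""

    table: pd.DataFrame  # index gene_id, columns gene_name, biotype

    def biotype(self, gene_id: str) -> str | None:
        if gene_id in self.table.index:
            return self.table.at[gene_id, "biotype"]
        return None

    def genes_of_biotype(self, biotype: str) -> list[str]:
        return list(self.table.index[self.table["biotype"] == biotype])

    def missing(self, gene_ids) -> list[str]:
        return [g for g in gene_ids if g not in self.table.index]


@dataclass
class SurvivalTable:
    """Per-patient follow-up time (days, > 0), event indicator in {0, 1}
    and categorical clinical covariates.

    Patients lacking time or event are dropped at read time; missing
    covariate values are kept as the explicit category ``"unknown"`` so
    that contingency-table tests never silently lose patients.
    """

    data: pd.DataFrame  # index patient_id; columns time, event, covariates...
    n_dropped: int = 0
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        d = self.data
        if d.index.duplicated().any():
            raise ParseError("duplicate patient identifiers after cleaning")
        if (d["time"] <= 0).any() or d["time"].isna().any():
            raise ParseError("follow-up times must be positive and present")
        ev = set(d["event"].unique())
        if not ev <= {0, 1}:
            raise ParseError(f"event indicator must be 0/1, got {sorted(ev)}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]

    def aligned_to(self, patient_ids) -> "SurvivalTable":
        shared = [p for p in patient_ids if p in self.data.index]
        return SurvivalTable(self.data.loc[shared])


def read_expression(path, group_map) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    ``group_map`` maps sample id -> "tumor" / "normal"; it may be a dict,
    Series, or the path of a two-column TSV (sample, group).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    import os

    if isinstance(group_map, (str, os.PathLike)) or hasattr(group_map, "read"):
        gm = pd.read_csv(group_map, sep="\t", index_col=0).iloc[:, 0]
    else:
        gm = pd.Series(group_map)
    m = ExpressionMatrix(df, gm)
    logger.info("read expression: %d genes x %d samples", *df.shape)
    return m


def write_expression(matrix: ExpressionMatrix, path, group_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    if group_path is not None:
        matrix.sample_group.rename("group").to_csv(group_path, sep="\t", index_label="sample_id")


def _normalise_biotype(raw: str) -> str:
    norm = BIOTYPE_SYNONYMS.get(str(raw).strip().lower())
    if norm is None:
        warnings.warn(f"unknown biotype {raw!r} classified as 'other'", stacklevel=3)
        return "other"
    return norm


def _parse_gtf_attributes(attr: str) -> dict:
    out = {}
    for chunk in attr.strip().strip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_annotation(path) -> GeneAnnotation:
    """Read gene annotation from an Ensembl GTF (``gene`` features) or a
    3-column TSV ``gene_id  gene_name  biotype``."""
    path = str(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    is_gtf = path.endswith((".gtf", ".gff")) or first.startswith("#!") or (
        "\t" in first and len(first.split("\t")) == 9
    )
    records = {}
    if is_gtf:
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
                if fields[2] != "gene":
                    continue
                attrs = _parse_gtf_attributes(fields[8])
                if "gene_id" not in attrs:
                    raise ParseError(f"{path}:{lineno}: gene feature lacks gene_id")
                gid = attrs["gene_id"]
                records[gid] = (
                    attrs.get("gene_name", gid),
                    _normalise_biotype(attrs.get("gene_biotype", attrs.get("gene_type", ""))),
                )
    else:
        df = pd.read_csv(path, sep="\t", header=0)
        if df.shape[1] < 3:
            raise ParseError(f"{path}: annotation TSV needs 3 columns (gene_id, gene_name, biotype)")
        for _, row in df.iterrows():
            records[str(row.iloc[0])] = (str(row.iloc[1]), _normalise_biotype(row.iloc[2]))
    table = pd.DataFrame.from_dict(records, orient="index", columns=["gene_name", "biotype"])
    table.index.name = "gene_id"
    return GeneAnnotation(table)


def write_annotation(annotation: GeneAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="gene_id")


def read_survival(path) -> SurvivalTable:
    """Read a clinical/survival TSV: patient id, time, event, covariates.

    Duplicated patients keep the first occurrence; rows with missing or
    non-positive follow-up time or missing event are dropped and counted;
    missing covariate values become the "unknown" category.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return clean_survival(df)


def clean_survival(df: pd.DataFrame) -> SurvivalTable:
    """Apply the deduplication/missingness policy to an in-memory table."""
    if "time" not in df.columns or "event" not in df.columns:
        raise ParseError("survival table needs 'time' and 'event' columns")
    n0 = len(df)
    dup = int(df.index.duplicated().sum())
    if dup:
        logger.warning("dropping %d duplicated patient rows (keeping first)", dup)
        df = df[~df.index.duplicated(keep="first")]
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    usable = time.notna() & (time > 0) & event.isin([0, 1])
    dropped = int((~usable).sum())
    if dropped:
        logger.warning("dropping %d patients with unusable time/event", dropped)
    df = df[usable].copy()
    if len(df) == 0:
        raise ParseError("zero usable patients after cleaning")
    df["time"] = time[usable].astype(float)
    df["event"] = event[usable].astype(int)
    for col in df.columns:
        if col in ("time", "event"):
            continue
        df[col] = df[col].astype(object).where(pd.notna(df[col]), "unknown").astype(str)
    return SurvivalTable(df, n_dropped=dropped, n_duplicates=dup)


def write_survival(table: SurvivalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="patient_id")


def read_gene_list(path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_score_table(path) -> pd.DataFrame:
    """Sample x variable table (shared by infiltration-score and IC50 inputs)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        raise ParseError("duplicate sample identifiers in score table")
    return df.apply(pd.to_numeric, errors="coerce")


def write_score_table(df: pd.DataFrame, path, index_label="sample_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)
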