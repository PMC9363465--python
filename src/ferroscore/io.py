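"""Readers and writers for the pipeline's text formats.

Matrices, clinical tables and signatures travel as delimited text
(tab-separated unless the extension says ``.csv``); gene sets as GMT;
configuration as YAML or JSON.  Matrices are feature-in-rows,
sample-in-columns; transposition is always explicit, never guessed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ClinicalTable,
    GeneSetCollection,
    FerroptosisSignature,
    OmicsMatrix,
    ParseError,
    ValidationError,
)

log = logging.getLogger(__name__)


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path, layer: str, transpose: bool = False) -> OmicsMatrix:
    """Read a delimited feature-by-sample matrix.

    First column holds feature ids, the header row sample ids.  Duplicated
    feature ids are collapsed by mean with a logged warning.  Non-numeric
    cells raise a :class:`ParseError` naming the offending row and column.
    """
    path = Path(path)
    numeric = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                          na_values=["NA", ""], float_precision="round_trip")
    numeric.index = numeric.index.astype(str).str.strip()
    numeric.columns = numeric.columns.astype(str).str.strip()
    object_cols = [c for c in numeric.columns if numeric[c].dtype == object]
    if object_cols:
        col = object_cols[0]
        coerced = pd.to_numeric(numeric[col].astype(str).str.strip(),
                                errors="coerce")
        bad = coerced.isna() & numeric[col].notna()
        row = numeric.index[np.argmax(bad.to_numpy())]
        raise ParseError(
            f"non-numeric value {numeric.loc[row, col]!r} at feature {row!r}, "
            f"sample {col!r} in {path.name}"
        )
    if transpose:
        numeric = numeric.T
    if numeric.index.duplicated().any():
        n_dup = int(numeric.index.duplicated().sum())
        log.warning("%s: %d duplicated feature id(s) collapsed by mean", path.name, n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()
    return OmicsMatrix(numeric.astype(float), layer)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    path = Path(path)
    matrix.data.to_csv(path, sep=_sep_for(path), index_label="feature_id",
                       float_format="%.17g")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then tab-separated gene ids."""
    collection = GeneSetCollection()
    path = Path(path)
    with open(path) as fh:
        n_lines = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path.name} line {lineno}: GMT lines need name, "
                    f"description and at least one gene (got {len(fields)} fields)"
                )
            collection.add(fields[0], fields[2:])
    if n_lines == 0:
        log.warning("%s: empty GMT file, returning empty collection", path.name)
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


DEFAULT_CLINICAL_COLUMNS = {
    "sample_id": "sample_id",
    "os_time": "os_time",
    "os_event": "os_event",
    "pfs_time": "pfs_time",
    "pfs_event": "pfs_event",
    "response": "response",
}


def read_clinical(path, column_map: dict | None = None) -> ClinicalTable:
    """Read the clinical table; "NA" and empty cells become missing.

    ``column_map`` maps the canonical names (sample_id, os_time, os_event,
    pfs_time, pfs_event, response) onto the file's column headers; columns
    not mentioned are kept as covariates under their own names.
    """
    path = Path(path)
    cmap = dict(DEFAULT_CLINICAL_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=_sep_for(path), na_values=["NA", ""])
    rename = {v: k for k, v in cmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    if "sample_id" not in df.columns:
        raise ValidationError(
            f"{path.name}: mandatory column {cmap['sample_id']!r} (sample_id) missing"
        )
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    df = df.set_index("sample_id")
    if "response" not in df.columns:
        log.warning("%s: no response column; all responses set to NA", path.name)
        df["response"] = "NA"
    df["response"] = df["response"].fillna("NA").astype(str).str.strip()
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep=_sep_for(path), index_label="sample_id",
                      na_rep="NA")


def read_signature(path) -> FerroptosisSignature:
    """Read a two-column (gene, role in {pro, anti}) signature file."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"gene", "role"} <= set(df.columns):
        raise ParseError(f"{path.name}: signature file needs 'gene' and 'role' columns")
    pro = df.loc[df["role"].str.strip() == "pro", "gene"].astype(str).str.strip()
    anti = df.loc[df["role"].str.strip() == "anti", "gene"].astype(str).str.strip()
    return FerroptosisSignature(tuple(pro), tuple(anti), provenance=str(path))


def write_signature(signature: FerroptosisSignature, path) -> None:
    rows = [{"gene": g, "role": "pro"} for g in signature.pro_genes]
    rows += [{"gene": g, "role": "anti"} for g in signature.anti_genes]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_candidates(path) -> pd.DataFrame:
    """Read a candidate annotation table (gene, role) for screening."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"gene", "role"} <= set(df.columns):
        raise ParseError(f"{path.name}: candidate file needs 'gene' and 'role' columns")
    df["gene"] = df["gene"].astype(str).str.strip()
    df["role"] = df["role"].astype(str).str.strip()
    return df[["gene", "role"]]


def read_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh) or {}
        return json.load(fh)


def write_run_summary(path, **entries) -> None:
    """Write a JSON run summary (seed, thresholds, versions, counts)."""
    import ferroscore

    payload = {"ferroscore_version": ferroscore.__version__, **entries}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def apply_alias_map(matrix: OmicsMatrix, alias_path) -> OmicsMatrix:
    """Rename matrix features via a two-column (alias, target) map file."""
    amap = pd.read_csv(alias_path, sep=_sep_for(alias_path))
    mapping = dict(zip(amap.iloc[:, 0].astype(str).str.strip(),
                       amap.iloc[:, 1].astype(str).str.strip()))
    renamed = matrix.data.rename(index=mapping)
    if renamed.index.duplicated().any():
        renamed = renamed.groupby(level=0, sort=False).mean()
        log.warning("alias mapping merged duplicate features by mean")
    return OmicsMatrix(renamed, matrix.layer)
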