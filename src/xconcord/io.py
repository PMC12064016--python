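"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is tab-delimited UTF-8 with a header row: expression matrices
(genes in rows by default, configurable and never inferred), sample
annotation, probe manifests, and GMT gene-set collections.  XLSX sheets are
accepted for supplementary-file ingestion via openpyxl/pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ProbeCountMatrix, SampleAnnotation


def _read_table(path: str | Path, sheet: str | int | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
    return pd.read_csv(path, sep="\t")


def read_expression_table(
    path: str | Path,
    unit: str = "counts",
    orientation: str = "genes_in_rows",
    id_column: str | int = 0,
    sheet: str | int | None = None,
) -> ExpressionMatrix:
    """Read a delimited (or XLSX) expression table into an ExpressionMatrix.

    ``orientation`` is declared by the caller, never inferred.  A
    ``gene_symbol`` column, when present, is captured as symbol metadata.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path, sheet)
    idcol = df.columns[id_column] if isinstance(id_column, int) else id_column
    if idcol not in df.columns:
        raise ValueError(f"id column {idcol!r} not found in {path}")
    if df[idcol].isna().any():
        rows = df.index[df[idcol].isna()][:5].tolist()
        raise ValueError(f"missing ids in {path} at rows {rows}")
    df = df.set_index(idcol)
    symbols = None
    if "gene_symbol" in df.columns and orientation == "genes_in_rows":
        symbols = df.pop("gene_symbol")
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric columns in {path}: {bad[:5]}")
    if orientation == "samples_in_rows":
        df = df.T
        symbols = None
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()[:5].tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    return ExpressionMatrix(df, unit, symbols)


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.data.copy()
    df.index.name = df.index.name or "ensembl_id"
    if m.symbols is not None:
        df.insert(0, "gene_symbol", m.symbols)
    df.to_csv(path, sep="\t")


def read_probe_counts(
    counts_path: str | Path, manifest_path: str | Path
) -> ProbeCountMatrix:
    """Read probe-level counts plus the probe -> gene manifest."""
    counts = _read_table(counts_path)
    idcol = counts.columns[0]
    counts = counts.set_index(idcol)
    bad = [c for c in counts.columns if not np.issubdtype(counts[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric columns in {counts_path}: {bad[:5]}")
    return ProbeCountMatrix(counts, read_probe_manifest(manifest_path))


def read_probe_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV: probe_id, gene_symbol, ensembl_id (header required)."""
    df = _read_table(path)
    need = {"probe_id", "gene_symbol", "ensembl_id"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        dups = df["probe_id"][df["probe_id"].duplicated()][:5].tolist()
        raise ValueError(f"duplicate probes in manifest: {dups}")
    return df.set_index("probe_id")


def write_probe_counts(pm: ProbeCountMatrix, counts_path, manifest_path) -> None:
    out = pm.counts.copy()
    out.index.name = "probe_id"
    out.to_csv(counts_path, sep="\t")
    man = pm.manifest.copy()
    man.index.name = "probe_id"
    man.to_csv(manifest_path, sep="\t")


def read_annotation(path: str | Path) -> SampleAnnotation:
    df = _read_table(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"annotation {path} missing 'sample_id' column")
    df = df.set_index("sample_id")
    df["phase"] = df["phase"].astype(str)
    return SampleAnnotation(df)


def write_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    out = ann.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.ndarray, pd.Index)):
            return list(o)
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
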