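"""Core in-memory containers: expression matrices, probe-level counts, sample annotation.

Expression values are carried in a pandas DataFrame (genes in rows, samples in
columns) together with a unit tag so that downstream stages can refuse input in
the wrong state (e.g. RLE normalization demands ``log2epm1`` input and a stage
can never be applied twice by accident).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

#: Recognised unit tags, in the order they appear along the pipeline.
UNITS = ("counts", "epm", "log2epm1", "rle")

PLATFORMS = ("TARGETED", "REFERENCE")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a unit tag.

    Parameters
    ----------
    data :
        DataFrame indexed by gene identifier (Ensembl id as primary key),
        one column per sample.
    unit :
        One of ``counts``, ``epm``, ``log2epm1``, ``rle``.
    symbols :
        Optional gene-symbol metadata aligned with ``data.index``.
    """

    data: pd.DataFrame
    unit: str
    symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not np.issubdtype(np.asarray(self.data).dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.symbols is not None:
            self.symbols = self.symbols.reindex(self.data.index)

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, unit: str | None = None) -> "ExpressionMatrix":
        sym = self.symbols.reindex(data.index) if self.symbols is not None else None
        return ExpressionMatrix(data, unit or self.unit, sym)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        missing = genes.difference(self.data.index)
        if len(missing):
            raise KeyError(f"genes not in matrix: {missing[:5].tolist()}")
        return self.with_data(self.data.loc[genes])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = pd.Index(samples)
        missing = samples.difference(self.data.columns)
        if len(missing):
            raise KeyError(f"samples not in matrix: {missing[:5].tolist()}")
        return self.with_data(self.data.loc[:, samples])


@dataclass
class ProbeCountMatrix:
    """Probe-level counts for the targeted platform (probes x samples).

    ``manifest`` maps each probe id to its gene symbol and Ensembl id; several
    probes may target the same gene, which is why the gene index is not unique
    until :func:`~xconcord.normalize.collapse_probes` is applied.
    """

    counts: pd.DataFrame
    manifest: pd.DataFrame  # index probe_id, columns gene_symbol, ensembl_id

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate probe ids in count matrix")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("probe counts must be numeric")
        if (vals < 0).any():
            raise ValueError("probe counts must be non-negative")
        missing = self.counts.index.difference(self.manifest.index)
        if len(missing):
            raise ValueError(
                f"probes missing from manifest: {missing[:5].tolist()}"
            )
        bad = self.manifest.loc[self.counts.index, "ensembl_id"].isna()
        if bad.any():
            raise ValueError(
                "probes with missing ensembl_id: "
                f"{self.counts.index[bad][:5].tolist()}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class SampleAnnotation:
    """Per-sample metadata: cell line, platform, phase, replicate index."""

    table: pd.DataFrame  # index sample_id; columns cell_line, platform, phase, replicate

    REQUIRED = ("cell_line", "platform", "phase", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in annotation")
        bad = ~self.table["platform"].isin(PLATFORMS)
        if bad.any():
            raise ValueError(
                f"unknown platform values: {self.table['platform'][bad].unique().tolist()}"
            )
        key = self.table[list(self.REQUIRED)]
        if key.duplicated().any():
            raise ValueError("(cell_line, platform, phase, replicate) must be unique")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        """Check every matrix sample is annotated; raise naming the culprits."""
        missing = pd.Index(sample_ids).difference(self.table.index)
        if len(missing):
            raise ValueError(f"samples missing from annotation: {missing[:5].tolist()}")

    def subset(self, sample_ids: Iterable[str]) -> "SampleAnnotation":
        self.require_samples(sample_ids)
        return SampleAnnotation(self.table.loc[pd.Index(sample_ids)])

    def factor(self, name: str, sample_ids: Iterable[str] | None = None) -> pd.Series:
        """Return one annotation column aligned to ``sample_ids`` order."""
        if name not in self.table.columns:
            raise KeyError(f"unknown annotation column {name!r}")
        col = self.table[name]
        if sample_ids is not None:
            self.require_samples(sample_ids)
            col = col.loc[pd.Index(sample_ids)]
        return col
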