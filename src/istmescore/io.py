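"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices travel as TSV (genes in rows, first column the gene id,
header row the sample ids) or read-only GCT v1.2; gene sets as Broad-dialect
GMT; clinical tables as TSV with ``sample_id``, ``os_time``, ``os_event``
columns.  Everything is UTF-8 with "." decimals.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ExpressionMatrix, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed file structure (header, declared dimensions, field counts)."""


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each duplicated gene id, the row with the highest mean."""
    if not df.index.has_duplicates:
        return df
    means = df.mean(axis=1).values
    order = np.argsort(-means, kind="stable")  # best rows first
    best_first = df.iloc[order]
    collapsed = best_first[~best_first.index.duplicated(keep="first")]
    collapsed = collapsed.loc[df.index.drop_duplicates()]  # restore file order
    n = df.shape[0] - collapsed.shape[0]
    logger.info("collapsed %d duplicate gene rows by max-mean rule", n)
    return collapsed


def read_expression(path, format: str = "tsv") -> ExpressionMatrix:
    """Read a gene x sample expression matrix from TSV or GCT v1.2.

    Duplicate gene ids are collapsed by keeping the row with the highest
    mean (logged).  Non-numeric cells raise with a row/column report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise FormatError(f"{path}: expected GCT v1.2 header, got {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise FormatError(f"{path}: missing GCT dimension line")
            n_rows, n_cols = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0, header=0)
        df = df.drop(columns=["Description"], errors="ignore")
        if df.shape[0] != n_rows or df.shape[1] != n_cols:
            raise FormatError(
                f"{path}: declared {n_rows}x{n_cols} but found {df.shape[0]}x{df.shape[1]}"
            )
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = _collapse_duplicate_genes(df)
    return ExpressionMatrix(df.astype(float), value_scale="raw")


def write_expression(m: ExpressionMatrix, path, format: str = "tsv") -> None:
    """Write an expression matrix as TSV (round-trips to 1e-12)."""
    if format != "tsv":
        raise ValueError("only TSV output is supported")
    if m.n_genes == 0:
        raise ValueError("refusing to write an empty (0-gene) matrix")
    df = m.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT collection: name, description, then tab-separated genes."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if len(set(genes)) != len(genes):
                logger.warning("%s:%d: duplicate genes in set %r deduplicated", path, lineno, name)
            sets.append(GeneSet(name=name, description=desc, genes=genes))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")


def read_clinical(path) -> ClinicalTable:
    """Read a clinical TSV; rows missing os_time/os_event are dropped and counted."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "os_time", "os_event"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    n_before = df.shape[0]
    df = df.dropna(subset=["os_time", "os_event"])
    n_dropped = n_before - df.shape[0]
    if n_dropped:
        logger.info("dropped %d samples without prognostic information", n_dropped)
    df = df.set_index("sample_id")
    df["os_time"] = df["os_time"].astype(float)
    ev = pd.to_numeric(df["os_event"], errors="coerce")
    if not ev.isin([0, 1]).all():
        raise FormatError(f"{path}: os_event must be 0/1")
    df["os_event"] = ev.astype(int)
    return ClinicalTable(df, n_dropped=n_dropped)


def write_clinical(c: ClinicalTable, path) -> None:
    df = c.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")
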