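"""Readers and writers for the tabular interchange formats.

Expression matrices travel either as a TSV with gene rows and cell columns or
as a Matrix Market (MTX) file with sidecar row/column name files; all other
tables are plain TSV/CSV with a header row.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene x cell matrix from TSV (first column = gene id, header = cell ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    df.columns.name = "cell"
    _check_expression(df, path)
    return df


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", float_format="%.6g")


def read_expression_mtx(path) -> pd.DataFrame:
    """Gene x cell matrix from MTX + ``<stem>_genes.txt`` / ``<stem>_cells.txt``."""
    path = Path(path)
    mat = scipy.io.mmread(path)
    genes = (path.parent / f"{path.stem}_genes.txt").read_text().split()
    cells = (path.parent / f"{path.stem}_cells.txt").read_text().split()
    df = pd.DataFrame(np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat),
                      index=pd.Index(genes, name="gene"),
                      columns=pd.Index(cells, name="cell"))
    _check_expression(df, path)
    return df


def write_expression_mtx(expr: pd.DataFrame, path) -> None:
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(expr.to_numpy()))
    (path.parent / f"{path.stem}_genes.txt").write_text("\n".join(expr.index) + "\n")
    (path.parent / f"{path.stem}_cells.txt").write_text("\n".join(expr.columns) + "\n")


def _check_expression(df: pd.DataFrame, path) -> None:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate cell id {dup!r} in {path}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative expression values in {path}")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chamber_id": str})
    required = {"chamber_id", "start_composition", "end_composition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    if "sequenced" in df.columns:
        df["sequenced"] = df["sequenced"].astype(bool)
    return df


def read_distances(path) -> pd.DataFrame:
    """CID x frame distance table (CSV, first column = cid id)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "cid_id"
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative distances in {path}")
    return df


def read_halflife(path, units: str = "hours") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"half-life table {path} needs gene + value columns")
    df = df.rename(columns={cols[0]: "gene", cols[1]: "half_life_hours"})
    if units == "minutes":
        df["half_life_hours"] = df["half_life_hours"] / 60.0
    elif units != "hours":
        raise ValueError(f"unknown half-life units {units!r}")
    return df[["gene", "half_life_hours"]]


def read_lr_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_A", "gene_B"} - set(df.columns)
    if missing:
        raise ValueError(f"LR pair table {path} lacks columns {sorted(missing)}")
    if "category" not in df.columns:
        df["category"] = ""
    return df[["gene_A", "gene_B", "category"]]


def read_gene_list(path) -> list[str]:
    return [g for g in Path(path).read_text().split() if g]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(path, record: dict) -> None:
    Path(path).write_text(json.dumps(record, indent=1, sort_keys=True, default=str))
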