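"""Readers and writers for the pipeline's tabular formats.

Expression matrices round-trip through GCT 1.2 (a "#1.2" version header, a
rows/columns dimension line, then Name/Description columns) or plain TSV with
the probe id in the first column. Everything else is ordinary TSV handled via
pandas.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ExpressionBatch

__all__ = [
    "read_expression",
    "read_gct",
    "write_gct",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_gmt",
    "read_probe_map",
    "read_clinical",
    "read_interactions",
]


def read_gct(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError(f"{path}: malformed GCT dimension line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        pos = fh.tell()
        _check_header_unique(fh.readline(), path)
        fh.seek(pos)
        body = pd.read_csv(fh, sep="\t", index_col=0)
    if "Description" in body.columns:
        body = body.drop(columns=["Description"])
    if body.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: dimension header says {n_rows}x{n_cols}, "
            f"found {body.shape[0]}x{body.shape[1]}"
        )
    return _validate_matrix(body, path)


def write_gct(path: str | Path, data: pd.DataFrame) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{data.shape[0]}\t{data.shape[1]}\n")
        out = data.copy()
        out.insert(0, "Description", "na")
        out.index.name = "Name"
        out.to_csv(fh, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        _check_header_unique(fh.readline(), path)
    body = pd.read_csv(path, sep="\t", index_col=0)
    return _validate_matrix(body, path)


def _check_header_unique(header_line: str, path: Path) -> None:
    names = header_line.rstrip("\n").split("\t")[1:]
    seen = set()
    for name in names:
        if name in seen:
            raise ValueError(f"{path}: duplicate sample id {name!r}")
        seen.add(name)


def write_matrix_tsv(path: str | Path, data: pd.DataFrame) -> None:
    out = data.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def _validate_matrix(body: pd.DataFrame, path: Path) -> pd.DataFrame:
    if body.columns.duplicated().any():
        dup = body.columns[body.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    for col in body.columns:
        converted = pd.to_numeric(body[col], errors="coerce")
        bad = converted.isna() & body[col].notna()
        if bad.any():
            row = body.index[bad][0]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        if converted.isna().any():
            row = body.index[converted.isna()][0]
            raise ValueError(f"{path}: missing value at row {row!r}, column {col!r}")
        body[col] = converted
    if not np.isfinite(body.to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: matrix contains non-finite values")
    return body


def read_expression(path: str | Path, fmt: str | None = None,
                    batch_id: str | None = None) -> ExpressionBatch:
    """Read an expression batch from GCT 1.2 or TSV (auto-detected by suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if fmt == "gct":
        data = read_gct(path)
    elif fmt == "tsv":
        data = read_matrix_tsv(path)
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    if batch_id is None:
        batch_id = path.stem.removeprefix("expr_")
    return ExpressionBatch(batch_id=batch_id, data=data)


def write_gmt(path: str | Path, sets: Mapping[str, Sequence[str]],
              descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with Path(path).open("w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(set(members))]) + "\n")


def read_probe_map(path: str | Path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene_symbol"}.issubset(pm.columns):
        raise ValueError(f"{path}: probe map needs columns probe_id, gene_symbol")
    return pm


def read_clinical(path: str | Path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    missing = required - set(clin.columns)
    if missing:
        raise ValueError(f"{path}: clinical table missing column(s) {sorted(missing)}")
    if (clin["time"] < 0).any():
        raise ValueError(f"{path}: negative survival time")
    if not clin["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event flag must be 0/1")
    return clin


def read_interactions(path: str | Path) -> pd.DataFrame:
    inter = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "drug", "source"}
    missing = required - set(inter.columns)
    if missing:
        raise ValueError(f"{path}: interaction table missing column(s) {sorted(missing)}")
    return inter
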