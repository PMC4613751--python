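"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV: first column ``transcript_id``, header
row of sample ids, missing values written as ``NA`` (both ``NA`` and empty
fields are accepted on read).  Feature flags travel in a sparse long TSV
listing only flagged cells.  A read-only parser for the GEO series-matrix
format (the table between ``!series_matrix_table_begin`` and
``!series_matrix_table_end``) is provided for users with a real deposit.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import FeatureFlags

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "read_flags",
    "write_flags",
    "read_phenotypes",
    "write_table",
    "manifest_hash",
]

_NA = "NA"


def _strip_comments(path: Path) -> _io.StringIO:
    lines = [l for l in Path(path).read_text().splitlines() if not l.startswith("#")]
    return _io.StringIO("\n".join(lines))


def read_expression(path, format: str = "tsv") -> pd.DataFrame:
    """Read a transcripts x samples expression matrix.

    ``format`` is ``"tsv"`` or ``"geo_series_matrix"``.  Duplicate
    transcript or sample ids and ragged rows are rejected.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(
            _strip_comments(path), sep="\t", index_col=0,
            na_values=[_NA, ""], keep_default_na=False,
        )
    elif format == "geo_series_matrix":
        df = _read_series_matrix(path)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate transcript ids in {path}: {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dups[:5]}")
    df.index.name = "transcript_id"
    return df.astype(float)


def _read_series_matrix(path: Path) -> pd.DataFrame:
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines)
                   if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ValueError(f"{path} has no series_matrix table delimiters") from None
    table = "\n".join(lines[start + 1:end])
    df = pd.read_csv(
        _io.StringIO(table), sep="\t", index_col=0,
        na_values=["null", _NA, ""], keep_default_na=False,
    )
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [c.strip('"') for c in df.columns]
    return df


def write_expression(matrix: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        matrix.to_csv(fh, sep="\t", na_rep=_NA, index_label="transcript_id")


def read_metadata(path, expression: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read sample metadata (sample_id, progeny, sex, array_id) from TSV."""
    meta = pd.read_csv(_strip_comments(Path(path)), sep="\t", index_col=0, dtype=str)
    if expression is not None:
        missing = [s for s in meta.index if s not in set(expression.columns)]
        if missing:
            raise ValueError(f"metadata samples absent from matrix: {missing[:5]}")
    return meta


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(_strip_comments(Path(path)), sep="\t", index_col=0)
    return df


def write_flags(flags: FeatureFlags, path) -> None:
    """Write flags as a sparse long TSV (only non-default cells listed)."""
    records = []
    nonuni = ~flags.uniform
    for (frame, col, truthy) in ((nonuni, "nonuniform", True),
                                 (flags.negative_filtered, "negative_filtered", True)):
        stacked = frame.stack()
        hits = stacked[stacked]
        for (t, s) in hits.index:
            records.append({"transcript_id": t, "sample_id": s, "flag": col})
    pd.DataFrame(records, columns=["transcript_id", "sample_id", "flag"]).to_csv(
        path, sep="\t", index=False
    )


def read_flags(path, matrix: pd.DataFrame) -> FeatureFlags:
    """Read the sparse long flag TSV back into dense boolean frames."""
    long = pd.read_csv(_strip_comments(Path(path)), sep="\t", dtype=str)
    uniform = pd.DataFrame(True, index=matrix.index, columns=matrix.columns)
    negative = pd.DataFrame(False, index=matrix.index, columns=matrix.columns)
    for _, row in long.iterrows():
        t, s, flag = row["transcript_id"], row["sample_id"], row["flag"]
        if t not in uniform.index or s not in uniform.columns:
            continue
        if flag == "nonuniform":
            uniform.loc[t, s] = False
        elif flag == "negative_filtered":
            negative.loc[t, s] = True
        else:
            raise ValueError(f"unknown flag {flag!r} in {path}")
    return FeatureFlags(uniform=uniform, negative_filtered=negative)


def manifest_hash(manifest: dict) -> str:
    """Short stable hash of a manifest dict for provenance headers."""
    payload = json.dumps(manifest, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, manifest: dict | None = None,
                index: bool = True) -> None:
    """Write a result table as TSV with an optional provenance header."""
    path = Path(path)
    with path.open("w") as fh:
        if manifest is not None:
            fh.write(f"# manifest_hash={manifest_hash(manifest)}\n")
            for key, val in manifest.items():
                fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", na_rep=_NA, index=index)
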