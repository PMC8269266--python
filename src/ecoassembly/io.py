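"""Reading and writing the tabular and tree formats used throughout.

Count tables are plain TSV: first column OTU ids, header row sample ids,
integer cells. Metadata tables are TSV keyed by ``sample_id``. Trees are
newick with branch lengths, handled by scikit-bio.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import FormatError

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_distance_matrix",
    "write_distance_matrix",
]

_FLOAT_FMT = "%.10g"


def read_count_table(path) -> pd.DataFrame:
    """Read an OTU x sample count table from TSV.

    Returns an integer DataFrame with OTU ids as the index and sample ids as
    columns. Raises :class:`FormatError` naming the offending cell for
    non-integer entries, duplicate ids, ragged rows or an empty file.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: file is empty, expected a count table")
    try:
        df = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise FormatError(f"{path}: malformed TSV ({exc})") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate OTU id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    if df.isna().any().any():
        row, col = next(
            (r, c) for c in df.columns for r in df.index if pd.isna(df.at[r, c])
        )
        raise FormatError(f"{path}: missing value at OTU {row!r}, sample {col!r}")
    data = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (row, raw) in enumerate(df[col].items()):
            try:
                val = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer cell {raw!r} at OTU {row!r}, sample {col!r}"
                ) from None
            if val < 0:
                raise FormatError(
                    f"{path}: negative count {raw!r} at OTU {row!r}, sample {col!r}"
                )
            data[i, j] = val
    out = pd.DataFrame(data, index=df.index, columns=df.columns)
    out.index.name = df.index.name or "otu_id"
    return out


def write_count_table(counts: pd.DataFrame, path) -> None:
    counts = counts.astype(np.int64)
    counts.rename_axis("otu_id").to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV indexed by ``sample_id``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: metadata must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    return df.set_index("sample_id")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample_id").to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_tree(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick", convert_underscores=False)


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_distance_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: distance matrix ids do not match across axes")
    return df


def write_distance_matrix(dist: pd.DataFrame, path) -> None:
    dist.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
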