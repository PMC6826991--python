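"""Tab-separated readers/writers for every intermediate table.

All stages exchange flat TSV files with documented headers so that real
exports in the same schema can replace any synthetic stage."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_timeseries(path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"plate", "row", "col", "strain", "drug", "dose", "time_h", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"time-series file missing column(s): {sorted(missing)}")
    return df


def read_annotations(path) -> pd.DataFrame:
    df = read_tsv(path)
    if not {"gene", "term"} <= set(df.columns):
        raise ValueError("annotation file needs columns gene, term")
    return df


def read_expression(path) -> pd.DataFrame:
    """Expression matrix TSV, genes in rows (first column), cell lines in columns."""
    return read_tsv(path, index_col=0)
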