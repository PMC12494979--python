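"""Readers for the two supported event-data inputs: FCS files and delimited
cell x channel tables."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ParameterError
from .fcs import read_fcs
from .matrix import ExpressionMatrix

#: Metadata columns recognized in delimited cell tables.
META_COLUMNS = ("cell_id", "sample", "batch", "treatment", "cell_line")


def _sniff_delimiter(path) -> str:
    header = Path(path).open("r").readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_delimited_matrix(path, meta_columns: Sequence[str] = META_COLUMNS
                          ) -> ExpressionMatrix:
    """Read a delimited cell table (header row; channels + metadata columns).

    Values are parsed with round-trip float precision so that export followed
    by re-import reproduces the matrix bit-exactly.
    """
    df = pd.read_csv(path, sep=_sniff_delimiter(path),
                     float_precision="round_trip")
    meta_cols = [c for c in meta_columns if c in df.columns]
    channels = [c for c in df.columns if c not in meta_cols]
    if not channels:
        raise ParameterError(f"{path}: no channel columns found")
    meta = df[meta_cols].copy() if meta_cols else pd.DataFrame(index=df.index)
    return ExpressionMatrix(
        values=df[channels].to_numpy(dtype=float),
        channel_names=channels,
        cell_meta=meta.reset_index(drop=True),
        scale_state="raw",
    )


def read_fcs_matrix(paths, sample_names: Sequence[str] | None = None
                    ) -> ExpressionMatrix:
    """Read one or more FCS files into a single raw-scale matrix.

    Channel names come from $PnS, falling back to $PnN. The file stem (or the
    provided sample name) becomes the per-cell ``sample`` label.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]
    if sample_names is None:
        sample_names = [p.stem for p in paths]
    if len(sample_names) != len(paths):
        raise ParameterError("sample_names must match the number of files")

    frames = []
    channels: list[str] | None = None
    for path, sample in zip(paths, sample_names):
        data, names, _ = read_fcs(path)
        if channels is None:
            channels = names
        elif names != channels:
            raise ParameterError(
                f"{path}: channel names differ from the first file"
            )
        df = pd.DataFrame(data, columns=channels)
        df["sample"] = sample
        frames.append(df)
    assert channels is not None
    merged = pd.concat(frames, ignore_index=True)
    meta = pd.DataFrame({"sample": merged.pop("sample")})
    return ExpressionMatrix(
        values=merged.to_numpy(dtype=float),
        channel_names=channels,
        cell_meta=meta,
        scale_state="raw",
    )
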