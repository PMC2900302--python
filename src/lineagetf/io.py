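"""TSV readers and writers for expression matrices and sample metadata.

Expression TSV: first column ``gene_id``, remaining columns sample ids,
values log2 intensities. Metadata TSV: columns ``sample_id``,
``lineage``, ``time_hours``, ``is_control`` (0/1).
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataError

#: Sample id of the shared time-0 uninduced control.
CONTROL_SAMPLE_ID = "ctrl_0h"

_METADATA_COLUMNS = ("sample_id", "lineage", "time_hours", "is_control")


def load_expression(paths: Sequence[str | Path] | str | Path) -> pd.DataFrame:
    """Load one or more expression TSVs, merging columns on gene_id.

    A column present in several files (typically the shared control) must
    agree across them; conflicting values are a hard error.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise DataError(f"expression file not found: {path}")
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        if frame.index.duplicated().any():
            dup = frame.index[frame.index.duplicated()][0]
            raise DataError(f"duplicate gene_id {dup!r} in {path}")
        frames.append(frame.astype(float))
    merged = frames[0]
    for frame in frames[1:]:
        if not merged.index.equals(frame.index):
            raise DataError("expression files do not share the same gene set/order")
        shared = [c for c in frame.columns if c in merged.columns]
        for column in shared:
            if not merged[column].equals(frame[column]):
                raise DataError(f"conflicting values for shared sample {column!r}")
        merged = pd.concat(
            [merged, frame[[c for c in frame.columns if c not in merged.columns]]],
            axis=1,
        )
    return merged


def write_expression(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = frame.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    return path


def load_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"metadata file not found: {path}")
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"metadata {path} lacks columns: {', '.join(missing)}")
    frame["time_hours"] = frame["time_hours"].astype(float)
    frame["is_control"] = frame["is_control"].astype(int)
    return frame


def write_metadata(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def write_behavior_calls(
    calls_osteo, calls_adipo, symbols: dict[str, str], path: str | Path
) -> Path:
    """Per-gene behavior table: one row per gene, both lineages."""
    rows = []
    for gene_id in sorted(calls_osteo):
        o, a = calls_osteo[gene_id], calls_adipo[gene_id]
        rows.append(
            {
                "gene_id": gene_id,
                "symbol": symbols.get(gene_id, gene_id),
                "osteoblast_call": o.call.value,
                "adipocyte_call": a.call.value,
                "osteoblast_up_times": ";".join(f"{t:g}" for t in o.up_times),
                "osteoblast_down_times": ";".join(f"{t:g}" for t in o.down_times),
                "adipocyte_up_times": ";".join(f"{t:g}" for t in a.up_times),
                "adipocyte_down_times": ";".join(f"{t:g}" for t in a.down_times),
            }
        )
    columns = ["gene_id", "symbol", "osteoblast_call", "adipocyte_call",
               "osteoblast_up_times", "osteoblast_down_times",
               "adipocyte_up_times", "adipocyte_down_times"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return Path(path)
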