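"""Frame-table and result-record I/O.

A frame table is TSV with header ``window theta e1 e2 [r_da]`` — one file
per EVB run, energies in kcal/mol, written with fixed precision so equal
seeds give byte-identical files on any platform.  Lines starting with
``#`` are comments.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import validate_frames
from .errors import MissingFieldError

__all__ = ["read_frames", "write_frames", "read_result", "write_result"]

_COLUMNS = ["window", "theta", "e1", "e2"]


def read_frames(path) -> pd.DataFrame:
    """Read a frame-table TSV; '#' comment lines are tolerated."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise MissingFieldError(
            f"{path}: frame table missing columns {missing}"
        )
    df["window"] = df["window"].astype("int64")
    validate_frames(df)
    return df


def write_frames(frames: pd.DataFrame, path) -> None:
    """Write a frame table with fixed (6-decimal) precision."""
    validate_frames(frames)
    cols = _COLUMNS + (["r_da"] if "r_da" in frames.columns else [])
    frames[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_result(record: dict, path) -> None:
    Path(path).write_text(
        json.dumps(record, sort_keys=True, indent=1) + "\n"
    )


def read_result(path) -> dict:
    return json.loads(Path(path).read_text())
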