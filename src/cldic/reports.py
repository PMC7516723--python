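"""Result writers: bit-stable CSV and JSON reports.

CSV reports round floats to 6 significant digits; JSON audit records keep
full precision and sorted keys, so identical inputs produce byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def write_result(obj, path: str | Path, fmt: str = "json") -> None:
    if fmt == "json":
        write_json(obj, path)
    elif fmt == "csv":
        if not isinstance(obj, pd.DataFrame):
            raise TypeError("csv output needs a DataFrame")
        write_csv(obj, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
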