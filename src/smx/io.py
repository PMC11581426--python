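"""File I/O: localization/spot CSVs, TIFF stacks, JSON reports.

Localization tables use the header ``x_nm,y_nm,frame,precision_nm``; spot
lists use ``x_px,y_px,channel``; images are 16-bit unsigned multi-page
TIFFs.  Ground truth travels as a JSON sidecar next to the table it
annotates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detect import SpotList
from .palm import REQUIRED_COLUMNS

__all__ = [
    "read_localizations", "write_localizations",
    "read_spots", "write_spots",
    "read_stack", "write_stack",
    "write_json", "read_json",
]


def read_localizations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing localization column(s) {missing}")
    return df


def write_localizations(df: pd.DataFrame, path):
    df.to_csv(path, index=False, columns=list(REQUIRED_COLUMNS))


def read_spots(path, channel: str = "") -> SpotList:
    df = pd.read_csv(path)
    if not {"x_px", "y_px"}.issubset(df.columns):
        raise ValueError(f"{path}: spot CSV needs x_px,y_px columns")
    ch = channel or (str(df["channel"].iloc[0]) if "channel" in df.columns and len(df) else "")
    return SpotList(coords=df[["x_px", "y_px"]].to_numpy(int), channel=ch)


def write_spots(spots, path, channel: str = ""):
    coords = getattr(spots, "coords", spots)
    ch = channel or getattr(spots, "channel", "")
    pd.DataFrame({"x_px": np.asarray(coords)[:, 0],
                  "y_px": np.asarray(coords)[:, 1],
                  "channel": ch}).to_csv(path, index=False)


def read_stack(path) -> np.ndarray:
    arr = tifffile.imread(path)
    return np.atleast_3d(arr) if arr.ndim == 2 else arr


def write_stack(stack, path):
    arr = np.asarray(stack)
    tifffile.imwrite(path, np.clip(arr, 0, 65535).astype(np.uint16))


def write_json(obj, path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
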