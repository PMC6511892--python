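"""Reading and writing RR-interval series and epoch annotations.

Supported RR input formats (auto-detected):

* plain text, one interval per line, seconds; ``#`` starts a comment;
* CSV with a ``rr_s`` column (seconds) or ``rr_ms`` column (milliseconds,
  auto-converted) and an optional ``t_s`` cumulative-time column.

Epoch annotations are CSV with columns ``label, start_s, end_s``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RRSeries

__all__ = ["read_rr", "write_rr", "read_epochs", "write_epochs"]


def read_rr(path: str | Path) -> RRSeries:
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"{path}: no data")
    header_like = any(c.isalpha() for c in lines[0])
    if "," in lines[0] or header_like:
        df = pd.read_csv(_io.StringIO("\n".join(lines)))
        df.columns = [c.strip().lower() for c in df.columns]
        if "rr_s" in df.columns:
            intervals = df["rr_s"].to_numpy(dtype=float)
        elif "rr_ms" in df.columns:
            intervals = df["rr_ms"].to_numpy(dtype=float) / 1000.0
        else:
            raise ValueError(f"{path}: need an rr_s or rr_ms column")
        beat_times = df["t_s"].to_numpy(dtype=float) if "t_s" in df.columns else None
    else:
        intervals = np.array([float(ln.strip()) for ln in lines])
        beat_times = None
    return RRSeries(intervals=intervals, beat_times=beat_times, source_id=path.stem)


def write_rr(rr: RRSeries, path: str | Path) -> None:
    df = pd.DataFrame({"rr_s": rr.intervals, "t_s": rr.beat_times})
    df.to_csv(path, index=False, float_format="%.6f")


def read_epochs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"label", "start_s", "end_s"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df[["label", "start_s", "end_s"]]


def write_epochs(df: pd.DataFrame, path: str | Path) -> None:
    df[["label", "start_s", "end_s"]].to_csv(path, index=False)
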