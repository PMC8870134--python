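"""Reading and writing trial CSVs.

A trial file has a ``time_s`` first column and one named column per
channel; EMG columns are prefixed ``emg_`` and the force column is
``force_n`` (newtons).  The sampling rate is inferred from the time
column (uniform sampling is assumed and checked loosely).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .signals import SignalTrace

__all__ = ["read_trial_csv", "write_trial_csv"]


def read_trial_csv(path: str | Path) -> dict[str, SignalTrace]:
    """Read one trial; returns channel label -> trace (force kind inferred)."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-6 * np.median(dt):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    fs = 1.0 / float(np.median(dt))
    out = {}
    for col in df.columns:
        if col == "time_s":
            continue
        kind = "force" if col.startswith("force") else "emg_raw"
        out[col] = SignalTrace(df[col].to_numpy(dtype=float), fs=fs,
                               label=col, kind=kind)
    return out


def write_trial_csv(path: str | Path, traces: dict[str, SignalTrace]) -> None:
    """Write channel traces (sharing fs and length) to a trial CSV."""
    items = list(traces.items())
    if not items:
        raise ValueError("no traces to write")
    fs, n = items[0][1].fs, len(items[0][1])
    for _, tr in items:
        if tr.fs != fs or len(tr) != n:
            raise ValueError("all traces must share sampling rate and length")
    cols = {"time_s": np.arange(n) / fs}
    for label, tr in items:
        cols[label] = tr.samples
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.8g")
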