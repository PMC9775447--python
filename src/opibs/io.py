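"""Readers and writers for the plain-text formats the pipeline consumes.

Supported inputs: one-interval-per-line text (seconds), CSV with
``beat_time_s,interval_s`` columns, single-column raw PPG CSV (sampling rate
supplied separately), and — when the optional ``wfdb`` library is installed —
a WFDB record/annotation pair for RR series.  Interval files with a median
value above 10 are interpreted as milliseconds (wearable exports vary) with a
logged notice.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import PPGSignal, PPISeries

__all__ = [
    "read_ppi",
    "read_ppg_csv",
    "read_labels",
    "write_ppi",
    "write_segments",
    "read_wfdb_rr",
]

log = logging.getLogger(__name__)

_MS_THRESHOLD = 10.0  # intervals with median above this are taken as ms


def _to_seconds(values: np.ndarray, source: str) -> np.ndarray:
    if len(values) and np.median(values) > _MS_THRESHOLD:
        log.info("%s: median interval > %g, interpreting as milliseconds",
                 source, _MS_THRESHOLD)
        return values / 1000.0
    return values


def read_ppi(path: str | Path) -> PPISeries:
    """Read a beat-interval file (plain list or ``beat_time_s,interval_s`` CSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    first = df.iloc[0].astype(str).str.lower().tolist()
    if "interval_s" in first:
        df.columns = first
        df = df.iloc[1:].astype(float)
        intervals = _to_seconds(df["interval_s"].to_numpy(), path.name)
        if "beat_time_s" in df.columns:
            t = df["beat_time_s"].to_numpy(dtype=float)
            beat_times = np.concatenate(([t[0] - intervals[0]], t))
            return PPISeries(intervals=intervals, beat_times=beat_times)
        return PPISeries(intervals=intervals)
    values = df.iloc[:, -1].to_numpy(dtype=float)
    return PPISeries(intervals=_to_seconds(values, path.name))


def read_ppg_csv(path: str | Path, fs: float) -> PPGSignal:
    """Read a single-column raw PPG waveform sampled at ``fs`` Hz."""
    samples = pd.read_csv(path, header=None, comment="#").iloc[:, 0]
    return PPGSignal(samples=samples.to_numpy(dtype=float), fs=fs)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a ``recording_id,ahi`` labels CSV."""
    df = pd.read_csv(path)
    if "recording_id" not in df.columns or "ahi" not in df.columns:
        raise ValueError(f"{path}: labels CSV needs recording_id and ahi columns")
    return df


def write_ppi(ppi: PPISeries, path: str | Path) -> None:
    path = Path(path)
    if ppi.beat_times is not None:
        pd.DataFrame(
            {"beat_time_s": ppi.beat_times[1:], "interval_s": ppi.intervals}
        ).to_csv(path, index=False)
    else:
        pd.DataFrame({"interval_s": ppi.intervals}).to_csv(path, index=False)


def write_segments(segs, out_dir: str | Path) -> list[Path]:
    """Write one cleaned-PPI CSV per segment; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, seg in enumerate(segs):
        p = out_dir / f"{segs.recording_id or 'recording'}_seg{i:03d}.csv"
        write_ppi(seg, p)
        paths.append(p)
    return paths


def read_wfdb_rr(record: str, annotator: str = "atr") -> PPISeries:
    """RR series from a WFDB record/annotation pair (requires ``wfdb``)."""
    try:
        import wfdb  # optional dependency
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise RuntimeError(
            "reading WFDB records requires the optional 'wfdb' package; "
            "install it or supply intervals as text/CSV"
        ) from exc
    ann = wfdb.rdann(record, annotator)  # pragma: no cover
    t = np.asarray(ann.sample, dtype=float) / ann.fs  # pragma: no cover
    from .preprocess import intervals_from_beats  # pragma: no cover

    return intervals_from_beats(t)  # pragma: no cover
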