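"""Adapters for on-disk dataset layouts → :class:`LabeledSeries`.

Three layouts are supported:

* ``generic_csv`` — the frame-codec CSV header (``ax, ay, az`` columns,
  optional ``label`` column with per-timestep labels);
* ``ucihar_raw`` — a directory of whitespace text files in the raw
  inertial-signal convention: one pre-windowed 128-step record per row in
  ``acc_x.txt``/``acc_y.txt``/``acc_z.txt`` plus one label per row in
  ``labels.txt`` (the engineered 561-feature files of that layout are
  ignored; the raw signals are what the pipeline consumes). Records are
  per-record-labeled and can be linearly resampled to the model window;
* ``pamap2_dat`` — space-delimited rows of (timestamp, activity id,
  heart rate, 3 IMUs × 17 channels) at 100 Hz. The chest accelerometer
  triple (0-based columns 21–23) is extracted; rows with activity id 0
  (invalid spans) are dropped; isolated missing values (gaps of at most
  10 samples) are linearly interpolated and longer gaps split the
  recording into separate segments.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .preprocess import LabeledSeries

LAYOUTS = ("generic_csv", "ucihar_raw", "pamap2_dat")

PAMAP2_TIMESTAMP_COL = 0
PAMAP2_ACTIVITY_COL = 1
PAMAP2_CHEST_ACC_COLS = (21, 22, 23)   # 16 g chest accelerometer x/y/z
PAMAP2_COLUMNS = 54
PAMAP2_MAX_GAP = 10
PAMAP2_FS = 100.0
UCIHAR_FS = 50.0
UCIHAR_STEPS = 128


def read_inertial_table(path: str, layout: str, fs: float | None = None):
    """Read ``path`` in the declared layout; returns a list of LabeledSeries."""
    if layout == "generic_csv":
        return _read_generic_csv(path, fs or 100.0)
    if layout == "ucihar_raw":
        return _read_ucihar_raw(path)
    if layout == "pamap2_dat":
        return _read_pamap2_dat(path)
    raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")


def _read_generic_csv(path: str, fs: float):
    df = pd.read_csv(path)
    for col in ("ax", "ay", "az"):
        if col not in df.columns:
            raise ValueError(f"generic_csv requires column {col!r}")
    samples = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return [LabeledSeries(samples=samples, labels=labels, fs=fs,
                          session_id=os.path.basename(path))]


def _read_ucihar_raw(directory: str):
    def load(name):
        fpath = os.path.join(directory, name)
        rows = []
        with open(fpath) as fh:
            for ln, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rows.append([float(v) for v in line.split()])
                except ValueError as exc:
                    raise ValueError(f"{fpath}: line {ln}: {exc}") from None
        return rows

    xs, ys, zs = load("acc_x.txt"), load("acc_y.txt"), load("acc_z.txt")
    with open(os.path.join(directory, "labels.txt")) as fh:
        labels = [line.strip() for line in fh if line.strip()]
    if not (len(xs) == len(ys) == len(zs) == len(labels)):
        raise ValueError("ucihar_raw: axis files and labels disagree on record count")
    records = []
    for i, (x, y, z) in enumerate(zip(xs, ys, zs)):
        if not (len(x) == len(y) == len(z)):
            raise ValueError(f"ucihar_raw: record {i} has mismatched axis lengths")
        samples = np.stack([x, y, z], axis=1)
        records.append(LabeledSeries(samples=samples, labels=labels[i],
                                     fs=UCIHAR_FS, session_id=f"record-{i}"))
    return records


def resample_records(records, t: int):
    """Linear time-resampling of per-record series to exactly ``t`` steps."""
    out = []
    for rec in records:
        x = rec.samples
        old = np.linspace(0.0, 1.0, len(x))
        new = np.linspace(0.0, 1.0, t)
        res = np.stack([np.interp(new, old, x[:, d]) for d in range(x.shape[1])], axis=1)
        out.append(LabeledSeries(samples=res, labels=rec.labels,
                                 fs=rec.fs * t / len(x), session_id=rec.session_id))
    return out


def _read_pamap2_dat(path: str):
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != PAMAP2_COLUMNS:
                raise ValueError(
                    f"{path}: line {ln}: expected {PAMAP2_COLUMNS} columns, "
                    f"got {len(parts)}")
            try:
                rows.append([float(v) for v in parts])
            except ValueError:
                raise ValueError(f"{path}: line {ln}: non-numeric value") from None
    data = np.asarray(rows)
    activity = data[:, PAMAP2_ACTIVITY_COL].astype(int)
    acc = data[:, list(PAMAP2_CHEST_ACC_COLS)]
    valid = activity != 0
    segments = []
    # contiguous runs of valid rows become candidate segments
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return segments
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    seg_no = 0
    for s, e in zip(starts, ends):
        sel = idx[s:e + 1]
        seg_acc = acc[sel]
        seg_lab = activity[sel]
        for chunk_acc, chunk_lab in _split_on_long_gaps(seg_acc, seg_lab):
            segments.append(LabeledSeries(
                samples=chunk_acc, labels=chunk_lab.astype(str), fs=PAMAP2_FS,
                session_id=f"{os.path.basename(path)}#{seg_no}"))
            seg_no += 1
    return segments


def _split_on_long_gaps(acc: np.ndarray, labels: np.ndarray):
    """Interpolate NaN gaps ≤ PAMAP2_MAX_GAP; split the series on longer ones."""
    nan_row = np.isnan(acc).any(axis=1)
    if not nan_row.any():
        yield acc, labels
        return
    # identify NaN runs
    edges = np.flatnonzero(np.diff(np.concatenate([[0], nan_row.view(np.int8), [0]])))
    runs = list(zip(edges[0::2], edges[1::2]))        # [start, end) of NaN runs
    long_runs = [(s, e) for s, e in runs if e - s > PAMAP2_MAX_GAP]
    cut_points = [0]
    for s, e in long_runs:
        cut_points += [s, e]
    cut_points.append(len(acc))
    for a, b in zip(cut_points[0::2], cut_points[1::2]):
        if b - a == 0:
            continue
        chunk = acc[a:b].copy()
        chunk_nan = np.isnan(chunk).any(axis=1)
        if chunk_nan.any():
            t = np.arange(len(chunk))
            for d in range(chunk.shape[1]):
                col = chunk[:, d]
                bad = np.isnan(col)
                if bad.all():
                    continue
                chunk[bad, d] = np.interp(t[bad], t[~bad], col[~bad])
        keep = ~np.isnan(chunk).any(axis=1)
        yield chunk[keep], labels[a:b][keep]
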