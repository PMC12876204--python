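"""Signal conditioning: denoise → window → label-filter → normalize.

The pipeline turns raw tri-axial inertial recordings into fixed-length,
z-scored windows with one activity label each:

1. zero-phase 4th-order Butterworth low-pass (default 2.5 Hz cutoff;
   human activity energy is concentrated below ~3 Hz),
2. Savitzky–Golay smoothing (window 11, polynomial order 3), which is
   exact on locally cubic signals and so preserves peaks and inflections,
3. overlapping sliding windows (default 200 steps, stride 100),
4. label-consistency filtering: windows straddling an activity
   transition are dropped,
5. per-axis z-scoring with statistics fitted on training data only
   (a ``scope="global"`` switch restores whole-dataset fitting).

Two sampling-rate presets are used throughout the package: ``hardware``
(100 Hz, so a 200-step window spans 2 s) and ``benchmark`` (20 Hz, 10 s
windows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

FS_PRESETS = {"hardware": 100.0, "benchmark": 20.0}

DEFAULT_WINDOW = 200
DEFAULT_STRIDE = 100
STD_EPS = 1e-8


@dataclass
class LabeledSeries:
    """An L×D sample matrix with per-timestep (or per-record) labels."""

    samples: np.ndarray
    labels: np.ndarray | str | int | None
    fs: float
    session_id: str = "session-0"

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.per_timestep_labels:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.samples):
                raise ValueError("per-timestep labels must match sample count")

    @property
    def per_timestep_labels(self) -> bool:
        return isinstance(self.labels, (np.ndarray, list, tuple))


@dataclass
class SampleWindow:
    values: np.ndarray          # (T, D)
    label: object               # class name or id
    source: tuple[str, int]     # (session id, start index)


@dataclass
class NormStats:
    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if np.any(self.std <= 0):
            raise ValueError("std components must be positive")


class LabelMap:
    """Bijective lexicographic mapping from class names to ids 0..K-1."""

    def __init__(self, names):
        self.names = sorted(set(str(n) for n in names))
        if not self.names:
            raise ValueError("at least one label required")
        self._to_id = {n: i for i, n in enumerate(self.names)}

    def __len__(self):
        return len(self.names)

    def encode(self, labels) -> np.ndarray:
        out = []
        for lab in np.atleast_1d(labels):
            key = str(lab)
            if key not in self._to_id:
                raise ValueError(f"unseen label {key!r}")
            out.append(self._to_id[key])
        return np.asarray(out, dtype=int)

    def decode(self, ids) -> list[str]:
        ids = np.atleast_1d(ids)
        if np.any(ids < 0) or np.any(ids >= len(self.names)):
            raise ValueError("id outside label map")
        return [self.names[int(i)] for i in ids]


def encode_labels(labels) -> tuple[np.ndarray, LabelMap]:
    lm = LabelMap(labels)
    return lm.encode(labels), lm


# ---------------------------------------------------------------------------
# denoising
# ---------------------------------------------------------------------------

def lowpass_filter(series: np.ndarray, fs: float, cutoff: float = 2.5,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass, applied per column.

    Forward-backward application (odd-reflection padding of length
    3·(order+1) at each end) cancels the phase response, so filtered
    features stay time-aligned with the raw signal.
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if cutoff <= 0 or cutoff >= fs / 2:
        raise ValueError(f"cutoff must lie in (0, fs/2) = (0, {fs / 2})")
    padlen = 3 * (order + 1)
    if x.shape[0] <= padlen:
        raise ValueError(f"series too short for zero-phase padding (need > {padlen})")
    b, a = sps.butter(order, cutoff, btype="low", fs=fs)
    y = sps.filtfilt(b, a, x, axis=0, padtype="odd", padlen=padlen)
    return y[:, 0] if squeeze else y


def savgol_smooth(series: np.ndarray, window: int = 11, polyorder: int = 3) -> np.ndarray:
    """Per-column Savitzky–Golay smoothing with polynomial edge handling."""
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if x.shape[0] < window:
        raise ValueError("series shorter than the smoothing window")
    y = sps.savgol_filter(x, window, polyorder, axis=0, mode="interp")
    return y[:, 0] if squeeze else y


def denoise(series: np.ndarray, fs: float, cutoff: float = 2.5, order: int = 4,
            sg_window: int = 11, sg_polyorder: int = 3,
            enabled: bool = True) -> np.ndarray:
    """Butterworth low-pass first, then Savitzky–Golay (fixed order)."""
    if not enabled:
        return np.asarray(series, dtype=float)
    return savgol_smooth(lowpass_filter(series, fs, cutoff, order),
                         sg_window, sg_polyorder)


# ---------------------------------------------------------------------------
# segmentation and label filtering
# ---------------------------------------------------------------------------

def window_count(length: int, t: int, stride: int) -> int:
    return (length - t) // stride + 1 if length >= t else 0


def segment_windows(series: LabeledSeries, t: int = DEFAULT_WINDOW,
                    stride: int = DEFAULT_STRIDE):
    """Half-open 0-based windows [start, start+T); short remainders dropped."""
    if t <= 0 or stride <= 0:
        raise ValueError("T and stride must be positive")
    x = series.samples
    out = []
    for w in range(window_count(len(x), t, stride)):
        start = w * stride
        if series.per_timestep_labels:
            lab_slice = np.asarray(series.labels)[start:start + t]
        else:
            lab_slice = series.labels
        out.append((x[start:start + t], lab_slice, start))
    return out


def enforce_label_consistency(windows, session_id: str = "session-0") -> list[SampleWindow]:
    """Keep only windows whose label slice is constant; assign that label."""
    kept = []
    for values, labels, start in windows:
        if isinstance(labels, np.ndarray):
            uniq = np.unique(labels)
            if len(uniq) != 1:
                continue
            label = uniq[0].item() if hasattr(uniq[0], "item") else uniq[0]
        else:
            label = labels
        kept.append(SampleWindow(values=values, label=label, source=(session_id, start)))
    return kept


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def fit_normalizer(windows) -> NormStats:
    """Per-axis mean/std over all timesteps of the given (training) windows."""
    stacked = _stack(windows)
    if stacked.shape[0] * stacked.shape[1] < 2:
        raise ValueError("need at least 2 training timesteps")
    flat = stacked.reshape(-1, stacked.shape[-1])
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    if np.any(std < STD_EPS):
        warnings.warn("constant axis detected; std clamped to epsilon", stacklevel=2)
        std = np.maximum(std, STD_EPS)
    return NormStats(mean=mean, std=std)


def apply_normalizer(stats: NormStats, windows):
    stacked = _stack(windows)
    out = (stacked - stats.mean) / stats.std
    if isinstance(windows, np.ndarray) and windows.ndim == 3:
        return out
    return [SampleWindow(values=out[i], label=w.label, source=w.source)
            for i, w in enumerate(windows)]


def _stack(windows) -> np.ndarray:
    if isinstance(windows, np.ndarray):
        return windows if windows.ndim == 3 else windows[None]
    return np.stack([w.values if isinstance(w, SampleWindow) else np.asarray(w)
                     for w in windows])


# ---------------------------------------------------------------------------
# whole pipeline
# ---------------------------------------------------------------------------

def windows_from_series(series_list, t: int = DEFAULT_WINDOW,
                        stride: int = DEFAULT_STRIDE, filter_enabled: bool = True,
                        cutoff: float = 2.5, order: int = 4,
                        sg_window: int = 11, sg_polyorder: int = 3):
    """Denoise and window every series; returns label-consistent windows.

    Normalization is *not* applied here: statistics must be fitted on the
    training portion only (see :func:`fit_normalizer`), which is the
    caller's (or the CV harness's) responsibility.
    """
    out: list[SampleWindow] = []
    for series in series_list:
        x = denoise(series.samples, series.fs, cutoff=cutoff, order=order,
                    sg_window=sg_window, sg_polyorder=sg_polyorder,
                    enabled=filter_enabled)
        conditioned = LabeledSeries(samples=x, labels=series.labels, fs=series.fs,
                                    session_id=series.session_id)
        segs = segment_windows(conditioned, t=t, stride=stride)
        out.extend(enforce_label_consistency(segs, session_id=series.session_id))
    return out


def crop_or_pad(series: LabeledSeries, t: int) -> np.ndarray:
    """Center-crop or edge-pad a per-record series to exactly T steps.

    Used for short single-label recordings (e.g. one golf swing per file)
    that are shorter or longer than the model window.
    """
    x = series.samples
    if len(x) >= t:
        start = (len(x) - t) // 2
        return x[start:start + t]
    pad_total = t - len(x)
    before = pad_total // 2
    after = pad_total - before
    return np.pad(x, ((before, after), (0, 0)), mode="edge")


def windows_to_arrays(windows, label_map: LabelMap | None = None):
    """Stack windows to (N, T, D) and encode labels; returns (X, y, map)."""
    if not windows:
        raise ValueError("no windows to stack")
    if label_map is None:
        label_map = LabelMap([w.label for w in windows])
    x = np.stack([w.values for w in windows])
    y = label_map.encode([w.label for w in windows])
    return x, y, label_map
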