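"""From annotated recordings to balanced, normalized, labeled windows.

The pipeline is: notch + band-pass filtering (zero-phase), optional
resampling, interval labeling around each seizure (pre-ictal horizon
before onset, ictal and post-ictal time excluded), tiling the labeled
intervals into non-overlapping windows, per-channel z-normalization,
class balancing by random under-sampling, and stratified splitting.
Defaults follow the clinical protocol: 50 Hz notch, 0.5–70 Hz band-pass,
1 h pre-ictal horizon, 1 h post-ictal exclusion, 10 s windows, and a
23-channel minimum.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.signal

from .io_formats import Recording
from .windows import LabeledWindow, WindowSet

INTERICTAL, PREICTAL, EXCLUDED = "interictal", "preictal", "excluded"


@dataclass(frozen=True)
class LabeledInterval:
    record_id: str
    start_s: float
    end_s: float
    label: str

    def __post_init__(self):
        if not self.start_s < self.end_s:
            raise ValueError("interval start must precede end")
        if self.label not in (INTERICTAL, PREICTAL, EXCLUDED):
            raise ValueError(f"unknown interval label {self.label!r}")


@dataclass(frozen=True)
class PreprocessConfig:
    notch_hz: float = 50.0
    band_hz: tuple[float, float] = (0.5, 70.0)
    preictal_horizon_s: float = 3600.0
    postictal_exclusion_s: float = 3600.0
    window_s: float = 10.0
    min_channels: int = 23
    balance_seed: int = 0
    notch_q: float = 30.0
    band_order: int = 4
    resample_hz: float | None = None

    def __post_init__(self):
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError("band_hz must satisfy 0 < low < high")
        if self.preictal_horizon_s <= self.window_s:
            raise ValueError("pre-ictal horizon must exceed the window length")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# filtering


def apply_filters(recording: Recording, config: PreprocessConfig) -> Recording:
    """Zero-phase notch (Q=30) + Butterworth band-pass, forward-backward."""
    lo, hi = config.band_hz
    fs = recording.fs
    if fs <= 2.0 * hi:
        raise ValueError(
            f"sampling rate {fs} Hz cannot support a band-pass to {hi} Hz "
            "(need fs > 2 * band high)")
    data = np.asarray(recording.data, dtype=np.float64)
    if config.notch_hz:
        b, a = scipy.signal.iirnotch(config.notch_hz, config.notch_q, fs=fs)
        data = scipy.signal.filtfilt(b, a, data, axis=-1)
    sos = scipy.signal.butter(config.band_order, [lo, hi], btype="bandpass",
                              fs=fs, output="sos")
    data = scipy.signal.sosfiltfilt(sos, data, axis=-1)
    out_fs = fs
    if config.resample_hz and config.resample_hz != fs:
        new = float(config.resample_hz)
        if new <= 2.0 * hi:
            raise ValueError("resample_hz must stay above 2 * band high")
        up, down = (np.array([new, fs]) /
                    np.gcd(int(round(new)), int(round(fs)))).astype(int)
        data = scipy.signal.resample_poly(data, up, down, axis=-1)
        out_fs = new
    return Recording(subject_id=recording.subject_id, data=data, fs=out_fs,
                     channel_names=list(recording.channel_names),
                     annotations=list(recording.annotations),
                     record_id=recording.record_id)


# ---------------------------------------------------------------------------
# interval labeling


def label_intervals(recording: Recording,
                    config: PreprocessConfig) -> list[LabeledInterval]:
    """Partition the record into pre-ictal / excluded / inter-ictal time.

    For each seizure onset t: ``[t - horizon, t)`` is pre-ictal (clipped
    at the record start and at the previous seizure's exclusion end);
    ``[onset, offset + postictal_exclusion_s)`` is excluded; everything
    else is inter-ictal. A record without seizures is one inter-ictal
    interval.
    """
    dur = recording.duration_s
    rid = recording.record_id
    marks: list[tuple[float, float, str]] = []
    prev_excl_end = 0.0
    for ann in recording.annotations:
        pre_start = max(ann.onset_s - config.preictal_horizon_s, 0.0,
                        prev_excl_end)
        if pre_start < ann.onset_s:
            marks.append((pre_start, ann.onset_s, PREICTAL))
        excl_end = min(ann.offset_s + config.postictal_exclusion_s, dur)
        marks.append((ann.onset_s, excl_end, EXCLUDED))
        prev_excl_end = excl_end

    out: list[LabeledInterval] = []
    cursor = 0.0
    for start, end, label in sorted(marks):
        if start > cursor:
            out.append(LabeledInterval(rid, cursor, start, INTERICTAL))
        out.append(LabeledInterval(rid, start, end, label))
        cursor = max(cursor, end)
    if cursor < dur:
        out.append(LabeledInterval(rid, cursor, dur, INTERICTAL))
    return out


# ---------------------------------------------------------------------------
# windowing and normalization


def extract_windows(recording: Recording, intervals: list[LabeledInterval],
                    config: PreprocessConfig) -> WindowSet:
    """Tile labeled intervals left-to-right with non-overlapping windows.

    Partial trailing segments are discarded; excluded intervals yield
    nothing.
    """
    fs = recording.fs
    wlen = int(round(config.window_s * fs))
    xs, ys, starts = [], [], []
    for iv in intervals:
        if iv.label == EXCLUDED:
            continue
        n_fit = int(np.floor((iv.end_s - iv.start_s) / config.window_s))
        label = 1 if iv.label == PREICTAL else 0
        for i in range(n_fit):
            t0 = iv.start_s + i * config.window_s
            a = int(round(t0 * fs))
            xs.append(recording.data[:, a:a + wlen])
            ys.append(label)
            starts.append(t0)
    if not xs:
        return WindowSet.empty(recording.n_channels, wlen, fs,
                               config.window_s, config.hash())
    return WindowSet(np.stack(xs), np.array(ys),
                     [recording.subject_id] * len(xs),
                     [recording.record_id] * len(xs), starts,
                     fs=fs, window_s=config.window_s,
                     config_hash=config.hash())


def normalize_window(window: LabeledWindow) -> LabeledWindow:
    """Per-channel zero mean, unit standard deviation; constant -> zeros."""
    x = np.asarray(window.x, dtype=np.float64)
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    out = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return LabeledWindow(window.subject_id, window.record_id, window.start_s,
                         out, window.y)


def normalize_windows(windows: WindowSet) -> WindowSet:
    x = windows.X.astype(np.float64)
    mu = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    out = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return WindowSet(out, windows.y, windows.subject_ids, windows.record_ids,
                     windows.start_s, windows.fs, windows.window_s,
                     windows.config_hash)


# ---------------------------------------------------------------------------
# balancing and splitting


def balance_undersample(windows: WindowSet, seed: int) -> WindowSet:
    """Equalize class counts by uniform random majority under-sampling."""
    n0, n1 = windows.class_counts()
    if n0 == 0 or n1 == 0:
        missing = "inter-ictal" if n0 == 0 else "pre-ictal"
        records = sorted(set(windows.record_ids))
        raise ValueError(
            f"cannot balance: no {missing} windows present (records: "
            f"{records})")
    if n0 == n1:
        return windows
    rng = np.random.default_rng(seed)
    maj = 0 if n0 > n1 else 1
    keep_min = np.nonzero(windows.y != maj)[0]
    maj_idx = np.nonzero(windows.y == maj)[0]
    keep_maj = rng.choice(maj_idx, size=min(n0, n1), replace=False)
    idx = np.sort(np.concatenate([keep_min, keep_maj]))
    return windows.subset(idx)


def split_multisubject(windows: WindowSet, fractions: tuple[float, float, float],
                       seed: int) -> tuple[WindowSet, WindowSet, WindowSet]:
    """Stratified (by class) disjoint, exhaustive train/val/test split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for cls in (0, 1):
        idx = np.nonzero(windows.y == cls)[0]
        rng.shuffle(idx)
        n = len(idx)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        n_va = min(n_va, n - n_tr)
        parts[0].append(idx[:n_tr])
        parts[1].append(idx[n_tr:n_tr + n_va])
        parts[2].append(idx[n_tr + n_va:])
    splits = []
    for i, p in enumerate(parts):
        sel = np.sort(np.concatenate(p))
        if fractions[i] > 0 and len(sel) == 0:
            raise ValueError(
                f"split {i} is empty under fractions {fractions} with "
                f"{len(windows)} windows")
        splits.append(windows.subset(sel))
    return tuple(splits)


# ---------------------------------------------------------------------------
# pipeline


def windows_from_recording(recording: Recording,
                           config: PreprocessConfig) -> WindowSet:
    """filters -> label -> window -> normalize, for one recording."""
    if recording.n_channels < config.min_channels:
        raise ValueError(
            f"recording {recording.record_id} has {recording.n_channels} "
            f"channels, fewer than the configured minimum "
            f"{config.min_channels}")
    filtered = apply_filters(recording, config)
    intervals = label_intervals(filtered, config)
    ws = extract_windows(filtered, intervals, config)
    return normalize_windows(ws)


def prepare_cohort(recordings: list[Recording], config: PreprocessConfig,
                   balance_per_subject: bool = True) -> WindowSet:
    """Windows for a whole cohort, optionally balanced within each subject."""
    sets = []
    for rec in recordings:
        ws = windows_from_recording(rec, config)
        if balance_per_subject and len(ws):
            ws = balance_undersample(ws, seed=config.balance_seed)
        sets.append(ws)
    return WindowSet.concat(sets)
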