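"""Reading and writing the file formats the pipeline touches.

* EDF recordings — read through :mod:`mne`; written with a small built-in
  16-bit EDF writer (one-second data records) so synthetic cohorts can
  exercise the same path real PhysioNet data would take.
* Seizure annotations — one canonical CSV schema with columns
  ``record_id,onset_s,offset_s``; a convenience parser for CHB-MIT
  ``-summary.txt`` files normalizes into the same rows.
* Window archives — compressed NumPy archives carrying tensors, labels,
  provenance, and the preprocessing-config hash.

All times are seconds from recording start; intervals are half-open
``[onset, offset)``. Signals are microvolts as declared by EDF headers.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .windows import WindowSet


@dataclass(frozen=True, order=True)
class SeizureAnnotation:
    onset_s: float
    offset_s: float

    def __post_init__(self):
        if not self.onset_s < self.offset_s:
            raise ValueError(
                f"annotation onset {self.onset_s} must precede offset "
                f"{self.offset_s}")
        if self.onset_s < 0:
            raise ValueError("annotation onset must be non-negative")


@dataclass
class Recording:
    """One subject's continuous multichannel EEG."""

    subject_id: str
    data: np.ndarray                       # channels x samples, microvolts
    fs: float
    channel_names: list[str]
    annotations: list[SeizureAnnotation] = field(default_factory=list)
    record_id: str = ""

    def __post_init__(self):
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data rows must match channel_names")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.record_id:
            self.record_id = self.subject_id
        dur = self.duration_s
        prev_end = 0.0
        for a in sorted(self.annotations):
            if a.onset_s < prev_end:
                raise ValueError("annotations overlap or are unsorted")
            if a.offset_s > dur + 1e-9:
                raise ValueError(
                    f"annotation [{a.onset_s}, {a.offset_s}) exceeds "
                    f"recording duration {dur}")
            prev_end = a.offset_s
        self.annotations = sorted(self.annotations)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs


# ---------------------------------------------------------------------------
# EDF


def _pad(text: str, width: int) -> bytes:
    b = str(text)[:width].encode("ascii")
    return b + b" " * (width - len(b))


def write_edf(recording: Recording, path) -> None:
    """Write a plain EDF file: 16-bit samples, one-second data records."""
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    data = np.asarray(recording.data, dtype=np.float64)
    ns, n_ch = data.shape[1], recording.n_channels
    n_records = ns // fs
    if n_records * fs != ns:
        data = data[:, :n_records * fs]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((data - pmin[:, None]) / scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad(recording.subject_id, 80),
        _pad(recording.record_id, 80),
        _pad("01.01.00", 8), _pad("00.00.00", 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),                      # record duration, seconds
        _pad(str(n_ch), 4),
    ])
    fields = [
        [_pad(name, 16) for name in recording.channel_names],
        [_pad("", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{v:.8g}", 8) for v in pmin],
        [_pad(f"{v:.8g}", 8) for v in pmax],
        [_pad(str(dmin), 8)] * n_ch,
        [_pad(str(dmax), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(fs), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.writelines(group)
        # interleave: per record, per channel, fs samples
        view = digital[:, :n_records * fs].reshape(n_ch, n_records, fs)
        fh.write(np.ascontiguousarray(view.transpose(1, 0, 2)).tobytes())


def _edf_header_channels(path) -> tuple[str, list[str], list[int]]:
    """Patient field, channel labels and per-record sample counts from the
    raw header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_ch = int(head[252:256].decode("ascii").strip())
        sig = fh.read(256 * n_ch)
    patient = head[8:88].decode("ascii", "replace").strip()
    labels = [sig[16 * i:16 * (i + 1)].decode("ascii", "replace").strip()
              for i in range(n_ch)]
    off = (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80) * n_ch
    counts = [int(sig[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip())
              for i in range(n_ch)]
    return patient, labels, counts


def read_edf(path, montage: list[str] | None = None, min_channels: int = 1,
             annotations: list[SeizureAnnotation] | None = None,
             subject_id: str | None = None) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (microvolts).

    Channels are returned in montage order when ``montage`` is given;
    channels not on the montage are dropped. Recordings whose selected
    channel count falls below ``min_channels`` are rejected, as are files
    whose selected channels carry different sampling rates.
    """
    import mne

    patient, labels, counts = _edf_header_channels(path)
    data_ch = [(l, c) for l, c in zip(labels, counts)
               if l.lower() not in ("edf annotations", "bdf annotations")]
    if montage is not None:
        selected = [(l, c) for l, c in data_ch if l in montage]
        selected.sort(key=lambda lc: montage.index(lc[0]))
    else:
        selected = data_ch
    rates = {c for _, c in selected}
    if len(rates) > 1:
        by_rate = {r: [l for l, c in selected if c == r] for r in rates}
        raise ValueError(
            f"selected channels have mixed sampling rates: {by_rate}")
    if len(selected) < min_channels:
        raise ValueError(
            f"recording has {len(selected)} usable channels, fewer than the "
            f"configured minimum of {min_channels}")

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = [l for l, _ in selected]
    picked = raw.get_data(picks=names) * 1e6        # volts -> microvolts
    sid = subject_id or patient or Path(path).stem
    return Recording(subject_id=sid, data=picked, fs=float(raw.info["sfreq"]),
                     channel_names=names,
                     annotations=list(annotations or []),
                     record_id=Path(path).stem)


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path) -> pd.DataFrame:
    """Read the canonical annotation CSV (record_id, onset_s, offset_s).

    Rows are validated and returned sorted by (record_id, onset_s); an
    empty file yields an empty table (a record without seizures).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["record_id", "onset_s", "offset_s"])
    if df.empty:
        return pd.DataFrame(columns=["record_id", "onset_s", "offset_s"])
    required = {"record_id", "onset_s", "offset_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation file must have columns {sorted(required)}")
    for i, row in df.iterrows():
        if not row["onset_s"] < row["offset_s"]:
            raise ValueError(
                f"row {i}: offset {row['offset_s']} must exceed onset "
                f"{row['onset_s']}")
    return df.sort_values(["record_id", "onset_s"]).reset_index(drop=True)


def annotations_for(table: pd.DataFrame, record_id: str) -> list[SeizureAnnotation]:
    sub = table[table["record_id"] == record_id]
    return [SeizureAnnotation(float(r.onset_s), float(r.offset_s))
            for r in sub.itertuples()]


def write_annotations(rows: list[tuple[str, float, float]], path) -> None:
    pd.DataFrame(rows, columns=["record_id", "onset_s", "offset_s"]).to_csv(
        path, index=False)


_CHB_START = re.compile(r"Seizure(?: \d+)? Start Time:\s*(\d+)\s*seconds", re.I)
_CHB_END = re.compile(r"Seizure(?: \d+)? End Time:\s*(\d+)\s*seconds", re.I)
_CHB_FILE = re.compile(r"File Name:\s*(\S+)", re.I)


def parse_chbmit_summary(path) -> pd.DataFrame:
    """Normalize a CHB-MIT ``-summary.txt`` listing into the canonical table."""
    rows: list[tuple[str, float, float]] = []
    record = None
    starts: list[float] = []
    with open(path) as fh:
        for line in fh:
            m = _CHB_FILE.search(line)
            if m:
                record = Path(m.group(1)).stem
                starts = []
                continue
            m = _CHB_START.search(line)
            if m:
                starts.append(float(m.group(1)))
                continue
            m = _CHB_END.search(line)
            if m and record is not None and starts:
                rows.append((record, starts.pop(0), float(m.group(1))))
    df = pd.DataFrame(rows, columns=["record_id", "onset_s", "offset_s"])
    return df.sort_values(["record_id", "onset_s"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# window archives


def save_windows(windows: WindowSet, path) -> None:
    """Lossless archive of a window set (compressed .npz)."""
    meta = {"fs": windows.fs, "window_s": windows.window_s,
            "config_hash": windows.config_hash}
    np.savez_compressed(
        path, X=windows.X, y=windows.y,
        subject_ids=np.asarray(windows.subject_ids, dtype=str),
        record_ids=np.asarray(windows.record_ids, dtype=str),
        start_s=windows.start_s, meta=json.dumps(meta))


def load_windows(path) -> WindowSet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return WindowSet(z["X"], z["y"], z["subject_ids"].astype(object),
                         z["record_ids"].astype(object), z["start_s"],
                         fs=meta["fs"], window_s=meta["window_s"],
                         config_hash=meta["config_hash"])
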