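"""Labeled-window containers shared by preprocessing, training and I/O."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np


@dataclass
class LabeledWindow:
    """One fixed-duration EEG segment with class label and provenance."""

    subject_id: str
    record_id: str
    start_s: float
    x: np.ndarray          # (channels, samples)
    y: int                 # 0 = inter-ictal, 1 = pre-ictal


class WindowSet:
    """A columnar collection of labeled windows.

    Stores the window tensors as one (n, C, T) array plus parallel label
    and provenance columns, with the hash of the preprocessing
    configuration that produced them so incompatible sets cannot be mixed.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, subject_ids, record_ids,
                 start_s, fs: float, window_s: float,
                 config_hash: str | None = None):
        self.X = np.asarray(X, dtype=np.float32)
        self.y = np.asarray(y, dtype=np.int64)
        self.subject_ids = np.asarray(subject_ids, dtype=object)
        self.record_ids = np.asarray(record_ids, dtype=object)
        self.start_s = np.asarray(start_s, dtype=np.float64)
        self.fs = float(fs)
        self.window_s = float(window_s)
        self.config_hash = config_hash
        n = len(self.X)
        if not (len(self.y) == len(self.subject_ids) == len(self.record_ids)
                == len(self.start_s) == n):
            raise ValueError("column lengths disagree")

    # -- basics -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.X)

    def __iter__(self):
        for i in range(len(self)):
            yield LabeledWindow(self.subject_ids[i], self.record_ids[i],
                                float(self.start_s[i]), self.X[i],
                                int(self.y[i]))

    @classmethod
    def empty(cls, n_channels: int, n_samples: int, fs: float,
              window_s: float, config_hash=None) -> "WindowSet":
        return cls(np.empty((0, n_channels, n_samples), dtype=np.float32),
                   np.empty(0, dtype=np.int64), [], [], [],
                   fs, window_s, config_hash)

    def subset(self, idx) -> "WindowSet":
        idx = np.asarray(idx)
        if idx.dtype != bool:
            idx = idx.astype(np.intp)
        return WindowSet(self.X[idx], self.y[idx], self.subject_ids[idx],
                         self.record_ids[idx], self.start_s[idx],
                         self.fs, self.window_s, self.config_hash)

    @classmethod
    def concat(cls, sets: list["WindowSet"]) -> "WindowSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        first = sets[0]
        for s in sets[1:]:
            if s.config_hash != first.config_hash:
                raise ValueError(
                    "refusing to merge window sets with different "
                    f"preprocessing hashes ({s.config_hash!r} vs "
                    f"{first.config_hash!r})")
            if s.X.shape[1:] != first.X.shape[1:]:
                raise ValueError(
                    f"refusing to merge window sets with different window "
                    f"shapes ({s.X.shape[1:]} vs {first.X.shape[1:]})")
        return cls(np.concatenate([s.X for s in sets]),
                   np.concatenate([s.y for s in sets]),
                   np.concatenate([s.subject_ids for s in sets]),
                   np.concatenate([s.record_ids for s in sets]),
                   np.concatenate([s.start_s for s in sets]),
                   first.fs, first.window_s, first.config_hash)

    # -- bookkeeping ----------------------------------------------------------

    def class_counts(self) -> tuple[int, int]:
        return int((self.y == 0).sum()), int((self.y == 1).sum())

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(s)
        return list(seen)

    def for_subject(self, subject_id: str) -> "WindowSet":
        return self.subset(np.nonzero(self.subject_ids == subject_id)[0])

    def not_subject(self, subject_id: str) -> "WindowSet":
        return self.subset(np.nonzero(self.subject_ids != subject_id)[0])

    def window_hashes(self) -> set[str]:
        """Content hash per window, for leakage audits between folds."""
        return {hashlib.sha1(np.ascontiguousarray(w).tobytes()).hexdigest()
                for w in self.X}

    def batches(self, batch_size: int, rng: np.random.Generator):
        idx = rng.permutation(len(self))
        for i in range(0, len(idx), batch_size):
            j = idx[i:i + batch_size]
            yield self.X[j][:, None, :, :], self.y[j]
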