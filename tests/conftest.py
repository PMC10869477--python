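"""Shared fixtures: small deterministic window sets and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from seizadapt.windows import WindowSet


def make_toy_windows(n_per_class: int = 40, subjects: tuple[str, ...] = ("A",),
                     C: int = 2, T: int = 256, fs: float = 25.6,
                     seed: int = 0, tone_amp: float = 2.0,
                     subject_tone_hz: dict[str, float] | None = None
                     ) -> WindowSet:
    """Small labeled windows: class 1 carries an extra sinusoid.

    ``subject_tone_hz`` gives each subject a different class-tone frequency
    (a crude stand-in for between-subject shift).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(T) / fs
    xs, ys, sids = [], [], []
    for sid in subjects:
        f0 = (subject_tone_hz or {}).get(sid, 4.0)
        for cls in (0, 1):
            for _ in range(n_per_class):
                x = rng.standard_normal((C, T))
                if cls == 1:
                    phase = rng.uniform(0, 2 * np.pi)
                    x = x + tone_amp * np.sin(2 * np.pi * f0 * t + phase)
                xs.append(x)
                ys.append(cls)
                sids.append(sid)
    n = len(xs)
    return WindowSet(np.stack(xs), np.array(ys), sids,
                     [f"{s}-r01" for s in sids],
                     np.arange(n, dtype=float) * (T / fs),
                     fs=fs, window_s=T / fs, config_hash="toy")


@pytest.fixture
def toy_windows() -> WindowSet:
    return make_toy_windows(n_per_class=40, seed=1)


@pytest.fixture
def toy_windows_multi() -> WindowSet:
    return make_toy_windows(
        n_per_class=30, subjects=("A", "B", "C"), seed=2,
        subject_tone_hz={"A": 3.5, "B": 4.0, "C": 4.5})
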