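"""Synthetic multi-subject EEG-like cohorts with known ground truth.

The generator produces, per subject, band-limited multichannel noise with

* a pink (1/f) broadband background,
* a subject-specific narrow-band oscillation at an alpha-like peak
  (8–13 Hz), the main carrier of between-subject spectral idiosyncrasy,
* a class-dependent band-limited component whose power is multiplied by
  ``preictal_gain**2`` during pre-ictal intervals — the signal a
  band-power-sensitive classifier can learn,
* short high-amplitude broadband bursts during annotated ictal intervals
  (so interval exclusion logic has something to exclude; waveform realism
  is a non-goal),

all mixed across channels by a per-subject near-orthonormal mixing
matrix. The inter-subject dispersion of every parameter scales with
``shift_strength``: at 0 all subjects share identical parameters and one
common mixing matrix (identically distributed subjects); at 1 background
peaks, gains, noise levels and mixing matrices are fully subject-specific
while the pre-ictal band stays largely shared, so a domain-invariant
class feature exists for adaptation methods to find.

Seed hierarchy: ``master_seed`` spawns one independent stream per subject
index, so adding a subject never perturbs existing subjects' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

from .io_formats import Recording, SeizureAnnotation

SUPPORTED_FS = (256, 512)
#: RMS amplitude of the class-dependent band component during inter-ictal
#: time (microvolt-scale units, same scale as noise_sd).
BAND_RMS = 2.0
ICTAL_DURATION_S = 20.0
ICTAL_GAIN = 5.0
#: quiet tail after each seizure block, seconds
POST_SEIZURE_TAIL_S = 60.0


@dataclass
class SubjectParams:
    """Ground-truth generative parameters of one synthetic subject."""

    subject_id: str
    mixing_matrix_seed: int
    background_peak_hz: float
    background_gain: float
    preictal_band: tuple[float, float]
    preictal_gain: float
    noise_sd: float
    # plumbing for the shift interpolation: the realized mixing matrix is
    # orth((1 - mixing_blend) * M(base) + mixing_blend * M(subject seed))
    mixing_blend: float = 1.0
    base_mixing_seed: int = 0

    def __post_init__(self):
        lo, hi = self.preictal_band
        if not lo < hi:
            raise ValueError("preictal_band low must be below high")
        if not (0.5 < lo and hi < 70.0):
            raise ValueError(
                "preictal_band must lie within (0.5, 70) Hz so the class "
                "signal survives the band-pass filter")
        if self.background_gain <= 0 or self.noise_sd <= 0:
            raise ValueError("gains and noise_sd must be positive")
        if self.preictal_gain <= 0:
            raise ValueError("preictal_gain must be positive")


@dataclass
class CohortConfig:
    n_subjects: int
    n_channels: int = 23
    sampling_rate_hz: int = 256
    record_duration_s: float = 7200.0
    seizures_per_subject: int = 1
    shift_strength: float = 0.0
    master_seed: int = 0
    preictal_horizon_s: float = 3600.0
    preictal_gain: float = 2.0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError(
                "a cohort needs at least 2 subjects (cross-subject "
                "protocols are undefined otherwise)")
        if not 0.0 <= self.shift_strength <= 1.0:
            raise ValueError("shift_strength must lie in [0, 1]")
        if self.seizures_per_subject > 0:
            block = (self.preictal_horizon_s + ICTAL_DURATION_S
                     + POST_SEIZURE_TAIL_S)
            if self.record_duration_s < self.seizures_per_subject * block:
                raise ValueError(
                    f"record_duration_s={self.record_duration_s} too short "
                    f"for {self.seizures_per_subject} seizures with "
                    f"non-overlapping {self.preictal_horizon_s} s pre-ictal "
                    "horizons")


def default_seizure_times(duration_s: float, n_seizures: int,
                          horizon_s: float) -> list[SeizureAnnotation]:
    """Place seizures in back-to-back blocks ending at the record's end.

    Each block is [horizon][ictal][tail]; the leading remainder of the
    record is seizure-free (inter-ictal) time.
    """
    block = horizon_s + ICTAL_DURATION_S + POST_SEIZURE_TAIL_S
    out = []
    for k in range(n_seizures):
        onset = duration_s - (n_seizures - k) * block + horizon_s
        out.append(SeizureAnnotation(onset, onset + ICTAL_DURATION_S))
    return out


def _orthonormal(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def mixing_matrix(params: SubjectParams, n_channels: int) -> np.ndarray:
    base = _orthonormal(params.base_mixing_seed, n_channels)
    own = _orthonormal(params.mixing_matrix_seed, n_channels)
    blend = ((1.0 - params.mixing_blend) * base
             + params.mixing_blend * own)
    q, r = np.linalg.qr(blend)
    return q * np.sign(np.diag(r))


def _filtered_noise(rng, n_samples: int, fs: float, gain_fn) -> np.ndarray:
    """Unit-variance noise with spectrum shaped by ``gain_fn(freqs)``."""
    white = rng.standard_normal(n_samples)
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = gain_fn(f)
    spec = sfft.rfft(white) * shape
    x = sfft.irfft(spec, n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_subject_recording(params: SubjectParams, duration_s: float,
                               fs: int, seed: int, n_channels: int = 23,
                               seizure_times: list[SeizureAnnotation] | None = None,
                               preictal_horizon_s: float = 3600.0,
                               ) -> Recording:
    """Simulate one subject's continuous recording with annotations.

    The pre-ictal gain is applied on ``[onset - preictal_horizon_s, onset)``
    for every seizure; outputs are a pure function of (params, seed).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs not in SUPPORTED_FS:
        raise ValueError(f"unsupported sampling rate {fs}; expected one of "
                         f"{SUPPORTED_FS}")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if seizure_times is None:
        seizure_times = []

    t = np.arange(n) / fs
    # class gain envelope: preictal_gain during pre-ictal spans, else 1
    env = np.ones(n)
    burst = np.zeros(n, dtype=bool)
    for ann in seizure_times:
        pre_start = max(ann.onset_s - preictal_horizon_s, 0.0)
        env[(t >= pre_start) & (t < ann.onset_s)] = params.preictal_gain
        burst[(t >= ann.onset_s) & (t < ann.offset_s)] = True

    lo, hi = params.preictal_band
    peak = params.background_peak_hz
    sources = np.empty((n_channels, n), dtype=np.float64)
    for ch in range(n_channels):
        pink = _filtered_noise(
            rng, n, fs, lambda f: 1.0 / np.sqrt(np.maximum(f, 1.0)))
        osc = _filtered_noise(
            rng, n, fs, lambda f: np.exp(-0.5 * ((f - peak) / 1.0) ** 2))
        band = _filtered_noise(
            rng, n, fs, lambda f: ((f >= lo) & (f < hi)).astype(float))
        s = (params.noise_sd * pink
             + params.background_gain * osc
             + BAND_RMS * env * band)
        if burst.any():
            s = s + np.where(burst,
                             ICTAL_GAIN * params.noise_sd
                             * rng.standard_normal(n), 0.0)
        sources[ch] = s

    M = mixing_matrix(params, n_channels)
    data = M @ sources
    names = [f"SYN{ch:02d}" for ch in range(n_channels)]
    return Recording(subject_id=params.subject_id, data=data, fs=float(fs),
                     channel_names=names, annotations=list(seizure_times),
                     record_id=f"{params.subject_id}-r01")


def draw_subject_params(config: CohortConfig) -> list[SubjectParams]:
    """Per-subject parameters with dispersion scaled by ``shift_strength``."""
    s = config.shift_strength
    out = []
    for k in range(config.n_subjects):
        ss = np.random.SeedSequence([config.master_seed, k, 17])
        rng = np.random.default_rng(ss)
        u = rng.uniform(-1.0, 1.0, size=5)
        # The class band (centered 12 Hz) overlaps the alpha-like background
        # peak (8-13 Hz): under shift, per-subject background gain and peak
        # confound absolute in-band power, so cross-subject transfer must
        # rely on subject-invariant contrasts -- the structure that makes
        # domain adaptation meaningful.
        center = 12.0 + 1.0 * s * u[3]
        out.append(SubjectParams(
            subject_id=f"S{k + 1:02d}",
            mixing_matrix_seed=int(
                np.random.SeedSequence([config.master_seed, k, 23])
                .generate_state(1)[0] % (2 ** 31)),
            background_peak_hz=10.5 + 2.5 * s * u[0],
            background_gain=1.5 * (1.0 + 0.8 * s * u[1]),
            preictal_band=(center - 4.0, center + 4.0),
            preictal_gain=config.preictal_gain,
            noise_sd=1.0 * (1.0 + 0.5 * s * u[2]),
            mixing_blend=s,
            base_mixing_seed=int(
                np.random.SeedSequence([config.master_seed, 1000003])
                .generate_state(1)[0] % (2 ** 31)),
        ))
    return out


def generate_cohort(config: CohortConfig) -> list[Recording]:
    """One recording per subject; dispersion scales with shift_strength."""
    params = draw_subject_params(config)
    seiz = default_seizure_times(config.record_duration_s,
                                 config.seizures_per_subject,
                                 config.preictal_horizon_s)
    recordings = []
    for k, p in enumerate(params):
        seed = int(np.random.SeedSequence([config.master_seed, k, 31])
                   .generate_state(1)[0] % (2 ** 31))
        recordings.append(generate_subject_recording(
            p, config.record_duration_s, config.sampling_rate_hz, seed,
            n_channels=config.n_channels, seizure_times=seiz,
            preictal_horizon_s=config.preictal_horizon_s))
    return recordings
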