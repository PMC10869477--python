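"""Filtering, interval labeling, windowing, normalization, balancing,
splitting — the clinical preprocessing contracts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seizadapt.io_formats import Recording, SeizureAnnotation
from seizadapt.preprocess import (EXCLUDED, INTERICTAL, PREICTAL,
                                  LabeledInterval, PreprocessConfig,
                                  apply_filters, balance_undersample,
                                  extract_windows, label_intervals,
                                  normalize_window, normalize_windows,
                                  split_multisubject, windows_from_recording)
from seizadapt.windows import LabeledWindow, WindowSet
from tests.conftest import make_toy_windows


def recording_of(data, fs=256.0, anns=()):
    return Recording("S01", np.atleast_2d(data), fs,
                     [f"c{i}" for i in range(np.atleast_2d(data).shape[0])],
                     annotations=list(anns))


def sine(freq, dur=10.0, fs=256.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


# ---------------------------------------------------------------------------
# filtering


def test_notch_attenuates_50hz_by_20db():
    rec = recording_of(sine(50.0))
    out = apply_filters(rec, PreprocessConfig(min_channels=1))
    core = slice(256, -256)        # ignore filter edge transients
    atten_db = 20 * np.log10(np.std(out.data[0][core]) /
                             np.std(rec.data[0][core]))
    assert atten_db <= -20.0


def test_passband_10hz_within_1db():
    rec = recording_of(sine(10.0))
    out = apply_filters(rec, PreprocessConfig(min_channels=1))
    core = slice(256, -256)
    gain_db = 20 * np.log10(np.std(out.data[0][core]) /
                            np.std(rec.data[0][core]))
    assert abs(gain_db) <= 1.0


def test_dc_channel_removed_by_highpass():
    rec = recording_of(np.full(2560, 7.0))
    out = apply_filters(rec, PreprocessConfig(min_channels=1))
    assert np.abs(out.data).max() < 0.1


def test_low_sampling_rate_rejected():
    rec = recording_of(np.zeros(1280), fs=128.0)
    with pytest.raises(ValueError, match="band-pass"):
        apply_filters(rec, PreprocessConfig(min_channels=1))
    # 512 Hz passes
    apply_filters(recording_of(np.zeros(5120), fs=512.0),
                  PreprocessConfig(min_channels=1))


def test_filtering_is_zero_phase():
    """A 10 Hz burst keeps its temporal location (no group delay)."""
    x = np.zeros(2560)
    x[1000:1500] = sine(10.0)[1000:1500]
    out = apply_filters(recording_of(x), PreprocessConfig(min_channels=1))
    assert np.argmax(np.abs(out.data[0])) == pytest.approx(
        np.argmax(np.abs(x)), abs=30)


def test_resampling_halves_samples():
    cfg = PreprocessConfig(min_channels=1, band_hz=(0.5, 60.0),
                           resample_hz=128.0)
    out = apply_filters(recording_of(np.random.default_rng(0)
                                     .standard_normal(2560)), cfg)
    assert out.fs == 128.0
    assert out.data.shape[1] == 1280


# ---------------------------------------------------------------------------
# interval labeling


def by_label(intervals, label):
    return [(iv.start_s, iv.end_s) for iv in intervals if iv.label == label]


def test_single_seizure_with_one_hour_horizon():
    """8000 s record, seizure [5000, 5030): pre-ictal [1400, 5000),
    excluded [5000, 8000), inter-ictal [0, 1400)."""
    rec = recording_of(np.zeros(8000 * 4), fs=4.0,
                       anns=[SeizureAnnotation(5000.0, 5030.0)])
    cfg = PreprocessConfig(min_channels=1)       # 3600 s horizon + exclusion
    ivs = label_intervals(rec, cfg)
    assert by_label(ivs, PREICTAL) == [(1400.0, 5000.0)]
    assert by_label(ivs, EXCLUDED) == [(5000.0, 8000.0)]
    assert by_label(ivs, INTERICTAL) == [(0.0, 1400.0)]


def test_no_seizures_is_one_interictal_interval():
    rec = recording_of(np.zeros(1000 * 4), fs=4.0)
    ivs = label_intervals(rec, PreprocessConfig(min_channels=1))
    assert [(iv.start_s, iv.end_s, iv.label) for iv in ivs] == [
        (0.0, 1000.0, INTERICTAL)]


def test_early_seizure_clips_preictal_at_record_start():
    rec = recording_of(np.zeros(8000 * 4), fs=4.0,
                       anns=[SeizureAnnotation(1800.0, 1830.0)])
    ivs = label_intervals(rec, PreprocessConfig(min_channels=1))
    assert by_label(ivs, PREICTAL) == [(0.0, 1800.0)]


def test_consecutive_seizures_preictal_clipped_at_previous_exclusion():
    """The second pre-ictal horizon starts where the first seizure's
    post-ictal exclusion ends."""
    anns = [SeizureAnnotation(2000.0, 2030.0),
            SeizureAnnotation(4000.0, 4030.0)]
    cfg = PreprocessConfig(min_channels=1, preictal_horizon_s=3600.0,
                           postictal_exclusion_s=1000.0)
    rec = recording_of(np.zeros(8000 * 4), fs=4.0, anns=anns)
    ivs = label_intervals(rec, cfg)
    assert by_label(ivs, PREICTAL) == [(0.0, 2000.0), (3030.0, 4000.0)]
    assert by_label(ivs, EXCLUDED) == [(2000.0, 3030.0), (4000.0, 5030.0)]
    assert by_label(ivs, INTERICTAL) == [(5030.0, 8000.0)]


def test_intervals_are_disjoint_and_exhaustive():
    anns = [SeizureAnnotation(1500.0, 1520.0),
            SeizureAnnotation(5000.0, 5040.0)]
    rec = recording_of(np.zeros(9000 * 4), fs=4.0, anns=anns)
    ivs = label_intervals(rec, PreprocessConfig(min_channels=1,
                                                postictal_exclusion_s=600.0))
    cursor = 0.0
    for iv in ivs:
        assert iv.start_s == pytest.approx(cursor)
        cursor = iv.end_s
    assert cursor == pytest.approx(9000.0)


# ---------------------------------------------------------------------------
# windowing


def test_hour_long_preictal_interval_yields_360_windows_of_2560_samples():
    fs = 256.0
    rec = recording_of(np.random.default_rng(0).standard_normal(
        (2, int(3605 * fs))), fs=fs)
    cfg = PreprocessConfig(min_channels=1)
    ivs = [LabeledInterval("S01", 0.0, 3600.0, PREICTAL)]
    ws = extract_windows(rec, ivs, cfg)
    assert len(ws) == 360
    assert ws.X.shape == (360, 2, 2560)
    assert np.all(ws.y == 1)
    assert np.allclose(np.diff(ws.start_s), 10.0)     # stride contract


def test_partial_trailing_window_discarded_and_excluded_yield_nothing():
    fs = 4.0
    rec = recording_of(np.zeros((1, int(100 * fs))), fs=fs)
    cfg = PreprocessConfig(min_channels=1)
    ws = extract_windows(rec, [LabeledInterval("S01", 0.0, 25.0, INTERICTAL)],
                         cfg)
    assert len(ws) == 2
    ws2 = extract_windows(rec, [LabeledInterval("S01", 0.0, 50.0, EXCLUDED)],
                          cfg)
    assert len(ws2) == 0


def test_window_count_bookkeeping_across_labels():
    """Total windows equals the sum of floor(interval / window) over all
    non-excluded intervals, and no window overlaps an excluded span."""
    fs = 4.0
    anns = [SeizureAnnotation(300.0, 320.0)]
    rec = recording_of(np.zeros((1, int(1000 * fs))), fs=fs, anns=anns)
    cfg = PreprocessConfig(min_channels=1, preictal_horizon_s=150.0,
                           postictal_exclusion_s=100.0)
    ivs = label_intervals(rec, cfg)
    ws = extract_windows(rec, ivs, cfg)
    expected = sum(int((iv.end_s - iv.start_s) // cfg.window_s)
                   for iv in ivs if iv.label != EXCLUDED)
    assert len(ws) == expected
    for t0 in ws.start_s:
        for s, e in by_label(ivs, EXCLUDED):
            assert t0 + cfg.window_s <= s or t0 >= e


# ---------------------------------------------------------------------------
# normalization


def test_normalize_window_zero_mean_unit_sd_and_constant_to_zero():
    w = LabeledWindow("S", "r", 0.0, np.array([[1.0, 2.0, 3.0, 4.0],
                                               [5.0, 5.0, 5.0, 5.0]]), 0)
    out = normalize_window(w)
    assert abs(out.x[0].mean()) < 1e-5
    assert abs(out.x[0].std() - 1.0) < 1e-5
    assert np.array_equal(out.x[1], np.zeros(4))
    # idempotence
    again = normalize_window(out)
    assert np.allclose(again.x, out.x, atol=1e-5)


def test_normalize_windows_vectorized_matches_per_window():
    ws = make_toy_windows(n_per_class=5, seed=3)
    out = normalize_windows(ws)
    mus = out.X.mean(axis=-1)
    sds = out.X.std(axis=-1)
    assert np.abs(mus).max() < 1e-5
    assert np.abs(sds - 1.0).max() < 1e-4


# ---------------------------------------------------------------------------
# balancing


def unbalanced_windows(n0=100, n1=40, seed=0) -> WindowSet:
    rng = np.random.default_rng(seed)
    n = n0 + n1
    y = np.array([0] * n0 + [1] * n1)
    return WindowSet(rng.standard_normal((n, 2, 32)), y, ["A"] * n,
                     ["A-r01"] * n, np.arange(n, dtype=float), 256.0, 0.125,
                     "h")


def test_undersampling_equalizes_and_keeps_minority_intact():
    ws = unbalanced_windows()
    out = balance_undersample(ws, seed=4)
    assert out.class_counts() == (40, 40)
    # minority class untouched
    assert np.array_equal(out.X[out.y == 1], ws.X[ws.y == 1])
    # reproducible
    out2 = balance_undersample(ws, seed=4)
    assert np.array_equal(out.X, out2.X)
    # already balanced -> identity
    out3 = balance_undersample(out, seed=9)
    assert np.array_equal(out3.X, out.X)


def test_undersampling_requires_both_classes():
    ws = unbalanced_windows(n0=10, n1=0)
    with pytest.raises(ValueError, match="A-r01"):
        balance_undersample(ws, seed=0)


# ---------------------------------------------------------------------------
# splitting


def window_key_multiset(ws: WindowSet):
    return sorted(map(tuple, ws.X.reshape(len(ws), -1)[:, :4].tolist()))


def test_split_is_stratified_disjoint_exhaustive():
    ws = unbalanced_windows(n0=600, n1=400, seed=5)
    tr, va, te = split_multisubject(ws, (0.6, 0.2, 0.2), seed=6)
    assert (len(tr), len(va), len(te)) == (600, 200, 200)
    for part, frac in ((tr, 0.6), (va, 0.2), (te, 0.2)):
        n0, n1 = part.class_counts()
        assert abs(n0 - 600 * frac) <= 1 and abs(n1 - 400 * frac) <= 1
    union = window_key_multiset(tr) + window_key_multiset(va) + \
        window_key_multiset(te)
    assert sorted(union) == window_key_multiset(ws)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 6),
       st.floats(0.4, 0.8), st.floats(0.05, 0.25))
def test_split_partition_property(seed, f_train, f_val):
    f_test = 1.0 - f_train - f_val
    ws = unbalanced_windows(n0=60, n1=40, seed=1)
    tr, va, te = split_multisubject(ws, (f_train, f_val, f_test), seed=seed)
    assert len(tr) + len(va) + len(te) == len(ws)
    hashes = [ws.window_hashes() for ws in (tr, va, te)]
    assert not (hashes[0] & hashes[1] or hashes[0] & hashes[2]
                or hashes[1] & hashes[2])


def test_split_rejects_bad_fractions_and_empty_split():
    ws = unbalanced_windows(n0=6, n1=4)
    with pytest.raises(ValueError, match="sum to 1"):
        split_multisubject(ws, (0.5, 0.2, 0.2), seed=0)
    with pytest.raises(ValueError, match="empty"):
        split_multisubject(ws, (0.98, 0.01, 0.01), seed=0)


# ---------------------------------------------------------------------------
# pipeline


def test_pipeline_is_reproducible_and_enforces_channel_minimum():
    from seizadapt.synthetic_cohort import CohortConfig, generate_cohort
    cfg = PreprocessConfig(min_channels=4, preictal_horizon_s=100.0,
                           postictal_exclusion_s=60.0, window_s=5.0)
    recs = generate_cohort(CohortConfig(
        n_subjects=2, n_channels=4, record_duration_s=400.0,
        seizures_per_subject=1, shift_strength=0.5, master_seed=3,
        preictal_horizon_s=100.0))
    a = windows_from_recording(recs[0], cfg)
    b = windows_from_recording(recs[0], cfg)
    assert np.array_equal(a.X, b.X)
    assert a.config_hash == cfg.hash()
    with pytest.raises(ValueError, match="fewer than the configured"):
        windows_from_recording(recs[0], PreprocessConfig(
            min_channels=23, preictal_horizon_s=100.0, window_s=5.0))
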