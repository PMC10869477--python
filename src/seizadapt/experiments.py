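"""Reduced-scale end-to-end studies on synthetic cohorts.

These drivers reproduce the qualitative findings of the evaluation
protocols at desk scale: pooled multiple-subject training outperforms the
leave-one-patient-out (LOPO) baseline under subject shift, adversarial
adaptation recovers part of the loss, and under zero shift adaptation
carries no systematic penalty.

Study conditions (the package's reduced-scale defaults): 6 subjects,
4 channels at 256 Hz resampled to 128 Hz after filtering, one seizure per
2100 s record, a 1000 s pre-ictal horizon, ~200 balanced 10 s windows per
subject, a small model (F1=2, F2=2, F3=4), batch 64, up to 10 epochs, and
5 seed replicates. The sizes keep a full 4-method LOPO comparison within
interactive runtimes while leaving enough windows per subject for stable
accuracy estimates.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .evaluate import ExperimentConfig, compare_adaptation, run_multisubject
from .preprocess import PreprocessConfig, split_multisubject, balance_undersample
from .synthetic_cohort import CohortConfig, generate_cohort
from .train import TrainConfig, train_adapted, train_supervised
from .model import build_model
from .evaluate import evaluate_model
from .preprocess import prepare_cohort
from .windows import WindowSet

DESK_N_SUBJECTS = 6
DESK_N_CHANNELS = 4
DESK_FS = 256
DESK_RESAMPLE_HZ = 128.0
DESK_RECORD_S = 2100.0
DESK_HORIZON_S = 1000.0
DESK_POSTICTAL_S = 600.0
DESK_MAX_EPOCHS = 6
DESK_PATIENCE = 5


def desk_cohort_config(shift: float, master_seed: int) -> CohortConfig:
    return CohortConfig(
        n_subjects=DESK_N_SUBJECTS, n_channels=DESK_N_CHANNELS,
        sampling_rate_hz=DESK_FS, record_duration_s=DESK_RECORD_S,
        seizures_per_subject=1, shift_strength=shift,
        master_seed=master_seed, preictal_horizon_s=DESK_HORIZON_S)


def desk_preprocess_config(balance_seed: int = 0) -> PreprocessConfig:
    # band top at 60 Hz so the 128 Hz resampled rate stays valid
    return PreprocessConfig(
        notch_hz=50.0, band_hz=(0.5, 60.0),
        preictal_horizon_s=DESK_HORIZON_S,
        postictal_exclusion_s=DESK_POSTICTAL_S,
        window_s=10.0, min_channels=DESK_N_CHANNELS,
        balance_seed=balance_seed, resample_hz=DESK_RESAMPLE_HZ)


def desk_experiment_config(seed: int, adapt_method: str = "none",
                           max_epochs: int = DESK_MAX_EPOCHS
                           ) -> ExperimentConfig:
    train = TrainConfig(max_epochs=max_epochs,
                        patience_epochs=min(DESK_PATIENCE, max_epochs - 1),
                        batch_size=64, seed=seed, adapt_method=adapt_method)
    return ExperimentConfig(train=train, F1=2, F2=2, F3=4, dropout_p=0.25)


def build_desk_windows(shift: float, master_seed: int) -> WindowSet:
    cohort = generate_cohort(desk_cohort_config(shift, master_seed))
    return prepare_cohort(cohort, desk_preprocess_config(
        balance_seed=master_seed), balance_per_subject=True)


def run_comparison_study(master_seed: int, n_seeds: int = 5,
                         shift: float = 1.0,
                         methods: tuple[str, ...] = ("none", "dann", "cdan",
                                                     "cdan_e")) -> dict:
    """Pooled vs LOPO vs LOPO+adaptation over several seed replicates.

    Each replicate draws a fresh cohort and runs the pooled protocol plus
    the full matched-seed LOPO method comparison; returns per-seed average
    metrics and their medians.
    """
    out: dict = {"seeds": [], "pooled_accuracy": [],
                 **{f"{m}_accuracy": [] for m in methods},
                 **{f"{m}_f1": [] for m in methods},
                 **{f"{m}_auc": [] for m in methods}}
    for rep in range(n_seeds):
        seed = int(np.random.SeedSequence([master_seed, rep])
                   .generate_state(1)[0] % (2 ** 31))
        ws = build_desk_windows(shift, seed)
        cfg = desk_experiment_config(seed)
        pooled = run_multisubject(ws, cfg)
        grid = compare_adaptation(ws, cfg, methods=methods)
        out["seeds"].append(seed)
        out["pooled_accuracy"].append(pooled.accuracy)
        for m in methods:
            out[f"{m}_accuracy"].append(float(grid.loc["Average", (m, "accuracy")]))
            out[f"{m}_f1"].append(float(grid.loc["Average", (m, "f1")]))
            out[f"{m}_auc"].append(float(grid.loc["Average", (m, "auc")]))
    for key in list(out):
        if key != "seeds":
            out[f"median_{key}"] = float(np.median(out[key]))
    return out


def run_zero_shift_control(master_seed: int, n_seeds: int = 5,
                           method: str = "dann") -> dict:
    """Paired supervised-vs-adapted comparison with no subject shift.

    The adversarial run receives the training windows themselves as the
    unlabeled target; with source and target identically distributed the
    adapted model's held-out accuracy should match the supervised one up
    to noise.
    """
    diffs, sup_accs, da_accs = [], [], []
    for rep in range(n_seeds):
        seed = int(np.random.SeedSequence([master_seed, 7000 + rep])
                   .generate_state(1)[0] % (2 ** 31))
        ws = build_desk_windows(0.0, seed)
        cfg = desk_experiment_config(seed)
        tr, va, te = split_multisubject(ws, cfg.fractions, seed=seed)
        tr = balance_undersample(tr, seed=seed)

        sup = build_model(cfg.model_config(ws), seed=seed)
        sup, _ = train_supervised(sup, tr, va, cfg.train)
        sup_acc = evaluate_model(sup, te).accuracy

        da = build_model(cfg.model_config(ws), seed=seed)
        da_cfg = replace(cfg.train, adapt_method=method)
        da, _ = train_adapted(da, tr, va, tr.X, da_cfg)
        da_acc = evaluate_model(da, te).accuracy

        sup_accs.append(sup_acc)
        da_accs.append(da_acc)
        diffs.append(da_acc - sup_acc)
    return {"supervised_accuracy": sup_accs, "adapted_accuracy": da_accs,
            "difference": diffs,
            "median_difference": float(np.median(diffs)),
            "median_supervised_accuracy": float(np.median(sup_accs)),
            "median_adapted_accuracy": float(np.median(da_accs))}
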