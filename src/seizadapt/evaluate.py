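"""Metrics and experiment protocols.

Three protocols mirror the clinical evaluation designs:

* ``run_multisubject`` — windows from all subjects pooled, stratified
  train/val/test split, one supervised model, one report.
* ``run_lopo`` — leave-one-patient-out: for each subject, train on the
  remaining subjects (with an internal source train/val split) and test
  on the held-out subject. With an adaptation method, the held-out
  subject's unlabeled windows are the target domain (transductively: the
  same windows are subsequently scored; an inductive variant adapts on
  one half and scores the other).
* ``compare_adaptation`` — LOPO for the baseline and each adversarial
  method with matched seeds, emitting the per-subject F1/ACC/AUC grid and
  deltas versus baseline.

Confusion-based metrics use a 0.5 threshold on the pre-ictal probability.
Summary rows report mean ± population standard deviation across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import sklearn.metrics

from .model import ModelConfig, SeizureCNN, build_model
from .preprocess import balance_undersample, split_multisubject
from .train import TrainConfig, train_adapted, train_supervised
from .windows import WindowSet


@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float = float("nan")
    undefined: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_and_metrics(y_true, y_pred) -> EvalReport:
    """Counts and the derived metric identities; undefined ratios are
    reported as NaN and flagged, never silently zero."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary (0/1)")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    acc = ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    if np.isnan(sens) or np.isnan(prec) or (prec + sens) == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return EvalReport(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=acc,
                      sensitivity=sens, specificity=spec, precision=prec,
                      f1=f1, undefined=tuple(undefined))


def roc_auc(y_true, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC by threshold sweep and trapezoidal AUC.

    With the mid-rank tie convention the AUC equals
    P(score+ > score-) + 0.5 P(tie). A single-class ``y_true`` has no
    ROC; NaN is returned.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(set(y_true.tolist())) < 2:
        return [], float("nan")
    fpr, tpr, _ = sklearn.metrics.roc_curve(y_true, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(
        sklearn.metrics.auc(fpr, tpr))


def evaluate_model(model: SeizureCNN, ws: WindowSet,
                   threshold: float = 0.5) -> EvalReport:
    """Score a window set: confusion metrics at ``threshold``, plus ROC/AUC."""
    probs = model.predict_proba(ws.X)[:, 1]
    report = confusion_and_metrics(ws.y, (probs >= threshold).astype(int))
    roc, auc = roc_auc(ws.y, probs)
    return replace(report, roc=roc, auc=auc,
                   undefined=report.undefined + (("auc",) if np.isnan(auc)
                                                 else ()))


# ---------------------------------------------------------------------------
# experiment configuration


@dataclass
class ExperimentConfig:
    """Bundles the architecture and optimization settings of one protocol run."""

    train: TrainConfig = field(default_factory=TrainConfig)
    F1: int = 8
    F2: int = 2
    F3: int = 16
    dropout_p: float = 0.25
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    source_val_fraction: float = 0.2
    balance_train: bool = True
    transductive: bool = True

    def model_config(self, ws: WindowSet) -> ModelConfig:
        return ModelConfig(C=ws.X.shape[1], T=ws.X.shape[2], F1=self.F1,
                           F2=self.F2, F3=self.F3, dropout_p=self.dropout_p)


@dataclass
class LopoResult:
    method: str
    per_subject: dict[str, EvalReport]
    leakage_free: bool
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summarize(self) -> pd.DataFrame:
        rows = {sid: {"f1": r.f1, "accuracy": r.accuracy, "auc": r.auc}
                for sid, r in self.per_subject.items()}
        df = pd.DataFrame(rows).T
        mean = df.mean()
        sd = df.std(ddof=0)       # population sd across subjects
        df.loc["Average"] = mean
        df.loc["SD"] = sd
        self.summary = df
        return df


# ---------------------------------------------------------------------------
# protocols


def _derive_seed(base: int, *salt: int) -> int:
    return int(np.random.SeedSequence([base, *salt]).generate_state(1)[0]
               % (2 ** 31))


def run_multisubject(cohort_windows: WindowSet,
                     config: ExperimentConfig) -> EvalReport:
    """Pooled multiple-subject protocol: stratified split, one model."""
    if len(cohort_windows.subjects()) < 2:
        raise ValueError("multiple-subject protocol needs >= 2 subjects")
    seed = config.train.seed
    train_ws, val_ws, test_ws = split_multisubject(
        cohort_windows, config.fractions, seed=_derive_seed(seed, 1))
    if config.balance_train:
        train_ws = balance_undersample(train_ws, seed=_derive_seed(seed, 2))
    model = build_model(config.model_config(cohort_windows),
                        seed=_derive_seed(seed, 3))
    model, _ = train_supervised(model, train_ws, val_ws, config.train)
    return evaluate_model(model, test_ws)


def _lopo_fold(cohort: WindowSet, subject: str, config: ExperimentConfig,
               fold_seed: int) -> tuple[EvalReport, bool]:
    source = cohort.not_subject(subject)
    target = cohort.for_subject(subject)
    f_val = config.source_val_fraction
    train_ws, val_ws, _ = split_multisubject(
        source, (1.0 - f_val, f_val, 0.0), seed=_derive_seed(fold_seed, 1))
    if config.balance_train:
        train_ws = balance_undersample(train_ws, seed=_derive_seed(fold_seed, 2))
    tcfg = replace(config.train, seed=_derive_seed(fold_seed, 3))
    model = build_model(config.model_config(cohort),
                        seed=_derive_seed(fold_seed, 4))
    if tcfg.adapt_method == "none":
        model, _ = train_supervised(model, train_ws, val_ws, tcfg)
        test_ws = target
    elif config.transductive:
        model, _ = train_adapted(model, train_ws, val_ws, target.X, tcfg)
        test_ws = target
    else:
        half = len(target) // 2
        order = np.random.default_rng(_derive_seed(fold_seed, 5)).permutation(
            len(target))
        adapt_ws = target.subset(order[:half])
        test_ws = target.subset(order[half:])
        model, _ = train_adapted(model, train_ws, val_ws, adapt_ws.X, tcfg)
    leak_free = not (train_ws.window_hashes() & test_ws.window_hashes())
    return evaluate_model(model, test_ws), leak_free


def run_lopo(cohort_windows: WindowSet, config: ExperimentConfig) -> LopoResult:
    """Leave-one-patient-out over every subject in the cohort."""
    subjects = cohort_windows.subjects()
    if len(subjects) < 2:
        raise ValueError("LOPO needs >= 2 subjects")
    per_subject: dict[str, EvalReport] = {}
    leak_free = True
    for k, sid in enumerate(subjects):
        fold_seed = _derive_seed(config.train.seed, 100 + k)
        report, ok = _lopo_fold(cohort_windows, sid, config, fold_seed)
        per_subject[sid] = report
        leak_free &= ok
    result = LopoResult(method=config.train.adapt_method,
                        per_subject=per_subject, leakage_free=leak_free)
    result.summarize()
    return result


def compare_adaptation(cohort_windows: WindowSet, config: ExperimentConfig,
                       methods: tuple[str, ...] = ("none", "dann", "cdan",
                                                   "cdan_e")
                       ) -> pd.DataFrame:
    """LOPO per method with matched seeds; per-subject metric grid + deltas.

    Matched seeds: every method sees identical fold splits and model
    initialization, so columns are directly comparable.
    """
    from dataclasses import replace as dc_replace

    results = {}
    for method in methods:
        cfg = dc_replace(config, train=dc_replace(config.train,
                                                  adapt_method=method))
        results[method] = run_lopo(cohort_windows, cfg)
    subjects = cohort_windows.subjects()
    cols = {}
    for method, res in results.items():
        for metric in ("f1", "accuracy", "auc"):
            col = [getattr(res.per_subject[s], metric) for s in subjects]
            cols[(method, metric)] = col
    df = pd.DataFrame(cols, index=subjects)
    df.loc["Average"] = df.mean()
    for method in methods:
        if method == "none":
            continue
        for metric in ("f1", "accuracy", "auc"):
            df[(f"{method}_minus_baseline", metric)] = (
                df[(method, metric)] - df[("none", metric)])
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["method", "metric"])
    df.attrs["leakage_free"] = all(r.leakage_free for r in results.values())
    return df
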