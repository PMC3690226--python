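"""Repeated random-subsampling evaluation of the hybrid and baselines.

Protocol: for each ``k``, draw ``k`` cases per class uniformly without
replacement for training, re-learn thresholds and the SVM on that draw, and
score the held-out remainder; repeat and average. Sensitivity and
specificity take lymphoma as the positive class. Train/test splits depend
only on ``(cohort order, seed, k, repetition index)``, never on the method
under evaluation, so different methods can be compared on paired splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import (
    CaseRecord,
    HybridModel,
    Prediction,
    baseline_threshold_classify,
    classify,
    learn_thresholds,
    midpoint_thresholds,
    train_svm,
)
from .histogram import DEFAULT_TH, luminance_range
from .phantom import GLIOBLASTOMA, LYMPHOMA

__all__ = [
    "METHODS",
    "EvalConfig",
    "metrics",
    "random_split_evaluate",
    "threshold_sweep",
    "kernel_comparison",
]

METHODS = (
    "adc_baseline",
    "range_baseline",
    "svm_only",
    "range_gate_plus_svm",
    "adc_gate_plus_svm",
    "full_hybrid",
)

RESULT_COLUMNS = [
    "k",
    "method",
    "accuracy",
    "sensitivity",
    "specificity",
    "repetitions",
    "n_undefined_sensitivity",
    "n_undefined_specificity",
]


@dataclass
class EvalConfig:
    """Evaluation protocol settings."""

    k_values: Sequence[int] = (19,)
    repetitions: int = 1000
    method: str = "full_hybrid"
    th: float = DEFAULT_TH
    kernel: str = "linear"
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be positive")
        self.k_values = [int(k) for k in self.k_values]


def metrics(
    predictions: Sequence[Prediction | str], truth: Sequence[str]
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity), lymphoma positive.

    A metric whose class is absent from ``truth`` is returned as NaN.
    """
    if len(predictions) != len(truth) or len(truth) == 0:
        raise ValueError("predictions and truth must be nonempty and aligned")
    pred = [p.label if isinstance(p, Prediction) else p for p in predictions]
    correct = np.array([p == t for p, t in zip(pred, truth)])
    acc = float(correct.mean())
    lym = np.array([t == LYMPHOMA for t in truth])
    gbm = np.array([t == GLIOBLASTOMA for t in truth])
    sens = float(correct[lym].mean()) if lym.any() else float("nan")
    spec = float(correct[gbm].mean()) if gbm.any() else float("nan")
    return acc, sens, spec


def _split_indices(
    n_lym: int, n_gbm: int, k: int, seed: int, rep: int
) -> tuple[np.ndarray, np.ndarray]:
    """Paired train/test index split; depends only on (counts, seed, k, rep)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, k, rep]))
    lym_train = rng.choice(n_lym, size=k, replace=False)
    gbm_train = n_lym + rng.choice(n_gbm, size=k, replace=False)
    train = np.concatenate([np.sort(lym_train), np.sort(gbm_train)])
    test = np.setdiff1d(np.arange(n_lym + n_gbm), train)
    return train, test


def _predict_method(
    method: str, train: list[CaseRecord], test: list[CaseRecord], cfg: EvalConfig
) -> list[str]:
    if method == "adc_baseline":
        t = learn_thresholds(train, use_adc=True)
        adc_mid, _ = midpoint_thresholds(t, require_adc=True)
        return [baseline_threshold_classify(c.adc_value, adc_mid) for c in test]  # type: ignore[arg-type]
    if method == "range_baseline":
        t = learn_thresholds(train, use_adc=False)
        _, range_mid = midpoint_thresholds(t)
        return [baseline_threshold_classify(c.range_feature.range_value, range_mid) for c in test]
    if method == "svm_only":
        svm = train_svm(train, kernel=cfg.kernel, C=cfg.C)
        return svm.predict(np.stack([c.histogram.freqs for c in test]))
    # hybrid variants
    use_adc = method in ("adc_gate_plus_svm", "full_hybrid")
    use_range = method in ("range_gate_plus_svm", "full_hybrid")
    t = learn_thresholds(train, use_adc=use_adc, use_range=use_range)
    svm = train_svm(train, kernel=cfg.kernel, C=cfg.C)
    model = HybridModel(thresholds=t, svm=svm, th=cfg.th)
    return [classify(c, model).label for c in test]


def random_split_evaluate(cohort: Sequence[CaseRecord], cfg: EvalConfig) -> pd.DataFrame:
    """Run the repeated random-subsampling protocol for one method.

    Returns a tidy DataFrame with one row per ``k`` carrying the mean
    accuracy / sensitivity / specificity over repetitions (undefined metrics
    excluded from the mean with their counts reported).
    """
    cohort = list(cohort)
    lym = [c for c in cohort if c.label == LYMPHOMA]
    gbm = [c for c in cohort if c.label == GLIOBLASTOMA]
    if not lym or not gbm:
        raise ValueError("cohort must contain both classes")
    if any(c.label is None for c in cohort):
        raise ValueError("all cohort cases must be labeled")
    ordered = lym + gbm  # class-blocked, stable order for reproducible splits
    n_lym, n_gbm = len(lym), len(gbm)
    for k in cfg.k_values:
        if not 1 <= k <= min(n_lym, n_gbm) - 1:
            raise ValueError(
                f"k={k} out of bounds: must leave >= 1 training and test case per class"
            )
    if cfg.method == "adc_baseline" and any(c.adc_value is None for c in ordered):
        raise ValueError("adc_baseline requires an ADC value for every case")

    rows = []
    for k in cfg.k_values:
        accs, senss, specs = [], [], []
        for rep in range(cfg.repetitions):
            tr_idx, te_idx = _split_indices(n_lym, n_gbm, k, cfg.seed, rep)
            train = [ordered[i] for i in tr_idx]
            test = [ordered[i] for i in te_idx]
            pred = _predict_method(cfg.method, train, test, cfg)
            a, s, p = metrics(pred, [c.label for c in test])  # type: ignore[arg-type]
            accs.append(a)
            senss.append(s)
            specs.append(p)
        senss_arr = np.array(senss)
        specs_arr = np.array(specs)
        rows.append(
            {
                "k": k,
                "method": cfg.method,
                "accuracy": float(np.mean(accs)),
                "sensitivity": float(np.nanmean(senss_arr)) if not np.all(np.isnan(senss_arr)) else float("nan"),
                "specificity": float(np.nanmean(specs_arr)) if not np.all(np.isnan(specs_arr)) else float("nan"),
                "repetitions": cfg.repetitions,
                "n_undefined_sensitivity": int(np.isnan(senss_arr).sum()),
                "n_undefined_specificity": int(np.isnan(specs_arr).sum()),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _refeature(cohort: Sequence[CaseRecord], th: float) -> tuple[list[CaseRecord], list[str]]:
    """Recompute range features at a new th; returns (records, failed_case_ids)."""
    out, failed = [], []
    for c in cohort:
        try:
            rf = luminance_range(c.histogram, th)
        except ValueError:
            failed.append(c.case_id)
            continue
        out.append(replace(c, range_feature=rf))
    return out, failed


def threshold_sweep(
    cohort: Sequence[CaseRecord], th_values: Sequence[float], cfg: EvalConfig
) -> pd.DataFrame:
    """Re-extract range features and re-evaluate at each frequency threshold.

    A ``th`` at which some histogram has no supra-threshold bin is flagged in
    the ``flagged`` column (with the failing case ids in ``flagged_cases``)
    rather than silently skipped; its metrics are NaN.
    """
    frames = []
    for th in th_values:
        if not 0 <= th < 1:
            raise ValueError(f"th must be in [0, 1), got {th}")
        records, failed = _refeature(cohort, th)
        if failed:
            frames.append(
                pd.DataFrame(
                    [
                        {
                            "k": k,
                            "method": cfg.method,
                            "th": th,
                            "accuracy": float("nan"),
                            "sensitivity": float("nan"),
                            "specificity": float("nan"),
                            "repetitions": 0,
                            "flagged": True,
                            "flagged_cases": ";".join(failed),
                        }
                        for k in cfg.k_values
                    ]
                )
            )
            continue
        df = random_split_evaluate(records, replace(cfg, th=th))
        df["th"] = th
        df["flagged"] = False
        df["flagged_cases"] = ""
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def kernel_comparison(
    cohort: Sequence[CaseRecord], kernels: Sequence[str], cfg: EvalConfig
) -> pd.DataFrame:
    """Evaluate the configured method once per kernel, on identical splits."""
    frames = []
    for kernel in kernels:
        df = random_split_evaluate(cohort, replace(cfg, kernel=kernel))
        df["kernel"] = kernel
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
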