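"""Hybrid threshold-gate + SVM classifier over tumor luminance histograms.

The classifier separates *typical* from *nontypical* tumors with four
thresholds learned from the training data — per class, the extrema of the
luminance range and (optionally) of the scalar ADC value:

* ``th_range_lym_max`` / ``th_adc_lym_max`` — maxima over lymphomas,
* ``th_range_gli_min`` / ``th_adc_gli_min`` — minima over glioblastomas.

Two threshold geometries arise. **Case 1** (the class extrema overlap for at
least one enabled criterion): a tumor is a typical lymphoma when its ADC is
smaller than the glioblastoma minimum or its range is narrower than the
glioblastoma minimum, and a typical glioblastoma when its ADC is larger than
the lymphoma maximum or its range is wider than the lymphoma maximum.
**Case 2** (a gap for every enabled criterion): the inequalities swap — a
typical lymphoma falls below the lymphoma maxima, a typical glioblastoma
above the glioblastoma minima, and everything between the extrema is
nontypical. All inequalities are strict.

A case flagged typical for *both* classes (possible in Case 1 when the two
criteria disagree) is treated as nontypical. Nontypical cases are classified
by a support vector machine trained on the full 256-bin normalized
histograms of *all* training cases, typical ones included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .histogram import DEFAULT_TH, N_BINS, LuminanceHistogram, RangeFeature, luminance_range
from .phantom import GLIOBLASTOMA, LABELS, LYMPHOMA

__all__ = [
    "KERNELS",
    "CaseRecord",
    "ThresholdSet",
    "HistogramSVM",
    "HybridModel",
    "Prediction",
    "learn_thresholds",
    "gate_typical",
    "train_svm",
    "kernel_value",
    "kernel_matrix",
    "classify",
    "midpoint_thresholds",
    "baseline_threshold_classify",
    "records_from_cohort",
]

KERNELS = ("linear", "gaussian", "chi_square", "histogram_intersection")

NONTYPICAL = "nontypical"
CASE1 = "case1"
CASE2 = "case2"


@dataclass
class CaseRecord:
    """Per-case state: histogram, range feature, optional ADC, optional label."""

    case_id: str
    histogram: LuminanceHistogram
    range_feature: RangeFeature
    adc_value: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        # the stored feature must be re-derivable from the stored histogram
        check = luminance_range(self.histogram, self.range_feature.threshold_used)
        if (check.lo_bin, check.hi_bin) != (self.range_feature.lo_bin, self.range_feature.hi_bin):
            raise ValueError("range_feature inconsistent with histogram at its threshold")


@dataclass
class ThresholdSet:
    """The four learned gate thresholds and the geometry they imply."""

    th_range_lym_max: int
    th_range_gli_min: int
    th_adc_lym_max: float | None = None
    th_adc_gli_min: float | None = None
    adc_enabled: bool = False
    range_enabled: bool = True
    geometry_case: str = field(init=False)

    def __post_init__(self) -> None:
        if self.adc_enabled and (self.th_adc_lym_max is None or self.th_adc_gli_min is None):
            raise ValueError("adc_enabled requires both ADC extrema")
        if not (self.adc_enabled or self.range_enabled):
            raise ValueError("at least one gate criterion must be enabled")
        overlap = False
        if self.adc_enabled:
            overlap = overlap or self.th_adc_gli_min <= self.th_adc_lym_max  # type: ignore[operator]
        if self.range_enabled:
            overlap = overlap or self.th_range_gli_min <= self.th_range_lym_max
        self.geometry_case = CASE1 if overlap else CASE2


def learn_thresholds(
    train: Sequence[CaseRecord], use_adc: bool = False, use_range: bool = True
) -> ThresholdSet:
    """Extract the four gate thresholds (class extrema) from labeled cases."""
    lym = [c for c in train if c.label == LYMPHOMA]
    gbm = [c for c in train if c.label == GLIOBLASTOMA]
    if not lym or not gbm:
        raise ValueError("training data must contain at least one case per class")
    if use_adc and any(c.adc_value is None for c in train):
        raise ValueError("use_adc requires an ADC value for every training case")
    kwargs: dict = {
        "th_range_lym_max": max(c.range_feature.range_value for c in lym),
        "th_range_gli_min": min(c.range_feature.range_value for c in gbm),
        "adc_enabled": use_adc,
        "range_enabled": use_range,
    }
    if use_adc:
        kwargs["th_adc_lym_max"] = max(c.adc_value for c in lym)  # type: ignore[type-var]
        kwargs["th_adc_gli_min"] = min(c.adc_value for c in gbm)  # type: ignore[type-var]
    return ThresholdSet(**kwargs)


def gate_typical(c: CaseRecord, t: ThresholdSet) -> tuple[str, dict]:
    """Apply the typical-case gate; returns (label-or-'nontypical', gate_detail).

    ADC clauses are skipped when the case carries no ADC value; with both
    criteria firing for opposite classes the case is routed to nontypical.
    """
    r = c.range_feature.range_value
    adc = c.adc_value if t.adc_enabled else None
    detail: dict = {"geometry_case": t.geometry_case}

    if t.geometry_case == CASE1:
        lym_adc = adc is not None and adc < t.th_adc_gli_min  # type: ignore[operator]
        lym_rng = t.range_enabled and r < t.th_range_gli_min
        gbm_adc = adc is not None and adc > t.th_adc_lym_max  # type: ignore[operator]
        gbm_rng = t.range_enabled and r > t.th_range_lym_max
    else:
        lym_adc = adc is not None and adc < t.th_adc_lym_max  # type: ignore[operator]
        lym_rng = t.range_enabled and r < t.th_range_lym_max
        gbm_adc = adc is not None and adc > t.th_adc_gli_min  # type: ignore[operator]
        gbm_rng = t.range_enabled and r > t.th_range_gli_min

    detail.update(
        lymphoma_by_adc=bool(lym_adc),
        lymphoma_by_range=bool(lym_rng),
        glioblastoma_by_adc=bool(gbm_adc),
        glioblastoma_by_range=bool(gbm_rng),
    )
    lym_fire = lym_adc or lym_rng
    gbm_fire = gbm_adc or gbm_rng
    if lym_fire and gbm_fire:
        detail["conflict"] = True
        return NONTYPICAL, detail
    detail["conflict"] = False
    if lym_fire:
        return LYMPHOMA, detail
    if gbm_fire:
        return GLIOBLASTOMA, detail
    return NONTYPICAL, detail


def kernel_value(
    x: np.ndarray, y: np.ndarray, kernel: str = "linear", gamma: float | None = None
) -> float:
    """Kernel between two normalized histograms.

    linear: sum(x*y); gaussian: exp(-gamma ||x-y||^2);
    histogram_intersection: sum(min(x, y));
    chi_square: exp(-gamma sum((x-y)^2 / (x+y))) with 0/0 terms dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if gamma is None:
        gamma = 1.0 / x.shape[-1]
    if kernel == "linear":
        return float(x @ y)
    if kernel == "gaussian":
        return float(np.exp(-gamma * np.sum((x - y) ** 2)))
    if kernel == "histogram_intersection":
        return float(np.minimum(x, y).sum())
    if kernel == "chi_square":
        denom = x + y
        num = (x - y) ** 2
        terms = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
        return float(np.exp(-gamma * terms.sum()))
    raise ValueError(f"unknown kernel {kernel!r}; expected one of {KERNELS}")


def kernel_matrix(
    X: np.ndarray, Y: np.ndarray, kernel: str = "linear", gamma: float | None = None
) -> np.ndarray:
    """Gram matrix K[i, j] = k(X[i], Y[j]) for row-wise histogram matrices."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if gamma is None:
        gamma = 1.0 / X.shape[1]
    if kernel == "linear":
        return X @ Y.T
    if kernel == "gaussian":
        d2 = np.sum((X[:, None, :] - Y[None, :, :]) ** 2, axis=-1)
        return np.exp(-gamma * d2)
    if kernel == "histogram_intersection":
        return np.minimum(X[:, None, :], Y[None, :, :]).sum(axis=-1)
    if kernel == "chi_square":
        num = (X[:, None, :] - Y[None, :, :]) ** 2
        denom = X[:, None, :] + Y[None, :, :]
        terms = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
        return np.exp(-gamma * terms.sum(axis=-1))
    raise ValueError(f"unknown kernel {kernel!r}; expected one of {KERNELS}")


@dataclass
class HistogramSVM:
    """A trained max-margin classifier over 256-bin normalized histograms."""

    kernel: str
    C: float
    gamma: float
    train_X: np.ndarray
    _svc: SVC

    def predict(self, X: np.ndarray) -> list[str]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = kernel_matrix(X, self.train_X, self.kernel, self.gamma)
        return [LABELS[i] for i in self._svc.predict(K)]


def train_svm(
    train: Sequence[CaseRecord], kernel: str = "linear", C: float = 1.0, gamma: float | None = None
) -> HistogramSVM:
    """Fit the SVM on every training case's histogram (typical cases included)."""
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; expected one of {KERNELS}")
    labels = [c.label for c in train]
    if len(set(labels) & set(LABELS)) < 2:
        raise ValueError("SVM training requires cases from both classes")
    X = np.stack([c.histogram.freqs for c in train])
    y = np.array([LABELS.index(c.label) for c in train])  # type: ignore[arg-type]
    if gamma is None:
        gamma = 1.0 / N_BINS
    svc = SVC(kernel="precomputed", C=C)
    svc.fit(kernel_matrix(X, X, kernel, gamma), y)
    return HistogramSVM(kernel=kernel, C=C, gamma=gamma, train_X=X, _svc=svc)


@dataclass
class HybridModel:
    """Learned gate thresholds plus the fallback SVM and the range threshold."""

    thresholds: ThresholdSet
    svm: HistogramSVM
    th: float = DEFAULT_TH


@dataclass
class Prediction:
    case_id: str
    label: str
    route: str  # typical_by_range | typical_by_adc | svm
    gate_detail: dict


def classify(c: CaseRecord, m: HybridModel) -> Prediction:
    """Gate first; only nontypical cases are passed to the SVM."""
    if abs(c.range_feature.threshold_used - m.th) > 1e-12:
        raise ValueError(
            f"case range feature extracted at th={c.range_feature.threshold_used}, "
            f"model expects th={m.th}"
        )
    gate_label, detail = gate_typical(c, m.thresholds)
    if gate_label != NONTYPICAL:
        by_range = detail[f"{gate_label}_by_range"]
        route = "typical_by_range" if by_range else "typical_by_adc"
        return Prediction(case_id=c.case_id, label=gate_label, route=route, gate_detail=detail)
    label = m.svm.predict(c.histogram.freqs[None, :])[0]
    return Prediction(case_id=c.case_id, label=label, route="svm", gate_detail=detail)


def midpoint_thresholds(t: ThresholdSet, require_adc: bool = False) -> tuple[float | None, float]:
    """Midpoints of the learned extrema, used by the single-value baselines.

    Returns ``(th_adc_mid, th_range_mid)`` where each midpoint is the
    arithmetic mean of the glioblastoma minimum and the lymphoma maximum.
    """
    th_range_mid = (t.th_range_gli_min + t.th_range_lym_max) / 2.0
    if t.th_adc_lym_max is None or t.th_adc_gli_min is None:
        if require_adc:
            raise ValueError("ADC midpoint requested but ADC extrema are absent")
        return None, th_range_mid
    return (t.th_adc_gli_min + t.th_adc_lym_max) / 2.0, th_range_mid


def baseline_threshold_classify(
    value: float, threshold: float, direction: str = "low_is_lymphoma"
) -> str:
    """Single-value thresholding: below the cut is lymphoma, at or above is
    glioblastoma (documented tie rule)."""
    if direction != "low_is_lymphoma":
        raise ValueError(f"unsupported direction {direction!r}")
    if not (np.isfinite(value) and np.isfinite(threshold)):
        raise ValueError("value and threshold must be finite")
    return LYMPHOMA if value < threshold else GLIOBLASTOMA


def records_from_cohort(cohort, th: float = DEFAULT_TH, masks=None) -> list[CaseRecord]:
    """Build CaseRecords (quantize → histogram → range) from labeled phantoms.

    ``masks`` overrides the ground-truth masks, e.g. with segmented ones.
    """
    from .histogram import quantize, tumor_histogram

    records = []
    for i, case in enumerate(cohort):
        mask = case.truth_mask if masks is None else masks[i]
        v8 = quantize(case.volume)
        h = tumor_histogram(v8, mask)
        records.append(
            CaseRecord(
                case_id=case.case_id,
                histogram=h,
                range_feature=luminance_range(h, th),
                adc_value=case.adc_value,
                label=case.label,
            )
        )
    return records
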