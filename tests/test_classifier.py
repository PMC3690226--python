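"""Gate threshold learning, Case 1/2 gating, kernels, SVM and baselines."""

import numpy as np
import pytest

from histogate import (
    GLIOBLASTOMA,
    LYMPHOMA,
    CaseRecord,
    HybridModel,
    LuminanceHistogram,
    RangeFeature,
    ThresholdSet,
    baseline_threshold_classify,
    classify,
    gate_typical,
    kernel_matrix,
    kernel_value,
    learn_thresholds,
    midpoint_thresholds,
    train_svm,
)
from histogate.classifier import CASE1, CASE2, NONTYPICAL

from conftest import make_record, random_feature_cohort


# ---------------------------------------------------------------- thresholds
def test_threshold_extrema_single_case_per_class():
    train = [
        make_record("l", 30, label=LYMPHOMA),
        make_record("g", 80, label=GLIOBLASTOMA),
    ]
    t = learn_thresholds(train, use_adc=False)
    assert (t.th_range_lym_max, t.th_range_gli_min) == (30, 80)
    assert t.geometry_case == CASE2
    assert not t.adc_enabled


def test_threshold_overlapping_ranges_give_case1():
    train = [
        make_record("l1", 30, label=LYMPHOMA),
        make_record("l2", 50, label=LYMPHOMA),
        make_record("g1", 40, label=GLIOBLASTOMA),
        make_record("g2", 80, label=GLIOBLASTOMA),
    ]
    t = learn_thresholds(train, use_adc=False)
    assert (t.th_range_lym_max, t.th_range_gli_min) == (50, 40)
    assert t.geometry_case == CASE1


def test_adc_overlap_alone_triggers_case1():
    """ADC extrema overlap -> Case 1 even with a clean range gap."""
    train = [
        make_record("l1", 30, adc=0.6, label=LYMPHOMA),
        make_record("l2", 35, adc=0.9, label=LYMPHOMA),
        make_record("g1", 60, adc=0.7, label=GLIOBLASTOMA),
        make_record("g2", 80, adc=1.2, label=GLIOBLASTOMA),
    ]
    t = learn_thresholds(train, use_adc=True)
    assert (t.th_adc_lym_max, t.th_adc_gli_min) == (0.9, 0.7)
    assert (t.th_range_lym_max, t.th_range_gli_min) == (35, 60)
    assert t.geometry_case == CASE1


def test_threshold_learning_matches_brute_force():
    rng = np.random.default_rng(12)
    for _ in range(50):
        cohort = random_feature_cohort(rng, n_per_class=rng.integers(1, 8))
        t = learn_thresholds(cohort, use_adc=True)
        lym = [c for c in cohort if c.label == LYMPHOMA]
        gbm = [c for c in cohort if c.label == GLIOBLASTOMA]
        assert t.th_range_lym_max == max(c.range_feature.range_value for c in lym)
        assert t.th_range_gli_min == min(c.range_feature.range_value for c in gbm)
        assert t.th_adc_lym_max == max(c.adc_value for c in lym)
        assert t.th_adc_gli_min == min(c.adc_value for c in gbm)


def test_threshold_learning_errors():
    only_lym = [make_record("l", 30, label=LYMPHOMA)]
    with pytest.raises(ValueError, match="per class"):
        learn_thresholds(only_lym)
    no_adc = [
        make_record("l", 30, label=LYMPHOMA),
        make_record("g", 80, label=GLIOBLASTOMA),
    ]
    with pytest.raises(ValueError, match="ADC"):
        learn_thresholds(no_adc, use_adc=True)


def test_thresholdset_invariants():
    with pytest.raises(ValueError, match="ADC extrema"):
        ThresholdSet(th_range_lym_max=30, th_range_gli_min=80, adc_enabled=True)
    with pytest.raises(ValueError, match="at least one"):
        ThresholdSet(th_range_lym_max=30, th_range_gli_min=80, range_enabled=False)


# --------------------------------------------------------------------- gate
def _case1_range_only():
    return ThresholdSet(th_range_lym_max=50, th_range_gli_min=40)


def test_gate_case1_strata_range_only():
    t = _case1_range_only()
    assert t.geometry_case == CASE1
    assert gate_typical(make_record("a", 35), t)[0] == LYMPHOMA
    assert gate_typical(make_record("b", 55), t)[0] == GLIOBLASTOMA
    assert gate_typical(make_record("c", 45), t)[0] == NONTYPICAL


def test_gate_case2_strata_range_only():
    t = ThresholdSet(th_range_lym_max=35, th_range_gli_min=60)
    assert t.geometry_case == CASE2
    assert gate_typical(make_record("a", 30), t)[0] == LYMPHOMA
    assert gate_typical(make_record("b", 70), t)[0] == GLIOBLASTOMA
    assert gate_typical(make_record("c", 45), t)[0] == NONTYPICAL


def test_gate_boundary_values_are_nontypical():
    """Strict inequalities: a value equal to a threshold never fires."""
    t = ThresholdSet(th_range_lym_max=35, th_range_gli_min=60)
    assert gate_typical(make_record("lo", 35), t)[0] == NONTYPICAL
    assert gate_typical(make_record("hi", 60), t)[0] == NONTYPICAL


def test_gate_conflict_routes_to_nontypical():
    """ADC says typical lymphoma, range says typical glioblastoma."""
    t = ThresholdSet(
        th_range_lym_max=35,
        th_range_gli_min=60,
        th_adc_lym_max=1.1,
        th_adc_gli_min=0.9,
        adc_enabled=True,
    )
    assert t.geometry_case == CASE1
    label, detail = gate_typical(make_record("x", 70, adc=0.5), t)
    assert label == NONTYPICAL
    assert detail["conflict"]
    assert detail["lymphoma_by_adc"] and detail["glioblastoma_by_range"]


def test_gate_skips_adc_clauses_when_case_has_no_adc():
    t = ThresholdSet(
        th_range_lym_max=35,
        th_range_gli_min=60,
        th_adc_lym_max=1.1,
        th_adc_gli_min=0.9,
        adc_enabled=True,
    )
    label, detail = gate_typical(make_record("x", 30, adc=None), t)
    assert label == LYMPHOMA
    assert not detail["lymphoma_by_adc"]


# ------------------------------------------------------------------ kernels
def test_kernel_values():
    x = np.zeros(256)
    x[3] = 1.0
    y = np.zeros(256)
    y[200] = 1.0
    uniform = np.full(256, 1 / 256)
    assert kernel_value(x, x, "chi_square") == pytest.approx(1.0)
    assert kernel_value(x, y, "histogram_intersection") == 0.0
    assert kernel_value(x, x, "histogram_intersection") == pytest.approx(1.0)
    assert kernel_value(uniform, uniform, "linear") == pytest.approx(1 / 256)
    assert kernel_value(x, x, "gaussian") == pytest.approx(1.0)
    with pytest.raises(ValueError, match="unknown kernel"):
        kernel_value(x, y, "sigmoid")


def test_kernel_matrix_agrees_with_pairwise_values():
    rng = np.random.default_rng(5)
    X = rng.dirichlet(np.ones(256), size=4)
    for kernel in ("linear", "gaussian", "chi_square", "histogram_intersection"):
        K = kernel_matrix(X, X, kernel)
        for i in range(4):
            for j in range(4):
                assert K[i, j] == pytest.approx(kernel_value(X[i], X[j], kernel))


def test_chi_square_zero_bins_are_dropped():
    x = np.zeros(256)
    x[0] = 1.0
    y = np.zeros(256)
    y[0] = 1.0
    # all other bins are 0/0 terms; the kernel must not emit NaN
    assert np.isfinite(kernel_value(x, y, "chi_square"))


# ---------------------------------------------------------------------- svm
def test_svm_separates_one_hot_pair():
    train = [
        make_record("l", 0, label=LYMPHOMA, lo_bin=10),
        make_record("g", 0, label=GLIOBLASTOMA, lo_bin=200),
    ]
    svm = train_svm(train)
    X = np.stack([c.histogram.freqs for c in train])
    assert svm.predict(X) == [LYMPHOMA, GLIOBLASTOMA]


def test_svm_single_class_errors():
    train = [make_record("l", 0, label=LYMPHOMA)]
    with pytest.raises(ValueError, match="both classes"):
        train_svm(train)


def test_svm_training_accuracy_on_cohort(records2020):
    svm = train_svm(records2020)
    X = np.stack([c.histogram.freqs for c in records2020])
    pred = svm.predict(X)
    acc = np.mean([p == c.label for p, c in zip(pred, records2020)])
    assert acc == 1.0


# ------------------------------------------------------------------ classify
def _model(thresholds, train):
    return HybridModel(thresholds=thresholds, svm=train_svm(train), th=0.002)


def _train_pair():
    return [
        make_record("l", 30, label=LYMPHOMA, lo_bin=10),
        make_record("g", 80, label=GLIOBLASTOMA, lo_bin=150),
    ]


def test_typical_case_never_invokes_svm():
    model = _model(ThresholdSet(th_range_lym_max=35, th_range_gli_min=60), _train_pair())

    def boom(X):  # call audit: the SVM must not be consulted
        raise AssertionError("SVM invoked for a typical case")

    model.svm.predict = boom
    pred = classify(make_record("t", 20), model)
    assert pred.label == LYMPHOMA
    assert pred.route == "typical_by_range"


def test_nontypical_case_routes_to_svm():
    model = _model(ThresholdSet(th_range_lym_max=35, th_range_gli_min=60), _train_pair())
    pred = classify(make_record("t", 45, lo_bin=10), model)
    assert pred.route == "svm"
    assert pred.label in (LYMPHOMA, GLIOBLASTOMA)


def test_classify_gate_detail_consistent_with_gate(records2020):
    train = records2020[:10] + records2020[20:30]
    t = learn_thresholds(train, use_adc=True)
    model = HybridModel(thresholds=t, svm=train_svm(train), th=0.002)
    for c in records2020:
        pred = classify(c, model)
        label, detail = gate_typical(c, t)
        assert pred.gate_detail == detail
        assert (pred.route == "svm") == (label == NONTYPICAL)


def test_classify_th_mismatch_errors():
    model = _model(ThresholdSet(th_range_lym_max=35, th_range_gli_min=60), _train_pair())
    bad = make_record("t", 20, th=0.01)
    with pytest.raises(ValueError, match="th="):
        classify(bad, model)


# ----------------------------------------------------------------- baselines
def test_midpoint_thresholds():
    t = ThresholdSet(
        th_range_lym_max=50,
        th_range_gli_min=40,
        th_adc_lym_max=0.9,
        th_adc_gli_min=0.7,
        adc_enabled=True,
    )
    adc_mid, range_mid = midpoint_thresholds(t)
    assert adc_mid == pytest.approx(0.8)
    assert range_mid == pytest.approx(45.0)
    eq = ThresholdSet(th_range_lym_max=40, th_range_gli_min=40)
    assert midpoint_thresholds(eq)[1] == 40.0
    with pytest.raises(ValueError, match="ADC midpoint"):
        midpoint_thresholds(eq, require_adc=True)


def test_baseline_threshold_direction_and_tie():
    assert baseline_threshold_classify(0.6, 0.8) == LYMPHOMA
    assert baseline_threshold_classify(200, 45) == GLIOBLASTOMA
    assert baseline_threshold_classify(45, 45) == GLIOBLASTOMA  # tie rule
    with pytest.raises(ValueError, match="direction"):
        baseline_threshold_classify(1.0, 0.5, direction="high_is_lymphoma")


def test_case_record_consistency_enforced():
    freqs = np.zeros(256)
    freqs[10] = 1.0
    h = LuminanceHistogram(freqs=freqs, n_voxels=5)
    bad = RangeFeature(lo_bin=10, hi_bin=50, range_value=40, threshold_used=0.002)
    with pytest.raises(ValueError, match="inconsistent"):
        CaseRecord(case_id="x", histogram=h, range_feature=bad)
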