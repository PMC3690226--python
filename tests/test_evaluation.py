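"""Random-subsampling protocol, metrics, sweeps and kernel comparison."""

import numpy as np
import pandas as pd
import pytest

from histogate import (
    GLIOBLASTOMA,
    LYMPHOMA,
    EvalConfig,
    kernel_comparison,
    metrics,
    random_split_evaluate,
    threshold_sweep,
)
from histogate.evaluation import _split_indices

from conftest import make_record


def _gapped_cohort(n_per_class=8, with_adc=True):
    """Range distributions with a clean gap: a midpoint cut is perfect."""
    rng = np.random.default_rng(3)
    cases = []
    for i in range(n_per_class):
        cases.append(
            make_record(
                f"l{i}", int(rng.integers(20, 35)),
                adc=float(rng.uniform(0.4, 1.0)) if with_adc else None,
                label=LYMPHOMA, lo_bin=60,
            )
        )
        cases.append(
            make_record(
                f"g{i}", int(rng.integers(120, 180)),
                adc=float(rng.uniform(0.6, 1.4)) if with_adc else None,
                label=GLIOBLASTOMA, lo_bin=20,
            )
        )
    return cases


def test_metrics_all_correct():
    truth = [LYMPHOMA, GLIOBLASTOMA]
    assert metrics(list(truth), truth) == (1.0, 1.0, 1.0)


def test_metrics_hand_confusion_table():
    """2 lymphomas called glioblastoma, 2 glioblastomas called glioblastoma."""
    truth = [LYMPHOMA, LYMPHOMA, GLIOBLASTOMA, GLIOBLASTOMA]
    pred = [GLIOBLASTOMA] * 4
    acc, sens, spec = metrics(pred, truth)
    assert (acc, sens, spec) == (0.5, 0.0, 1.0)


def test_metrics_absent_class_is_nan():
    acc, sens, spec = metrics([LYMPHOMA], [LYMPHOMA])
    assert acc == 1.0 and sens == 1.0 and np.isnan(spec)


def test_metrics_length_mismatch_errors():
    with pytest.raises(ValueError, match="aligned"):
        metrics([LYMPHOMA], [LYMPHOMA, GLIOBLASTOMA])


def test_accuracy_decomposition():
    """accuracy == (sens * n_lym + spec * n_gbm) / n, exactly, per repetition."""
    rng = np.random.default_rng(9)
    labels = (LYMPHOMA, GLIOBLASTOMA)
    for _ in range(50):
        n_lym, n_gbm = rng.integers(1, 10, size=2)
        truth = [LYMPHOMA] * n_lym + [GLIOBLASTOMA] * n_gbm
        pred = [labels[i] for i in rng.integers(0, 2, size=n_lym + n_gbm)]
        acc, sens, spec = metrics(pred, truth)
        assert acc == pytest.approx((sens * n_lym + spec * n_gbm) / (n_lym + n_gbm))


def test_split_sizes_at_k_max():
    """k = 19 on a 20+20 cohort leaves exactly one test case per class."""
    train, test = _split_indices(20, 20, k=19, seed=0, rep=0)
    assert len(train) == 38 and len(test) == 2
    assert sum(i < 20 for i in test) == 1 and sum(i >= 20 for i in test) == 1


def test_splits_independent_of_method_and_kernel():
    a = _split_indices(10, 10, 3, seed=5, rep=7)
    b = _split_indices(10, 10, 3, seed=5, rep=7)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    c = _split_indices(10, 10, 3, seed=5, rep=8)
    assert not np.array_equal(a[0], c[0])


def test_evaluation_is_deterministic():
    cohort = _gapped_cohort()
    cfg = EvalConfig(k_values=[3], repetitions=1, method="full_hybrid", seed=11)
    df1 = random_split_evaluate(cohort, cfg)
    df2 = random_split_evaluate(cohort, cfg)
    pd.testing.assert_frame_equal(df1, df2)


def test_range_baseline_perfect_on_gapped_cohort():
    cohort = _gapped_cohort(with_adc=False)
    cfg = EvalConfig(k_values=[1, 3, 5, 7], repetitions=30, method="range_baseline", seed=2)
    df = random_split_evaluate(cohort, cfg)
    assert np.allclose(df["accuracy"], 1.0)
    assert np.allclose(df["sensitivity"], 1.0)
    assert np.allclose(df["specificity"], 1.0)


def test_k_bounds_validation():
    cohort = _gapped_cohort(n_per_class=4)
    with pytest.raises(ValueError, match="out of bounds"):
        random_split_evaluate(cohort, EvalConfig(k_values=[4], repetitions=1, seed=0))
    with pytest.raises(ValueError, match="out of bounds"):
        random_split_evaluate(cohort, EvalConfig(k_values=[0], repetitions=1, seed=0))


def test_unknown_method_rejected():
    with pytest.raises(ValueError, match="unknown method"):
        EvalConfig(method="deep_net")


def test_threshold_sweep_reruns_per_th():
    cohort = _gapped_cohort()
    cfg = EvalConfig(k_values=[3], repetitions=5, method="range_baseline", seed=4)
    df = threshold_sweep(cohort, [0.0, 0.001, 0.003], cfg)
    assert sorted(df["th"].unique()) == [0.0, 0.001, 0.003]
    assert not df["flagged"].any()
    assert np.allclose(df["accuracy"], 1.0)


def test_threshold_sweep_flags_degenerate_th():
    cohort = _gapped_cohort()
    cfg = EvalConfig(k_values=[3], repetitions=5, method="range_baseline", seed=4)
    df = threshold_sweep(cohort, [0.7], cfg)  # every histogram fully sub-threshold
    assert df["flagged"].all()
    assert df["accuracy"].isna().all()
    assert (df["flagged_cases"].str.len() > 0).all()


def test_kernel_comparison_runs_all_kernels_on_shared_splits():
    cohort = _gapped_cohort()
    cfg = EvalConfig(k_values=[3], repetitions=5, method="svm_only", seed=6)
    kernels = ["linear", "gaussian", "chi_square", "histogram_intersection"]
    df = kernel_comparison(cohort, kernels, cfg)
    assert sorted(df["kernel"].unique()) == sorted(kernels)
    assert (df["repetitions"] == 5).all()
    assert df["accuracy"].between(0, 1).all()


def test_more_training_data_never_hurts(records2020):
    """Mean full-hybrid accuracy at k = 19 is at least its k = 1 value - 0.02."""
    cfg = EvalConfig(k_values=[1, 19], repetitions=100, method="full_hybrid", seed=13)
    df = random_split_evaluate(records2020, cfg).set_index("k")
    assert df.loc[19, "accuracy"] >= df.loc[1, "accuracy"] - 0.02
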