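"""Shared fixtures: seeded phantom cohorts and synthetic feature records."""

from __future__ import annotations

import numpy as np
import pytest

from histogate import (
    CaseRecord,
    LuminanceHistogram,
    PhantomParams,
    RangeFeature,
    generate_cohort,
    records_from_cohort,
)

COHORT_SEED = 7


@pytest.fixture(scope="session")
def default_params() -> PhantomParams:
    return PhantomParams()


@pytest.fixture(scope="session")
def noiseless_params() -> PhantomParams:
    """All stochastic intensity sources off: exact two/three-intensity images."""
    return PhantomParams(
        noise_sigma=0.0,
        lymphoma_sd_lum=0.0,
        gbm_sd_lum=0.0,
        background_sd_lum=0.0,
    )


@pytest.fixture(scope="session")
def cohort2020(default_params):
    """The 20+20 study cohort at default generator conditions."""
    return generate_cohort(20, 20, default_params, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def records2020(cohort2020):
    """Feature records (th = 0.002, ground-truth masks) for the study cohort."""
    return records_from_cohort(cohort2020)


def make_record(
    case_id: str,
    range_value: int,
    adc: float | None = None,
    label: str | None = None,
    lo_bin: int = 10,
    th: float = 0.002,
) -> CaseRecord:
    """A minimal consistent CaseRecord with a prescribed range feature.

    Two equal-mass bins at ``lo_bin`` and ``lo_bin + range_value`` (one bin
    when the range is 0) give exactly the requested supra-threshold span.
    """
    freqs = np.zeros(256)
    hi_bin = lo_bin + range_value
    assert hi_bin <= 255
    if range_value == 0:
        freqs[lo_bin] = 1.0
    else:
        freqs[lo_bin] = 0.5
        freqs[hi_bin] = 0.5
    hist = LuminanceHistogram(freqs=freqs, n_voxels=1000)
    rf = RangeFeature(lo_bin=lo_bin, hi_bin=hi_bin, range_value=range_value, threshold_used=th)
    return CaseRecord(case_id=case_id, histogram=hist, range_feature=rf, adc_value=adc, label=label)


def random_feature_cohort(rng: np.random.Generator, n_per_class: int = 6) -> list[CaseRecord]:
    """A labeled cohort of synthetic feature records with random range/ADC values."""
    from histogate import GLIOBLASTOMA, LYMPHOMA

    cases = []
    for i in range(n_per_class):
        cases.append(
            make_record(
                f"lym_{i}",
                int(rng.integers(5, 120)),
                adc=float(rng.uniform(0.3, 1.2)),
                label=LYMPHOMA,
                lo_bin=int(rng.integers(0, 100)),
            )
        )
        cases.append(
            make_record(
                f"gbm_{i}",
                int(rng.integers(30, 220)),
                adc=float(rng.uniform(0.5, 1.7)),
                label=GLIOBLASTOMA,
                lo_bin=int(rng.integers(0, 30)),
            )
        )
    return cases
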