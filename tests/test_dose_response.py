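"""Percent inhibition, Logit IC50 fitting, and potency comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inhibkit import (
    AssayRecord,
    DoseResponse,
    SyntheticConfig,
    compare_to_reference,
    fit_ic50_logit,
    fold_potency,
    gen_dose_response,
    percent_inhibition,
)
from inhibkit.errors import (
    ExtrapolationError,
    InsufficientDataError,
    InsufficientReplicatesError,
    InvalidControlError,
    ValidationError,
)

NOISELESS = SyntheticConfig()


@pytest.mark.parametrize(
    "control,sample,expected",
    [(1.0, 0.5, 50.0), (0.73, 0.73, 0.0), (0.8, 0.0, 100.0)],
)
def test_percent_inhibition_arithmetic(control, sample, expected):
    assert percent_inhibition(control, sample) == pytest.approx(expected)


def test_percent_inhibition_rejects_nonpositive_control():
    with pytest.raises(InvalidControlError):
        percent_inhibition(0.0, 0.5)


def test_negative_inhibition_returned_not_truncated():
    assert percent_inhibition(0.5, 0.6) == pytest.approx(-20.0)


@given(
    scale=st.floats(min_value=1e-3, max_value=1e3),
    control=st.floats(min_value=0.1, max_value=2.0),
    sample=st.floats(min_value=0.0, max_value=2.0),
)
@settings(derandomize=True, max_examples=50)
def test_percent_inhibition_scale_invariant(scale, control, sample):
    """Rescaling both absorbances by the same factor leaves % inhibition fixed."""
    base = percent_inhibition(control, sample)
    scaled = percent_inhibition(scale * control, scale * sample)
    assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


@pytest.mark.parametrize("ic50_true", [100.0, 12.44])
def test_logit_fit_inverts_noiseless_logistic(ic50_true):
    """Noiseless one-site logistic data invert to the generating IC50."""
    grid = ic50_true * np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    dr = gen_dose_response(ic50_true, 1.0, grid, NOISELESS)
    fit = fit_ic50_logit(dr)
    assert fit.ic50_uM == pytest.approx(ic50_true, rel=1e-9)
    assert fit.slope > 0
    assert fit.r2 == pytest.approx(1.0)


@given(
    log_ic50=st.floats(min_value=0.0, max_value=3.0),
    n_extra=st.integers(min_value=0, max_value=4),
)
@settings(derandomize=True, max_examples=60)
def test_logit_fit_recovery_property(log_ic50, n_extra):
    """Recovery holds for any IC50 in [1, 1000] uM on a geometric grid spanning it."""
    ic50_true = 10.0**log_ic50
    ratios = np.geomspace(0.2, 5.0, 3 + n_extra)
    dr = gen_dose_response(ic50_true, 1.0, ic50_true * ratios, NOISELESS)
    fit = fit_ic50_logit(dr)
    assert fit.ic50_uM == pytest.approx(ic50_true, rel=1e-6)


def test_logit_fit_noisy_recovery_median_under_10pct():
    """5% multiplicative noise: 100 replicate fits, median relative error < 10%."""
    ic50_true = 12.44
    grid = ic50_true * np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    errs = []
    for seed in range(100):
        cfg = SyntheticConfig(seed, "multiplicative_gaussian", 0.05)
        fit = fit_ic50_logit(gen_dose_response(ic50_true, 1.0, grid, cfg))
        errs.append(abs(fit.ic50_uM - ic50_true) / ic50_true)
    assert np.median(errs) < 0.10


def test_logit_fit_replicates_report_mean_and_sd():
    cfg = SyntheticConfig(7, "multiplicative_gaussian", 0.05)
    grid = np.array([3.11, 6.22, 12.44, 24.88, 49.76])
    dr = gen_dose_response(12.44, 1.0, grid, cfg, n_replicates=3)
    fit = fit_ic50_logit(dr)
    assert fit.sd_uM is not None and fit.sd_uM > 0
    assert fit.ic50_uM == pytest.approx(12.44, rel=0.2)


def test_logit_fit_all_low_inhibition_is_extrapolation():
    dr = DoseResponse("weak", [1.0, 2.0, 4.0], [1.0, 2.5, 4.5])
    with pytest.raises(ExtrapolationError):
        fit_ic50_logit(dr)


def test_dose_response_needs_three_distinct_concentrations():
    with pytest.raises(InsufficientDataError):
        DoseResponse("x", [1.0, 1.0, 2.0], [10.0, 12.0, 60.0])


def test_from_records_converts_absorbances():
    records = [
        AssayRecord("cpd", c, 1, 1.0, a)
        for c, a in [(5.0, 0.9), (10.0, 0.6), (20.0, 0.4), (40.0, 0.2)]
    ]
    dr = DoseResponse.from_records(records)
    assert dr.pct_inhibition == pytest.approx([10.0, 40.0, 60.0, 80.0])


@pytest.mark.parametrize(
    "ref,sample,expected", [(750.0, 12.44, 60.3), (7.0, 7.0, 1.0), (750.0, 375.0, 2.0)]
)
def test_fold_potency(ref, sample, expected):
    assert fold_potency(ref, sample) == pytest.approx(expected, abs=0.05)


@given(
    a=st.floats(min_value=1e-3, max_value=1e4),
    b=st.floats(min_value=1e-3, max_value=1e4),
)
@settings(derandomize=True, max_examples=50)
def test_fold_potency_reciprocal_identity(a, b):
    assert fold_potency(a, b) * fold_potency(b, a) == pytest.approx(1.0, rel=1e-12)


def test_fold_potency_rejects_nonpositive():
    with pytest.raises(ValidationError):
        fold_potency(-1.0, 5.0)


def test_welch_t_test_identical_lists():
    t, p = compare_to_reference([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
    assert t == 0.0 and p == 1.0


def test_welch_t_test_separated_groups_significant():
    """Triplicate IC50s far apart (lead vs reference scale) give p << 0.001."""
    sample = [12.06, 12.44, 12.82]  # mean 12.44, sd 0.38
    ref = [748.5, 750.0, 751.5]  # mean 750.0, sd 1.5
    t, p = compare_to_reference(sample, ref)
    assert p < 0.001
    assert t < 0


def test_welch_t_test_requires_replicates():
    with pytest.raises(InsufficientReplicatesError):
        compare_to_reference([5.0], [4.0, 4.5])
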