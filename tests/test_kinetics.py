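"""Lineweaver-Burk fitting, the Km_app replot, Ki extraction and
inhibition-mode classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from inhibkit import (
    KineticFitPerI,
    SyntheticConfig,
    analyze_kinetics,
    classify_inhibition_mode,
    gen_velocity_dataset,
    ki_from_replot,
    km_app,
    lineweaver_burk_fit,
    michaelis_menten_velocity,
)
from inhibkit.errors import (
    InsufficientDataError,
    NoInhibitionError,
    ValidationError,
)

NOISELESS = SyntheticConfig()


@pytest.mark.parametrize(
    "vmax,km,s,expected",
    [
        (1.0, 2.0, 2.0, 0.5),  # v = Vmax/2 at S = Km
        (1.0, 2.0, 2e6, 1.0),  # saturation limit
        (1.0, 4.0, 4.0, 0.5),  # Km doubled by [I] = Ki, evaluated at S = Km_app
    ],
)
def test_michaelis_menten_velocity(vmax, km, s, expected):
    assert michaelis_menten_velocity(vmax, km, s) == pytest.approx(expected, rel=1e-6)


def test_michaelis_menten_rejects_nonpositive():
    with pytest.raises(ValidationError):
        michaelis_menten_velocity(1.0, 0.0, 2.0)


@pytest.mark.parametrize(
    "km,i,ki,expected",
    [(3.0, 0.0, 11.0, 3.0), (3.0, 11.0, 11.0, 6.0), (1.0, 12.4, 11.0, 2.127)],
)
def test_km_app_competitive_scaling(km, i, ki, expected):
    assert km_app(km, i, ki) == pytest.approx(expected, abs=5e-4)


@given(
    km=st.floats(min_value=0.1, max_value=10.0),
    i1=st.floats(min_value=0.0, max_value=50.0),
    di=st.floats(min_value=0.1, max_value=50.0),
    ki=st.floats(min_value=1.0, max_value=100.0),
)
@settings(derandomize=True, max_examples=50)
def test_km_app_monotone_in_inhibitor_and_ki(km, i1, di, ki):
    assert km_app(km, i1 + di, ki) > km_app(km, i1, ki)
    assert km_app(km, i1 + di, 2 * ki) < km_app(km, i1 + di, ki)


def test_lineweaver_burk_exact_double_reciprocal_line():
    s = np.array([1.0, 2.0, 4.0, 8.0])
    v = s / (2.0 + s)
    fit = lineweaver_burk_fit(s, v)
    assert fit.slope == pytest.approx(2.0, rel=1e-9)
    assert fit.intercept == pytest.approx(1.0, rel=1e-9)
    assert fit.km_app_mM == pytest.approx(2.0, rel=1e-9)
    assert fit.vmax == pytest.approx(1.0, rel=1e-9)


def test_lineweaver_burk_zero_order_regime_flagged():
    s = np.array([1.0, 2.0, 4.0])
    fit = lineweaver_burk_fit(s, np.full(3, 0.8))
    assert fit.slope == 0.0
    assert fit.km_app_mM == 0.0
    assert any("degenerate" in w for w in fit.warnings)


def test_lineweaver_burk_needs_three_points():
    with pytest.raises(InsufficientDataError):
        lineweaver_burk_fit(np.array([1.0, 2.0]), np.array([0.3, 0.5]))


def test_lineweaver_burk_matches_nonlinear_fit_oracle():
    """Double-reciprocal Km_app equals a direct Michaelis-Menten fit (noiseless)."""
    s = np.arange(1.0, 11.0)
    for km_true in (0.5, 2.0, 8.0):
        v = 1.3 * s / (km_true + s)
        fit = lineweaver_burk_fit(s, v)
        (vmax_nl, km_nl), _ = curve_fit(
            lambda x, vm, km: vm * x / (km + x), s, v, p0=(1.0, 1.0)
        )
        assert fit.km_app_mM == pytest.approx(km_nl, rel=1e-8)
        assert fit.vmax == pytest.approx(vmax_nl, rel=1e-8)


def test_ki_from_replot_study_grid():
    """Replot of Km_app over the 0/3.1/6.2/12.4 uM grid inverts to Ki = 11."""
    pairs = [(i, km_app(1.0, i, 11.0)) for i in (0.0, 3.1, 6.2, 12.4)]
    res = ki_from_replot(pairs)
    assert res.ki_uM == pytest.approx(11.0, rel=1e-9)
    assert res.km_mM == pytest.approx(1.0, rel=1e-9)


def test_ki_from_replot_two_point_line():
    res = ki_from_replot([(0.0, 2.0), (2.0, 4.0)])
    assert res.ki_uM == pytest.approx(2.0)
    assert res.km_mM == pytest.approx(2.0)


def test_ki_from_replot_decreasing_km_app_is_no_inhibition():
    with pytest.raises(NoInhibitionError):
        ki_from_replot([(0.0, 2.0), (5.0, 1.5), (10.0, 1.0)])


@given(
    km=st.floats(min_value=0.5, max_value=10.0),
    ki=st.floats(min_value=1.0, max_value=100.0),
    vmax=st.floats(min_value=0.5, max_value=5.0),
)
@settings(derandomize=True, max_examples=60)
def test_round_trip_parameter_recovery(km, ki, vmax):
    """Noiseless data on the study grids invert to the generating (Km, Ki, Vmax)."""
    ds = gen_velocity_dataset(km_mM=km, vmax=vmax, ki_uM=ki, cfg=NOISELESS)
    fits, res = analyze_kinetics(ds)
    assert res.ki_uM == pytest.approx(ki, rel=1e-6)
    assert res.km_mM == pytest.approx(km, rel=1e-6)
    assert all(f.vmax == pytest.approx(vmax, rel=1e-6) for f in fits)


def _fit(i, km, vm):
    return KineticFitPerI(
        inhibitor_uM=i, slope=km / vm, intercept=1 / vm, km_app_mM=km, vmax=vm, r2=1.0
    )


@pytest.mark.parametrize(
    "kms,vmaxes,expected",
    [
        ([1.0, 1.28, 1.56, 2.13], [1.0, 1.0, 1.0, 1.0], "competitive"),
        ([2.0, 2.0, 2.0], [1.0, 0.8, 0.6], "noncompetitive"),
        ([2.0, 1.5, 1.0], [1.0, 0.75, 0.5], "uncompetitive"),
        ([1.0, 1.5, 2.0], [1.0, 0.7, 0.5], "mixed"),
    ],
)
def test_classify_inhibition_mode_patterns(kms, vmaxes, expected):
    fits = [_fit(float(i), km, vm) for i, (km, vm) in enumerate(zip(kms, vmaxes))]
    assert classify_inhibition_mode(fits) == expected


def test_classify_requires_two_fits():
    with pytest.raises(InsufficientDataError):
        classify_inhibition_mode([_fit(0.0, 1.0, 1.0)])


def test_classification_robust_to_2pct_noise():
    """Competitive generation stays classified competitive in >=95/100 runs."""
    hits = 0
    for seed in range(100):
        cfg = SyntheticConfig(seed, "multiplicative_gaussian", 0.02)
        _, res = analyze_kinetics(gen_velocity_dataset(cfg=cfg))
        hits += res.mode == "competitive"
    assert hits >= 95
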