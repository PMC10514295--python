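"""Competitive-inhibition kinetics: Lineweaver-Burk fits, the Km_app
replot, Ki extraction, and inhibition-mode classification.

For each inhibitor concentration [I], initial velocities over a substrate
series are fitted in double-reciprocal space:

    1/v = (Km_app/Vmax) * (1/[S]) + 1/Vmax

so Vmax = 1/intercept and Km_app = slope/intercept.  Under competitive
inhibition Km_app = Km * (1 + [I]/Ki), hence the secondary replot of
Km_app against [I] is a line with intercept Km and slope Km/Ki; Ki is
intercept/slope.

The fits are unweighted least squares in reciprocal space, matching the
classical graphical treatment; a direct nonlinear Michaelis-Menten fit is
used only as a cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidReplotError,
    NoInhibitionError,
    NonSaturatingDataError,
    ValidationError,
)

#: Relative-spread tolerances below which Vmax (tau_v) or Km_app (tau_k)
#: are treated as constant across the inhibitor series.
TAU_V = 0.10
TAU_K = 0.10


@dataclass
class VelocityDataset:
    """Initial-velocity matrix over a substrate x inhibitor grid."""

    inhibitor_uM: np.ndarray  # one entry per row of v
    substrate_mM: np.ndarray  # one entry per column of v
    v: np.ndarray

    def __post_init__(self) -> None:
        self.inhibitor_uM = np.asarray(self.inhibitor_uM, dtype=float)
        self.substrate_mM = np.asarray(self.substrate_mM, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != (self.inhibitor_uM.size, self.substrate_mM.size):
            raise ValidationError(
                f"velocity matrix shape {self.v.shape} does not match grids "
                f"({self.inhibitor_uM.size} inhibitor x {self.substrate_mM.size} substrate)"
            )
        if np.any(self.substrate_mM <= 0):
            raise ValidationError("substrate concentrations must be > 0")
        if np.any(self.v <= 0):
            raise ValidationError("velocities must be > 0")
        if self.substrate_mM.size < 3:
            raise InsufficientDataError("need >= 3 substrate concentrations")
        if self.inhibitor_uM.size < 2 or not np.any(self.inhibitor_uM == 0):
            raise ValidationError(
                "need >= 2 inhibitor concentrations including an uninhibited row"
            )


@dataclass
class KineticFitPerI:
    """Lineweaver-Burk line for one inhibitor concentration."""

    inhibitor_uM: float
    slope: float
    intercept: float
    km_app_mM: float
    vmax: float
    r2: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class KiResult:
    """Secondary-replot outcome: uninhibited Km, Ki, and inhibition mode."""

    ki_uM: float
    km_mM: float
    replot_slope: float
    r2: float
    mode: str | None = None


def michaelis_menten_velocity(vmax: float, km_app_mM: float, s_mM: float) -> float:
    """Michaelis-Menten rate: v = Vmax * [S] / (Km_app + [S])."""
    if vmax <= 0 or km_app_mM <= 0 or s_mM <= 0:
        raise ValidationError("vmax, km_app and substrate must all be > 0")
    return vmax * s_mM / (km_app_mM + s_mM)


def km_app(km_mM: float, i_uM: float, ki_uM: float) -> float:
    """Apparent Km under competitive inhibition: Km * (1 + [I]/Ki)."""
    if ki_uM <= 0:
        raise ValidationError(f"ki_uM must be > 0, got {ki_uM}")
    if km_mM <= 0:
        raise ValidationError(f"km_mM must be > 0, got {km_mM}")
    if i_uM < 0:
        raise ValidationError(f"i_uM must be >= 0, got {i_uM}")
    return km_mM * (1.0 + i_uM / ki_uM)


def lineweaver_burk_fit(
    s_mM: np.ndarray, v: np.ndarray, inhibitor_uM: float = 0.0
) -> KineticFitPerI:
    """Fit one double-reciprocal line: OLS of 1/v on 1/[S].

    Vmax = 1/intercept and Km_app = slope/intercept.  Velocities constant
    across substrate (zero-order regime) give slope = 0 and Km_app = 0
    with a degenerate-data warning rather than an error.
    """
    s = np.asarray(s_mM, dtype=float)
    vel = np.asarray(v, dtype=float)
    if s.size < 3:
        raise InsufficientDataError("need >= 3 substrate points per line")
    if np.any(s <= 0) or np.any(vel <= 0):
        raise ValidationError("substrate and velocity values must be > 0")
    res = stats.linregress(1.0 / s, 1.0 / vel)
    if res.intercept <= 0:
        raise NonSaturatingDataError(
            f"reciprocal intercept {res.intercept:.3g} <= 0: "
            "velocities do not saturate"
        )
    warnings: list[str] = []
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else float("nan")
    if res.slope == 0 or np.allclose(vel, vel[0]):
        warnings.append(
            "degenerate data: velocity independent of substrate (zero-order regime)"
        )
    return KineticFitPerI(
        inhibitor_uM=float(inhibitor_uM),
        slope=float(res.slope),
        intercept=float(res.intercept),
        km_app_mM=float(res.slope / res.intercept),
        vmax=float(1.0 / res.intercept),
        r2=r2,
        warnings=warnings,
    )


def fit_velocity_dataset(ds: VelocityDataset) -> list[KineticFitPerI]:
    """One Lineweaver-Burk fit per inhibitor concentration, ordered by [I]."""
    order = np.argsort(ds.inhibitor_uM)
    return [
        lineweaver_burk_fit(ds.substrate_mM, ds.v[i], ds.inhibitor_uM[i])
        for i in order
    ]


def ki_from_replot(pairs: list[tuple[float, float]]) -> KiResult:
    """Ki from the secondary replot of Km_app against [I].

    Km_app = Km + (Km/Ki) * [I]; OLS gives intercept Km and slope Km/Ki,
    so Ki = intercept/slope.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be (inhibitor_uM, km_app_mM) tuples")
    i_uM, km_vals = arr[:, 0], arr[:, 1]
    if np.unique(i_uM).size < 2:
        raise InsufficientDataError("need >= 2 distinct inhibitor concentrations")
    if np.any(km_vals <= 0):
        raise ValidationError("Km_app values must be > 0")
    res = stats.linregress(i_uM, km_vals)
    if res.slope <= 0:
        raise NoInhibitionError(
            f"replot slope {res.slope:.3g} <= 0: Km_app does not increase "
            "with inhibitor; Ki is undefined"
        )
    if res.intercept <= 0:
        raise InvalidReplotError(
            f"replot intercept {res.intercept:.3g} <= 0: no valid uninhibited Km"
        )
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else float("nan")
    return KiResult(
        ki_uM=float(res.intercept / res.slope),
        km_mM=float(res.intercept),
        replot_slope=float(res.slope),
        r2=r2,
    )


def _rel_spread(x: np.ndarray) -> float:
    return float((x.max() - x.min()) / np.mean(x))


def _increasing(x: np.ndarray, tau: float) -> bool:
    return bool(np.all(np.diff(x) > 0) and (x[-1] - x[0]) / x[0] > tau)


def _decreasing(x: np.ndarray, tau: float) -> bool:
    return bool(np.all(np.diff(x) < 0) and (x[0] - x[-1]) / x[0] > tau)


def classify_inhibition_mode(
    fits: list[KineticFitPerI], tau_v: float = TAU_V, tau_k: float = TAU_K
) -> str:
    """Classify the inhibition mode from per-[I] kinetic fits.

    competitive    - Vmax constant (relative spread < tau_v) while Km_app
                     rises monotonically by more than tau_k overall;
    noncompetitive - Km_app constant while Vmax falls monotonically;
    uncompetitive  - both fall monotonically;
    mixed          - anything else.
    """
    if len(fits) < 2:
        raise InsufficientDataError("need >= 2 inhibitor concentrations to classify")
    fits = sorted(fits, key=lambda f: f.inhibitor_uM)
    km_vals = np.array([f.km_app_mM for f in fits])
    vmax_vals = np.array([f.vmax for f in fits])
    if _rel_spread(vmax_vals) < tau_v and _increasing(km_vals, tau_k):
        return "competitive"
    if _rel_spread(km_vals) < tau_k and _decreasing(vmax_vals, tau_v):
        return "noncompetitive"
    if _decreasing(km_vals, tau_k) and _decreasing(vmax_vals, tau_v):
        return "uncompetitive"
    return "mixed"


def analyze_kinetics(ds: VelocityDataset) -> tuple[list[KineticFitPerI], KiResult]:
    """Full kinetics pipeline: per-[I] fits, replot Ki, and mode label."""
    fits = fit_velocity_dataset(ds)
    result = ki_from_replot([(f.inhibitor_uM, f.km_app_mM) for f in fits])
    result.mode = classify_inhibition_mode(fits)
    return fits, result
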