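"""Fluorescence static-quench binding analysis.

A protein at fixed total concentration Pt is titrated with ligand (total
concentration Dt) and the intrinsic fluorescence F recorded.  Under a
static-quench model only free protein fluoresces, so F0/F = Pt/Pf.  With
an association constant KA and site number n, mass balance over free and
complexed species yields an exactly linear relation in the transformed
coordinates

    y = F0/F,   x = Dt * F0 / (F0 - F):      y = KA * x - n * KA * Pt

(the intercept is -n*KA*Pt, the slope is KA).  This rearrangement follows
algebraically from the complex-formation equilibrium and the two mass
balances Pt = Pf + [complex], Df = Dt - n*[complex]; it also matches the
conventional plot of F0/F against Dt*F0/(F0-F).  Fitting the transformed
points by ordinary least squares therefore recovers KA from the slope and
n from -intercept/(slope*Pt).

KA is an equilibrium association constant in L/mol.  Whether quenching is
static or dynamic is decided from its temperature dependence: a complex
that dissociates on warming (KA falling with T) indicates static
quenching, while collisional (dynamic) quenching grows with T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidBindingError,
    MissingBaselineError,
    NoQuenchingError,
    ValidationError,
)

#: Relative change in KA below which the temperature trend is called flat.
QUENCH_REL_TOL = 0.01


@dataclass
class FluorescenceTitration:
    """Intensity series at fixed total protein and one temperature.

    The dt = 0 point defines F0.  Intensities above F0 are physically
    inconsistent with quenching and are flagged (then excluded by the
    transform).  Concentrations are molar throughout.
    """

    temperature_K: float
    pt_M: float
    dt_M: np.ndarray
    intensity: np.ndarray
    excitation_nm: float | None = None
    emission_peak_nm: float | None = None

    def __post_init__(self) -> None:
        self.dt_M = np.asarray(self.dt_M, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.pt_M <= 0:
            raise ValidationError(f"pt_M must be > 0, got {self.pt_M}")
        if self.dt_M.size != self.intensity.size:
            raise ValidationError("dt and intensity arrays must have equal length")
        if np.any(self.dt_M < 0) or np.any(self.intensity <= 0):
            raise ValidationError("dt must be >= 0 and intensities > 0")
        if np.sum(self.dt_M == 0) != 1:
            raise MissingBaselineError(
                "titration must contain exactly one dt = 0 point (defines F0)"
            )
        order = np.argsort(self.dt_M)
        self.dt_M = self.dt_M[order]
        self.intensity = self.intensity[order]
        if np.any(np.diff(self.dt_M) <= 0):
            raise ValidationError("ligand concentrations must be strictly increasing")

    @property
    def f0(self) -> float:
        return float(self.intensity[self.dt_M == 0][0])


@dataclass
class BindingFit:
    """Linearized quench-plot fit at one temperature."""

    temperature_K: float
    ka_per_M: float
    n_sites: float
    r: float
    n_points: int = 0
    excluded_points: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def quench_transform(t: FluorescenceTitration) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Map a titration onto the linear quench coordinates.

    Returns (x, y, excluded) with x = dt*F0/(F0-F) and y = F0/F for each
    quenched point (dt > 0, F < F0); unquenched points are excluded and
    their dt values reported.
    """
    f0 = t.f0
    mask = t.dt_M > 0
    dt = t.dt_M[mask]
    f = t.intensity[mask]
    quenched = f < f0
    excluded = [float(d) for d in dt[~quenched]]
    if not np.any(quenched):
        raise NoQuenchingError(
            "no titration point lies below F0; cannot form the quench plot"
        )
    dt, f = dt[quenched], f[quenched]
    x = dt * f0 / (f0 - f)
    y = f0 / f
    return x, y, excluded


def estimate_binding(t: FluorescenceTitration) -> BindingFit:
    """Estimate KA and n from a titration by the linearized quench fit.

    OLS of y on x gives KA = slope and n = -intercept/(slope*Pt); r is the
    Pearson correlation of the transformed points.
    """
    x, y, excluded = quench_transform(t)
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 quenched points to fit, got {x.size}"
        )
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise InvalidBindingError(
            f"quench-plot slope {res.slope:.3g} <= 0: no binding constant"
        )
    warnings = []
    if excluded:
        warnings.append(
            f"{len(excluded)} unquenched point(s) excluded at dt (M): {excluded}"
        )
    return BindingFit(
        temperature_K=t.temperature_K,
        ka_per_M=float(res.slope),
        n_sites=float(-res.intercept / (res.slope * t.pt_M)),
        r=float(res.rvalue),
        n_points=int(x.size),
        excluded_points=excluded,
        warnings=warnings,
    )


def classify_quenching(fit_low_T: BindingFit, fit_high_T: BindingFit) -> str:
    """Static vs dynamic quenching from KA's temperature dependence.

    static  - KA falls with temperature by more than QUENCH_REL_TOL
              (ground-state complex dissociates on warming);
    dynamic - KA rises by more (collisional quenching grows with T);
    indeterminate - the change is within tolerance.
    """
    if fit_low_T.temperature_K >= fit_high_T.temperature_K:
        raise ValidationError(
            "fit_low_T must be at a strictly lower temperature than fit_high_T"
        )
    rel = (fit_high_T.ka_per_M - fit_low_T.ka_per_M) / fit_low_T.ka_per_M
    if rel < -QUENCH_REL_TOL:
        return "static"
    if rel > QUENCH_REL_TOL:
        return "dynamic"
    return "indeterminate"
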