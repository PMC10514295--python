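"""Dose-response analysis: percent inhibition and Logit-method IC50.

Raw plate readings (control vs sample absorbance) are converted to percent
inhibition, and the IC50 is estimated by the Logit method: ordinary least
squares of ln(p/(1-p)) on log10(concentration), with p the inhibited
fraction.  The IC50 is the concentration where the fitted line crosses
p = 0.5, i.e. 10^(-intercept/slope).

Fractions are clipped to [0.01, 0.99] before the logit transform so that
0% and 100% observations stay finite; clipped points are retained in the
fit but counted in the result's warnings.  Negative percent inhibition
(activation) is kept, not truncated, because truncation would bias the
line fit - the clip band governs such points instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    ExtrapolationError,
    InsufficientDataError,
    InsufficientReplicatesError,
    InvalidControlError,
    NonInhibitorError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Clip band for the inhibited fraction before the logit transform.
LOGIT_CLIP = (0.01, 0.99)


@dataclass(frozen=True)
class AssayRecord:
    """One well: compound, concentration, replicate and paired absorbances."""

    compound_id: str
    conc_uM: float
    replicate: int
    abs_control: float
    abs_sample: float

    def __post_init__(self) -> None:
        if self.conc_uM < 0:
            raise ValidationError(f"conc_uM must be >= 0, got {self.conc_uM}")
        if self.abs_control <= 0:
            raise InvalidControlError(
                f"abs_control must be > 0, got {self.abs_control}"
            )
        if self.abs_sample < 0:
            raise ValidationError(f"abs_sample must be >= 0, got {self.abs_sample}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")


@dataclass
class DoseResponse:
    """Percent-inhibition series for one compound, optionally replicated."""

    compound_id: str
    conc_uM: np.ndarray
    pct_inhibition: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        self.pct_inhibition = np.asarray(self.pct_inhibition, dtype=float)
        if self.replicate is None:
            self.replicate = np.ones(self.conc_uM.size, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate, dtype=int)
        if not (self.conc_uM.size == self.pct_inhibition.size == self.replicate.size):
            raise ValidationError("conc/pct/replicate arrays must have equal length")
        if np.any(self.conc_uM <= 0):
            raise ValidationError("dose-response concentrations must be > 0")
        if np.unique(self.conc_uM).size < 3:
            raise InsufficientDataError(
                "need >= 3 distinct positive concentrations"
            )
        order = np.lexsort((self.replicate, self.conc_uM))
        self.conc_uM = self.conc_uM[order]
        self.pct_inhibition = self.pct_inhibition[order]
        self.replicate = self.replicate[order]

    @classmethod
    def from_records(cls, records: list[AssayRecord]) -> "DoseResponse":
        """Build a series from assay records of a single compound."""
        if not records:
            raise InsufficientDataError("no assay records supplied")
        ids = {r.compound_id for r in records}
        if len(ids) != 1:
            raise ValidationError(f"records mix compounds: {sorted(ids)}")
        kept = [r for r in records if r.conc_uM > 0]
        return cls(
            compound_id=records[0].compound_id,
            conc_uM=np.array([r.conc_uM for r in kept]),
            pct_inhibition=np.array(
                [percent_inhibition(r.abs_control, r.abs_sample) for r in kept]
            ),
            replicate=np.array([r.replicate for r in kept]),
        )


@dataclass
class IC50Fit:
    """Logit-line fit summary; ic50_uM is where the line crosses 50%."""

    compound_id: str
    ic50_uM: float
    slope: float
    intercept: float
    r2: float
    sd_uM: float | None = None
    n_points: int = 0
    warnings: list[str] = field(default_factory=list)


def percent_inhibition(abs_control: float, abs_sample: float) -> float:
    """Percent inhibition from paired absorbances.

    Returns ``100 * (abs_control - abs_sample) / abs_control``.  Values
    below zero (apparent activation) are returned as-is with a logged
    warning; values cannot exceed 100 for nonnegative sample absorbance.
    """
    if abs_control <= 0:
        raise InvalidControlError(f"abs_control must be > 0, got {abs_control}")
    if abs_sample < 0:
        raise ValidationError(f"abs_sample must be >= 0, got {abs_sample}")
    pct = 100.0 * (abs_control - abs_sample) / abs_control
    if pct < 0:
        logger.warning(
            "negative inhibition (%.2f%%): sample absorbance exceeds control", pct
        )
    return pct


def _logit_line(conc: np.ndarray, pct: np.ndarray):
    """OLS of logit(clipped fraction) on log10(concentration)."""
    p = np.clip(pct / 100.0, *LOGIT_CLIP)
    n_clipped = int(np.sum((pct / 100.0 < LOGIT_CLIP[0]) | (pct / 100.0 > LOGIT_CLIP[1])))
    y = np.log(p / (1.0 - p))
    x = np.log10(conc)
    res = stats.linregress(x, y)
    return res, n_clipped


def fit_ic50_logit(dr: DoseResponse, per_replicate: bool = True) -> IC50Fit:
    """Fit IC50 by the Logit method.

    The pooled fit supplies slope, intercept and r2.  When replicates are
    present (and ``per_replicate`` is true), each replicate is fitted
    separately and ``ic50_uM``/``sd_uM`` are the mean and standard
    deviation of the per-replicate estimates, matching a mean +/- SD
    presentation; otherwise ``ic50_uM`` comes from the pooled line.
    """
    warnings: list[str] = []
    pct = dr.pct_inhibition
    if not (np.any(pct < 50.0) & np.any(pct >= 50.0)) and not (
        np.any(pct <= 50.0) & np.any(pct > 50.0)
    ):
        raise ExtrapolationError(
            f"{dr.compound_id}: dose-response never crosses 50% inhibition; "
            "IC50 would be an extrapolation"
        )

    pooled, n_clipped = _logit_line(dr.conc_uM, pct)
    if n_clipped:
        warnings.append(f"{n_clipped} point(s) clipped to the logit band {LOGIT_CLIP}")
    if pooled.slope <= 0:
        raise NonInhibitorError(
            f"{dr.compound_id}: logit slope {pooled.slope:.3g} <= 0; "
            "not an inhibitor dose-response"
        )

    reps = np.unique(dr.replicate)
    ic50s: list[float] = []
    if per_replicate and reps.size > 1:
        for rep in reps:
            m = dr.replicate == rep
            if np.unique(dr.conc_uM[m]).size < 3:
                warnings.append(f"replicate {rep}: <3 concentrations, skipped")
                continue
            line, _ = _logit_line(dr.conc_uM[m], pct[m])
            if line.slope <= 0:
                warnings.append(f"replicate {rep}: nonpositive slope, skipped")
                continue
            ic50s.append(10.0 ** (-line.intercept / line.slope))
    if len(ic50s) >= 2:
        ic50 = float(np.mean(ic50s))
        sd = float(np.std(ic50s, ddof=1))
    else:
        ic50 = 10.0 ** (-pooled.intercept / pooled.slope)
        sd = None
    if ic50 <= 0 or not math.isfinite(ic50):
        raise NonInhibitorError(f"{dr.compound_id}: degenerate IC50 {ic50}")

    return IC50Fit(
        compound_id=dr.compound_id,
        ic50_uM=ic50,
        slope=float(pooled.slope),
        intercept=float(pooled.intercept),
        r2=float(pooled.rvalue**2),
        sd_uM=sd,
        n_points=int(dr.conc_uM.size),
        warnings=warnings,
    )


def fold_potency(ref_ic50_uM: float, ic50_uM: float) -> float:
    """Potency of a compound relative to a reference: ref IC50 / IC50.

    A value above 1 means the compound is that many times more potent
    than the reference inhibitor.
    """
    if ref_ic50_uM <= 0 or ic50_uM <= 0:
        raise ValidationError("IC50 values must be > 0 for a potency ratio")
    return ref_ic50_uM / ic50_uM


def compare_to_reference(
    sample_ic50s: list[float], ref_ic50s: list[float]
) -> tuple[float, float]:
    """Welch two-sample t-test of replicate IC50s against a reference.

    Returns ``(t, p)`` with a two-sided p-value.  Two identical constant
    lists compare equal by convention: ``(0.0, 1.0)``.
    """
    a = np.asarray(sample_ic50s, dtype=float)
    b = np.asarray(ref_ic50s, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientReplicatesError(
            "need >= 2 replicates in each group for a t-test"
        )
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.inf if a.mean() > b.mean() else -math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
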