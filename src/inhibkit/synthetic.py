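"""Seeded synthetic-data generators for every pipeline stage.

Each generator produces data with exactly the statistical structure the
corresponding fitter assumes, so all estimators are testable by parameter
recovery.  Defaults reproduce the study conditions of the reference
characterization: an inhibitor grid of 0/3.1/6.2/12.4 uM over substrate
1-10 mM for kinetics, and fluorescence titrations at 46 nM total protein
with ligand 0-1.0 uM at two temperatures for binding.

Noise model: multiplicative Gaussian with a relative standard deviation
(constant coefficient of variation), matching the error behavior of plate
readers; noised values are floored at 1e-12 to preserve positivity.  All
randomness flows through an explicit seed in :class:`SyntheticConfig` -
there is no global random state, and a fixed seed reproduces bit-identical
datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .binding import FluorescenceTitration
from .dose_response import DoseResponse
from .errors import MissingBaselineError, ModelViolationError, ValidationError
from .kinetics import VelocityDataset

#: Positivity floor applied after noising.
_FLOOR = 1e-12

#: Study-condition defaults: inhibitor and substrate grids for kinetics,
#: protein/ligand concentrations and temperatures for titrations.
INHIBITOR_GRID_UM = (0.0, 3.1, 6.2, 12.4)
SUBSTRATE_GRID_MM = tuple(float(s) for s in range(1, 11))
PROTEIN_CONC_M = 4.6e-8
LIGAND_GRID_M = tuple(np.round(np.linspace(0.0, 1.0e-6, 11), 12))
TEMPERATURES_K = (293.0, 333.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Seed and noise model shared by all generators."""

    seed: int = 0
    noise_model: str = "none"  # "none" | "multiplicative_gaussian"
    noise_sd_rel: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_model not in ("none", "multiplicative_gaussian"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if (self.noise_sd_rel == 0) != (self.noise_model == "none"):
            raise ValidationError(
                "noise_sd_rel must be 0 exactly when noise_model is 'none'"
            )
        if self.noise_sd_rel < 0:
            raise ValidationError("noise_sd_rel must be >= 0")


def _apply_noise(values: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.noise_model == "none":
        return values.copy()
    noised = values * (1.0 + rng.normal(0.0, cfg.noise_sd_rel, size=values.shape))
    return np.maximum(noised, _FLOOR)


def gen_dose_response(
    ic50_uM: float,
    hill_slope: float,
    conc_grid_uM: np.ndarray,
    cfg: SyntheticConfig,
    compound_id: str = "synthetic",
    n_replicates: int = 1,
) -> DoseResponse:
    """Logistic dose-response: pct = 100 / (1 + (IC50/c)^hill_slope)."""
    conc = np.asarray(conc_grid_uM, dtype=float)
    if conc.size == 0:
        raise ValidationError("concentration grid must be nonempty")
    if ic50_uM <= 0 or hill_slope <= 0 or np.any(conc <= 0):
        raise ValidationError("ic50, hill_slope and concentrations must be > 0")
    rng = np.random.default_rng(cfg.seed)
    pct_true = 100.0 / (1.0 + (ic50_uM / conc) ** hill_slope)
    concs, pcts, reps = [], [], []
    for rep in range(1, n_replicates + 1):
        concs.append(conc)
        pcts.append(_apply_noise(pct_true, cfg, rng))
        reps.append(np.full(conc.size, rep))
    return DoseResponse(
        compound_id=compound_id,
        conc_uM=np.concatenate(concs),
        pct_inhibition=np.concatenate(pcts),
        replicate=np.concatenate(reps),
    )


def gen_velocity_dataset(
    km_mM: float = 1.0,
    vmax: float = 1.0,
    ki_uM: float = 11.0,
    s_grid_mM: np.ndarray = SUBSTRATE_GRID_MM,
    i_grid_uM: np.ndarray = INHIBITOR_GRID_UM,
    cfg: SyntheticConfig = SyntheticConfig(),
) -> VelocityDataset:
    """Michaelis-Menten velocities under competitive inhibition.

    v(i, s) = vmax * s / (km*(1 + i/ki) + s), optionally noised.
    """
    s = np.asarray(s_grid_mM, dtype=float)
    i = np.asarray(i_grid_uM, dtype=float)
    if s.size == 0 or i.size == 0:
        raise ValidationError("substrate and inhibitor grids must be nonempty")
    if min(km_mM, vmax, ki_uM) <= 0:
        raise ValidationError("km, vmax and ki must all be > 0")
    rng = np.random.default_rng(cfg.seed)
    km_app = km_mM * (1.0 + i / ki_uM)
    v = vmax * s[None, :] / (km_app[:, None] + s[None, :])
    return VelocityDataset(
        inhibitor_uM=i, substrate_mM=s, v=_apply_noise(v, cfg, rng)
    )


def forward_static_quench(ka_per_M: float, n_sites: float, pt_M: float, dt_M: float) -> float:
    """Bound-protein fraction f under the static-quench mass balance.

    With complex fraction f = [complex]/Pt, free protein Pf = Pt*(1-f) and
    free ligand Df = Dt - n*f*Pt, the equilibrium KA = f / (Df * (1-f))
    rearranges to the quadratic

        KA*n*Pt * f^2 - (1 + KA*n*Pt + KA*Dt) * f + KA*Dt = 0.

    The smaller root is the physical one: the quadratic (with positive
    leading coefficient) evaluates to -1 at f = 1, so its roots always
    straddle 1 and exactly the smaller root lies in [0, 1).  F/F0 = 1 - f.
    """
    if ka_per_M < 0 or n_sites < 0 or dt_M < 0:
        raise ValidationError("ka, n and dt must be >= 0")
    if pt_M <= 0:
        raise ValidationError(f"pt_M must be > 0, got {pt_M}")
    a = ka_per_M * n_sites * pt_M
    kd = ka_per_M * dt_M
    if a == 0.0:
        # ligand depletion vanishes (n = 0 or ka = 0): linear solution
        return kd / (1.0 + kd)
    b = -(1.0 + a + kd)
    disc = b * b - 4.0 * a * kd
    if disc < 0:
        raise ModelViolationError("negative discriminant in quench mass balance")
    # b < 0, so q > 0 and f = c/q is the smaller root, computed stably
    q = (math.sqrt(disc) - b) / 2.0
    f = kd / q
    if not 0.0 <= f < 1.0:
        raise ModelViolationError(f"no physical bound fraction: f = {f}")
    return f


def gen_titration(
    ka_per_M: float = 4.05e5,
    n_sites: float = 0.3,
    pt_M: float = PROTEIN_CONC_M,
    dt_grid_M: np.ndarray = LIGAND_GRID_M,
    f0_intensity: float = 1000.0,
    temperature_K: float = TEMPERATURES_K[0],
    cfg: SyntheticConfig = SyntheticConfig(),
) -> FluorescenceTitration:
    """Static-quench fluorescence titration: F(dt) = F0 * (1 - f(dt))."""
    dt = np.asarray(dt_grid_M, dtype=float)
    if not np.any(dt == 0):
        raise MissingBaselineError("ligand grid must include dt = 0 (defines F0)")
    if f0_intensity <= 0:
        raise ValidationError("f0_intensity must be > 0")
    rng = np.random.default_rng(cfg.seed)
    f_bound = np.array(
        [forward_static_quench(ka_per_M, n_sites, pt_M, d) for d in dt]
    )
    intensity = _apply_noise(f0_intensity * (1.0 - f_bound), cfg, rng)
    return FluorescenceTitration(
        temperature_K=temperature_K,
        pt_M=pt_M,
        dt_M=dt,
        intensity=intensity,
        excitation_nm=280.0,
        emission_peak_nm=340.0,
    )
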