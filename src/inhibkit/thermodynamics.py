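"""Binding thermodynamics: van't Hoff enthalpy, Gibbs energy, entropy,
and classification of the dominant non-covalent interaction.

From association constants at two temperatures, the standard two-point
van't Hoff relation gives the enthalpy change:

    ln(K2/K1) = -(dH/R) * (1/T2 - 1/T1)

The Gibbs energy follows either from a constant directly, dG = -RT ln KA,
or from the enthalpy/entropy pair, dG = dH - T*dS; the entropy from the
rearrangement dS = (dH - dG)/T.  Both Gibbs routes are kept available and
the assembled profile records which route produced each quantity, because
they need not agree on real data (the two routes use the data
differently and propagate errors differently).

Sign-based force classification: dH > 0 and dS > 0 indicates hydrophobic
interactions; dH < 0 and dS < 0 hydrogen bonding plus van der Waals
contacts; dH < 0 with dS > 0 electrostatic interactions.  Other sign
combinations are left unclassified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError

#: Gas constant, J/(mol*K).
R_GAS = 8.314


@dataclass(frozen=True)
class ThermoInputs:
    """Association constants at two temperatures (L/mol, K)."""

    ka1_per_M: float
    t1_K: float
    ka2_per_M: float
    t2_K: float

    def __post_init__(self) -> None:
        if min(self.ka1_per_M, self.ka2_per_M, self.t1_K, self.t2_K) <= 0:
            raise ValidationError("constants and temperatures must be > 0")
        if self.t1_K == self.t2_K:
            raise ValidationError("temperatures must differ for a van't Hoff slope")


@dataclass
class ThermodynamicProfile:
    """dH/dS/dG triple with reference temperature and force class."""

    dh_kJ_mol: float
    ds_J_mol_K: float
    dg_kJ_mol: float
    t_ref_K: float
    force_class: str
    provenance: dict[str, str] = field(default_factory=dict)


def vant_hoff_enthalpy(inputs: ThermoInputs) -> float:
    """Two-point van't Hoff enthalpy in kJ/mol.

    dH = -R * ln(ka2/ka1) / (1/T2 - 1/T1); negative when the association
    constant falls with rising temperature (exothermic binding).
    """
    dh_J = (
        -R_GAS
        * math.log(inputs.ka2_per_M / inputs.ka1_per_M)
        / (1.0 / inputs.t2_K - 1.0 / inputs.t1_K)
    )
    return dh_J / 1000.0


def gibbs_from_ka(ka_per_M: float, t_K: float) -> float:
    """Gibbs energy from an association constant: -R*T*ln(KA), kJ/mol."""
    if ka_per_M <= 0 or t_K <= 0:
        raise ValidationError("ka and temperature must be > 0")
    return -R_GAS * t_K * math.log(ka_per_M) / 1000.0


def gibbs_from_enthalpy_entropy(
    dh_kJ_mol: float, ds_J_mol_K: float, t_K: float
) -> float:
    """Gibbs energy from the enthalpy/entropy pair: dH - T*dS, kJ/mol."""
    if t_K <= 0:
        raise ValidationError(f"temperature must be > 0, got {t_K}")
    return dh_kJ_mol - t_K * ds_J_mol_K / 1000.0


def entropy_from(dh_kJ_mol: float, dg_kJ_mol: float, t_K: float) -> float:
    """Entropy change from dH and dG: (dH - dG)/T, in J/(mol*K)."""
    if t_K <= 0:
        raise ValidationError(f"temperature must be > 0, got {t_K}")
    return 1000.0 * (dh_kJ_mol - dg_kJ_mol) / t_K


def classify_forces(dh_kJ_mol: float, ds_J_mol_K: float) -> str:
    """Dominant non-covalent interaction from the signs of dH and dS."""
    if dh_kJ_mol > 0 and ds_J_mol_K > 0:
        return "hydrophobic"
    if dh_kJ_mol < 0 and ds_J_mol_K < 0:
        return "hbond_vdw"
    if dh_kJ_mol < 0 and ds_J_mol_K > 0:
        return "electrostatic"
    return "unclassified"


def build_profile(inputs: ThermoInputs, t_ref_K: float | None = None) -> ThermodynamicProfile:
    """Assemble a full thermodynamic profile from a KA pair.

    dH comes from the van't Hoff slope; dG from -RT ln KA at the reference
    temperature (default: the lower measurement temperature, using the KA
    measured there); dS from the rearrangement (dH - dG)/T.  The triple is
    Gibbs-consistent at t_ref by construction, and the provenance mapping
    records the route behind each quantity.
    """
    low_first = inputs.t1_K < inputs.t2_K
    t_low = inputs.t1_K if low_first else inputs.t2_K
    ka_low = inputs.ka1_per_M if low_first else inputs.ka2_per_M
    if t_ref_K is None:
        t_ref_K = t_low
    if t_ref_K == t_low:
        ka_ref = ka_low
    elif t_ref_K == (inputs.t2_K if low_first else inputs.t1_K):
        ka_ref = inputs.ka2_per_M if low_first else inputs.ka1_per_M
    else:
        raise ValidationError(
            f"t_ref_K={t_ref_K} must be one of the measurement temperatures"
        )
    dh = vant_hoff_enthalpy(inputs)
    dg = gibbs_from_ka(ka_ref, t_ref_K)
    ds = entropy_from(dh, dg, t_ref_K)
    return ThermodynamicProfile(
        dh_kJ_mol=dh,
        ds_J_mol_K=ds,
        dg_kJ_mol=dg,
        t_ref_K=t_ref_K,
        force_class=classify_forces(dh, ds),
        provenance={
            "dh_kJ_mol": "two-point van't Hoff from (ka1, t1), (ka2, t2)",
            "dg_kJ_mol": f"-RT ln KA at {t_ref_K} K",
            "ds_J_mol_K": "(dH - dG)/T at the reference temperature",
        },
    )
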