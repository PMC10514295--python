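# inhibkit

Toolkit for characterizing a small-molecule enzyme inhibitor from plate
assays, the way a wet-lab study of an alpha-glucosidase inhibitor would:

- **Dose-response**: percent inhibition from control/sample absorbances
  and IC50 by the **Logit method** — OLS of `ln(p/(1-p))` on `log10(c)`,
  IC50 at the 50% crossing — plus fold-potency ratios and Welch t-tests
  against a reference inhibitor such as acarbose.
- **Kinetics**: per-inhibitor-concentration **Lineweaver-Burk** fits
  (`1/v = (Km_app/Vmax)(1/S) + 1/Vmax`), the secondary replot
  `Km_app = Km + (Km/Ki)[I]` giving **Ki**, and inhibition-mode
  classification (competitive / noncompetitive / uncompetitive / mixed).
- **Binding**: fluorescence static-quench titrations linearized as
  `F0/F = KA * Dt*F0/(F0-F) - n*KA*Pt`, yielding the association constant
  **KA** and site number **n**; static-vs-dynamic quenching from KA's
  temperature dependence.
- **Thermodynamics**: two-point **van't Hoff** enthalpy
  `ln(K2/K1) = -(dH/R)(1/T2 - 1/T1)`, both Gibbs routes
  (`-RT ln KA` and `dH - T dS`), entropy, and sign-based classification of
  the dominant non-covalent force (hydrophobic / H-bond+vdW /
  electrostatic).
- **CD structure**: validation and comparison of secondary-structure
  compositions (helix/turn/coil) between native and inhibitor-bound
  enzyme.
- **Synthetic data**: seeded generators for every stage (logistic curves,
  competitive velocity matrices, static-quench titrations solved from the
  exact mass balance), so every fitter is verified by parameter recovery.

It is aimed at medicinal-chemistry and enzymology groups who run these
assays and want the downstream arithmetic reproducible, validated, and
scriptable instead of living in spreadsheet formulas.

## Worked example

Characterize a competitive inhibitor end-to-end on synthetic data
generated at realistic study conditions (Ki 11 uM kinetics on a
0/3.1/6.2/12.4 uM inhibitor grid; 46 nM protein titrated with 0-1 uM
ligand at 20 and 60 C):

```python
import numpy as np
from inhibkit import (
    SyntheticConfig, ThermoInputs, analyze_kinetics, build_profile,
    classify_quenching, estimate_binding, fit_ic50_logit, fold_potency,
    gen_dose_response, gen_titration, gen_velocity_dataset,
)

cfg = SyntheticConfig()  # noiseless; add seed + noise model for realism

# IC50 by the Logit method
grid = 12.44 * np.array([0.25, 0.5, 1.0, 2.0, 4.0])
fit = fit_ic50_logit(gen_dose_response(12.44, 1.0, grid, cfg))
print(f"IC50 = {fit.ic50_uM:.2f} uM, {fold_potency(750.0, fit.ic50_uM):.1f}x acarbose")

# Ki and inhibition mode from Lineweaver-Burk + replot
fits, ki = analyze_kinetics(gen_velocity_dataset(km_mM=1.0, ki_uM=11.0, cfg=cfg))
print(f"Ki = {ki.ki_uM:.1f} uM, Km = {ki.km_mM:.1f} mM, mode = {ki.mode}")

# Binding constants at two temperatures, quench mechanism, thermodynamics
low = estimate_binding(gen_titration(ka_per_M=4.05e5, temperature_K=293, cfg=cfg))
high = estimate_binding(gen_titration(ka_per_M=3.66e5, temperature_K=333, cfg=cfg))
print(f"KA(20C) = {low.ka_per_M:.3g} L/mol, n = {low.n_sites:.2f}, "
      f"quenching = {classify_quenching(low, high)}")
profile = build_profile(ThermoInputs(low.ka_per_M, 293, high.ka_per_M, 333))
print(f"dH = {profile.dh_kJ_mol:.2f} kJ/mol, dS = {profile.ds_J_mol_K:.1f} J/(mol K), "
      f"forces = {profile.force_class}")
```

Output:

```
IC50 = 12.44 uM, 60.3x acarbose
Ki = 11.0 uM, Km = 1.0 mM, mode = competitive
KA(20C) = 4.05e+05 L/mol, n = 0.30, quenching = static
dH = -2.05 kJ/mol, dS = 100.3 J/(mol K), forces = electrostatic
```

Reading the numbers: the inhibitor is 60.3 times more potent than the
reference; Km rises with inhibitor while Vmax stays put, so it competes
with substrate at the active site with Ki = 11 uM; the binding constant
falls on warming (static quenching, a ground-state complex); and the
exothermic-but-entropy-favored profile classifies the dominant contact as
electrostatic.

The same pipeline runs from the shell on CSV inputs:

```bash
inhibkit simulate kinetics --seed 3 --out velocity.csv
inhibkit kinetics --input velocity.csv --out kinetics.json
inhibkit thermo --ka1 40.5e4 --t1-C 20 --ka2 36.6e4 --t2-C 60
inhibkit report --assay assay.csv --velocity velocity.csv \
    --titration titration.csv --composition composition.csv \
    --compound 11j --reference acarbose --out report.json
```

See `docs/methods.md` for the models, numerical choices, and known
limitations (notably the noise sensitivity of linearized fits on shallowly
quenched titrations).

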