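# Methods

`inhibkit` implements the standard biophysical workflow for characterizing
a small-molecule enzyme inhibitor: dose-response potency, inhibition
kinetics, binding by fluorescence quenching, binding thermodynamics, and
secondary-structure change. This note records the models, the numerical
choices, and what the synthetic-data tests do and do not establish.

## Dose-response (Logit IC50)

Percent inhibition is computed from paired absorbances,
`100 * (A_control - A_sample) / A_control`. The IC50 fit uses the Logit
method: with p the inhibited fraction, `ln(p/(1-p))` is regressed on
`log10(c)` by ordinary least squares and the IC50 is `10^(-b0/b1)`, the
concentration where the line crosses p = 0.5. For one-site binding with a
Hill slope of 1, the logit of the true response is exactly linear in
log-concentration, so noiseless synthetic curves invert to the generating
IC50 to machine precision; this is the basis of the recovery tests.

Numerical choices:

- Fractions are clipped to [0.01, 0.99] before the transform so 0% and
  100% observations remain finite. Clipped points stay in the fit and are
  counted in the result's warnings. The band is a pragmatic guard, not a
  statistical correction; heavily clipped series should be re-designed
  rather than re-fit.
- Negative percent inhibition (apparent activation) is retained, not
  truncated to zero: truncation would bias the line, while the clip band
  already bounds the transform.
- A fit is refused (extrapolation error) unless the data straddle 50%
  inhibition, and refused as a non-inhibitor if the fitted slope is
  nonpositive.
- With replicates, each replicate is fitted separately and the IC50 is
  reported as mean +/- SD of the per-replicate estimates (the convention
  used when potencies are tabulated as mean +/- SD); slope, intercept and
  r^2 come from the pooled line. Replicate-level fitting is the default;
  pooled-only fitting is available via `per_replicate=False`.

Potency comparisons use the ratio of IC50s (fold potency) and a Welch
two-sample t-test on replicate IC50s (unequal variances; two-sided p).

## Inhibition kinetics (Lineweaver-Burk and the Ki replot)

Per inhibitor concentration, initial velocities v over a substrate series
S follow the Michaelis-Menten law `v = Vmax*S/(Km_app + S)`. Each series
is fitted in double-reciprocal space, `1/v = (Km_app/Vmax)(1/S) + 1/Vmax`,
by unweighted OLS; `Vmax = 1/intercept`, `Km_app = slope/intercept`. For
competitive inhibition `Km_app = Km (1 + [I]/Ki)`, so the secondary replot
of Km_app on [I] is a line with intercept Km and slope Km/Ki, and
`Ki = intercept/slope`. Units: substrate in mM, inhibitor in uM; the
replot mixes them, which is dimensionally harmless because Ki emerges in
the inhibitor's units.

Choices and caveats:

- Unweighted least squares in reciprocal space matches the classical
  graphical treatment but distorts the error structure (small velocities
  dominate 1/v). A direct nonlinear Michaelis-Menten fit is kept as an
  independent cross-check in the test suite: on noiseless data the two
  agree to < 1e-8 relative; on noisy data the reciprocal fit is the one
  reported, by design.
- Ki is read from intercept/slope of the replot, not from the -Ki axis
  intercept; the two are algebraically identical on a perfect line but the
  former follows directly from the replot equation.
- Mode classification compares the per-[I] fit series: Vmax constant
  (relative spread < tau_V = 0.10) with Km_app rising monotonically by
  more than tau_K = 0.10 overall is competitive; Km_app constant with
  Vmax falling is noncompetitive; both falling is uncompetitive; anything
  else is mixed (the deliberate fallback). The 0.10 tolerances are
  configurable; at 2% velocity noise on the default grids the competitive
  call is stable in >= 95 of 100 seeded replicates.

## Fluorescence static-quench binding

A protein at fixed total concentration Pt (default 46 nM) is titrated
with ligand Dt (0 to 1.0 uM) and the intrinsic tryptophan fluorescence F
recorded. Under static quenching only free protein fluoresces, so
`F0/F = Pt/Pf`. With association constant KA and site number n, the mass
balances `Pt = Pf + [complex]` and `Df = Dt - n*[complex]` make the bound
fraction f = [complex]/Pt the root in [0, 1) of

    KA*n*Pt*f^2 - (1 + KA*n*Pt + KA*Dt)*f + KA*Dt = 0,

and the transformed coordinates `y = F0/F`, `x = Dt*F0/(F0 - F)` satisfy
the exactly linear relation `y = KA*x - n*KA*Pt`. This rearrangement is
the single most consequential modeling interpretation in the package: the
commonly printed form of the double-log/ratio relation is not well formed
as published, whereas this rearrangement follows algebraically from the
equilibrium plus mass balance and matches the conventional plot axes.
The fit is OLS of y on x; KA is the slope, n is `-intercept/(slope*Pt)`,
and r is the Pearson correlation of the transformed points.

- The quadratic solver takes the smaller root: the quadratic has positive
  leading coefficient and evaluates to -1 at f = 1, so its roots always
  straddle 1 and exactly one lies in [0, 1). An independent damped
  fixed-point solve of the same mass balance confirms the root to
  < 1e-10 over a 1000-point random parameter sweep.
- KA is an equilibrium constant in L/mol. (Published tables sometimes
  carry a spurious s^-1 in the unit; no rate is involved here.)
- Quenching mechanism: KA falling with temperature by more than 1%
  relative is static (ground-state complex dissociates on warming), rising
  is dynamic, within tolerance is indeterminate.
- Inner-filter and background corrections are assumed applied upstream; an
  optional per-point background column is subtracted on read.

**Known limitation (noise amplification).** The linear coordinates divide
by F0 - F, so shallowly quenched points amplify intensity noise: at
KA = 4.05e5 L/mol with Dt <= 1 uM (maximum quench ~29%), 1% multiplicative
intensity noise produces a median KA error near 47% and occasional
negative slopes - the familiar pathology of reciprocal-style
linearizations. The < 10% median-error guarantee tested in the suite holds
for deeply quenched titrations (KA*Dt_max ~ 1, e.g. KA = 1e6 under the
same grid: median error ~6%). Noiseless recovery is < 0.1% everywhere in
the supported parameter box, and the estimator agrees with a brute-force
grid search minimizing intensity residuals of the forward model to < 1%.
Precision claims on real data therefore depend on quench depth, replicate
averaging, and instrument noise, none of which the generator's single-read
noise model fully emulates.

## Thermodynamics and force classification

From association constants at two temperatures, the two-point van't Hoff
relation `ln(K2/K1) = -(dH/R)(1/T2 - 1/T1)` gives the enthalpy change
(R = 8.314 J/(mol K)). The standard sign convention is used deliberately:
some published statements of this equation omit the minus sign, which
flips the sign of dH and contradicts the accompanying conclusions;
evaluating the standard form on a falling-KA pair correctly yields an
exothermic (negative) dH.

Two Gibbs routes are implemented and never silently interchanged:
`dG = -RT ln KA` (direct, from one constant) and `dG = dH - T dS`
(from the profile). The entropy follows from `dS = (dH - dG)/T`. On real
data the routes can disagree by several kJ/mol because they use the
measurements differently; `build_profile` uses the direct route at the
lower measurement temperature (the reference temperature, default 293 K)
and records the route behind each quantity in a provenance block, so the
assembled triple is Gibbs-consistent at t_ref by construction.

Force classification from the signs: dH > 0 and dS > 0 - hydrophobic;
dH < 0 and dS < 0 - hydrogen bonds plus van der Waals; dH < 0 and
dS > 0 - electrostatic. The traditional four-rule list assigns the
(dH < 0, dS > 0) quadrant twice (van der Waals and electrostatic); this
implementation keeps the three unambiguous classes, maps that quadrant to
electrostatic, and labels every other combination (zeros, dH > 0 with
dS < 0) unclassified.

## Circular dichroism composition

Secondary-structure compositions (alpha-helix, beta-turn, random coil
percentages from a CD deconvolution program) are validated to sum to
100 +/- 2%; the 2% tolerance absorbs deconvolution rounding. Comparison
returns per-class treated-minus-control deltas and a direction summary.
Only the three printed classes are modeled; sheet subclasses are out of
scope, as is deconvolution from raw ellipticity.

## Synthetic data

Generators produce data with exactly the statistical structure each fitter
assumes: logistic dose-response curves, competitive Michaelis-Menten
velocity matrices on the 0/3.1/6.2/12.4 uM inhibitor by 1-10 mM substrate
grids, and static-quench titrations at 46 nM protein with ligand 0-1.0 uM
in eleven evenly spaced points (the published conditions report the range
but not the point count; eleven points is a realistic plate-reader
titration). Noise is multiplicative Gaussian (constant CV), the error
behavior of plate readers, floored at 1e-12 to preserve positivity. All
randomness flows through an explicit integer seed; generators are
bit-reproducible per seed and there is no global random state.

Because the generators realize the fitters' own forward models, passing
recovery tests establishes correctness of the algebra and code, not
robustness to the ways real data deviate: instrument drift,
photobleaching, inner-filter effects, non-Gaussian outliers, substrate
depletion during the initial-rate window, and tight-binding behavior are
all outside the noise model.

## Problem sizes used in the shipped checks

The recovery checks run at the study-condition sizes: 5-point dose-response
grids, 4 x 10 velocity matrices, 11-point titrations; stochastic claims
use 100 (kinetics) or 200 (binding) seeded replicates at 2% and 1%
relative noise respectively, and the quench solver is swept over 1000
random parameter draws.
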