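# Methods

## The measurement model

A small fluorescent tracer (here a fluorescein-maytansinol conjugate,
"FcMaytansine", which occupies the maytansine site on β-tubulin) tumbles
rapidly when free and shows a low steady-state anisotropy
rf; bound to a protein target it co-rotates with the complex and shows a
high anisotropy rb. The measured anisotropy of a mixture is the
*intensity-weighted* average of both states:

    r = Fb·rb + Ff·rf,        Fb + Ff = 1,

where Fb and Ff are *fluorescence* fractions — the share of emitted
photons from each state — not molar fractions. Fluorescein conjugates
commonly change quantum yield on binding (the carboxyl pKa shifts when
the dye packs against the protein surface); with a bound/free intensity
ratio R = Ib/If the fluorescence fraction over-weights the bright state,

    Fb = νb·Ib/It,   It = If·νf + Ib·νb,

and the molar fraction bound is recovered as

    νb = (r − rf) / [(r − rf) + R·(rb − r)],

which reduces to the familiar linear interpolation
νb = (r − rf)/(rb − rf) when R = 1. With the default probe parameters
(rf = 0.016, rb = 0.245, R = 3.1) ignoring the correction is a large
systematic error: at true νb = 0.21 the uncorrected read-out reports
0.46. Both directions of the model live in `binding_model`; the forward
map is strictly increasing in νb, and the inverse is its exact algebraic
inverse (round-trip verified to 1e−12 across the full range in the test
suite).

Anisotropy is dimensionless internally; milli-anisotropy (mA = r·1000) is
accepted and emitted at the I/O boundary via an explicit unit field in the
plate CSV header, because bench instruments print mA while the algebra is
scale-free.

Readings pushed slightly outside [rf, rb] by noise are inverted
algebraically, clamped into [0, 1] for reporting, and flagged
(`SaturationValue.clamped`); fitting always consumes the *unclamped*
value (`nu_b_raw`), because clamping residuals near the endpoints would
bias low- and high-occupancy fits.

## Equilibrium with ligand depletion

The assay operates with tracer (10 nM) and sites (4 nM in competition
mode) at concentrations comparable to the dissociation constants, so
bound material is a substantial fraction of the totals and "free ≈
total" approximations (hyperbolic dose–response, Cheng–Prusoff IC50
conversion) are invalid. `equilibrium` solves the coupled 1:1 mass-action
and conservation equations exactly:

* tracer + sites: the standard quadratic, evaluated in the
  cancellation-free form bound = 2·P·T / (S + √(S² − 4PT)) with
  S = P + T + Kd;
* tracer + competitor + sites: the free-site concentration x is the
  single unknown of

      x + P·x/(Kd_p + x) + L·x/(Kd_l + x) = T,

  which is strictly monotone in x with a guaranteed sign change on
  [0, T]. Brent's method on that bracket (xtol 1e−12 nM) cannot miss or
  invent roots; one to two guarded Newton steps then polish the root,
  because the conservation slope can reach 1 + P/Kd_p + L/Kd_l and would
  otherwise amplify the bracketed root's error above the mass-balance
  tolerance. Every returned state carries its conservation residual and
  is rejected above 1e−10 nM.

The site balance is sites_free = sites_total − tracer_bound −
competitor_bound; stoichiometry is fixed at 1:1 per species. Multiple
site classes, cooperativity and kinetics are out of scope. Association
constants are stored per nM (Kd = 1/Ka in nM); molar quantities are
converted explicitly at interfaces.

An independent damped fixed-point iteration on the same conservation map
(with step-halving when an update overshoots, which keeps the map
contractive even for tight binders) serves as the oracle in the test
suite; on 1000 random systems spanning concentrations 0–1000 nM and Kd
0.1–10⁴ nM the two routes agree to better than 1e−8 nM.

## Fitting and replicate statistics

**Direct titration** (tracer calibration): each well's r is inverted to
νb, the free-site concentration is corrected for depletion
(x = sites_total − νb·probe_total), and the single-site isotherm
νb = x/(Kd + x) is least-squares fitted. Fitting νb against *free* sites
keeps the procedure exact under depletion without requiring the solver in
the loop.

**Competition**: with the tracer's Ka fixed from calibration, the
competitor's Kd is the only parameter. Predicted equilibria are pushed
through the observation model and residuals are minimized in anisotropy
space, where the additive measurement noise actually lives — inverting
noisy r through the nonlinear νb map first would distort the error
structure near the endpoints. Control wells (tracer-only, saturated)
carry no information about the competitor and are excluded from the
competition likelihood.

Numerical choices: Kd is parameterized as log10 Kd (positivity,
conditioning), bounded to [−2, 7] in log10 nM; the initial guess is the
concentration at half-maximal signal by linear interpolation; scipy's
trust-region-reflective `least_squares` with xtol = ftol = gtol = 1e−14.
A displacement series whose anisotropy span is below 5% of the probe's
dynamic range is classified as a non-binder and reported as a *lower
bound* on Kd (the highest dose tested) with a flag, never as a point
estimate — the behavior of off-site negative controls such as
vinblastine or colchicine in this assay.

Replicates are fitted independently and reported as mean ± SEM with the
sample SD (ddof = 1); pooled global fitting is deliberately not used, so
the quoted SEM measures genuine between-replicate scatter. With n = 3
replicates the statistic (mean − truth)/SEM follows Student's t with
2 degrees of freedom — heavier-tailed than normal — so a ±3·SEM interval
covers the truth about 90% of the time, not 99.7%; the test suite
verifies this calibration directly (KS test against t(df = 2)).

**Z-factor**: Z = 1 − 3(σp + σn)/|μp − μn| over positive (saturated) and
negative (tracer-only) control groups, sample SDs, ≥3 wells per group.
Z is invariant under positive affine rescaling of the anisotropy axis, so
mA and dimensionless data score identically.

## What the synthetic generator emulates — and what it does not

`synthetic` produces plate-structured data by running the exact forward
model per well (equilibrium → observation) and adding Gaussian noise:
additive on r (default σ 0.001, matching routine endpoint scatter of this
assay class) and relative on intensity (default 1.6%, matching a ±0.05
scatter on a 3.1-fold signal). Noise is applied to r and It directly, not
to the underlying polarized channel intensities, since only r and It are
modeled quantities; channel-level simulation would add structure no part
of the pipeline could verify.

Default study conditions (in `reference`): tracer 10 nM; direct titration
with a zero well plus 12 log-spaced site concentrations to 400 nM;
competition at 4 nM sites with 12 log-spaced competitor doses spanning
0.1×–1000× the ground-truth Kd; 3 replicates; a free/saturated control
pair per replicate; 384-well layout.

Not emulated: instrument artifacts (edge effects, drift, automatic gain),
solvent (DMSO) effects, fluorophore photochemistry beyond the two-state
R ratio, and day-to-day reagent variability. Passing recovery tests
therefore demonstrate correctness of the *analysis* under the model's own
assumptions — unbiased inversion, exact equilibria, calibrated replicate
statistics — not robustness to systematic errors real plates can contain.

## Reproduction panel

The published panel this package validates against: tracer calibration
Kd = 6.8 nM (also expressed as Ka = 1.6×10⁸ M⁻¹; the two printed values
are independent roundings from the original study and are treated as two
separate generator settings, never cross-asserted) and six
maytansine-site ligands measured by displacement — ansamitocin P3
15.0 nM, PM060184 111 nM, the DM1-lysine diastereoisomers M9A 12.6 nM and
M9B 17.5 nM, spongistatin-1 9.5 nM, disorazole Z 576 nM. Noiseless
generate-and-refit closes the loop to machine precision
(`scripts/acceptance.py`, `anisobind reproduce`).

Problem sizes used throughout (12-point titrations, 200-draw noise
ensembles, 1000-system oracle grids) are the package's validation scale:
large enough for the statistical checks to be sharp, small enough to run
routinely.

## Known limitations

* Single site class, 1:1 binding, equilibrium only.
* The non-binder classifier is a fixed 5%-of-range span threshold; very
  weak binders (Kd far above the dose range) are reported as lower
  bounds rather than extrapolated.
* Endpoint parameters are treated as known constants during fitting;
  their measured SDs are carried on `ProbeParams` but not propagated
  into the Kd uncertainty, which is replicate-scatter based.
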