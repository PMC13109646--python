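# Methods

## The assay and its estimators

A channel protein (an aquaporin or aquaglyceroporin) is expressed in a
*Xenopus laevis* oocyte (~1.2 mm diameter). The oocyte, equilibrated in
~200 mOsmol/kg medium, is transferred either to a hypotonic bath
(~100 mOsmol/kg, water assay) or to an isotonic bath in which 180 mM of a
permeant solute (glycerol, urea or boric acid) replaces salt at an unchanged
total osmolality of 200 mOsmol/kg (solute assay). The oocyte is imaged from
above every 30 s for 10 min; each image yields one diameter, and volume
V = (π/6)d³ and surface S = πd² follow from spherical geometry. V₀ and S₀
are taken from the t = 0 frame.

From the initial relative swelling rate d(V/V₀)/dt, obtained here as the
ordinary least-squares slope of V/V₀ against time,

    P_water  = [V₀ · d(V/V₀)/dt] / [S₀ · V_w · (osm_in − osm_out)]
    P_solute = osm_total · [V₀ · d(V/V₀)/dt] / [S₀ · (sol_out − sol_in)]

with V_w = 18 cm³/mol the molar volume of water. Internally all
concentrations are mol/cm³ (1 mOsmol/kg ≡ 1 mM ≡ 10⁻⁶ mol/cm³); in
P_solute the osmolality and the solute gradient enter only through their
dimensionless ratio (200/180 in the standard design). Note V₀/S₀ = d₀/6, so
both estimators reduce to P ∝ (d₀/6) · slope / gradient. Permeabilities are
reported on the 10⁻⁶ cm/s scale. Negative slopes (shrinking oocytes) map to
negative permeabilities and are never clamped: the small negative values a
leaky control cohort produces are part of the read-out.

The fit window defaults to the full 10-min trace. At the permeability
magnitudes these assays report, total swelling over 10 min is small and the
trace is near-linear, so the full-trace OLS slope is the lowest-variance
choice; an explicit `window=(t_start, t_end)` restricts the fit to an
initial segment when curvature is a concern.

## The forward simulator

No raw swelling traces are publicly deposited for this assay family, so the
package verifies its estimation pipeline by parameter recovery against its
own forward model. Water flux follows

    dV/dt = P_w · S(V) · V_w · (C_in − C_out),

with S(V) = π^(1/3)(6V)^(2/3) the apparent sphere surface (no
membrane-folding correction, matching the estimators). In solute assays a
second state, the internal permeant-solute amount N_s, evolves as

    dN_s/dt = P_s · S(V) · (C_s,out − C_s,in),

and the internal solute contributes to C_in. Two gradient models are
provided:

* **dilution** (default for single traces): C_in = (N_imp + N_s)/(V − v_b V₀)
  with the impermeant osmolyte amount N_imp fixed, so the gradient decays as
  the cell swells. Integrated with LSODA at rtol 10⁻⁸ (trajectories are
  smooth; accuracy must exceed estimator tolerance). N_imp is a parameter,
  not an integrated state, so osmolyte conservation is exact by
  construction; the non-osmotic-volume equilibrium identity
  V_f/V₀ = v_b + (1 − v_b)·osm_in0/osm_out is what the tests check instead,
  and it fails if the bookkeeping drifts. With v_b = 0 a 200→100 mOsmol/kg
  shift must exactly double the volume at equilibrium.
* **constant** (default for cohort generation): the estimators' own model
  world — the driving gradient *and* the surface are frozen at their initial
  values, and in the solute assay water is assumed to equilibrate instantly
  so that volume tracks solute content, dV/dt = (dN_s/dt)/osm_total.
  Trajectories are exactly linear and the estimators invert this model
  exactly, which is what makes recovered-vs-generating comparisons clean.

The choice of the constant model for the cohort recovery surface is
deliberate. The solute estimator is an index defined by its formula, not a
parameter of the coupled two-ODE model: at the reported solute-permeability
magnitudes (tens of 10⁻⁶ cm/s against a 180 mM gradient) the nominal
swelling implied by the formula exceeds 100% in 10 min, while the reported
water permeabilities (~10⁻⁶–10⁻⁵ cm/s) could not supply water fast enough
for volume to track solute entry. Under the fully coupled model the
recovered solute index therefore reflects the water-limited volume response
rather than the generating P_s, and a recovery comparison would be
ill-posed. The dilution model remains the tool for quantifying estimator
bias where it is well-defined: for hypotonic water assays the bias is
negative (the gradient only decays) and stays below 5% while total swelling
stays below 5%, which the tests exercise directly.

### Measurement noise

Gaussian noise of sd `noise_sd_frac · d₀` is added to each diameter.
The single-trace default, 0.001 (≈1.2 µm on a 1.2 mm oocyte), represents
realistic stereomicroscope digitization. Cohort generation defaults to
10⁻⁶ instead: error propagation through the slope gives a noise-induced
per-oocyte sd of

    σ_P ≈ 3 f σ_d-factor / (√Σ(t−t̄)² · V_w · Δosm · S₀/V₀)

≈ 4×10⁻⁵ cm/s at f = 0.001 for the water design — forty times the control
cohort's entire biological spread, because at these permeability magnitudes
the 10-min diameter change is itself on the micron scale. The cohort
surface exists to compare recovered against generating permeabilities, so
its noise default is set where measurement error is negligible against the
biological spread; the realistic noise level is exercised by the
single-trace tests instead.

### Cohort draws

Per-oocyte true permeabilities are drawn i.i.d. from a normal with the
cohort's (mean, sd), floored at −(mean + 3 sd): mild negative leak values
pass through (they are observed in control and non-transporting cohorts),
absurd runaway-shrinkage trajectories do not. All randomness flows from one
master seed through `numpy.random.SeedSequence.spawn`, one child per
construct × assay; a cohort is byte-reproducible from its spec.

In solute assays the drawn truth is P_s; P_w is set to the construct's
water-assay mean when the spec includes one (inert under the constant
model, used by the dilution model).

## Group statistics

Constructs are compared per assay panel with the tie-corrected
Kruskal–Wallis test,

    H = [12/(N(N+1)) Σ R_i²/n_i − 3(N+1)] / [1 − Σ(t³−t)/(N³−N)],

p from χ² with k−1 df, followed by Dunn's all-pairwise z tests,

    z_ij = (R̄_i − R̄_j) / √[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j)],

two-sided, with the default multiplicity adjustment multiplying p by the
number of comparisons m = k(k−1)/2 (capped at 1; `adjust="none"` is
available). Both are implemented from the formulas — mid-ranks, tie terms
and all — rather than delegated to a statistics package, so that the test
suite can pin them against enumeration: an exact permutation oracle for
small N and a cross-check against an independent implementation. If every
pooled value is identical the tie-correction denominator vanishes and H is
defined as 0 with p = 1.

Box-plot summaries use inclusive linear-interpolation quartiles (the
convention is fixed for determinism; at these cohort sizes the choice does
not move any conclusion). Outliers are flagged only above the box
(> Q3 + 1.5·IQR); the lower whisker is the minimum — the asymmetry mirrors
the assay's plotting convention, where only high-permeability outliers are
separated. Cohorts are rendered as ``mean ± sd (n)`` with one decimal on
the 10⁻⁶ cm/s scale.

## Problem sizes and determinism

Recovery runs simulate cohorts at the published per-cell sample sizes
(9–27 oocytes) and average four replicate cohorts per target — the assay
itself pools oocytes from at least three donor frogs — so the Monte-Carlo
error of a reported mean is sd/√(4n), well inside the ±2·sd/√n band used
to judge recovery. Each cohort takes well under a second; the full test
suite runs in seconds. The type-I-error calibration uses 2000 null
replicates of 3 × 10 observations. Every stochastic quantity is a pure
function of the configured seed.

## Known limitations

* The simulator emulates clean single-sphere imaging: no segmentation
  error beyond i.i.d. Gaussian diameter noise, no membrane folding, no
  oocyte lysis at extreme swelling, no per-frog batch effects. Passing
  recovery therefore demonstrates the correctness of the estimation
  pipeline, not the field accuracy of the assay.
* The constant-gradient recovery surface treats the solute estimator as its
  defining formula; the dilution model shows that, as a physical parameter
  of a coupled osmotic system, the same index can be strongly
  water-limited. Comparisons *between* cohorts analysed identically are
  unaffected.
* Internal osmolality is assumed equal to the 200 mOsmol/kg incubation
  medium (configurable via ``osm_in0``); non-osmotic volume defaults to 0.
* No temperature correction, mercury-inhibition modelling, image
  processing, or parametric ANOVA.
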