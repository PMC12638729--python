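# Methods

`vffr1d` computes virtual fractional flow reserve (vFFR) — the simulated
ratio of distal coronary pressure Pd to aortic pressure Pa — from a
one-dimensional description of a coronary artery: 200 lumen radii
sampled along the reconstruction centreline, plus two boundary
conditions (Pa and the microvascular resistance MVR of the distal bed).
Five steady-flow models are provided that differ only in how flow lost
to unreconstructed side branches ("leakage") is represented.

## Flow model

Steady, incompressible flow of a Newtonian fluid (default
mu = 0.0035 Pa·s, rho = 1050 kg/m³; optionally
mu = 0.0014 + 0.0035·haematocrit) in a rigid, axisymmetric tube.  In
healthy sections the pressure gradient is

    -dP/ds = 8 mu Q / (pi r^4)  +  (alpha rho / 2) d(u^2)/ds,

the Poiseuille loss plus an advective (momentum) term with
profile-correction alpha = 4/3 (parabolic profile), u = Q/(pi r²).  The
advective term is on by default and switchable off
(`SolverConfig.advection`); whether all published 1-D variants include
it is not documented, so both behaviours are reachable.  Pressure is
marched from inlet to outlet with trapezoidal integration between
adjacent samples; the advective contribution is taken as the exact
difference of alpha·rho·u²/2 across each healthy edge.

Axial flow obeys mass conservation, Q(s) = Q_in − ∫₀ˢ q ds, where
q(s) ≥ 0 is the leakage per unit length; the identity
Q_in − Q_out = ∫ q ds holds to round-off by construction.

### Stenosis sub-model

Stenosed intervals violate the healthy-flow assumptions (radial flow,
separation), so a lumped empirical drop of the Young–Tsai lineage is
applied instead:

    dP = ∫ 8 mu Q / (pi r^4) ds  +  kt (rho/2) (A_h/A_min − 1)² (Q/A_h)²,

the viscous integral over the interval's actual radii plus an expansion
loss at the interval exit, with A_min the minimal lumen area, A_h the
healthy reference area at the same location, and kt = 1.52 by default
(exposed in `StenosisModelConfig`; the empirical coefficient is not
printed in the validation literature, so it is configuration, not a
constant).  No leakage occurs inside stenosed intervals.

### Boundary conditions and inlet-flow optimisation

Inputs are clinical units (mmHg, Wood units = mmHg·min/L, mL/min);
internals are SI.  Inlet flow is not prescribed: it is the root of
Pd(q)/Q_out(q) = MVR inside the admissible range 50–450 mL/min, found
by bisection on the monotone residual to a relative residual of 1e-9.
MVR is defined against *outlet* flow because it is the resistance of
the distal bed.  A root outside the bounds clamps the flow to the
nearer bound and flags the result (`"flow clamped"`) rather than
erroring.  vFFR = Pd/Pa of the converged run.

Any iterate reaching non-positive pressure (or non-positive flow) makes
the run **fail** with a recorded reason (`"negative pressure"`); batch
runners count failures, they never see exceptions.

## Healthy lumen estimation (Fourier filtration)

Stenosed points are defined as those where the reconstructed
cross-sectional area falls *strictly* below 80% of the estimated
healthy area (`FiltrationConfig.area_threshold`, default 0.80; strict
inequality, so a point exactly at the threshold is healthy).

The healthy area is a low-pass Fourier estimate with one quality
parameter, `n_harmonics` (default 8 over a 200-point profile).  The
low-pass operator removes the straight line through the endpoints,
mirror-extends the residual (no periodicity artefacts), truncates the
DFT, restores the trend and re-pins both endpoints exactly — inlet and
outlet calibre set the side-branch budget, so they must survive
filtration.

A plain low-pass dips into lesions, and a lesion wider than the cutoff
wavelength is *spectrally indistinguishable* from taper (it is exactly
representable by the retained harmonics, so no reweighting or
replacement scheme at that single scale can remove it).  The estimate
is therefore built in two stages:

1. **Detection** — a coarse-to-fine upper envelope: at cutoffs
   k = 1 … n_harmonics, the working signal is repeatedly lifted to the
   current fit wherever it falls below it, then re-filtered
   (per-scale stopping rule: relative fit change < 1e-6, at most 300
   iterations, a `FiltrationWarning` on non-convergence).  Lesions are
   erased while they are out of band, so the envelope rides over dips
   of any width.
2. **Refinement** — points below the area threshold of the envelope
   (dilated outward while the ratio stays below 0.98, so lesion flanks
   are included) are bridged by linear interpolation between their
   healthy neighbours, and the bridged signal is re-filtered at the
   full cutoff.  This removes the upward bias the ratcheting envelope
   leaves on curved or stepped tapers.

On synthetic vessels this recovers the generating stenosis-free
baseline to within about 1% across the lesion for Gaussian lesions of
30–70% diameter stenosis and widths from sub-millimetre to several
millimetres.  Segmentation cleanup: single-point gaps inside a flagged
run are bridged, runs shorter than `min_run = 2` points are discarded
(no morphological rule is documented for the reference workflow; this
is the package's choice).

## Side-branch leakage models

Vessel taper implies side branches by the Huo–Kassab morphometric
scaling law, Q_in/Q_out = (R_in/R_out)^(7/3).  The total budget,
total_leak = Q_in (1 − (R_out/R_in)^(7/3)), uses the *healthy* radii at
the profile endpoints, so stenoses do not masquerade as taper; an
expanding vessel yields zero budget (leakage never reverses).

- **none** — q ≡ 0.
- **homogenous** — the budget spread uniformly over healthy arc length.
- **localized** — per-point weight w = max(0, −d/ds r_h^(7/3)),
  zero on stenosed points, normalised to the budget.  Using the
  gradient of r^(7/3) makes the local distribution consistent with the
  law that sets the total; regions of radius recovery carry zero
  weight.  If all taper lies inside flagged intervals the distribution
  falls back to homogenous and is flagged.  Weights below 1e-9 of the
  vessel's own taper scale are treated as zero (interpolation
  round-off otherwise attracts the entire budget onto noise).
- **conductance** — a wall conductance g(s) = q_localized(s)/P(s) is
  computed once on the *unstenosed configuration* of the vessel
  (radius = healthy radius, no stenosed intervals) at the same inlet
  flow; on the real vessel the leak iterate is q = g·P, zeroed on
  stenosed points, fixed-point-iterated with the solver (initial
  pressure field: the localized-leak simulation) until the maximum
  relative pressure change is below `ptol = 1e-6` (at most 100
  iterations).  A disease-free vessel thus leaks exactly its
  anatomical budget, while regions distal to stenosis-induced pressure
  loss leak proportionally less.  The reference-pressure choice is the
  package's own: venous pressure is taken as zero and the healthy
  configuration supplies the reference field.
- **porosity** — the wall is a porous medium obeying the
  Darcy–Forchheimer relation P = v/kappa + beta·rho·v², with transmural
  pressure equal to luminal pressure (venous reference 0); the wall
  flux is q = 2·pi·r_h·v on healthy points.  The linear mobility kappa
  is calibrated per vessel so that the coupled solution on the
  unstenosed configuration reproduces the Huo–Kassab flow ratio
  (multiplicative fixed-point update, tolerance 1e-12); beta defaults
  to 0 and is exposed, as is a taper-weighted mobility profile
  (`calibration_mode="taper"`).  The published variant of this model
  relies on coefficients from supplementary material that is not part
  of the open record, so this calibrated realization is the package's
  own design.

A consequence of per-vessel calibration worth knowing: the calibrated
porosity leak is non-negative and bounded, so its pressure field is
bounded below by the no-leak field — the porosity model here can only
fail on geometries where the no-leak model also fails.
Fixed-coefficient porosity variants are considerably more fragile; the
published failure pattern (porosity failing far more often than the
other models) is not reproduced by the calibrated realization.

## Synthetic vessels and virtual cohorts

`generate_vessel` builds tapered tubes — smooth linear taper, or
`n_steps` equal radius decrements at evenly spaced positions
(bifurcation-like steps) — with focal stenoses as Gaussian radius
reductions r ← r·(1 − DS·exp(−(s−c)²/2σ²)).  Gaussian shape is a
convention, not a claim about lesion morphology.

`generate_cohort` draws, per case (single seeded generator):
inlet/outlet radii N(1.35, 0.25)/N(0.95, 0.20) mm winsorised at 1.5 sd
(the reconstruction calibre scales of intermediate coronary disease),
length U(20, 45) mm, one lesion with DS U(0.2, 0.65) and σ U(1.0, 2.5)
mm (intermediate-disease severities), Pa N(90, 10) mmHg clipped to
70–120, haematocrit N(0.42, 0.04), and MVR lognormal around a
361-Wood-unit median scaled by (0.95 mm / r_out)³ — a Murray-type
coupling of distal-bed resistance to outlet calibre, without which
small synthetic vessels would face implausibly large flows.  The
reference FFR of each case re-runs this package's own pipeline on a
2000-point grid (localized model), giving cohort statistics a
self-consistent ground truth; it is a grid-refined self-simulation, not
an external standard.

What the generator does *not* emulate: angiographic reconstruction
error and noise, lesion eccentricity and morphology, multi-lesion
interplay, vessel curvature, pulsatility and compliance.  Passing tests
on synthetic cohorts therefore demonstrate internal consistency of the
method chain, not clinical accuracy.

Healthy synthetic vessels land at vFFR ≈ 0.88–0.99 under these
boundary conditions, matching the clinical observation that
minimally-diseased vessels sit around FFR 0.89 [0.84–0.96] — not at
1.0.

## Validation statistics

- **Diagnostic metrics** (accuracy, sensitivity, specificity, PPV,
  NPV) in percent with Clopper–Pearson exact binomial intervals (beta
  quantiles; a zero denominator reports the metric as undefined, never
  0).  Disease-positive means FFR ≤ 0.80 (resting Pd/Pa uses ≤ 0.90).
- **Chi-square** test of independence (Pearson, no continuity
  correction) for per-model success/failure tables.
- **Bland–Altman by quantile regression**: the difference test−reference
  is regressed on the pair mean at the 2.5th, 50th and 97.5th centiles
  (check-loss linear programming via `statsmodels` QuantReg); the three
  lines are evaluated at a reference mean of 0.80, the diagnostic
  threshold.  Degenerate spread (constant means or constant
  differences) falls back to unconditional quantiles, flagged.
- **Passing–Bablok** regression: shifted-median of pairwise slopes with
  the standard tie rules (slopes of exactly −1 excluded, offset by the
  count of slopes below −1); implemented in-package as no installed
  library provides it.
- **ROC/AUC** oriented so that *lower* scores predict disease
  (a case is test-positive when its vFFR is at or below threshold);
  trapezoidal AUC, identical to the tie-averaged rank statistic.
- **Paired-t sample size**: smallest n whose exact noncentral-t power
  (df = n−1, noncentrality d_z·√n, two-tailed) reaches the target; a
  normal-approximation variant is provided for comparison.

## Numerical choices and degenerate inputs

- Trapezoidal marching on the sampled grid; refinement studies on
  smooth vessels show first-to-second-order convergence of vFFR and a
  200- vs 2000-point difference of order 1e-5.
- Flow-matching residual tolerance 1e-9 (relative); pressure
  fixed-point tolerance 1e-6 (relative to Pa), 100 iterations.
- With the advective term on, decelerating flow can recover a small
  amount of pressure (observed < 0.2% of Pa on cohort vessels);
  pressure is strictly decreasing with the term off.
- Radii are validated strictly positive, arc length strictly
  increasing; resampling is piecewise-linear (no interpolation scheme
  is documented for the reference workflow).
- The stenosis threshold comparison is strict (`<`), so an area ratio
  exactly at the threshold is healthy.

## Known limitations

- Sharp idealized bifurcation steps can leave a short (couple-of-point)
  flagged sliver at the step when the per-step calibre drop approaches
  the 80% area threshold; real, smoother bifurcations do not.
- The calibrated porosity model is markedly more robust than the
  published fixed-coefficient variant (see above), so per-model failure
  *rates* are not comparable with the published ones, only the failure
  *semantics*.
- Quantile-regression agreement limits need on the order of 50+ pairs
  to stabilise; the implementation warns below 20.
- No pulsatile flow, no compliance, no vessel curvature, no 3-D
  comparator: out of scope by design.
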