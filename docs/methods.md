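# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `whiskerglm`, in the spirit of a methods appendix.

## Whisker mechanics

**Model.** The whisker is a 2D cantilever clamped at the base: a truncated
cone of length L (default 25 mm), base radius 70 µm tapering linearly to
3 µm, Young's modulus E = 3.3 GPa — typical literature values for rat
macrovibrissae, all configurable.  The cross-section's second moment of
area is I(s) = π r(s)⁴/4.  Contact with a probe or pole is quasi-static
and frictionless: at each frame the whisker is in equilibrium under a
single point force applied where it touches the object, oriented
perpendicular to the local whisker tangent.  Inertia, vibrations,
friction, 3D bending/torsion, and follicle motion are all outside the
model; consistent with the quasi-static idealization, every mechanical
signal is *exactly* zero during non-contact.

**Discretization and solver.** A discrete elastica: N−1 rigid segments of
uniform arc length joined by elastic hinges obeying the Euler–Bernoulli
moment–curvature law M(s) = E I(s) (κ(s) − κ₀(s)).  This reduces to the
continuous beam in the fine-mesh limit and remains valid at large
deflections.  The forward solve relaxes the curvature profile toward the
moment profile of the current force estimate while adjusting (i) the force
magnitude via the small-deflection compliance C(a) = ∫₀^a (a−s)²/(E I(s)) ds
as a Newton gain, and (ii) the contact arc position, letting the contact
slide along the whisker as it bends.  Safeguards: a trust region of
0.1 rad per hinge per sweep, a relaxation factor that halves when the
constraint residual grows, and displacement continuation (ramping the
constraint out from the resting shape) for cold starts far from rest.
Tolerances: constraint residual < 10⁻³ mm, force increment < 10⁻³ µN,
iteration cap 10⁴.  Doubling the node count (100 → 200) changes reported
reactions by < 0.5 %; against a uniform cylinder the solver matches the
cantilever closed forms δ = F a³/(3EI), M = F a to ≈ 0.1 %.

Some configurations have no contact equilibrium — a large push applied
very near the tip makes the contact point slide off the end (the whisker
slips past the probe).  The solver raises a contact-lost signal and the
trial renderer treats such frames as non-contact.

**Sign conventions.** Whisker frame: x along the base tangent pointing
tipward, y rostral, moments positive counterclockwise.  Reported Fx is
positive pointing out of the follicle (the −x component of the applied
force), Fy is the rostral (+y) component, M the z-moment about the base.
Units: µN, µN·m, mm, degrees.

**Inverse solve.** Given an observed (tracked) shape and contact point:
the shape is rigidly registered to the base frame (translation to the
first node; rotation from the tangent at s = 0 of a quadratic arc-length
fit to the most-proximal 10 % of nodes — a straight-line fit over that span
would be biased by proximal bending), the contact arc position is read off
the registered polyline, and the force magnitude is found by least squares
between the forward-model shape and the observation (coarse bracket, then
bounded scalar minimization).  Forward → inverse round trips recover base
reactions to < 1 %.  A shape residual above 0.05 mm RMS flags the result
low-confidence.

A note on linearity: for small pushes Fy and M scale linearly with the
imposed displacement, but the axial force Fx is second order (it vanishes
in the linearized cantilever) — tests of load scaling therefore check Fy
and M.

## Kinematics and preprocessing

r is the basepoint-to-contact distance.  θ_deflection (passive) is the
signed angle between the basepoint→initial-contact and
basepoint→current-contact segments; θ_push (active) is the angle swept by
the base tangent since contact onset.  Both reset to zero at every contact
onset and are positive rostrally, matching Fy.  Kinematic variables are
undefined off contact (NaN sentinel); for model input they are imputed to
zero, mirroring the exact mechanical zeros — a choice we make explicitly,
and configurable, since a tracked dataset offers no observed value there.

Preprocessing: 5-sample median filter with edge replication (kills
single-frame tracker glitches without moving ramp endpoints), linear
interpolation from the native frame rate (300 or 1000 fps) to the common
1 kHz grid, nearest-neighbor resampling of the contact mask, velocity by
central differences with one-sided ends, then a 4th-order Butterworth
low-pass at 85 Hz applied forward–backward (zero phase).  A consequence of
filtering across contact boundaries is ~1–2-frame smearing of r and θ at
episode edges; mechanical channels are re-zeroed exactly on non-contact
bins after resampling.

## Spike processing

Spike times are rounded to the nearest ms (ties to even; coincident
rounded spikes collapse to one, with a logged count).  The smoothed rate
is the plain Gaussian-kernel sum with σ = 15 ms by default, kernel
truncated at ±5σ and not renormalized at trial edges, so the rate
integrates to the spike count up to boundary truncation.  A sweep harness
(`sigma_sweep`) reports cross-validated prediction quality for σ from 1 to
500 ms.

## The GLM

Bernoulli likelihood at 1 ms bins with a logistic link.  Temporal filters
α_j(t′) are expanded in L = 5 raised cosines b_l(t′) =
½[cos(clip(a·log(t′+c) − φ_l, −π, π)) + 1] with φ_l = a·log(p_l + c), which
makes each bump peak exactly at its nominal time p_l ∈ {0, 1, 3, 8, 17} ms.
The two stretch parameters (a, c) are solved numerically from two
conditions: the last bump reaches zero exactly at the 75 ms support, and
the warped peaks are spaced π/2 apart on average — the standard tiling of
this basis family.  Raw predictors are whitened (zero mean, unit SD over
the whole recording by default; train-only scope available) before the
causal convolution, with pre-trial history treated as zeros.

Fitting is a damped Newton iteration (IRLS with step halving) on the
penalized log-likelihood; the default ridge of 10⁻⁶ on non-intercept
coefficients guards against perfect separation while leaving estimates
indistinguishable from the MLE on well-posed problems; ridge = 0 gives the
pure MLE, which can diverge on separable data (such fits are flagged, and
the aggregation step excludes fits whose largest |β| exceeds 10³).
Standard errors come from the inverse observed Fisher information.  The
basis-space prediction and the prediction rebuilt from the reconstructed
filters agree to numerical precision (an exact algebraic identity, tested
to 10⁻¹⁰), and refits from different initializations agree in likelihood
to 10⁻⁶ relative — the problem is convex.

Cross-validation uses k = 10 contiguous temporal blocks (contiguity limits
autocorrelation leakage between train and test); every bin is predicted
exactly once by a model fit on the other nine blocks.

## Model comparison

Accuracy is Pearson R between out-of-fold p(t) and the smoothed rate **on
contact bins only**: these afferents are silent off contact, and silent
bins are trivially predictable, so including them inflates R (the package
tests this inflation directionally).  Subset models are compared to the
full model by the squared Pearson correlation of their prediction series —
a measure of shared information, not of accuracy — and by the percent
difference 100·(R_full − R_subset)/R_full (negative when the subset wins).
Population statistics follow the usual non-parametric repertoire
(signed-rank within preparation, rank-sum between preparations, paired t,
below-diagonal fraction, OLS slope of R_kin on R_mech with a normal-theory
95 % CI).  Neurons whose full model does worse than both subsets are
excluded before percent-error tests; undefined correlations (constant
series) propagate as missing.  The median-R split used for highlighting is
recomputed from the analyzed population, not hardcoded.

## Synthetic experiments

**Passive protocol** (300 fps): 20–40 ramp–hold–release pushes of a point
probe at radial fractions sampled uniformly in a configurable range
(decoupling regime: 0.4–0.9 of L; coupled comparator: one fixed fraction
with small pushes), two directions, two speed classes (half-cosine ramps
of 50 ms / 250 ms — the fast/slow distinction is qualitative in the field,
so the durations are package defaults), peak displacements 1–4 mm, ~20 %
of holds lasting ~3 s (adaptation probes), inter-push gaps 0.3–0.8 s.  The
probe moves along the resting whisker's normal at the chosen radial
location; multiplicative band-limited tremor (5 % RMS, < 25 Hz) gives each
push naturalistic variability while keeping displacement continuous
through onset and release.  The contact point may slide along the whisker
as it bends; frames where the whisker slips off the probe become
non-contact.

**Active protocol** (1000 fps): sinusoidal base-angle whisking (default
8 Hz, 20° amplitude, 8 % cycle-to-cycle amplitude jitter) against a rigid
vertical pole (3 mm diameter) placed at a configurable fraction of the
whisker length inside the protraction half of the sweep.  Free whisking is
rigid rotation about the basepoint; during contact the beam solver takes
over with the pole surface as the constraint.  Head motion is not modeled
(body-restrained preparation).

**Ground-truth neurons** are linear–nonlinear Bernoulli spikers whose
filters are weighted sums of the fitting basis, so exact recovery is
representable.  Filter weights follow a recency-dominated profile, scaled
so the filter integral (total gain on a whitened sustained input) is
1.0–1.6 for the primary driver and 0.3–0.6 for the secondary; baseline
bias ≈ logit(0.01) per 1 ms bin.  Simulation applies the filters to
whitened predictors with whole-recording statistics, matching the fitting
convention, so true β are directly comparable to fitted β.

Population neurons additionally carry slow private excitability noise
(AR(1), τ = 50 ms, SD 1.5 in logit units — comparable to the stimulus
drive): exactly-realizable neurons are predicted at R ≈ 0.99, which is
nothing like real afferent data, where stimulus models capture only part
of the variance.  Estimator-recovery tests use noise-free neurons, since
private noise attenuates logistic coefficient estimates.  Even with this
noise the synthetic accuracies (median R_full ≈ 0.75–0.9 for long decoupled
trials) run above those of real recordings — the generator models neither
tracking error nor the full richness of afferent variability, so passing
tests demonstrate the *logic* of the analysis (the decoupling argument and
the estimator's correctness), not its performance on any real dataset.

**Problem sizes.** Standard runs use one ~50 s passive trial (30
deflections, ≈ 45,000–50,000 one-ms bins) shared by all neurons of a
population, 20 neurons per condition, and 3×10⁵ bins for recovery
exercises — sizes at which all the tested properties are stable on a
single CPU.

## Known limitations

* 2D only; no torsion, no intrinsic-curvature default (configurable but
  zero by default), no friction, no dynamics — high-frequency micromotion
  and resonances that real whiskers exhibit are absent.
* The synthetic tracker is noise-free; the median filter in the
  preprocessing chain is exercised by tests but idle on synthetic data.
* The coupled-protocol equivalence of subset models is marginally
  resolvable at n = 20 neurons: a residual |ΔR| ≈ 0.003 asymmetry remains
  because the derived predictors are not symmetric between the two sets
  (V hands the kinematic model a precomputed derivative; Fy duplicates M
  when the contact point is fixed).  Real pipelines share this structure.
* The Bernoulli GLM deliberately omits spike-history terms, whisking-phase
  covariates, and any regularization path beyond the fixed tiny ridge.
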