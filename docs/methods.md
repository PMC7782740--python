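# Methods

This note documents the models implemented in `ecospheroid`, the
numerical and statistical choices behind them, what the synthetic-data
generator does and does not emulate, and known limitations.

## Non-spatial growth models

Homogeneous spheroids follow logistic growth dV/dt = rV(1 − V/K) with
growth rate r (day⁻¹), carrying capacity K (mm³) and initial volume V0
(mm³). The closed form is evaluated as K / (1 + (K/V0 − 1)e^{−rt}),
which avoids overflow for large rt.

Mixed parental/radioresistant spheroids follow a two-species
Lotka–Volterra competition-type model in which each population's
per-capita growth rate is reduced (λ > 0) or enhanced (λ < 0) by the
scaled volume of the other population:

    dV_P/dt  = r_P  V_P  (1 − V_P/K_P  − λ_RR V_RR/K_P)
    dV_RR/dt = r_RR V_RR (1 − V_RR/K_RR − λ_P  V_P/K_RR)

We deliberately use the standard multiplicative r·V prefactor. A variant
with an r·K prefactor circulates in print for this system; it does not
reduce to the logistic law when one population is absent and allows
negative volumes, so we treat it as a typesetting artefact and document
the r·V form as this package's model. With r·V, volumes started
non-negative remain non-negative, the system has fixed points at (0,0),
(K_P,0), (0,K_RR) and — when componentwise positive — at the solution of
V_P + λ_RR V_RR = K_P, V_RR + λ_P V_P = K_RR (`lv_coexistence_equilibrium`).

Sign convention for interaction classes: competition (both λ > 0),
mutualism (both λ < 0), antagonism (opposite signs, named for the harmed
population). A coupling exactly 0 contributes neutrally on its axis; any
zero coupling yields the neutral class. Some narrative descriptions of
this system swap the names attached to the signs; all behaviour in this
package is keyed to the signs, never to the names.

λ is stored as a plain number. In the model it multiplies a volume ratio
and is therefore dimensionless; sources that quote it in day⁻¹ mm⁻¹ are
reporting the same numerical value, which we do not convert.

**Integration.** The public `simulate_lv` uses an adaptive explicit
Runge–Kutta scheme (scipy RK45, rtol 1e−8, atol 1e−10) with a blow-up
event at total volume 10⁷ mm³; strong mutualism with λ_P·λ_RR ≥ 1 (both
negative) diverges in finite time and raises a `DivergenceError`
carrying the last valid time. The fitting and bootstrap inner loops use
a numba-compiled fixed-step RK4 (`_fastlv`, substep ≤ 0.02 day) whose
agreement with the adaptive solver is asserted in the test suite at
rtol 1e−6; at the growth rates in play its truncation error is far below
measurement noise.

## Parameter inference

**Logistic fits** minimise residuals on log volume (matching the
multiplicative error structure of spheroid volume measurements) over
(r, K, V0), via Levenberg–Marquardt on log-parameters with data-driven
starts. At least four distinct timepoints are required.

**Lotka–Volterra fits** hold each population's r and K fixed at the
homogeneous-spheroid estimates and estimate (λ_P, λ_RR, V_P0, V_RR0);
the seeding volumes are re-estimated within ±50% of their nominal values
because seeding ratios are nominal. The objective stacks log residuals
on total volume with natural-scale residuals on the parental proportion,
the latter weighted by √(n_volume/n_proportion) so the two blocks
contribute comparably per observation. The objective surface is
multi-modal in the couplings, so five local fits are run — one neutral
start plus four with couplings drawn uniformly from [−0.5, 1.0] from a
per-call seeded generator — and the best objective wins (ties by first
found). Couplings are bounded in [−2, 2]; parameter sets whose
trajectories blow up receive large residuals and are thereby rejected.

**Confidence intervals** are parametric-bootstrap percentile intervals
(default 200 replicates): data are resimulated from the fitted
trajectory with the fitted noise magnitude and refit from the original
solution. The volume noise SD is the log-residual SD. The proportion
noise SD cannot be estimated from the proportion residuals alone — the
fit nearly interpolates the few proportion points — so it is tied to the
fitted volume noise through the declared noise law (fraction SD = half
the volume CV), with the residual SD as a floor. With this choice the
bootstrap 95% CIs for the couplings cover the truth at 90–97% over 200
replicate datasets at 5% noise (asserted in the suite).

**Identifiability study.** For each noise level (defaults 5/10/20%) and
each of `n_reps` replicate synthetic experiments, the same realisation
is fit twice — volumes plus proportions, and volumes only — and bias,
mean CI width and CI coverage of both couplings are tabulated. The study
uses 100 bootstrap replicates per fit (half the single-fit default) to
keep a 50-replicate, three-level study around four CPU-minutes; results
are reproducible bit-for-bit from the seed. Volume-only CI widths
saturate near the coupling bounds once the couplings are essentially
unidentified, so their growth with noise level is monotone only up to
Monte-Carlo jitter.

## Radiation response

A single fraction of dose d multiplies each population instantaneously
by its linear-quadratic surviving fraction exp(−αd − βd²). Defaults are
the PC3 clonogenic-fit means (parental α = 0.44 Gy⁻¹, β = 0.04 Gy⁻²;
radioresistant α = 0.35, β = 0.03); `perturb_lq` resamples α and β from
their reported ±SD for optional uncertainty propagation (off by
default). No mitotic-death lag or doomed-cell compartment is modelled,
and oxygen dependence of α/β is excluded from the non-spatial models,
which carry no oxygen variable.

`regrowth_time` grows the mixed system from its seeding state until the
total volume first reaches the trigger (default 0.9 mm³), applies the
kill, and integrates until the total re-crosses the endpoint (default
0.9 mm³). Crossings are located by root-finding on the dense ODE
solution, making the times grid-independent to well below 0.1 day
(checked against an independent fine-grid fixed-step oracle). Either
phase exceeding the follow-up horizon (default 300 days) censors the
result with a recorded reason, as does divergence. In-silico 1:1 seeding
uses V_P0 = V_RR0 = 0.038 mm³ (the mean of the PC3 homogeneous seeding
estimates, split equally).

A structural property of this model worth stating plainly: after the
kill both populations restart from ~0.01–0.03 mm³, where the interaction
terms are negligible, so early regrowth always proceeds at the intrinsic
rates r ≈ 0.29–0.36 day⁻¹ and the 0.9 mm³ endpoint is re-crossed in
~10–12 days for every coupling choice. The couplings shift regrowth
times by fractions of a day (mutualism fastest, competition slowest — an
ordering that follows from pointwise comparison of the right-hand sides
and is asserted in the suite), not by orders of magnitude. Much larger
spreads would require a different regrowth notion (e.g. relaxation to
the post-treatment equilibrium, which is slow near marginal stability of
the competitive-exclusion state) or additional low-density growth
suppression; both are outside this model.

**Growth delay** compares an irradiated curve against untreated
baselines at an endpoint defined as a multiple (e.g. 2.5×/3.5×/4×) of
the volume at irradiation. Crossing times use monotone log-linear
interpolation and extrapolation is refused: a baseline short of the
endpoint is an error, an irradiated curve short of it is censored at its
last observation. Simulated baselines always bracket the endpoint, so
interpolation suffices where a smoother (e.g. loess) would be needed
only for sparse lab data.

## Hybrid cellular automaton

Two phenotypes occupy a square lattice (default 200×200 sites of 20 µm)
coupled to a continuum oxygen field c solved to quasi-steady state each
step: D∇²c − k(x)c = 0 with c fixed at the medium concentration on the
grid edge, where k(x) is proportional to the occupying phenotype's OCR.
First-order (oxygen-limited) uptake makes the discrete operator an
M-matrix, so 0 ≤ c ≤ c_boundary holds everywhere without clamping. The
system is solved matrix-free by conjugate gradients with a fast-Poisson
(discrete sine transform) preconditioner, warm-started from the previous
step; the relative residual is verified ≤ 1e−6 on every solve.

Per step (default dt = one tenth of the shortest cycle time): cells
whose local oxygen stays below their phenotype's hypoxia threshold for
longer than a 12 h grace period die; cycle clocks advance, and a cell
with an expired clock divides into a free von Neumann neighbour or one
obtainable by shoving at most 5 cells along the shortest straight path,
otherwise its clock is held (contact inhibition); dead cells lyse at a
phenotype-specific rate, freeing their site. Update order is randomised
each step from the state's own generator, so runs are bit-reproducible
from the seed.

Default phenotype parameters (PC3-like): parental cycle 30 h, OCR 1.0,
hypoxia threshold 0.08; radioresistant cycle 25 h (its higher bulk
growth rate), OCR 0.83 (the measured 17% reduction), hypoxia threshold
0.16; lysis 0.3 day⁻¹ for both; oxygen diffusivity 100 site²h⁻¹, uptake
scale 1 h⁻¹, boundary concentration 1. The two thresholds are a
calibration choice, not a measurement: they are set so that a hypoxic
core develops at roughly half the spheroid radius around day 11, and so
that the radioresistant phenotype — faster-cycling but less
hypoxia-tolerant — accumulates at the well-oxygenated periphery while
parental cells persist in the centre. With these defaults the day-10
radial segregation index (mean RR radial distance minus mean parental
radial distance, over the spheroid radius) is ≈ +0.2 and positive in
essentially every seed.

Growth curves derive from the filled cross-section area A — the occupied
region with interior holes filled, matching what an outer-contour
(brightfield) volume measurement sees, since lysed cores remain inside
the spheroid contour — via the equivalent-sphere convention
V = (4/3)π^{−1/2}A^{3/2}; this mapping is a documented convention, not a
measurement. Homogeneous runs produce
logistic-like curves (fit R² > 0.95 over 10 days); mixed runs stay
within the envelope of the homogeneous runs — competition for space and
oxygen alone produces no super-additive growth, so the enhanced growth
of real mixed spheroids is not explained by this mechanism (the model's
informative negative result).

## Synthetic data

Volumes are perturbed multiplicatively by exp(σZ) with
σ = √(log(1+cv²)), unbiased on the log scale with empirical CV equal to
the nominal cv (draws clipped below at 10⁻⁶ of the true value);
proportions receive additive Gaussian noise with SD = cv/2, clipped to
[0,1]. Defaults mirror the emulated study design: 12 spheroids per
group sampled daily to day 15 (or 20), proportions at days 5/10/15 in 4
replicate measurements, seeding 1:1 (or 9:1 via the V0 arguments). The
generator does not emulate imaging artefacts, segmentation error
structure, gating error, batch effects, or inter-spheroid parameter
heterogeneity — recovery results on synthetic data are therefore
best-case statements about estimator behaviour under the declared noise
law, not about robustness to those real-data features.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the recovery loops at 50–100
replicates, the bootstrap at 100–200 replicates, the landscape on 0.05
steps of the coupling grid, and the CA at 200×200 sites for 10 simulated
days (20 seeds); these sizes give Monte-Carlo error comfortably inside
the asserted tolerances while keeping a full run in the tens of minutes
on one core.

## Known limitations

- Couplings are constant in time; interaction changes after treatment
  are not modelled.
- Radiation is a single instantaneous fraction; no fractionation,
  dose-rate effects or tumour-control statistics.
- The CA is 2D, has no direct cell–cell signalling, secreted-factor
  fields or vasculature, and its radiation response is not modelled
  (oxygen-dependent α/β would be required and is not parameterised).
- Fits assume a single shared trajectory per group; no hierarchical
  between-spheroid variation.
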