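# Methods

## Model

The forward model is a mass-action/Hill reaction network
`dy/dt = f(y; u, κ)`, `y(t₀) = y₀`, with states y in molecules per cell,
rate constants κ > 0, and the inhibitor potency u = IC50 as the control
input.  A declared subset of κ is the uncertain vector θ that inference
targets.  Rate laws are written as plain expressions in a YAML model file,
parsed once with sympy, and emitted (together with the analytic Jacobians
∂f/∂y and ∂f/∂θ) as numba-compiled machine code.

Integration uses LSODA (adaptive, stiff-capable) with the analytic
state Jacobian, at rtol 1e-6 / atol 1e-9 by default (overridable per
model).  The apoptosis indicator needs the *running maximum* of the
activated-caspase state, so trajectories are returned on a dense output
grid of 500 points over [t₀, τ] by default — a coarse unit-spaced grid
can clip the caspase peak; halving the spacing moves the peak by well
under 0.1% on the bundled model.  The death threshold comparison is
inclusive (peak ≥ 1000 molecules).  Concentrations within 10× atol below
zero are clipped to zero (integrator round-off); anything more negative
raises an error, since it indicates a mis-specified model rather than
round-off.  Failed integrations always raise or are explicitly counted —
never silent NaNs.

### The bundled reduced network

`reduced_apoptosis_model()` is a synthetic, desk-scale stand-in with the
same decision structure as a full PARP1-apoptosis pathway model: 10
species, 11 uncertain rate constants, 5 measurable species (candidate
designs), and two competing fates — repair of DNA double-strand breaks
versus p53 → Bax → caspase-mediated death.  The inhibitor enters through
a Hill factor `u/(u + K_I)` multiplying the repair flux, so a potent
(low-IC50) inhibitor shuts repair down.  Rates are calibrated so that at
nominal parameters apoptosis triggers at u ≤ 0.001 and not at u ≥ 100,
with the switch mid-grid (near u ≈ 0.06).  It is *not* a transcription of
any published 23-ODE parameterisation; conclusions about which species
wins on the fixture carry no biological weight.  Users can substitute a
full model via the YAML schema.

## Priors

Each uncertain rate gets an independent log-normal prior.  The nominal
value is treated as the **median** (scale-equivariant under the log
transform, matching how rate constants are quoted), so μ = ln(nominal);
σ is recovered from the stated CI's total log-width,
σ = (ln cᴴ − ln cᴸ)/(2 z) with z the standard-normal quantile of
(1+level)/2, level defaulting to 0.95.  Asymmetric CIs are
log-symmetrised around the nominal with a warning.  The bundled prior
table uses a factor of 5 either side of nominal (σ ≈ 0.82 in ln units —
order-of-magnitude uncertainty).  A global `scale_factor` multiplies
every σ; medians are invariant under scaling.

## Simulated experiments

An experiment is a single final-time observation of one measurable
species at a chosen dose: `y_obs ~ Normal(ŷ, r·ŷ)` with r = 10% and
ŷ the model prediction at t = τ under the generating parameters
(default: prior medians).  The default campaign is 100 replicates per
design; the generating dose defaults to u = 1.0, mid-grid, where a
final-time observation is most informative about the switch region.
Negative draws are kept — the Gaussian error model is applied honestly
and the likelihood handles them.  Time-series (multi-time-point)
calibration is out of scope by design.

## Inference

The likelihood mirrors the generator:
`ln Normal(y_obs; ŷ(θ), r·ŷ(θ))`.  The noise scale follows the
prediction, so the normalisation term −ln(r·ŷ(θ)) varies with θ and is
kept.  Gradients of ŷ come from the forward-sensitivity ODE system
S' = (∂f/∂y)S + ∂f/∂θ, integrated alongside the states.  The
sensitivity system is supplied with an analytic block Jacobian (exact in
the state block and the ∂S'/∂S blocks; the second-derivative coupling
∂S'/∂y is dropped, which only affects the implicit solver's Newton
convergence, not solution accuracy) — without it LSODA finite-differences
an (n + n·m)-square Jacobian and is an order of magnitude slower.

Sampling runs in whitened log space, x = (ln θ − μ)/σ, where the
log-normal prior including its Jacobian is exactly standard normal.  The
sampler is Hamiltonian Monte Carlo with:

* leapfrog path lengths jittered uniformly on [1, 10] (avoids
  resonances);
* dual-averaging step-size adaptation to a 0.8 acceptance target;
* warm-up of 20% of the chain length, discarded.  Its first half runs
  under an identity metric; the sample covariance of that phase (shrunk
  toward a small multiple of the identity, Stan's recipe) then becomes a
  dense metric via its Cholesky factor and the step size is re-tuned.
  The dense metric matters here: a single observation carves one narrow,
  oblique ridge through the 11-dimensional prior, and identity-mass HMC
  would need a step size matched to the ridge width;
* divergences (energy error > 1000 or a non-finite trajectory) rejected
  and counted, never fatal;
* an 8σ rejection box in whitened space: beyond it the prior mass is
  < 1e-15 but the ODE system turns pathologically stiff, so the region
  is rejected outright rather than integrated.

One chain is run per measurement replicate; the ensemble of replicate
posteriors is the object the design metrics act on.  Desk-scale defaults
are 10 replicates × 2000-sample chains; the config schema accepts
campaign-scale values (100 × 50,000).

Effective sample size uses FFT autocorrelation with Geyer's
initial-positive-sequence truncation, capped at the chain length;
constant columns are reported as undefined (NaN) with a warning.

### Biological constraints

Dose-boundary knowledge — the cell must die at u ≤ 0.001 and live at
u ≥ 100 — is enforced by *post-hoc filtering* of the chains: a draw θ is
kept only if the forward model triggers apoptosis at the potent boundary
and not at the impotent one.  Filtering after sampling (rather than
inside the likelihood or prior) keeps the HMC geometry smooth; the cost
is a retention fraction that can be small, which is reported per chain.
Draws that fail to integrate cannot be certified and are removed.
Forward solves are deduplicated across repeated rows (MCMC rejections
duplicate states).  An empty filtered chain is a *signal* (the replicate
is skipped and counted), not an exception.

## Lethality curves and design objectives

`p_apoptosis` is the plain indicator average over the sample table; the
same sample set is reused across all grid doses (common random numbers,
reducing curve-to-curve jitter).  Failed integrations count as
non-apoptotic — conservative for a lethality claim — and are tallied,
never dropped (dropping would bias p upward).  Curves built from chains
use n_sub = 200 equally spaced (deterministic) draws per chain.  With
`apply_bounds`, curve values at u ≤ 0.001 / u ≥ 100 are overridden to
1 / 0; the override is idempotent.  Both bounded and raw curves can be
emitted, flagged by `constrained`.

σ_apop(u) is the n−1 sample standard deviation of the replicate curves'
values at u.  σ_IC50(T) works on the log₁₀ concentration scale (the grid
spans five orders of magnitude; reported units are stated in output
metadata): each curve's crossing dose is the first transition from
p ≥ T to p < T scanning ascending u — lethality falls with weaker
inhibitors — located by linear interpolation in (log₁₀ u, p).
Multi-crossing curves use the first crossing and are tallied.
Non-crossing curves are excluded and counted rather than clamped to a
grid edge, which would artificially deflate the spread; fewer than two
crossing curves makes the metric undefined (NaN with counts) rather than
an error.  Rankings sort ascending (smaller σ = more informative design),
break ties lexicographically by name (flagged), and exclude designs with
undefined objectives with a warning.  The weighted objective is evaluated
at u\* = 0.01 and T\* = 0.90 by default.

The prior-sensitivity study scales every prior σ by factors
{1, 0.1, 0.01, 0.001, 0.0001}, draws 1,000 samples per factor (same seed
across factors, so curves differ only through the prior width), and
reports the lethality curve per factor with and without bounds.  On the
bundled model the curve range grows monotonically from ≈ 0.44 at the
full prior to 1.0 (a deterministic switch) by factor 0.01.

## Orchestration and determinism

`run_study` derives every stage's seed from the master seed via
`SeedSequence([master, design_index, replicate, stage])`, with the design
index taken in the model's *full* measurable-species list — removing a
design from a study never changes another design's seeds or results.
Partial failures (a design with all-empty filtered chains) degrade to
exclusion with a warning.  `results.json` contains no wall-clock or other
volatile fields, so identical config + seed reproduce it byte for byte;
timing and versions go to a separate `run_log.json`.

## Problem sizes

Unit and integration tests run seconds-scale configurations; the
parameter-recovery check uses the full desk-scale setting (10 replicates
× 2000-sample chains, ≈ 4 minutes on one CPU).  `scripts/acceptance.py`
uses 10 replicates × 600-sample chains × 5 designs (≈ 7 minutes),
chosen so a complete from-scratch rerun stays workstation-friendly; the
statistical character of the results is unchanged from the desk-scale
defaults, only Monte-Carlo noise grows.

## Known limitations

* The fixture is a reduced synthetic network: retention fractions
  (tens of percent) and best-vs-worst reduction percentages on it differ
  from what a 23-ODE pathway model at campaign scale produces, and the
  winning species on the fixture is not a biological conclusion.
* A single final-time observation leaves the 11-parameter posterior
  strongly non-identifiable; per-chain ESS is accordingly low (tens per
  600–2000 draws).  The design metrics average over replicate chains,
  which is where their stability comes from.
* Independent log-normal priors ignore parameter correlations; the
  prior-sensitivity study scales all σ jointly and says nothing about
  correlated reductions.
* Gaussian measurement noise with sd proportional to the prediction is
  an idealisation of assay error; real assays have floors and
  saturation.
* No within-sampler (soft) constraint enforcement; constraint
  relaxation inside the likelihood is future work, not implemented.
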