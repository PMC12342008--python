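# Methods

## Problem setting

Given one patient's biomarker time series c (several biomarkers, at most
eight visits from baseline to week 24, possibly missing biomarkers,
strictly positive values), find parametrizations θ of a mechanistic
treatment-response simulator whose output matches c — and quantify how
probable alternative parametrizations are. The package learns, per
patient, a posterior p(θ | x_o) rather than a point estimate, and reuses
learned parametrizations of similar patients to sharpen priors across a
cohort.

## Surrogate simulator

Production disease models in this field are large proprietary ODE systems;
`npfit` ships a deliberately small surrogate that preserves the problem
shape (positive parameters, treatment-driven decline of an inflammatory
driver, several coupled readouts on different scales):

- states: inflammatory mediator P, acute-phase biomarker C, degradation
  biomarker M, initialized at their pre-treatment steady state;
- drug effect E(t) = Emax·(1 − e^(−k_on·t)) suppressing production of P;
- observables: CRP_like = C, MMP_like = M, CELL_like = L0·(1 + a_L·P),
  SCORE_like = d0 + d1·ln(1 + C) + d2·P (a composite disease score).

Reference parametrization (a "typical treated patient", configuration not
ground truth): k_p=10, k_dp=1, k_c=2, k_dc=0.5, k_m=1, k_dm=0.4, L0=2,
a_L=0.05, d0=2, d1=1.5, d2=0.1, Emax=0.6, k_on=0.5 (rates per week). The
system is solved numerically (LSODA, absolute and relative tolerances
1e-6) even though a closed form exists, keeping the simulator interface
general; simulator failures are signalled, not fatal, because inference
must treat them as invalid draws. Emax ≥ 1 is outside the model's domain
and is treated as a simulation failure — during inference such prior
draws are simply dropped.

The default fitting subset is {k_p, k_dp, k_c, k_dc, k_m, Emax, k_on}
plus the noise scale σ (8 dimensions), chosen with the sensitivity module
to mimic a combined expert + global-sensitivity selection at reduced
scale; the remaining parameters stay frozen at the reference.

## Synthetic cohorts

The generator emulates the statistical structure of sparse trial data:

- true per-patient parameters drawn per dimension from
  LogNormal(loc = ln θ_ref, scale = pop_scale), default pop_scale = 0.35
  (large inter-patient variability: 95% of draws within roughly a factor
  of 2 of the reference); draws outside the simulator's domain are
  rejected and redrawn;
- multiplicative lognormal measurement noise with a per-patient scale
  drawn uniformly from [0.05, 0.2] (5–20% relative error, a realistic
  range for blood biomarkers);
- sparsity: each non-core biomarker dropped entirely with probability
  0.2, each non-baseline visit with probability 0.2; CRP_like and
  SCORE_like are "core" and always present (mirroring the availability
  of CRP and composite disease scores in trials);
- observation grid: weeks {0, 2, 4, 8, 12, 16, 20, 24}.

What the generator does **not** emulate: patient subpopulations or
correlated parameters (truth is drawn independently per parameter),
biomarker-specific noise levels, informative missingness, dropout over
time, or measurement limits of quantification. Passing recovery tests on
these cohorts therefore demonstrates correctness of the inference
machinery under the stated noise/sparsity model, not clinical validity.
The independent-truth design also means patients do not cluster, which
bounds how much a nearest-patient prior can help (see Limitations).

## Summary features and patient similarity

Each biomarker series is encoded as (median, Q0.9 − Q0.1), quantiles by
linear interpolation between order statistics — stated explicitly because
with 3–8 observations the convention is visible in the values. K
available biomarkers give a 2K-dimensional observation; 16 biomarkers
would give 32. Features are normalized per feature by cohort median and
IQR (robust statistics, since clinical biomarkers are heavy-tailed; zero
IQR falls back to scale 1). Patient similarity is the Euclidean distance
over the biomarkers both patients share,

    d(i, j) = sqrt( 3/(2|CB|) · Σ_{b∈CB} (Δmedian_b)² + (Δspread_b)² ),

with the 1/|CB| factor stabilizing the scale across different numbers of
common biomarkers; a pair with no common biomarker is "incomparable" and
sorts after every finite distance. Spread terms compare the two patients'
own spread features (per-patient Q0.9 − Q0.1), keeping the metric
consistent with the declared feature set.

## Inference engine

Sequential neural posterior estimation, implemented self-contained in
numpy. The conditional density estimator is a masked autoregressive
("MADE"-family) network with Gaussian per-dimension conditionals: one
hidden tanh layer (default 50 units at desk scale; 100 reproduces the
full-scale setting) with Germain-style degree masks; degree-0 hidden
units carry pure conditioning information to every output dimension. The
estimator operates on z = ln θ, standardized with first-round statistics:
the lognormal prior becomes Gaussian there and samples are positive by
construction.

Per round (defaults: 10 rounds × 50 simulations; full-scale 50 × 100):

1. draw θ from the prior (round 1) or from the current posterior estimate
   conditioned on x_o (later rounds — the proposal);
2. simulate each draw through the stochastic forward model (simulate →
   restrict to the patient's observation schedule → multiply by lognormal
   noise with the draw's own σ → summarize → normalize); invalid
   simulations are dropped, not resampled, keeping round cost bounded;
3. retrain on the cumulative sample set (training continues from the
   current weights): round 1 by maximum likelihood, later rounds with the
   atomic proposal correction (default 25 atoms) — each sample's loss is
   a softmax over prior-density-corrected candidate parameters, which
   makes the network estimate the true posterior rather than the
   proposal posterior. Adam (lr 5e-4), minibatch 50, 10% validation
   held-out, early stopping with patience 10 (max 100 epochs).

Masked features of absent biomarkers are imputed to 0 after
normalization; the patient-specific observation schedule is baked into
the forward closure, so simulated and observed summaries are masked
identically and the estimator sees a fixed-length input. All randomness
flows from one per-patient seed split into (init, prior, simulator,
training, proposal) streams; fits are bitwise reproducible.

Verification: on a 1-parameter conjugate toy (x = θ·e^ε, lognormal prior,
closed-form lognormal posterior) the engine's posterior median lands
within a few percent of the analytic value, and its spread in the right
regime; the test suite asserts the 10% tolerance.

## Priors

Independent lognormal marginals with a single shared scale 0.25. Plain
fitting centers at θ_ref (loc = ln θ_ref); the noise dimension is
centered at σ = 0.2. NPF centers at the nearest container patient's
learned parametrization with the same scale — the two paths differ only
in the center. The noise center is *not* inherited from the neighbor:
measurement noise is a property of the data, not of the neighbor's
biology. No prior correlations are imposed.

## Nearest-patient-fit pipeline

Batches (default size 4) of pending patients nearest to the container are
fitted in sequence; the container is frozen within a batch and extended
afterwards with fits passing the quality gate (best-of-posterior loss
strictly below the reference loss). Per-patient seeds are derived by
hashing (master seed, patient id, stage), so results are independent of
batch composition and order; with batch size = cohort size, NPF and plain
fitting coincide exactly under equal seeds — a structural identity the
tests exploit.

## Evaluation

All evaluation is noise-free (σ models measurement error, not biology):
loss L is the max-scaled mean squared deviation over the patient's
observed biomarkers and times, with the max taken over that biomarker's
*observations* (a biomarker whose observed maximum is 0 is skipped with a
warning); gap = (L_ref − L)/L_ref; the reported parametrization is the
best of 100 posterior draws, and frac_better is the fraction of those
same draws with loss strictly below L_ref — sharing the draw set makes
best-of and frac consistent by construction. Population tables (per-
patient metrics, pooled observed-vs-simulated pairs, week-24 endpoints)
support visual predictive checks.

## Sensitivity analysis

Saltelli design on uniform ±30% ranges around the reference (Sobol
quasi-random base sample, scrambled, seeded), Jansen estimator for the
total-order index per output, outputs defaulting to every biomarker at
weeks 4, 12 and 24 (snapshots during treatment). Output variances are
sample variances over the design. Aggregation across outputs is the
variance-weighted mean; selection returns an expert-priority list plus
the most sensitive remaining parameters. More than 5% simulation failures
in a design aborts the analysis; rare failures are imputed by the design
mean.

## Numerical choices and degenerate inputs

- log-sigma outputs of the estimator clamped to ±7; standardization
  frozen after round 1 so continued training is well-posed.
- Nearest-neighbor and batch-selection ties break lexicographically by
  patient id; best-of-posterior ties by first occurrence.
- A patient whose engine fit aborts yields a failed FitResult (NaN gap,
  gate failed) without halting the cohort.
- Constant features (zero IQR) normalize with scale 1; a biomarker absent
  from every patient normalizes to loc 0/scale 1 and stays masked.

## Problem sizes used in the shipped tests

The test suite exercises the desk-scale configuration: 10 rounds × 50
simulations per fit, cohorts of 4–20 patients, 5 replicates for the
NPF-vs-plain comparison at 6 patients with batch size 1 (so the container
grows before most patients receive priors), and N = 1024 base samples for
the Sobol checks. The full-scale configuration (50 × 100, hidden 100,
25-parameter subsets) is reachable purely through configuration.

## Known limitations

- The surrogate is linear given E(t); it cannot exhibit multimodal
  posteriors as rich as large nonlinear disease models, so the estimator's
  multimodal capacity is exercised only lightly.
- With independently drawn truth, nearest neighbors in feature space are
  only weakly informative about parameter space; the benefit of NPF on
  these synthetic cohorts is therefore structurally smaller than on real
  cohorts with patient subtypes, and at desk scale plain fitting already
  reaches high gaps, leaving NPF little headroom.
- A single shared noise scale across biomarkers; no per-biomarker noise.
- Posterior models are not serialized (only their draws are); refitting
  is cheap at desk scale.
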