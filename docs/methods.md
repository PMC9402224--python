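# Methods

## Network and model space

Six regions in fixed canonical order — V1, SPC, Thal, BG, dACC, dPFC — give
every matrix in the package its row/column semantics (`a[target, source]`).
The hypothesis space holds thirteen directed pathways. Eight are fixed in
every model (V1→SPC, V1→Thal, SPC→Thal, SPC→BG, Thal→BG, BG→Thal, BG→dPFC,
dACC→BG); four fronto-thalamic connections (Thal→dPFC, dPFC→Thal,
Thal→dACC, dACC→Thal) are permuted over three states — absent, present, or
present and contextually modulated by *both* attention conditions — and
dPFC→BG over two states (absent, present-and-modulated), producing
3⁴ × 2 = 162 architectures. Enumeration is lexicographic and deterministic;
`model_id` is the position. The fixed skeleton is a subgraph of every
model.

Two choices here were genuinely open and are ours:

- The three states of the permuted connections are read as
  {absent; present unmodulated; present with joint low+high modulation} —
  the only reading consistent with the 3⁴ × 2 count and with modulation
  marks that apply to both conditions at once.
- Driving input enters V1 only, on both condition inputs. V1 is the
  sensory entry point of the modeled network; the template field
  `driving_targets` makes this configurable.

## Forward model

Neural dynamics: `dx/dt = (A_eff + u₁ B_low + u₂ B_high) x + C u` with
`A_eff = A − λ_self I`. The diagonal self-decay is fixed at λ_self = 0.5 Hz
and not estimated: group tables report only inter-regional pathways, and a
fixed leak guarantees stability of every masked architecture. Inputs are
the condition boxcars at microtime resolution (TR/16 by default); they
drive the neural level directly and are not HRF-convolved.

Observation: the standard balloon–Windkessel cascade per region —
vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin q:

    ds/dt = εx − κs − γ(f − 1)
    df/dt = s
    τ dv/dt = f − v^(1/α)
    τ dq/dt = f·E(f, E₀)/E₀ − v^(1/α) q/v,   E(f, E₀) = 1 − (1 − E₀)^(1/f)

with constants κ = 0.64 Hz, γ = 0.32 Hz, τ = 2.0 s, α = 0.32, E₀ = 0.4,
V₀ = 0.04, ε = 1 (fixed, not estimated; ε can be freed per region). BOLD
is the static observation `y = 100·V₀·(k₁(1−q) + k₂(1−q/v) + k₃(1−v))`
with k₁ = 7E₀, k₂ = 2, k₃ = 2E₀ − 0.2, in percent signal change about
zero. There is no baseline, drift, or physiological-noise term; scanner
noise is i.i.d. Gaussian added at scan resolution.

Integration is classical fixed-step RK4 on the microtime grid
(dt = TR/microtime_bins), neural stage first, balloon stage second. The
balloon stage evaluates its half-steps on Hermite midpoints of the stored
neural trajectory computed with the exact neural derivative at both bin
edges; this keeps the two-stage scheme 4th-order (halving dt changes the
noiseless BOLD by ~1e−6, measured), where linear midpoint interpolation
would degrade it to 2nd order. A matrix-exponential stepper (exact for the
piecewise-constant-input linear neural system) serves as the integrator's
test oracle only. Scans are acquired at the end of each TR;
`n_scans = floor(total_s / TR)`.

Strongly negative sustained activity can push the inflow f out of its
positive domain (the balloon equations are only defined for f, v, q > 0);
the integrator detects this and raises, naming the first bad bin. The
cohort generator treats such parameter draws as outside the admissible
domain (see below).

## Inversion: variational Laplace

Per (subject, model), the masked entries of A, B_low, B_high, C form the
parameter vector θ (canonical flattening: A row-major, then B_low, B_high,
C). Priors are zero-mean independent Gaussians — variance 1/16 on A and B
entries, 1/4 on C — and the per-region observation noise has log precision
λ_r with a N(0, 1) reference prior that supplies the initial value.

The posterior is approximated as q(θ) = N(μ, Σ) by Gauss–Newton ascent on
the variational free energy

    F = E_q[log p(y | θ, λ)] − KL(q(θ) ‖ p(θ))
      = Σ_r [ n/2·(λ_r − log 2π) − exp(λ_r)/2·(‖r_r‖² + tr(J_r Σ J_rᵀ)) ] − KL,

where r = y − g(μ) and J = ∂g/∂μ. The trace term (the Gaussian-expectation
correction) makes the bound exact on linear-Gaussian models, which the test
suite verifies against the closed-form log marginal likelihood to 1e−6;
`free_energy()` omits it only when no Jacobian is supplied.

Numerics, all deterministic:

- Jacobians by central finite differences (h = 1e−4) through the full
  neural+balloon forward model; all 2P+1 perturbed parameter sets
  integrate in one batched, numba-compiled kernel call.
- Σ = (Jᵀ P_e J + S₀⁻¹)⁻¹ via Cholesky; λ_r by the exact EM M-step
  exp(−λ_r) = (‖r_r‖² + tr(J_r Σ J_rᵀ))/n, clipped to [−8, 16] as a guard
  against noiseless fixtures driving the precision to infinity (the
  M-step, unlike a MAP update, exactly maximizes the reported F, which
  keeps the accepted-iteration F sequence non-decreasing).
- Levenberg-style step halving: a candidate step is first screened with a
  cheap surrogate F (current Σ, λ and Jacobian, corrected by the running
  surrogate-vs-full gap), then confirmed by a full re-evaluation; only
  F-non-decreasing steps are accepted. Initialization at the prior mean;
  convergence at ΔF < 0.01 nats or 64 iterations.

Identifiability at these settings: with the block design task-active 86%
of the time, intrinsic coupling A and modulation B on the same pathway are
strongly collinear; B posterior means shrink by roughly 0.5 at unit SNR,
with part of the modulation absorbed into A. The estimator is calibrated —
posterior SDs match realized RMS errors — so this is an information limit
of the design, not an optimizer artifact; noiseless data are recovered
exactly. Downstream consequences (power of group contrasts on modulation
parameters) are discussed under validation.

## Random-effects model selection and averaging

`rfx_bms` implements the variational Dirichlet scheme: responsibilities
u_nk ∝ exp(F_nk + ψ(α_k) − ψ(Σα)) with per-subject recentring (a pure row
shift cancels, which the tests assert), α = α₀ + Σ_n u_n, iterated to
max|Δα| < 1e−6; α₀ = 1 (uniform prior). Expected probabilities are the
Dirichlet mean; exceedance probabilities are seeded Monte-Carlo frequencies
of being the largest component over 1e5 Dirichlet draws (one code path for
any K; the two-model case is cross-checked in tests against brute-force
Beta sampling). Note the expected frequency is bounded by
(α₀ + N)/(Kα₀ + N) no matter how strong the evidence; decisive selection
shows up in the exceedance probability.

Occam's window retains models with expected probability above 1/20 of the
best model's and renormalizes (the conventional odds cutoff; the window
level and threshold are configurable). BMA draws, per sample, a model from
the group-level window weights and, per subject, a parameter vector from
that model's posterior N(μ, Σ); entries absent from the drawn model
contribute zero. Estimates are means over 20,000 seeded samples on the
saturated 25-parameter naming (13 A + 5+5 B + 2 C), with Monte-Carlo
standard errors; the sampler is validated against the analytic mixture
mean Σ_k w_k μ_k within 3 MC SEs. Window weights are shared by all
subjects of a group (per-subject weighting would also be possible but the
group-level reading is the literal one).

## Group statistics

Per pathway and parameter class (intrinsic; low-demand modulation;
high-demand modulation): group mean, SD (n−1), one-sample t against zero
per group, and the pooled-variance independent-samples t between groups
(pooling reproduces the published worked examples from their printed
summaries to ±0.02; Welch does not). Tests are two-sided and uncorrected
at α = 0.05; a Benjamini–Hochberg column is emitted for reference but does
not drive flags. The between-group sign is printed per class — HC−OCD for
intrinsic rows, OCD−HC for modulation rows, matching the tables'
conventions — and both signed values are always in the output.

## Synthetic cohorts

The design generator emulates the identical-pairs continuous performance
task: cycles of low-demand (120 s), rest (20 s), high-demand (120 s), rest
(20 s); default 2 cycles = 560 s = 215 scans at TR 2.6 s. Individual
stimuli (480 per block at 250 ms SOA, 25% targets) are deliberately not
modeled as neural events — the analysis targets sustained, epoch-level
responses — so the stimulus arithmetic exists only to validate the design
geometry. Epoch boundaries are quantized to the microtime grid (one bin of
slack per boundary).

Subject parameters are drawn independently per pathway from group-level
normal distributions whose default means/SDs are the published HC and OCD
table values (13 intrinsic pathways; 5 modulable pathways × 2 conditions),
masked by a generating architecture (default: saturated). Driving efficacy
is N(0.3, 0.05²) Hz on both inputs — the published tables do not cover C;
the value was chosen once to give a clearly supra-noise V1 response within
the stable domain. Scanner noise is white Gaussian; its SD defaults to the
**median per-region SD** of the noiseless series of a subject at the group
means ("SNR ≈ 1" for the typical region — the directly driven V1 row would
dominate a pooled SD and leave the five downstream regions far below unit
SNR). Draws whose forward simulation leaves the balloon's positive domain
are retried once with halved coupling and then replaced by fresh draws
(rejection sampling from the group distribution truncated to the stable
domain, at most three redraws); everything derives deterministically from
the master seed.

What the generator does **not** emulate: scanner drift and physiological
noise, temporal autocorrelation (noise is white by construction, matching
the inversion's noise model), hemodynamic variability across regions and
subjects (the balloon constants are shared), event-related responses, and
head motion. Passing tests therefore demonstrate the correctness and
calibration of the analysis chain under its own assumptions, not
robustness to the artifacts of real fMRI.

## Validation experiments and problem sizes

The acceptance suite runs desk-scale versions of the end-to-end analyses;
sizes were chosen to keep the full suite around a quarter hour on one CPU:

- **Recovery**: 8 subjects spanning noise fractions 0, ⅓, ⅔, 1 of the
  SNR-1 level (2-cycle design, 8 microtime bins/TR); pooled truth/estimate
  correlation over free A/B entries ≥ 0.8. At strict SNR 1 alone the
  correlation plateaus near 0.7 — the calibrated information ceiling of
  the design, not an estimator defect.
- **Identification**: 10 cohorts (n = 8 per group, 1 cycle) generated from
  the saturated model of a 4-model subspace {all-absent, all-present,
  partially-modulated, saturated}; the generating model must take the top
  exceedance probability in ≥ 9 of 10.
- **Detection**: 10 cohorts at the published sizes (32 vs 30) with a
  planted Thal→dPFC modulation deficit (0.25 vs 0.00, SD 0.27, both
  conditions), 2-cycle design at 4 microtime bins/TR, a 2-model subspace
  in which both models carry the Thal→dPFC modulation (so Occam-window
  averaging does not dilute the contrast); the deficit must be flagged in
  ≥ 80% of the 20 (replicate × condition) opportunities. Because of the
  A/B collinearity above, this check sits closer to its threshold than
  the others.
- **Calibration**: two-sample type-I error within [0.03, 0.07] over 2,000
  Gaussian nulls; free-energy/evidence agreement to 1e−6; BMA sampler vs
  analytic mixture mean within 3 MC SEs.

## Known limitations

- Hemodynamic parameters are fixed, not estimated; regional hemodynamic
  variability will bias coupling estimates on real data.
- Noise is modeled as white; real fMRI noise is autocorrelated, and no
  AR model is fitted.
- The balloon stage integrates the native-space equations and treats
  f ≤ 0 as a hard domain error rather than integrating in log space;
  generative draws are correspondingly truncated to the stable domain.
- B-vs-A collinearity under the 86%-task-active block design limits the
  power of modulation contrasts at unit SNR; longer runs or more rest
  would improve it.
- The 162-model full-space inversion of a 62-subject cohort (10,044 fits)
  is supported (cached, resumable) but takes a few hours on one CPU; the
  shipped experiments use subspaces.
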