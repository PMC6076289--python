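# Methods

## Models

Both built-in models describe the three-tier RAF → MEK → ERK kinase cascade
in terms of the active forms `aRAF, aMEK, aERK`. Each active form draws on a
finite pool `iX = X_TOT − aX`, so all trajectories started in the box
`[0, totals]` stay there: activation terms vanish as the inactive pool
empties, decay terms vanish as the active form empties. Rates are built from
two Michaelis–Menten primitives,

```
Ma(k, K, S, M) = k·S·M/(K+S)      (modifier-driven activation)
M0(V, K, S)    = V·S/(K+S)        (phosphatase-mediated decay)
```

**EGF-driven cascade** (16 rate parameters). EGF enters directly as the
modifier of RAF activation; active ERK catalyses the deactivation of both
RAF and MEK (two negative feedback loops):

```
d(aRAF)/dt = Ma(k_f1, K_mf1, iRAF, EGF)  − Ma(k_r1, K_mr1, aRAF, aERK) − M0(V_m1, K_m1, aRAF)
d(aMEK)/dt = Ma(k_f2, K_mf2, iMEK, aRAF) − Ma(k_r2, K_mr2, aMEK, aERK) − M0(V_m2, K_m2, aMEK)
d(aERK)/dt = Ma(k_f3, K_mf3, iERK, aMEK)                               − M0(V_m3, K_m3, aERK)
```

Defaults are the published study values (`k_f1 = 1, K_mf1 = 10, V_m1 = 2, …`).
The total pools are not part of the sixteen free parameters; the study
protocol treats them as known. Their default, `RAF_TOT = MEK_TOT = ERK_TOT
= 100`, is a documented choice on the order of the Michaelis constants
(half-saturation 10), not a published value. Units are arbitrary
concentration units; time is minutes.

**EGF/NGF cascade** (24 rate parameters + 3 totals = 27 unknowns). RAF is
driven by a transient RAS-GTP pulse `RAS(t) = (L/(1+L))·t^5·exp(−kd·t)`
(zero at t = 0, peak at t = 5/kd) rather than by the ligand directly, and
binary flags `(b_e, b_n)` select ligand-specific wiring: under EGF a
negative feedback aERK ⊣ aRAF (`k_r12`); under NGF a positive feedback
aERK → aRAF (`k_f14`) and a feed-forward aRAF → aERK (`k_f32`). The model
is non-autonomous (the pulse decays), so it has pseudo-steady states only —
time points where all rates transiently vanish.

## From data and model to the same feature space

*Data side.* Replicate measurements are averaged per (condition,
perturbation, species) — sample means, per the study protocol. Global
response coefficients use the symmetric relative difference
`R_ij = 2(x_i^j − x_i)/(x_i + x_i^j)`, a finite-perturbation approximation
of `d ln x_i / d ln x_j`; any common reporter gain cancels. Classical MRA
(exactly one perturbation per node) inverts this into the local response
matrix `r = −(dg(R⁻¹))⁻¹ R⁻¹`. The sign makes every diagonal −1 exactly,
consistent with the scaled-Jacobian definition below; the inversion refuses
ill-conditioned `R` (condition number above 1e8 by default). Ligand response
ratios `ρ_i = x_i^dose / x_i^ref` compare unperturbed steady levels across
doses against the lowest dose.

*Model side.* At a stable steady state the same LRCs are
`r_ij = −J_ij x_j / (J_ii x_i)` with the diagonal set to −1. Computing them
needs one steady-state solve per condition and the Jacobian — no simulated
perturbation. Degenerate states (a zero concentration or zero Jacobian
diagonal) are rejected rather than regularised.

*Distance.* The fit error sums, over stimulation conditions, Euclidean
distances on the off-diagonal LRCs and on the ligand ratios, each scaled by
the observed-side norm (`n_r = ‖offdiag r‖`, `n_ρ = ‖ρ‖`). Diagonals are
excluded — they are −1 on both sides by construction. The augmented variant
adds time-course blocks (normalised by the observed curve norm) and
pseudo-steady-state blocks (the plain norm of the model's rate vector at
the stated peak times, weight 1; the observed side is zero by definition).

## Steady states

`find_steady_state` integrates from the starved state for a burn-in horizon
and then polishes the endpoint with a damped Newton solve, doubling the
horizon (500 → 64 000 min by default) if the polished root fails the
residual (1e-9) or box test. Integrating first keeps the search on the
attractor actually reached from the initial state and away from unstable
fixed points such as the origin under stimulation. Stability is declared
when all Jacobian eigenvalues have negative real part.

The ABC evaluator uses a compiled (numba) specialisation of the same
procedure for the EGF cascade: adaptive implicit Euler (L-stable, safe on
stiff random parameter draws; step budget 4000 so pathological draws fail
fast) followed by damped Newton, stability via the Routh–Hurwitz conditions
on the characteristic cubic. The test suite asserts agreement between the
compiled and generic routes on the published parameters and on random prior
draws (relative difference ≤ 1e-5 where both converge). A burn-in cap of
4800 min applies inside the sampler: parameter draws with slower relaxation
are treated as failed evaluations (infinite distance) and rejected — the
position taken for any draw without a computable stable steady state.

## The sampler

Adaptive-weight ABC-SMC over log-normal priors. The stated prior mean `m`
is interpreted as the natural-scale median (`log θ ~ N(log m, s²)`,
default `m = 2.3`, `s = 2`); a `log_scale_location` switch honours the
alternative reading `log θ ~ N(m, s²)`. Proposals act in log space, which
preserves positivity.

Design choices where the published description is silent or under-specified
(each validated on the simulation study during development):

* **Stage 1** is classic quantile-threshold rejection sampling: a fixed
  pool of prior draws (300 000 in the scaled study protocol) is evaluated
  and the best `N` kept; the first threshold is the worst kept distance.
  This buys a far lower starting threshold for a known evaluation budget
  than accept-first-N at an arbitrary ε₁.
* **Threshold schedule**: ε_t is the α-quantile (default 0.5) of the
  previous stage's accepted distances; the run stops at the stage cap, on
  an acceptance stall, or when accepted distances degenerate.
* **Resampling** follows the adaptive-weight idea — ancestors are drawn
  with probability ∝ weight × Gaussian closeness kernel of their distance.
  The kernel bandwidth is ε_t/30: sharp enough that ancestors already
  satisfying the next threshold dominate. With a bandwidth of order
  ε_{t−1} the kernel is nearly flat over the accepted population and the
  sampler stalls on this 16-parameter posterior.
* **Proposal kernels** are per-ancestor Gaussians: covariance of the 40
  nearest next-threshold survivors around the ancestor (a local variant of
  the optimal-covariance kernel) and a drift of 0.5 toward their mean, so
  moves follow the locally surviving ridge. A scalar step-size multiplier
  follows a 1/5-success-style rule per batch (grow ×1.4 above 25%
  acceptance, shrink ×0.75 below 8%).
* **Importance weights** use the exact mixture: particle weight =
  prior density / Σ_j p_j q(θ|θ_j) where p_j are the *actual* selection
  probabilities (weight × closeness kernel) and q the per-ancestor
  proposal density at the recorded step scale. Normalising by the previous
  weights alone — omitting the closeness-kernel factor from the mixture —
  produces a posterior-mean bias several Monte-Carlo standard errors wide
  on a conjugate Gaussian toy; the exact form passes the 3-SE check.
* Evaluation failures score infinite distance and are rejected. Batch
  evaluation is deterministic given the seed; per-stage randomness derives
  from (seed, stage), so a run resumed from a persisted stage reproduces
  the original exactly.

Posterior summaries (`predict_features`) default to importance-weighted
means with standard errors `sd/√ESS`; the fit-error experiment
(`ssq_experiment`) averages the final population plainly — the
ensemble-of-models reading in which every sampled parameter set counts once
— which is markedly more stable when the effective sample size degenerates,
as it routinely does for broad priors in sixteen dimensions.

## The synthetic experiment generator

Emulates the in-silico protocol end to end: starved initial state (all
active forms zero); EGF doses 0.1, 1, 2, 5 ng/ml; relaxation to steady
state; siRNA knockdowns modelled as a fractional reduction of one total
pool (default fraction 0.5, a typical siRNA efficiency); reporter
amplification by a constant gain `k_f = 100`; six replicates with additive
Gaussian noise (σ ∈ {0, 2, 5, 10, 15, 20}) on the amplified scale, floored
at 1e-6·k_f so ratio-based quantities stay defined. The default grid is
4 doses × (control + 3 knockdowns) × 3 species × 6 replicates = 288 records
per noise level.

What it does **not** emulate: biological replicate variability beyond
i.i.d. Gaussian noise, batch effects, off-target knockdown activity,
partial-efficiency heterogeneity across replicates, reporter saturation, or
stochastic (low-copy) kinetics. Passing tests therefore certify the
estimator pipeline under the stated noise model, not robustness to real
antibody-array artefacts.

Because `k_f` and the knockdown fraction are not published, two
consequences of the defaults are worth stating plainly. First, 50%
knockdowns leave a visible finite-perturbation bias in the estimated LRCs
(the fit error of the true parameters against noise-free data is 0.06, not
0). Second, with `k_f = 100` a noise sd of 10 is ~25% of the smallest
signals, and the feature-estimation noise at σ = 10 alone dwarfs the
published high-noise fit-error band — the corresponding acceptance check
fails for any sampler, including one handed the true parameters. No single
amplification reconciles the published low-noise and high-noise bands under
this noise model; the defaults are kept as stated rather than calibrated to
the bands.

## Protocol sizes

The scaled study protocol used by the tests and the fit helper: 200
particles per stage, α = 0.5, at most ten stages, a 300 000-draw initial
pool, and a 120 000-evaluation cap per stage. Under this budget the
threshold contracts by ~0.85 per stage from a starting value near 1.9 (the
α-quantile of a population filling a ~9-dimensional constrained feature
shell cannot contract faster), which bounds the reachable fit error at
σ = 0 to roughly 0.5–3 — above the published low-noise band, which was
obtained at 1000 particles with an unpublished (plausibly much longer)
threshold schedule. The corresponding checks are encoded at their published
values and report honestly.

## Bimodality analysis

Every sampled parameter set is read as one cell; the ensemble of readouts
is a cell population, with no extra noise injected. A Gaussian KDE
(Silverman bandwidth) of the pooled readouts is fitted by least squares
with one- and two-component Gaussian mixtures; the component count with the
smaller fitting error is selected, and the reported mode count is the
number of local maxima of the selected mixture density — two heavily
overlapping components therefore still count as one mode (the two-component
fit is never worse in raw error, being the richer family). Dose–response
display fits a four-parameter logistic by least squares; ensemble bands use
the 16.5/83.5 percentiles (a 67% interval).
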