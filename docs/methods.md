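# Methods

`stabflex` implements a two-module attractor model of cognitive
stability and flexibility, its Bayesian fit to trial-level behavior,
and the downstream stability analyses (potential landscapes, minimal
transition actions, BOLD regressors).  This note records the model,
the numerical choices, and the points where the published description
of the underlying circuit left genuine design freedom.

## The rule module

The working-memory module maintaining the active task rule is a
mean-field reduction of a spiking network with two rule-selective
excitatory pools, a nonselective excitatory pool, and shared
inhibitory interneurons.  Its state is the pair of NMDA gating
variables (S1, S2); rates follow instantaneously through an effective
transfer function

    r_i = H(x_i, x_j) = (a x_i - f_A(x_j) - b) / (1 - exp(-d (a x_i - f_A(x_j) - b)))

whose gain a, threshold b and curvature d carry corrections for fast
recurrent AMPA coupling (a = 239400 J_A,11 + 270, b = 97000 J_A,11 +
108, d = -30 J_A,11 + 0.154), and whose cross term f_A = J_A,12
(-276 x_j + 106) θ(x_j - 0.4) switches on only above an effective
current of 0.4 (we fix θ(0) = 0).  Gating integrates as

    dS_i/dt = -S_i/τ_NMDA + (1 - S_i) γ r_i / 1000      (t in ms, r in Hz)

with γ = 0.641, τ_NMDA = 100 ms, and effective currents
x_1 = J_N,11 S1 - J_N,12 S2 + I0 + I1 (mirrored for x_2).

### Effective couplings and the adopted reading

The couplings follow from the biophysical constants (conductances,
mean voltages, f-I gains, coding level f = 0.15, potentiated weight
w+ = 1.68, derived depressed weight w- = 0.88).  Each coupling is a
difference of a direct excitatory term and a disynaptic inhibition
loop: selective activity drives the interneurons, whose linearized
rate response (gain c_I/g_I2) converts through the GABA conductance
into inhibition of the excitatory cells.  Two elements of this map
required reconstruction because the circulating description of the
reduction is typographically corrupted:

1. **Interneuron self-inhibition.**  The inhibition-loop gain is
   attenuated by the interneurons' own GABAergic feedback,
   η = 1 / (1 + (c_I/g_I2) · g_GABA,I · (⟨V_I⟩ - V_I,rev) · C_I ·
   τ_GABA/1000) ≈ 0.0714.  This is the only reading that uses the
   otherwise-unreferenced g_GABA,I constant, and without it the
   inhibition loop is ~8× stronger than recurrent excitation and no
   attractor structure exists for any baseline current.

2. **The baseline current offset.**  The constant part of I0
   contributed by the interneurons is read as
   g_GABA,E (⟨V_E⟩ - V_I,rev)(τ_GABA/1000) C_I (η I_I/g_I2 - ψ_ns r0),
   with ψ_ns the nonselective-pool gating value (0.1136).  The
   criterion for this reading was the circuit's documented behavior:
   it yields I0 = 0.3537, dead-center of the narrow window
   (≈ [0.352, 0.356]) in which the module is tristable with a
   spontaneous rate near 3 Hz.  The neighbouring reading
   η (I_I/g_I2 - r0) gives I0 = 0.375, which destabilizes the
   spontaneous state and leaves a single symmetric high-activity
   attractor; it was therefore rejected.

With the adopted reading and standard scaling (s_NMDA = s_GABA = 1)
the module has exactly three stable states: a symmetric spontaneous
state at 2.77 Hz and two rule states at (0.594, 0.054) / (0.054,
0.594) firing at ≈ 23 Hz, separated by two saddles.  The
subject-specific parameters s_NMDA and s_GABA scale only the NMDA and
GABA conductances onto excitatory cells.

### Noise convention

Fluctuations enter the gating equations as an Ornstein-Uhlenbeck
process with correlation time τ_AMPA = 2 ms.  The circulating
formulas state both a stationary OU variance σ_rule²/2 and a
Fokker-Planck diffusion coefficient D = (σ_rule/2)²; these are
mutually inconsistent (the diffusion of an OU-forced slow variable is
its stationary variance times its correlation time, and no time-unit
convention reconciles the two while preserving a structured
landscape).  The package resolves this by making the **diffusion
coefficient authoritative**:

    D = (σ_rule / 2)²  per second.

The simulation OU keeps τ_AMPA = 2 ms and its amplitude is set so its
white-noise-limit diffusion equals D; the landscape and action
modules use D directly.  Consequence: trial simulations, the
steady-state density, the Boltzmann potential and the minimal action
all describe the *same* stochastic process, which the test suite
verifies by comparing the Fokker-Planck steady state against a
long-trajectory occupancy histogram.  The stationary variance of the
implemented OU is D/τ_AMPA, not σ_rule²/2.

Inside the batched fitting kernels, the OU forcing is replaced by
Gaussian increments applied every ~2-4 ms with exactly the same
diffusion coefficient.  The gating variables relax on 100 ms, so they
only see the noise spectrum below ~10 Hz, where the two constructions
agree; the reference trajectory APIs (`simulate_rule`,
`simulate_decision`) keep the exact-discretization OU.

## The decision module

The four-choice decision circuit (four stimulus-selective pools, one
shared inhibitory pool) is expanded at the bifurcation where the
spontaneous state loses stability.  The winner-take-all instability
has a three-dimensional null space with coordinates (X, Y, Z), in
which the four single-pool activity directions form a symmetric
tetrahedron; the amplitude equations are

    τ dX/dt = α/2 (δI1 - δI2) + β X Z + n_X
    τ dY/dt = α/2 (δI3 - δI4) - β Y Z + n_Y
    τ dZ/dt = α/4 (δI1 + δI2 - δI3 - δI4) + β/4 (X² - Y²) + n_Z

with τ = τ_NMDA = 100 ms, α fixed at 1 (any scale is absorbed by the
fitted inputs), β the fitted nonlinearity, and OU noise n with
stationary variance σ_decision²/2.  Projections back onto the four
population directions (p1 = X/2 + Z/2, p2 = -X/2 + Z/2,
p3 = Y/2 - Z/2, p4 = -Y/2 - Z/2; they sum to zero) are compared with
a threshold of 10; the first crossing fixes choice and reaction time.
The quadratic terms make trajectories diverge in finite time, so RTs
are insensitive to the exact bound (checked: moving the bound 10×
changes noise-free RTs by < 10%).  If two projections cross within a
step, the larger one wins; no crossing by trial end is a non-response.
There is no separate non-decision-time parameter.

Inputs act only during the 900 ms stimulus window (δI_i = 0
afterwards, including the feed-forward rule input — the literal
reading of the trial protocol; the alternative of letting c+·r feed
continue until trial end was not adopted).

## Trial protocol and the synthetic-data generator

A session is 300 two-second trials: 240 baseline, 20 distractor, 20
switch, 20 ambiguous, pseudorandomized so that each critical trial is
preceded by 3-6 baseline trials (gap lengths are a uniformly sampled
composition of 240 into 60 parts from {3..6}).  Digits are drawn from
{1..9}\{5}; brightness cues follow the published intervals (bright
digit gray value uniform on [169, 195], partner at 255 minus that,
ambiguous lower digit on [117, 137]).  Ambiguous trials appear in
logs but are never simulated or fitted.

Each simulated trial starts the rule module at the rule-1 attractor
(noise-free settle from (0.8, 0.1)) and the decision module at the
origin.  Rule-module inputs per condition: baseline (I1_base, 0);
distractor (I1_base + Ī_dist ± ΔI_dist/2); switch (I1_base + Ī_switch
∓ ΔI_switch/2, brighter-below cue favoring rule 2).  Decision-pool
drives: D11 to the correct-parity pool always; D12 to the
correct-magnitude pool when a lower digit is shown; wrong-feature
drives fixed at zero; plus c+·r1 to the parity pools and c+·r2 to the
magnitude pools.

The **reference synthetic subject** (used throughout tests and
examples; chosen once) is s_NMDA = s_GABA = 1, I1_base = 0.03,
D11 = 0.09, D12 = 0.05, Ī_dist = 0.015, ΔI_dist = 0.02,
Ī_switch = 0.03, ΔI_switch = 0.02, c+ = 0.035, σ_rule = 0.12,
σ_decision = 0.35, β = 0.3.  It reproduces the qualitative pattern of
trained subjects: ≈96% baseline and distractor accuracy, ≈91% switch
accuracy with occasional non-responses, median RTs ordered baseline
(≈580 ms) < distractor (≈660 ms) < switch (≈1270 ms), right-skewed RT
distributions, and per-trial rule-module energy rising baseline →
distractor → switch.  What the generator does *not* emulate: lapses,
non-decision (motor) time, sequential/learning effects, and the
ambiguous condition — conclusions from synthetic-data tests therefore
concern the model machinery, not those aspects of real behavior.

## Likelihood, priors and sampling

A subject is summarized per condition by the 4-category decision
counts of responded trials and the RT sample per (condition,
decision) cell.  The likelihood of subject data given parameters is
the product of the multinomial probability of the observed counts
under simulated decision rates (1024 simulated trials per condition
at study scale; rates floored at 1/(2 n_sim) and renormalized so an
observed-but-unsimulated decision is not impossible) and, per cell
with at least 3 RTs on both sides, the two-sample
Kolmogorov-Smirnov probability

    D = sup|F1 - F2| √(nm/(n+m)),    p = 1 - (√(2π)/D) Σ exp(-(2k-1)²π²/(8D²)),

the survival function of the Kolmogorov statistic (the series above
is its CDF; an alternating-series form is used for large D; both are
cross-checked against an independent implementation).  Gaussian
shrinkage priors (mean 1 for the conductance scalings, 0 otherwise;
std 0.07) complete the posterior.  Non-responses are excluded from
the multinomial, which therefore conditions on responding.

Sampling uses random-walk Metropolis-Hastings with an isotropic
Gaussian proposal, σ_MH = 0.01, on all 13 parameters.  The likelihood
is stochastic; by default each proposal is evaluated with fresh
simulation noise while the current state keeps its stored estimate
(pseudo-marginal scheme).  A common-random-numbers mode evaluates
every proposal with one fixed simulation seed per chain, trading a
small surface bias for much faster mixing at reduced simulation
budgets.  Negative σ proposals are canonicalized by absolute value
(only σ² enters the dynamics), so σ parameters are identified up to
sign and their marginals may be folded.

MAP estimates are per-marginal argmaxes of Gaussian-kernel density
estimates (Silverman bandwidth, 512-point grid spanning the sampled
range ±10%) of the pooled post-burn-in chains, with the full width at
half maximum read off the same curves.  This is a marginal — not
joint — mode, a deliberate simplification.

Study scale is 2 chains × 1,000,000 steps with 50,000 burn-in and
1024 simulated trials per condition (the `paper` preset).  The `desk`
preset uses 2 × 20,000 steps, 256 trials, and a 2 ms integration step
in the fitting kernels.  The test suite runs a further-reduced
recovery (2 × 5,000 steps, 128 trials, common random numbers, a
near-prior truth with strong stimulus drives) and verifies the
decision parameters D11, c+ and σ_decision to within two prior
standard deviations; at this budget the posterior is still
contracting, so this is a floor on, not a measure of, the information
in the data.

## Potential landscape

The input-free stochastic gating dynamics define a Fokker-Planck
equation ∂P/∂t = -∇·(F P) + D ΔP on [0,1]².  Its steady state P_ss
yields the generalized (Boltzmann) potential U = -ln P_ss; the
dynamics violate detailed balance, so a divergence-free rotational
flux coexists with -D∇U, but only U is computed.  Numerics:

* conservative flux form with exponentially fitted
  (Scharfetter-Gummel) face weights B(w) = w/(e^w - 1), w = u h/D.
  At the model's parameters the grid Peclet number reaches several
  hundred, where a centered advection stencil produces spurious
  oscillations and negative densities; the fitted scheme reduces to
  the centered one for |w| ≪ 1 (verified) and preserves positivity.
* implicit (backward Euler) time stepping, LU-factorized once; the
  scheme is unconditionally stable, so the step (default 1 s) is
  chosen for convergence speed.  Iteration starts from the uniform
  density, renormalizes every step, and stops when
  max|ΔP|/(Δt · max P) < 1e-12.
* default grid 128×128 (the inter-basin barrier changes by < 5%
  between 64 and 128).
* boundaries: absorbing (P = 0) by default.  A reflecting (zero-flux)
  option matches trajectory simulations, whose gating variables are
  clamped to [0,1]; the landscape-vs-simulation equivalence test uses
  it because at mixing-level noise the rule basins press against the
  boundary.  At landscape-regime noise (σ_rule ≈ 0.1) the two choices
  are indistinguishable away from the edges.
* U is computed with a density floor of 1e-300 and shifted so its
  minimum is 0.

The equivalence test runs at σ_rule = 0.3.  The choice is an
ergodicity requirement fixed before measuring: the occupancy
comparison needs many inter-basin transitions within the simulated
5×10⁵ ms, which requires barriers of order unity; at σ_rule = 0.1 the
barrier is ≈ 23 (in units of ln P) and no finite simulation mixes.
At σ_rule = 0.1 the density peaks are instead verified to co-locate
with the three deterministic fixed points.

## Minimal action

Transition probabilities between attractors are dominated by the
minimal-action path.  In the Hamilton-Jacobi form the action of a
path is

    S = ∫ [ √((E_eff + V)/D) - F_l/(2D) ] dl,
    V = |F|²/(4D) + (∇·F)/2,   F_l = F·dl/|dl|,

with E_eff = -min V over the landscape grid (the longest-kinetic-time
choice; kinetic time t = ∫ dl / (2√(D(E_eff + V)))).  The printed
rendition of these expressions is corrupted; the adopted reading is
the standard one of the weak-noise path-integral framework, and the
package treats it as fixed.  Discretization: 51 nodes (50 line
elements), midpoint quadrature, endpoints at the rule minima of the
landscape potential (falling back to the noise-free fixed points when
a basin drops below floating-point density resolution), L-BFGS over
the interior nodes from two starts (straight line; polyline through
the spontaneous minimum), a penalty of 1e5 × Var(Δl) regularizing the
parameterization (excluded from the reported action), and clipping of
the rare negative (E_eff + V) values from discretization noise.
Doubling the penalty or quadrupling the element count changes the
reported action by < 1%.

At standard parameters the two directions are symmetric (equal
actions, mirror-image paths through the spontaneous basin), the
action decreases monotonically in σ_rule and increases in s_NMDA —
noise erodes, recurrent excitation deepens, the rule attractors.

## BOLD regressor

Per-trial metabolic load is proxied by ∫(r1 + r2) dt over the full
2000 ms trial.  1024 trials per condition at the fitted parameters
give a mean energy per (condition, decision) cell, normalized to the
mean over correct baseline trials (cells never reached fall back to
their condition mean; if a degenerate parameter set yields no correct
baseline trials the baseline-trial mean anchors the normalization).
Each logged non-ambiguous trial places its cell value as an impulse
at its onset on a 0.1 s grid; the series is z-scored and convolved
with a canonical double-gamma HRF (peak delay 6 s, undershoot delay
16 s, unit dispersions, peak:undershoot 6:1, 32 s support, unit-sum
normalized), then read out on the 2 s scanner grid.  A session whose
trials all carry the same energy has no contrast and maps to the zero
regressor by convention.  Ambiguous trials contribute nothing (they
are nuisance-modeled downstream, outside this package's scope).

## Degenerate inputs and edge conventions

* σ parameters: canonicalized by absolute value everywhere.
* gating variables: clamped to [0,1] after every step.
* transfer-function singularity at zero numerator: limit value 1/d.
* exact multinomial test with N = 0: p = 1; observations in
  zero-probability categories: p = 0; probability ties use a relative
  tolerance of 1e-12.
* empty RT cells: skipped in the likelihood (minimum 3 per side).
* fitted parameter sets without two rule attractors: the pipeline
  records the action as degenerate instead of failing.

## Problem sizes in the test suite

The suite verifies every component at sizes that run on a single CPU:
sessions of 300 trials, 10,000-trial choice-probability checks,
2×10⁶-step occupancy simulations on 64² landscape grids, five-point
noise sweeps of the minimal action, 20-subject goodness-of-fit
calibration at 512 simulated trials per condition, and the reduced
recovery budget stated above.  The `paper` preset reproduces the
study-scale settings (10⁶-step chains, 1024-trial likelihoods,
128² grids, 50 line elements) for users with the compute to run them.

## Known limitations

* The exact-test enumeration is O(N³) in the per-condition trial
  count; it is instantaneous at N = 240 but not meant for N ≫ 10³.
* The KS probability is the asymptotic (Brownian-bridge) formula also
  used in the original analysis; for cells with < ~10 RTs it is
  approximate in the direction of conservatism.
* MAP-from-marginals ignores posterior correlations; at reduced
  sampling budgets the shrinkage priors dominate weakly identified
  parameters (the rule-input asymmetries Ī_dist/Ī_switch are the
  least identified, as their effects trade against ΔI and c+).
* The landscape's rotational flux component is not computed; U alone
  does not determine transition rates, which is why the minimal
  action is computed from the path functional rather than from U.
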