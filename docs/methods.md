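# Methods

## Model

Each region of a parcellation is reduced to an excitatory and an
inhibitory neural mass with synaptic gating variables `S_E`, `S_I`
(NMDA/GABA kinetics). Regions interact only through their excitatory
populations, via a symmetric nonnegative structural connectivity matrix
`C` scaled by a global coupling `G`. Input currents, transfer curves and
gating dynamics are the standard reduced Wong–Wang equations (see
`dmfsim.model`); parameters default to the canonical set (`dmfsim.params`,
all values in s/Hz/nA, with the ms-quoted time constants converted at
construction).

**Units and the noise term.** Drift terms use strict SI-style seconds.
The noise amplitude σ = 0.01 nA is quoted *per square-root millisecond*,
the convention of the reference neural-mass implementations, which
integrate in ms; the Euler–Maruyama update therefore adds
`σ·sqrt(dt/1 ms)·ξ` per step. This choice is load-bearing: with it, an
uncoupled region fluctuates around a mean excitatory rate of ≈3.45 Hz and
mean gating ≈0.18 (matching the field's reference values of 3.4 Hz and
0.179), and the gating–rate covariance sits just below 0.1. The strict
per-√s reading would leave the system at its deterministic fixed point
(3.14 Hz) and make all three benchmarks unreachable.

**Transfer curve.** `F(I) = g(I−Ithr)/(1−exp(−d·g(I−Ithr)))` has a
removable singularity at threshold; inside `|g(I−Ithr)| < 1e−6` a
first-order series `(1 + d·x/2)/d` is used, keeping the curve C¹ across
the threshold.

**Integration.** Euler–Maruyama at `dt = 0.1 ms` (configurable); gating
clamped to [0, 1] after every step. Initial state `S_E = S_I = 0.001`
deterministically; randomness enters only through two independent,
sequentially consumed noise streams (one per population, spawned from one
seed), so the trajectory is bit-reproducible and independent of the
streaming block partition. The Balloon–Windkessel (BK) consumer runs at
`dt = 1 ms` on the mean rate of each 1-ms window; BOLD is read out every
TR = 2 s and the first 10 s are discarded.

**Producer/consumer memory contract.** Rates are produced into a reused
buffer of at most `buffer_capacity` (default 10,000) steps; the BK
consumer drains each block before the next is produced. Peak live
fast-signal memory is `2·buffer_capacity·N` samples (rates + gating
trace) regardless of duration.

**Hemodynamics.** The vasodilatory signal follows
`ds/dt = 0.5·r + 3 − κs − γ(f−1)`, `df/dt = s`, with the standard
volume/deoxyhemoglobin pair `τ·dv/dt = f − v^{1/α}`,
`τ·dq/dt = f·(1−(1−ρ)^{1/f})/ρ − q·v^{1/α−1}` and readout
`B = V0·(k1(1−q) + k2(1−q/v) + k3(1−v))`. Constants: κ=0.65 s⁻¹,
γ=0.41 s⁻¹, τ=0.98 s, α=0.32, ρ=0.34, V0=0.02, k1=2.77264, k2=0.572,
k3=−0.43 (the standard hemodynamic set; all overridable).

**Divergence.** Gating clamping keeps states finite, so "divergence" is
defined physiologically: any per-block mean excitatory rate above
`max_rate` (default 20 Hz) aborts with a `DivergenceError` naming the
step and region. 20 Hz separates the low-activity branch the model is
meant to describe (feedback-controlled rates stay below ~4 Hz) from the
hyperexcited branch (tens of Hz) that feedback inhibition exists to
prevent. Without this boundary the FCD fitting objective develops a
spurious valley inside the hyperexcited regime, where pooled FCD
distributions can mimic physiological ones while firing rates are far out
of range. Code that deliberately measures the uncontrolled regime (the
iterative FIC calibrator's probes) overrides the ceiling to 200 Hz.

## Feedback inhibition control

The closed-form route solves the uncoupled stationary system at the
reference rate 3.4 Hz: `E[S_E] = γτr/(1+γτr) = 0.1789`; `E[I_E]` from
inverting `F_E` (bracketed Brent to 1e−14); `E[S_I]` as the scalar fixed
point of `S = τ_GABA·F_I(W_I·I0 + J_NMDA·E[S_E] − S)`. This gives
`α = J_NMDA·E[S_E]/E[S_I] = 0.665` and
`c = (W_E·I0 + w₊·J_NMDA·E[S_E] − E[I_E])/E[S_I] = 0.968`, i.e. (0.67,
0.97) at two decimals; `c = 1` is used in the rule `J = αGβ + 1`. The
derivation neglects the gating–rate covariance (measured ≈0.097 on long
single-region trajectories, below the 0.1 validity bound) and evaluates
`E[F(I)] ≈ F(E[I])`; both hold at and near G = 0 and degrade as G grows.

Node strength β is the plain row sum by default; halving (compensating
double-counted symmetric edges) is an explicit flag and is used nowhere
internally, so regressed α values are directly comparable to the analytic
one.

The iterative calibrator runs 20-s probe simulations (2 s discarded) and
updates `J ← max(J + 0.05·(r̄ − 3.4), 0)` until all regions are within
0.2 Hz of target; because one probe estimates r̄ with a standard error
close to that tolerance, convergence is declared on the mean of the last
three probes. Divergent probes inflate J by ×1.5 + 0.1 and continue.
Non-convergence is reported, never raised. `fit_alpha` pools one point
per region per G and regresses `J − 1` on `G·β` through the origin
(optionally up-weighting G > 2.1 by ×10).

## Observables and fitting

BOLD (simulated and "empirical" alike) is band-passed at 0.01–0.1 Hz with
a zero-phase order-2 Butterworth (edge padding 3·(order+1) samples). FCD
uses 30-sample windows advancing by 2 (28 overlap); window FCs are
vectorized by their strict upper triangles and correlated pairwise. The
fitting objective is the raw two-sample Kolmogorov–Smirnov statistic
between pooled upper-triangle FCD samples (a binned variant exists behind
a flag); divergent simulations score the worst case 1.0 so optimization
continues.

Bayesian optimization uses a Matérn-5/2 GP with a fitted white-noise term
(scikit-learn backend) on inputs normalized to the unit box
(G ∈ [0, 3] × α ∈ [0.6, 0.9] by default), a scrambled-Sobol initial
design, and expected improvement maximized over 4,096 random candidates
plus an L-BFGS-B polish. Each evaluation is one fresh-seeded simulation
(the objective is stochastic). The reported optimum is the minimizer of
the final GP posterior mean — the estimated minimum, which averages
objective noise — with the best raw evaluation kept alongside.

Because FCD correlations carry no information about the absolute firing-
rate level, the K-S surface is degenerate along a constant-effective-gain
diagonal: over-inhibited strong-coupling states (rates ~2–3 Hz) can match
a physiological cohort's pooled FCD almost perfectly. The joint fit's
premise is that the optimum also satisfies the firing-rate constraint, so
the recovery experiment reports the best *rate-admissible* working point:
diverse candidate minima of the GP posterior mean are verified by
simulation in ascending order and the first with all mean rates in
3–4 Hz is selected (the unconstrained minimizer is reported if none
qualifies, flagged by the failed rate check).

## Turbulence

Instantaneous phases come from the Hilbert transform of the filtered
signals; 5 samples are trimmed at each end (transform edge artifacts).
The local Kuramoto order parameter weights unit phasors with
`K = exp(−λ·r)` (λ = 0.18 mm⁻¹, self-term included), and the turbulence
level D is the standard deviation of its modulus pooled over regions and
time. The grid scan (`turbulence_grid`) reuses the *same* seeds in every
(G, α) cell — common random numbers — so cell-to-cell comparisons cancel
the shared seed effect; divergent cells are recorded as missing.

## Synthetic data

The generators supply what tractography and fMRI would: connectomes
(distance-exponential with 40-mm decay, uniform-random, or two-block
modular; symmetric, connected, zero-diagonal, optionally rescaled to a
target mean strength), coordinates (sphere surface or box, mm), and
surrogate "empirical" cohorts simulated at a known working point so that
fitting has a ground truth.

The canonical test fixture is a 20-node modular connectome with mean
strength 0.5 and box coordinates of 30 mm side. Both numbers are
calibrated properties of the desk-scale setting, fixed once: a 20-node
network averages input fluctuations over far fewer neighbors than a
90-region connectome, so equal stability margins require weaker strengths
— at mean strength 0.5 the linear rule at α = 0.75 holds rates in 3–4 Hz
up to G ≈ 2 and loses control by G ≈ 2.5, reproducing the published
stability phenomenology; and a 30-mm box gives pairwise distances over
which the λ = 0.18 kernel is informative. The modular structure matters
for fitting: it produces switching, bimodal FCD whose distribution is
sensitive to the working point, whereas spatially homogeneous fixtures
collapse onto a single global synchrony mode that cannot identify α.

**What the surrogates do not emulate:** tractography biases, distance-
dependent interhemispheric structure, subject-to-subject anatomical
variability, scanner noise and physiological confounds in BOLD. Passing
tests demonstrate the internal consistency and recoverability of the
method at desk scale, not empirical validity on real cohorts.

## Experiment sizes and numerical choices

Problem sizes used by the test experiments, fixed once as the package's
desk-scale study conditions: single-region moment checks use a 1010-s
trajectory (the 100-s estimator of cov(S_E, r_E) and mean gating carries
~0.005 sampling noise, comparable to the margins being tested); the
FIC-linearity and stability-contrast experiments use the 20-node fixture
at G ∈ {0.5, 1, 1.5} with 110-s verification runs; parameter recovery
uses a 13-subject surrogate cohort of 500 s each at (G*, α*) = (1.6,
0.75) and a 40-evaluation optimization; turbulence self-recovery scans
the 5×4 grid (G ∈ [0, 2], α ∈ [0.65, 0.8]) at 500 s × 3 common seeds per
cell against a reference generated at (1.5, 0.8) from 3 independent
seeds, asserting recovery to within one grid step per coordinate — the
within-column α gradient of D (~0.002 per step) is comparable to seed
noise at these durations, so exact-cell α recovery is not statistically
resolvable at this scale.

Known limitations: the linear FIC rule inherits the first-order closure
and weakens near the bifurcation; pooled-FCD K-S is a one-dimensional
summary and identifies α only weakly away from the bifurcation; the
divergence ceiling is a modeling boundary, not a numerical necessity; BK
constants are not fit to any dataset here.
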