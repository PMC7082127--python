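# Methods

## The cost model

`syncache` treats synaptic plasticity as a metered resource. A learning run
produces a weight trajectory w(t); the model charges, in arbitrary units,

* **consolidation** — |Δl|^α for every change of a persistent weight
  (α ≥ 0, default 1: cost proportional to the change, potentiation and
  depression alike; a `potentiation_only` flag makes depression free);
* **maintenance** — c·|s| per time step for every unit of transient weight
  held (c ≥ 0, default 0);
* **transient change** — b·|Δs| per change of a transient weight
  (b ≥ 0, default 0; a change that is consolidated in the same step is
  exempt).

One time step Δt is one pattern presentation, whether or not an update
occurs. The *minimal energy* of a run is Σᵢ|wᵢ(T) − wᵢ(0)|, the cost of
moving each synapse straight to its final value; the *inefficiency* of an
algorithm is its actual energy divided by this bound. No attempt is made to
calibrate the units to joules or ATP: every reported quantity is a ratio or
is compared across conditions at fixed units.

## Perceptron track

The perceptron is the classic threshold unit y = Θ(w·x) trained with
Δw = η(d−y)x on P random ±1 patterns over N synapses plus an always-on
bias input whose weight is learned like any other. Targets are encoded
{0, 1} so that (d−y) ∈ {−1, 0, +1}. Training cycles through the patterns
(fixed order by default; per-epoch reshuffling available) until a full pass
makes no update. Conventions the classic description leaves open, fixed
here:

* Θ(0) → 0. Ties occur generically only at the all-zero start, which then
  updates on every d=1 pattern.
* Initial weights are all zero, so the minimal energy is simply Σ|wᵢ(T)|.
* η = 1 without loss of generality: the noise-free perceptron is
  scale-free and every reported quantity is a ratio.
* The default epoch cap is 20× the expected epoch count
  max(K, T)/P (see the scaling laws below), with a floor of 100. The
  expected number of epochs grows as √P·(2−P/N)⁻², so a cap based on the
  update count alone would cut off legitimately converging runs near
  capacity. Runs that exceed the cap are reported as non-converged, never
  raised as errors; they are expected near and above the critical load
  P = 2N.

Because inputs are ±1, every update moves every weight by exactly ±η, and
the α=1 path energy is (N+1)·K·η for K update events; the ledger uses this
closed form (the potentiation-only variant counts the positive changes,
which the ±1 inputs keep near half).

### Scaling laws

Below capacity the random-walk picture gives the closed forms

    K = 2P/(2 − P/N)²         (updates)
    T = P^{3/2}/(2 − P/N)²    (presentations)
    M_min ≈ √(2/π)·η·N·√K     (minimal energy)
    M/M_min = √(πP)/(2 − P/N) (inefficiency)

Simulations track K and T closely (within a few percent at moderate load).
The inefficiency formula sits ~20–30 % below simulation: the weight
variance after learning is smaller than the free random walk predicts
(correlations in the update sequence), and the deficit grows near
capacity. The formula is asymptotic in N, so the acceptance check of the
curve runs at N = 2000 where the finite-size part of the deviation is
small; at N ≤ 1000 and P/N = 1.8 it reaches ~40 %.

Near capacity the update count is strongly heavy-tailed: at P/N = 1.9,
N = 1000, individual pattern sets were observed needing up to ~90× the
expected number of updates (a finite-size shadow of the capacity
transition). The headline inefficiency is therefore estimated as the median
of per-seed ratios over runs that converge within 6× the expected number
of presentations, with the excluded count reported; a mean (bounded or
not) is dominated by those rare sets and is not a stable estimator of the
typical cost the ratio describes.

## Synaptic caching

Each weight is split as w = s + l. Updates land in the transient part s,
which decays as s → s·e^(−Δt/τ); when the accumulated transient plasticity
crosses the threshold θ it is transferred into l ("consolidated") and s is
reset. Trigger variants:

* `local` — a synapse crossing θ consolidates alone;
* `global-any` (default) — any synapse crossing θ consolidates the whole
  neuron, the analogue of synaptic tagging and capture;
* `global-sum` — the summed Σ|sᵢ| crossing θ consolidates the whole
  neuron. Its θ lives on the Σ|s| scale and is always re-optimized
  separately when variants are compared.

Per presentation the order of operations is: decay, predict with s + l,
update s on error (b-cost, waived for synapses consolidated this step),
trigger check, consolidation (α-cost on Δl), maintenance on the
end-of-step state. This ordering makes two limits exact, which the tests
assert to machine precision: θ ≤ η reproduces plain perceptron energy
update-for-update, and θ = ∞ with τ = ∞, c = b = 0 (one final
consolidation) costs exactly the minimal energy. The trigger uses ≥ so a
threshold exactly reached fires; decay can never cause a crossing, so the
trigger is only evaluated after updates. Maintenance is charged on the
end-of-step state, so a step that consolidates (resetting s) pays no
maintenance that step — consistent with treating consolidation as
instantaneous. At convergence all residual transient weight is
consolidated once. Without decay, consolidation conserves s + l exactly,
so the learning trajectory is identical to the plain perceptron — caching
changes the bookkeeping, not the dynamics; with decay the dynamics change,
non-convergence becomes possible (strong decay with a high threshold
forgets unconsolidated progress faster than it accumulates), and such runs
are excluded from energy averages with their count reported.

The closed-form optimal threshold θ̂² = η²·3K/(1+cT) (floored at η, below
which every update consolidates anyway) and the cached inefficiency
min(√(2π(1+cT)/3), √(πK/2)) both come from the *per-synapse* random-walk
argument, i.e. they describe local consolidation. The threshold scan
confirms them in local mode (empirical θ* within a few percent of θ̂, the
energy ratio within ~16 %). Under the cell-wide triggers the optimum
shifts upward by a factor ~2: a global event consolidates many synapses
still below threshold, making each event cheaper per synapse than the
local argument assumes. Related: with b ≥ 1 (changing a transient weight
costs as much as consolidating it) caching can no longer beat immediate
consolidation — exactly true in local mode, while a cell-wide trigger at
low θ can still undercut it by ~1 % through the same sub-threshold
transfer effect. All three variants, each at its own optimized threshold,
land within 25 % of one another for c ∈ {0, 0.001, 0.01}.

## Steady state of the transient weight

With update probability p per presentation (updates ±η), decay τ, and
reset at ±θ, the transient weight of a synapse is a discrete
Ornstein–Uhlenbeck process with two absorbing thresholds and re-insertion
at the origin. For small steps its density obeys the stationary
Fokker–Planck equation with σ_s² = pη², σ² = τσ_s²:

    0 = (1/τ)(sP)′ + (σ_s²/2)P″ + r·δ(s),   P(±θ) = 0

    P(s) = (1/Z)·e^(−s²/σ²)·[erfi(θ/σ) − erfi(|s|/σ)]

with Z = √π σ erf(a) erfi(a) − (2θ²/(√π σ))·₂F₂(1,1;3/2,2;−a²) at
a = θ/σ, mean ⟨|s|⟩ = [σ² erfi(a) − 2θσ/√π]/Z, and boundary flux
(consolidation rate) r = 2σ_s²/(√π σ Z). The maintenance and
consolidation powers are m_trans = cN⟨|s|⟩ and m_cons = Nθr. Limits used
as checks: a → 0 gives the triangular density (θ−|s|)/θ², ⟨|s|⟩ → θ/3 and
r → σ_s²/θ²; large a gives the decay-dominated truncated Gaussian with
⟨|s|⟩ → σ/√π and r → 0. The no-decay consolidation rate is written in
terms of the per-step variance σ_s², which is the dimensionally consistent
reading and reproduces m_cons = pNη²/θ.

Numerics: erfi from scipy; the ₂F₂ via mpmath (arbitrary precision), with
quadrature of the unnormalized density as a permanent cross-check. Z grows
like e^(a²), so for a ≳ 26 it exceeds the double range; the density, mean
and rate are therefore computed internally from Z/erfi(a) using
e^(−x²)erfi(x) = (2/√π)·dawsn(x), which is stable at any a, and
`normalization_Z` itself reports the overflow. Signs are fixed by
requiring a non-negative density and outward boundary flux.

### Monte-Carlo oracle

`simulate_reset_walk` checks the closed forms with an ensemble of
independent walkers: exact OU transition per unit step, absorbing
boundaries at ±θ with a Brownian-bridge correction for within-step
crossings (without it the effective threshold is displaced by
~0.58·σ_s, a visible bias), re-insertion at 0, burn-in of 12τ. Ensemble
independence gives honest standard errors (across walkers) and keeps the
Kolmogorov–Smirnov noise floor of the 10⁶ recorded samples near 0.005 at
τ = 200, where the time-discretization bias of the boundary treatment is
a fraction of the Monte-Carlo error. The no-decay triangular limit is
checked separately with the exact ±η lattice walk, whose stationary mean
is (1 − (η/θ)²)·θ/3.

### Power-curve comparison

The per-epoch power comparison feeds the measured per-epoch update rate
p(t) into the formulas (quasi-stationary approximation) and is run with
*local* consolidation, the variant the theory describes; under the
cell-wide trigger both powers shift by tens of percent because whole-neuron
resets truncate every synapse at once. Agreement is scored on the
seed-averaged epoch curves — totals within 25 % per power and an epoch
profile correlation above 0.95 — measured agreement is ~4 % (maintenance)
and ~18 % (consolidation), the residual being the discrete-step (η = θ/5)
correction to the continuum theory. Runs that stall (with strong decay a
last misclassified pattern can bump the same synapses coherently, a regime
outside the independent-update assumption) are excluded as non-converged.

## Multilayer track

The backprop network is deliberately plain, matching the reference
architecture: one hidden layer (default 100 logistic units), 10 logistic
outputs with one-hot targets, mean-squared-error loss, pure online SGD,
no regularization, momentum or softmax. Weights (biases included) start
uniform in ±1/√fan-in. Energy is charged exactly as in the perceptron —
|Δw|^α per weight per update — and the minimal energy is Σ|w − w(0)|
tracked at each evaluation point, along with held-out accuracy. Caching
wraps every weight with an (s, l) pair and a single global-any trigger
across the whole network; the θ = ∞ limit again equals the minimal energy
exactly, and without decay the trajectory is cost-independent (accounting
never feeds back into learning). Divergence at large η (non-finite
weights) terminates a run and returns the partial curve. Bias weights are
included in all energy sums.

### Synthetic digits

The generator emulates a 10-class image classification task without
external data: one fixed random prototype per class in [0,1]^(side²)
(default side 8) plus i.i.d. Gaussian pixel noise (default sd 0.2),
clipped to [0,1], classes exactly balanced, prototypes seeded separately
from the noise so held-out sets share prototypes. What it reproduces from
the real handwritten-digit setting: a 10-way task learnable to high
accuracy by a small logistic MLP, with tunable difficulty. What it does
not: stroke structure, background sparsity, within-class style variation,
and scale (hundreds rather than tens of thousands of samples). Passing
tests on it therefore demonstrate the *energy accounting and its scaling
structure* — the several-fold gap to the minimal energy, the U-shaped
dependence on hidden-unit count, rate-invariance in the small-rate
regime — not digit-recognition performance.

One scale effect matters for interpretation: on the desk-scale task the
"large learning rate" regime, where energy starts to grow with η and the
rate-invariance argument breaks, begins around η ≈ 0.05 — far below where
it begins on the full-size task, which trains for many thousands of steps
per unit of accuracy. The invariance check accordingly compares
η ∈ {0.003, 0.01, 0.03}, a triple inside the small-rate window of this
task (measured agreement ~7 %; at η = 0.1 the cost is ~40 % higher — the
onset of the large-rate regime, not an accounting artifact). The full-size
MNIST pipeline (IDX readers, the same training loop) is present and takes
user-supplied files; nothing is downloaded.

Desk-scale problem sizes used by the test-suite: 10 classes × 100/50
train/test samples, hidden grid 2–80, target accuracy 0.9. The hidden-unit
sweep records the cumulative energy at the first crossing of the target;
undersized networks that never cross are flagged rather than extrapolated.

## Experiment drivers

`run_experiment` exposes the six study protocols (inefficiency curve,
threshold scan, decay sweep, trigger-variant comparison, multilayer curve,
power curves) as named configurations: flat YAML/JSON mappings validated
against a schema (unknown keys are errors), one CSV plus a JSON manifest
(parameters, seeds, version, wall time) per run, deterministic
byte-identical output for identical configs. The CLI (`syncache`) is a
thin layer over these drivers and the library; results go only to files,
logging to stderr.
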