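# Methods

## Models and assumptions

Both circuits are deterministic mass-action/Hill ODE models of transcription
and translation lumped into single production terms. Cooperative binding is
modelled by Hill functions; repressor sequestration by an input molecule is
algebraic (`r = S/(1+u)`), i.e. binding equilibrates instantly relative to
protein turnover. Stochasticity, promoter-level mechanism, and more than two
stimulus channels are out of scope. The Hebbian circuit's right-hand side is
written over a channel list, so N > 2 would work mechanically, but nothing
beyond N = 2 is tested or supported.

Hill coefficients are restricted to positive integers (1–4 is the studied
range); non-integer or non-positive values are rejected at parameter
construction, because the behaviour classifications studied here are defined
on that lattice and fractional cooperativity would silently change the
phenotype boundaries.

## Nondimensionalisation

For the Hebbian circuit, scaling each concentration by its downstream Hill
constant (`p̄ = p/K_p`, `ω̄ = ω/K_ω`, `r̄ = r/K_r`), time by the response
lifetime (`t̄ = δ_p t`) and inputs by the binding coefficient (`ū = k u`)
gives, by the chain rule,

    α = v_p / (K_p δ_p),  β = v_ω / (K_ω δ_p),  θ = δ_ω / δ_p,
    τ_j = ε_j / (K_ω δ_p),  S = R / K_r.

For the dissociation circuit the published reduction does not print its
scaling; we adopt the analogous convention `t̄ = δ_y t`, `x̄ = x/K_x`,
`z̄ = z/K_z`, `ū = u/K_u`, `v̄ = v/K_v`, and leave `y` unscaled because no
downstream Hill term reads it, so it has no natural concentration scale.
That yields `ᾱ_y• = α_y•/δ_y`, `ᾱ_ux = α_ux/(K_u δ_y)`,
`ᾱ_vx = α_vx/(K_v δ_y)`, `β_u = δ_u/δ_y`, `β_v = δ_v/δ_y`. Both reductions
are verified by simulating random dimensional parameter sets and comparing
the mapped trajectories against the dimensionless systems (RK4, dt = 1e-3,
sup-norm < 1e-6).

A numerical footnote: the equivalence test draws the time-scale factors
(δ_p, δ_y) from powers of two. With an incommensurate factor, the scaled
step grid lands a few ulp away from the scaled pulse edges, and one system
samples a rectangular edge one RK4 stage before the other — an O(dt)
artifact of discontinuous inputs, not a model discrepancy.

## Numerics

* Forward Euler with dt = 0.01 is the workhorse; classical RK4 at the same
  step is the accuracy benchmark. On both default conditioning scenarios the
  two agree to < 0.5% of the peak response, and Euler refinement from
  dt = 0.1 to 0.01 shrinks monotonically.
* Inputs are pre-sampled on the step grid (half-step grid for RK4, whose
  stages fall on t, t+dt/2, t+dt). Stage inputs see rectangular pulse edges,
  so accuracy at an edge is locally O(dt); away from edges RK4 is O(dt⁴).
  Pulse windows are half-open, `[start, start+duration)`; overlapping pulses
  on one channel take the maximum.
* States are never clamped. Undershoot beyond −1e−9 aborts the run with the
  failure time (clamping would mask an unstable step size); roundoff-scale
  undershoot is tolerated. Under the shipped parameters and protocols no
  state goes negative at dt = 0.01.
* The step count must divide the horizon exactly (to 1e-6·dt); refinement
  studies require each coarser step to be an integer multiple of the finest
  so that deviations are computed on a common grid.
* The entire pipeline is deterministic: no random numbers anywhere, repeated
  runs are byte-identical.

## Stimulus protocols: what is calibrated and why

The training schedules are the synthetic study conditions of this package.
No published timings or amplitudes exist for these circuits — the
experiments are defined only by their qualitative shape (which stimulus,
which order, paired or alone, "short" versus "widened" gaps). The factory
defaults below were therefore calibrated once, by simulation, so that the
circuits display their documented phenotypes with the table-default kinetic
parameters, and then frozen. They are choices, not measurements; every value
is overridable from the config file.

**Hebbian schedule** (10 events: US; CS; paired; CS; paired; 3 rapid CS
probes; 2 CS probes after widened gaps): onset 10, pulse duration 4,
inter-event interval 15, widened gaps 60 and 90, amplitude 100 on both
channels, relaxation tail 250 (≈ 5/θ, so the weights visibly relax).
Rationale: duration ≥ ~4 is needed for the response-to-weight feedback to
regenerate ω₂ during each CS probe — that self-sustaining regrowth is what
holds probes 6–8 at equal amplitude; interval 15 keeps the weight decay
(θ = 0.02) small between probes; gaps of 60/90 are long enough for visible
decay yet short enough that the response does not fall back to the naive
level (no forced dissociation, by design of this circuit). Amplitude 100
makes repressor release essentially total (r = S/101).

**Dissociation schedule** (8 events: US; CS; paired; CS; paired; CS; 2 rapid
CS probes): onset 26, duration 2.1, interval 21, probe interval 10,
amplitudes x = 3.2 and z = 5 (in units of the Hill constant), tail 250.
Rationale: the phenotype contrast across Hill coefficients lives in the
graded part of the binding curve, so the conditioned-channel amplitude sits
near the Hill constant rather than deep in saturation; onset 26 lets the
pre-stocked inhibitor (v₀ = 5) decay to the level where the unconditioned
response is visible but still inhibitor-limited; interval 21 balances
inhibitor pumping by the CS against its decay (β_v = 0.02) so that pairing
measurably depletes it.

**Initial states** (same status: calibration choices): Hebbian p = 0,
ω₁ = 5 (its basal fixed point τ/θ), ω₂ = 0.3 — a visible but small naive CS
response; set ω₂ = 0 to suppress it entirely. Dissociation circuit y = 0,
u = 0, v = 5 — the inhibitor must be stocked before each experiment,
otherwise the CS alone overexpresses the response.

The margins by which several phenotypes hold are a few percent — notably
the a = 3 versus a = 4 cut in the dissociation sweep and the moderator
sensitivity example. This mirrors the circuit's documented fragility (a 25%
parameter change flips its behaviour); the margins are stable under step
refinement (dt 0.02 → 0.005 moves them by < 0.5%).

## Peak extraction and classification

Each stimulation event owns the half-open window from its onset to the next
onset (the last extends to the horizon). The *peak* is the window's maximum
recorded response; the *baseline* is the response at the window's first
sample. Window-max is used instead of prominence-based peak finding because
windows are disjoint and the dynamics are pulse-driven, so the maximum is
unambiguous and deterministic.

Verdicts, with relative tolerance `tol` (default 0.05):

| verdict | definition |
|---|---|
| learning_formed | first post-conditioning CS peak > naive CS peak · (1+tol) |
| reinforced | second learned peak > first learned peak · (1+tol) |
| forced_dissociation | final CS peak ≤ naive CS peak · (1+tol) |
| baseline_return | response < baseline_eps at every window start after the first |
| conditioning_dominant | every paired peak > US peak · (1+tol) |
| desirable | conjunction of the four conditioning verdicts above |

Two deliberate definitional choices:

* **Dominance uses (1+tol).** "Paired response more significant than the
  unconditioned one" means exceeding it by more than the equality band. This
  also makes all strict verdicts uniformly monotone: enlarging the tolerance
  can only flip them toward "equal"/False (and the equality verdict,
  dissociation, toward True) — a property the test suite pins.
* **baseline_eps = 0.05.** The Hebbian circuit has an irreducible repressor
  leak (with both weights saturated, baseline p → 2α/(1+S²) ≈ 0.02), so
  "came back down to 0" is judged at 5% of the O(1) conditioned response.
  This cleanly separates the a = b = 1 failure (baseline ≈ 0.15) from the
  well-behaved coefficients (≈ 0.02), with better than two-fold margin on
  each side.

## Problem sizes

Default runs integrate horizons of ≈ 400 (dissociation schedule) and ≈ 519
(Hebbian schedule) dimensionless time units at dt = 0.01 (40k–52k steps,
about a second each). Sweeps are 4 such runs per coefficient grid; the
oracle and scaling checks use 100 random evaluation points per system and
two random dimensional parameter sets per family over a 10-unit horizon.
These sizes keep the full test suite under a minute while leaving every
comparison far above numerical noise.

## What the calibrated scenarios do and do not show

Passing phenotypes demonstrate that the *models* express the claimed
behaviours under at least one realistic stimulation regime — the question
the simulator is built to answer. They do not show robustness across
stimulation regimes (the schedules are fixed calibrations), nor anything
about molecular noise, resource loading, growth dilution or promoter-level
mechanism, none of which are modelled. The Hill-coefficient sweep
conclusions are specific to the shipped amplitudes: stimuli deep in
saturation wash out most of the coefficient contrast.

## Known limitations

* Rectangular pulses only; no smooth or stochastic stimuli.
* Fixed-step explicit integrators only; the models are non-stiff at the
  shipped parameters, but strongly rescaled dimensional variants may need a
  smaller step (the non-negativity guard will abort rather than mislead).
* The classifier requires labelled protocols (US/CS/paired); unlabeled
  custom protocols default to CS-only labelling unless labels are given.
* `Trajectory.from_tsv` cannot infer the state/input split without being
  told the number of state columns.
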