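# assoclearn

A deterministic simulator and phenotype classifier for Hill-equation
molecular circuits that implement **associative (Pavlovian-style) learning**
in synthetic gene regulatory networks.

It is written for synthetic/systems biologists and modellers who want to
test, before committing to wet-lab work, whether a proposed circuit design
can express the advanced conditioning behaviours beyond mere learning:

* **reinforcement** — the learned response grows with repeated conditioning;
* **forced dissociation** — rapidly re-cuing the conditioned stimulus alone,
  shortly after conditioning, actively pushes the learned response back to
  its naive level (an "unlearn" switch).

## The models

Two circuit families are implemented, each in dimensional and dimensionless
form (all regulation is Hill kinetics; `A(x) = x^a/(1+x^a)` is activation,
`R(x) = 1/(1+x^a)` repression, with the Hill constant scaled to 1).

**Hebbian weight circuit.** Response `p`, weight molecules `ω₁, ω₂`,
stimulus channels `u₁` (unconditioned) and `u₂` (conditioned); each input
sequesters a repressor, `r_j = S/(1+u_j)`:

```
dp/dt  = Σⱼ α · A(ωⱼ) · R(rⱼ)  −  p
dωⱼ/dt = β · A_b(p) · R(rⱼ)  −  θ·ωⱼ  +  τⱼ
```

The response feeds back onto the weights (a Hebbian update): pairing both
stimuli potentiates `ω₂`, so the conditioned stimulus alone later evokes the
response. The learned state decays only with time (`θ` small): this circuit
cannot be forcibly dissociated.

**Forced-dissociation circuit.** Response `y`, moderator `u`, inhibitor `v`,
conditioned input `x`, unconditioned input `z`:

```
dy/dt = α_yx·A(x)R(z)R(v) + α_yz·R(x)A(z)R(v) + α_xyz·A(x)A(z)R(v) − y
du/dt = α_ux·A(x) − β_u·u
dv/dt = α_vx·A(x)·R(u)·R(z) − β_v·v
```

`x` drives both the response and its own inhibitor `v`; during pairing, `z`
blocks inhibitor production while `u` accumulates and slows its recovery —
that is what makes the learned response grow with conditioning. Re-cuing `x`
alone restocks `v` and actively shuts the response down. An *adjusted*
variant gives `z` its own operator site (`dy/dt = α_yx·A(x)R(v) + α_yz·A(z)
− y`), trading biological simplicity for a more abundant response.

Default kinetic parameters are the published values for each circuit
(Hebbian: α=1, β=0.8, θ=0.02, τ₁=0.1, S=10, a=4, b=2; dissociation:
α_yx=2, α_yz=4, α_xyz=4, α_ux=0.6, α_vx=1.5, β_u=0.1, β_v=0.02, a=2;
adjusted: α_yx=4, α_yz=1, α_ux=0.6, α_vx=1, same β's).

## Worked example

```python
from assoclearn import simulate_and_classify

trajectory, spikes, report = simulate_and_classify("fd")
print(spikes.round(4).to_string(index=False))
print(report.desirable)
```

prints the per-event response peaks of the calibrated eight-event training
schedule (US alone; naive CS probe; two conditioning rounds, each followed
by a CS test; two rapid dissociation probes):

```
 event   label   peak  peak_time  baseline
     1 US_only 0.3613    28.1000    0.0000
     2 CS_only 0.1487    48.2100    0.0000
     3  paired 0.4060    70.1000    0.0000
     4 CS_only 0.1646    90.2700    0.0000
     5  paired 0.4689   112.1000    0.0000
     6 CS_only 0.1820   132.2300    0.0000
     7 CS_only 0.0966   142.8200    0.0001
     8 CS_only 0.0752   153.1000    0.0000
True
```

Reading the table: conditioning is dominant (paired peaks 0.406, 0.469 well
above the unconditioned 0.361); the learned response grows across rounds
(0.165 → 0.182, reinforcement); and the two rapid CS-alone probes drive it
back below the naive level 0.149 (0.097 → 0.075, forced dissociation), so
`report.desirable` — the conjunction of all four verdicts — is `True`.

The same interface runs the Hebbian circuit (`"fernando"`), the adjusted
variant (`"adjusted_fd"`), and the dimensional forms; `hill_sweep` and
`perturb_and_classify` drive coefficient sweeps and sensitivity studies.

From the shell:

```
assoclearn reproduce --scenario fd-conditioning --out out/
assoclearn simulate  --config run.yaml --out out/
assoclearn sweep     --config sweep.yaml --out out/
```

Scenario names: `fernando-conditioning`, `fd-conditioning`,
`fd-no-conditioning`, `adjusted-conditioning`, `fernando-sweep-a`,
`fernando-sweep-ab`, `fd-sweep-a`, `adjusted-sweep-a`, `fd-perturbed`
(short ids `fig3a` … `fig9` are accepted as aliases).

Stimulus timings and amplitudes are calibration choices, not measured
values; every one of them can be overridden from the config file.  See
`docs/methods.md` for the model details, the calibration rationale and the
classifier definitions.

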