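# glymphsim

Deterministic compartmental simulator of beta-amyloid (Aβ) turnover in a
1 mm³ volume of aging hippocampal CA1 tissue, for researchers studying how
glymphatic (perivascular) clearance and blood-brain-barrier transport shape
Alzheimer's-type amyloid accumulation.

## The model

Aβ40 and Aβ42 are generated by neurons into parenchymal interstitial fluid
(ISF), convected by bulk ISF flow into the perivascular space (PVS), and
removed there by LRP-1 receptor transport into blood (a sink), by continued
glymphatic flow toward the cervical lymph nodes, or by slow irreversible
deposition. Per species (shown for Aβ40; C₁ = parenchymal ISF pool, C₂ =
PVS pool, C₃/C₉ = vessel-wall and parenchymal deposits, all in molecules
per model volume, daily steps):

    dC₁/dt = k₃k₄N(t) − min(k₅M(t), C₁ available) − (v/L)C₁ − k₇ₐC₁
    dC₂/dt = (v/L)C₁ − k₆·(LRP(t)/LRP₀)·C₂ − k_exit·C₂ − k₇C₂
    dC₉/dt = k₇ₐC₁        dC₃/dt = k₇C₂

Cell pools (neurons N, microglia M, endothelial cells EC, LRP-1 receptors)
decay geometrically; parenchymal Aβ40 above a threshold triggers an
additional neuron-loss rate k₁. The bulk ISF velocity responds to
cardiovascular state, v = v₀ · (HR/60) · compliance(S(t)), where S(t) is an
exponential vessel-stiffening ramp. Two flow parameters are not directly
measurable and are calibrated by bisection against endpoint anchors: v₀
(against the 50-year normal-aging parenchymal Aβ40 deposit, constrained to
the literature velocity range 0.144–0.43 mm/day) and k_exit (against the
ApoE4-to-baseline vessel deposit ratio). Every simulation keeps an exact
cumulative-flux ledger, so mass conservation is checked on every run.

## Worked example

```python
import glymphsim as g

scenarios = g.builtin_scenarios()
baseline = g.run_simulation(scenarios["normal_aging"])   # 18,250 daily steps
brady = g.run_simulation(scenarios["bradycardia"])       # heart rate 50

print(f"parenchymal Ab40 deposit, baseline: {baseline.endpoint('C9'):.4g}")
print(f"parenchymal Ab40 deposit, HR 50:    {brady.endpoint('C9'):.4g}")
print(f"ratio: {brady.endpoint('C9') / baseline.endpoint('C9'):.3f}")
print(f"LRP-1 pool remaining: {baseline.endpoint('LRP')/9.3e11:.1%}")
```

prints

    parenchymal Ab40 deposit, baseline: 5.929e+09
    parenchymal Ab40 deposit, HR 50:    7.11e+09
    ratio: 1.199
    LRP-1 pool remaining: 60.5%

i.e. over 50 simulated years the healthy-aging arm deposits ~5.9×10⁹ Aβ40
molecules in the parenchyma of the model volume, slowing the heart from 60
to 50 beats/min raises that by ~20% (the weakened arterial pulsations slow
perivascular clearance), and the LRP-1 receptor pool ends at ~60% of its
initial size as endothelial cells senesce at 1%/yr.

The same is available from the shell:

    glymphsim run --scenario normal_aging --out results/
    glymphsim table3 --out results/          # all nine arms, normalized ratios
    glymphsim sensitivity --param k4 --values 1.5,2.0
    glymphsim calibrate

## Layout

- `glymphsim.params` — rate constants, geometry, unit conversions, TOML presets
- `glymphsim.physiology` — heart rate / stiffness / ApoE → ISF velocity
- `glymphsim.dynamics` — the daily update map with per-step fluxes
- `glymphsim.engine` — runs, mass-balance ledger, RK4 reference, calibration
- `glymphsim.scenarios` — the nine study arms, ratio report, sensitivity sweeps
- `glymphsim.config` / `glymphsim.cli` — TOML run configs and the `glymphsim` CLI

See `docs/methods.md` for modeling assumptions, parameter provenance and
known limitations.
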