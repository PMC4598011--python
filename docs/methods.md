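# Methods

## Scope and model structure

`glymphsim` simulates Aβ40 and Aβ42 turnover in a well-mixed 1 mm³ volume
of hippocampal CA1 tissue over 50 years of daily steps (18,250 steps,
representing ages 30–80). Three compartments are represented: the brain
parenchyma (neurons, microglia, dissolved Aβ in interstitial fluid), the
perivascular space (PVS) between astrocyte end-feet and the capillary
endothelium, and the blood, which is treated as a perfect sink — cardiac
output clears transported Aβ far faster than any other process here, so no
blood-side state is kept. Twelve state variables evolve: four cell pools
(neurons N, microglia M, endothelial cells EC, LRP-1 receptors) and eight
Aβ pools (dissolved parenchymal C1/C4, perivascular C2/C5, vessel-wall
deposits C3/C6, parenchymal deposits C9/C10), all as molecule counts per
model volume.

Spatial transport is deliberately absent. Capillaries sit ~40 μm apart, so
concentration gradients relax on a timescale that is negligible against
the daily step; each compartment is well-mixed and advection between
parenchyma and PVS reduces to a first-order transfer at rate v/L (bulk ISF
velocity over the 1 mm segment length). Diffusive transport, Aβ
oligomerization/fibrillization kinetics, enzymatic degradation (negligible
in vivo), sleep effects, aquaporin-4, tau pathology, and neuroinflammation
are out of scope.

## The update map

Cell pools decay geometrically. Rates quoted per year (neuron loss d = 1%,
stimulated neuron loss k1 = 3.4%, endothelial senescence k2 = 1%, LRP-1
loss k10 = k2) are converted to daily survival factors by geometric
compounding, 1 − (1 − r)^(1/365), so 365 daily steps reproduce the annual
fraction exactly — this is what makes 1%/yr neuron loss halve the pool in
69 years, and the LRP-1 pool end a 50-year run at 0.99⁵⁰ ≈ 60.5%.
Equations of the "dX/dt = (1 − k)X" family are read as discrete decay maps
X(t+1) = (1 − k_daily)X(t); a literal ODE reading would give exponential
*growth*. Microglial dystrophy (k12 = 7.3e-5/day) is already a daily rate.

Aβ pools advance by explicit forward differences. All fluxes within a step
are evaluated from the start-of-step state and applied simultaneously
(Jacobi update), which makes the cumulative-flux ledger close to machine
precision; the run aborts if it does not. Microglial uptake is a
zeroth-order demand (k5·M, k11·M molecules/day) clamped to the Aβ actually
available after the other outflows — the only clamp in the scheme, and the
new pool is computed as `available − uptake` so a fully clamped pool lands
on exactly zero. Whenever the largest first-order outflow fraction of a
dissolved pool would exceed 0.9 per step, the step subdivides
automatically, keeping the explicit update positive for any valid
parameter set (at default rates the largest fraction is ~0.54/day for the
PVS pool, so full runs take exactly one sub-step per day).

Elevated parenchymal Aβ40 accelerates neuron loss: once C1 exceeds
theta_k1 = 20× its initial value the loss rate switches from d to d + k1.
The threshold is chosen so that no heart-rate or ApoE arm ever triggers it
(those arms report unchanged cell counts) while flow-collapse arms trigger
it within days; C1 peaks near 6.5× its initial value in the baseline run,
a factor ~3 below the threshold.

## Parameters

Defaults (see `glymphsim/presets/*.toml` for the full annotated set):
generation k3 = 16,000 and k8 = 3,000 molecules/neuron/day (the ~5:1
Aβ40:Aβ42 ratio), stimulated-generation multiplier k4 = 1.5 applied
unconditionally, uptake k5 = 1,400 and k11 = 200 molecules/microglia/day,
LRP-1 transport k6 = 0.4/day (ApoE2/3) or 0.12/day (ApoE4, the ~2.5-fold
slowing), vessel deposition 0.004/0.002 per day and parenchymal deposition
0.001/day for Aβ40/Aβ42, N0 = 5,275, M0 = 4,500, EC0 = 22,050 (a 21×21
capillary array, 50 endothelial cells per 1 mm vessel), LRP0 = 9.3e11
receptors, initial ISF concentrations 450/70 pg/mL converted to molecules
with monomer masses 4,330/4,514 Da, and PVS pools seeded at 10% of the ISF
pools.

Two published endothelial senescence figures (0.1 and 1.7 %/yr) bracket
the default k2 = 1 %/yr used here; only ~1 %/yr is consistent with the
observed ~40% decline of endothelial cells and LRP-1 receptors across a
50-year adult window, and both bracketing values remain available as named
constants (`K2_NO_STIM`, `K2_STIM`). LRP0 is taken at its printed
9.3e11-receptor figure rather than re-derived from the 31 fmol/mm³
density, which Avogadro arithmetic would place near 1.9e10; the two cannot
be reconciled and the integrated figure is the one the endpoint scale
depends on.

### Calibrated flow parameters

The baseline ISF velocity v0 and the PVS exit rate k_exit cannot be
measured directly and are fitted once, in a fixed order, each against a
monotone one-dimensional objective (bisection/Brent, residuals < 1e-12):

1. **v0 = 0.2946 mm/day** (≈ 0.2 μm/min, interior to the literature range
   0.144–0.43 mm/day) matches the 50-year normal-aging parenchymal Aβ40
   deposit of 5.929e9 molecules. The deposit is strictly decreasing in v0
   and independent of k_exit, because the parenchyma is upstream of the
   PVS.
2. **k_exit = 0.1304/day** matches the 1.96× vessel Aβ40 deposit ratio
   produced by slowing LRP-1 transport to its ApoE4 value. The ratio is
   strictly decreasing in k_exit (the larger the lymphatic exit share, the
   less LRP-1 matters).

The exit flux k_exit·C2 represents continuation of glymphatic flow to the
cervical lymph nodes; without it the PVS would have no non-depositing
outlet besides LRP-1 and the vessel deposit ratio could not be finite and
~2 simultaneously. A companion literature figure — that LRP-1 handles ~40%
of clearance — is structurally incompatible with that ratio in this model:
at the fitted k_exit, LRP-1 carries ~70% of PVS outflow. The ApoE4 ratio
is the anchor; the realized share is logged by `calibrate_k_exit`, not
enforced.

## Physiology mapping

v(t) = v0 · (HR/60) · compliance(S(t)). Linear heart-rate scaling is the
simplest law consistent with pulsation-driven flow and reproduces the
observed bradycardia effect with no additional freedom: because the
parenchymal outflow is dominated by v/L ≫ k7a, the 50-year parenchymal
deposit scales ≈ (v + k7a)⁻¹, so HR 50 gives a ratio ≈ 0.2956/0.2465 ≈
1.20 and HR 90 gives ≈ 66.7% of baseline. Vessel stiffness S(t) ramps
exponentially from 1 to its fold change over the run. Three compliance
laws are available (inverse, linear-to-floor, flow-off) because the
stiffness-to-velocity mapping is not experimentally constrained; the
built-in stiffening scenarios use `flow_off` (glymphatic drive abolished),
the only regime that yields the qualitative signature of severe
stiffening — parenchymal deposition up by two orders of magnitude, vessel
deposition collapsing by five — and its quantitative endpoints are
treated as qualitative, not matched. No separate age ramp is applied to
velocity in the baseline: with the calibrated v0 a constant-velocity
baseline already lands on the anchored endpoint.

## Scenario endpoints

The nine built-in arms differ from baseline only in HR, stiffness profile,
k6, or k4. At the calibrated defaults, with no further tuning:

- bradycardia (HR 50): parenchymal Aβ40 ratio 1.199
- elevated HR (90): parenchymal Aβ40 at 66.7% of baseline
- ApoE4: vessel Aβ40 ratio 1.960 (the anchor; parenchymal endpoints
  identical to baseline by construction — k6 only acts downstream)
- doubled generation (k4 2.0): parenchymal ratio 1.345 (the analytic
  expectation (4/3·G − U)/(G − U) with uptake U ≈ 3.5% of generation G)
- flow-off stiffening: parenchymal ratio ~142, vessel ratio ~3e-6,
  neurons well below baseline (the Aβ trigger fires within days);
  adding bradycardia changes nothing, since v is already zero.

Ratios are insensitive to halving/doubling the PVS initial condition
(< 1% endpoint shifts; the initial PVS pool turns over in ~2 days).

## Numerical verification

- The per-step mass-balance residual (generation vs. stock change +
  removals) stays below 1e-9 relative on every run, by construction.
- An independent fixed-step classical RK4 integrator of the
  continuous-rate counterpart (hazards −ln(1−r)/365) agrees with the
  daily map within 2% on all twelve endpoints; it shares no code with the
  stepping path and is used only in tests.
- Synthetic parameter recovery: calibrating against an endpoint generated
  by a known v0* or k_exit* returns the truth to ≤ 1%.
- The simulator is deterministic; identical configurations are
  bit-identical, and no seed exists anywhere in the interface.

## Limitations

The model inherits the well-mixed, single-volume idealization: no
diffusion gradients, no vascular network topology, no pulsatile
within-heartbeat dynamics, and blood as a perfect sink. The stiffness
arms are qualitative by design (the stiffness-to-velocity law is
unconstrained). Dystrophic microglia are assumed to lose uptake capacity
entirely. Absolute vessel-wall deposit levels are not anchored — the
model matches the vessel ratio across ApoE genotypes, not the printed
absolute vessel endpoints, which are unreachable simultaneously with that
ratio under this structure.
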