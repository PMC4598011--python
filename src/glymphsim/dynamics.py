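"""The daily update map for cell pools and the eight Aβ pools.

State layout (all amounts per 1 mm³ model volume):

==========  ==========================================================
``N``       neurons
``M``       functional (non-dystrophic) microglia
``EC``      brain capillary endothelial cells
``LRP``     LRP-1 receptors at the blood-brain barrier
``C1/C4``   Aβ40/Aβ42 dissolved in parenchymal interstitial fluid
``C2/C5``   Aβ40/Aβ42 in the perivascular space (PVS)
``C3/C6``   Aβ40/Aβ42 deposited in the vessel wall (cerebral amyloid
            angiopathy pools)
``C9/C10``  Aβ40/Aβ42 deposited in the brain parenchyma (plaque pools)
==========  ==========================================================

Aβ is generated by neurons into the parenchymal ISF, removed there by
microglial uptake and slow parenchymal deposition, and convected into the
PVS at rate v/L (bulk ISF velocity over segment length).  From the PVS it
leaves by LRP-1 transport into blood (a perfect sink), by continued
glymphatic flow to the cervical lymph nodes (``k_exit``), or by vessel-wall
deposition.  Cell pools decay geometrically; elevated parenchymal Aβ40
(above ``theta_k1`` times its initial value) triggers the additional
neuron-loss rate ``k1``.

All fluxes within one step are evaluated from the start-of-step state and
applied simultaneously (a Jacobi update), so the cumulative-flux ledger
closes exactly; the only clamp is microglial uptake, a zeroth-order demand
limited to the Aβ actually available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .errors import InvariantError, ParameterError
from .params import DEFAULT_GEOMETRY, ModelParams, annual_to_daily
from .physiology import Physiology, isf_velocity, lrp_fraction


@dataclass(frozen=True, slots=True)
class ModelState:
    """The twelve dynamic quantities at one time point (t in days)."""

    t: float
    N: float
    M: float
    EC: float
    LRP: float
    C1: float
    C4: float
    C2: float
    C5: float
    C3: float
    C6: float
    C9: float
    C10: float

    def validate(self, params: ModelParams | None = None) -> None:
        for f in fields(self):
            if f.name != "t" and getattr(self, f.name) < 0:
                raise InvariantError(f"state field {f.name} is negative")
        if params is not None:
            tol = 1.0 + 1e-12
            for pool, cap in (("N", params.N0), ("M", params.M0),
                              ("EC", params.EC0), ("LRP", params.LRP0)):
                if getattr(self, pool) > cap * tol:
                    raise InvariantError(f"{pool} exceeds its initial pool size")


@dataclass(frozen=True, slots=True)
class StepFluxes:
    """Per-step flux amounts (molecules/step), all non-negative."""

    gen40: float = 0.0
    gen42: float = 0.0
    upt40: float = 0.0
    upt42: float = 0.0
    glym40: float = 0.0
    glym42: float = 0.0
    lrp40: float = 0.0
    lrp42: float = 0.0
    exit40: float = 0.0
    exit42: float = 0.0
    dep_brain40: float = 0.0
    dep_brain42: float = 0.0
    dep_vessel40: float = 0.0
    dep_vessel42: float = 0.0


FLUX_NAMES = tuple(f.name for f in fields(StepFluxes))
STATE_NAMES = tuple(f.name for f in fields(ModelState) if f.name != "t")


def initial_state(params: ModelParams, pvs_init_scale: float = 1.0) -> ModelState:
    """Model state at t=0: full cell pools, measured ISF Aβ levels, PVS
    seeded at ``pvs_init_fraction`` of the ISF pools, no deposits."""
    if pvs_init_scale <= 0:
        raise ParameterError("pvs_init_scale must be > 0")
    c1 = params.c1_init_molecules()
    c4 = params.c4_init_molecules()
    frac = params.pvs_init_fraction * pvs_init_scale
    return ModelState(
        t=0.0, N=params.N0, M=params.M0, EC=params.EC0, LRP=params.LRP0,
        C1=c1, C4=c4, C2=frac * c1, C5=frac * c4,
        C3=0.0, C6=0.0, C9=0.0, C10=0.0,
    )


# ---------------------------------------------------------------------------
# Individual fluxes (rates per day unless noted)
# ---------------------------------------------------------------------------

def generation_flux(N: float, params: ModelParams,
                    multiplier: float = 1.0) -> tuple[float, float]:
    """Neuronal Aβ generation (molecules/day): k3·k4·N and k8·k4·N, with an
    optional extra sweep multiplier."""
    if N < 0:
        raise ParameterError("N must be >= 0")
    if multiplier <= 0:
        raise ParameterError("multiplier must be > 0")
    base = params.k4 * multiplier * N
    return params.k3 * base, params.k8 * base


def uptake_flux(M: float, available40: float, available42: float,
                params: ModelParams) -> tuple[float, float]:
    """Microglial uptake demand (molecules/day), clamped to availability."""
    if M < 0 or available40 < 0 or available42 < 0:
        raise ParameterError("uptake arguments must be >= 0")
    return (min(params.k5 * M, available40),
            min(params.k11 * M, available42))


def glymphatic_flux(C: float, v: float, L: float) -> float:
    """Convective parenchyma→PVS transfer (molecules/day): (v/L)·C."""
    if C < 0 or v < 0:
        raise ParameterError("C and v must be >= 0")
    if L <= 0:
        raise ParameterError("L must be > 0")
    return (v / L) * C


def lrp_flux(C_pvs: float, ell: float, k6: float) -> float:
    """LRP-1 transport out of the PVS into blood (molecules/day)."""
    if C_pvs < 0:
        raise ParameterError("C_pvs must be >= 0")
    if not 0.0 <= ell <= 1.0:
        raise ParameterError("LRP fraction must be in [0, 1]")
    return k6 * ell * C_pvs


def deposition_fluxes(state: ModelState,
                      params: ModelParams) -> tuple[float, float, float, float]:
    """(brain Aβ40, brain Aβ42, vessel Aβ40, vessel Aβ42) deposition,
    molecules/day, first-order in the respective dissolved pool."""
    return (params.k7a * state.C1, params.k9 * state.C4,
            params.k7 * state.C2, params.k9a * state.C5)


def neuron_loss_rate(C1: float, C1_init: float, params: ModelParams) -> float:
    """Annual neuron-loss fraction: the natural rate ``d``, plus ``k1``
    once parenchymal Aβ40 exceeds ``theta_k1`` times its initial level."""
    if C1 < 0 or C1_init < 0:
        raise ParameterError("C1 and C1_init must be >= 0")
    if C1 > params.theta_k1 * C1_init:
        return params.d + params.k1
    return params.d


# ---------------------------------------------------------------------------
# The step
# ---------------------------------------------------------------------------

def step(state: ModelState, params: ModelParams, phys: Physiology,
         dt: float = 1.0, gen_multiplier: float = 1.0,
         c1_init: float | None = None) -> tuple[ModelState, StepFluxes]:
    """Advance the state by ``dt`` days; return the new state and the flux
    amounts moved during the step.

    The step sub-divides automatically whenever the largest first-order
    outflow fraction of any dissolved pool would exceed 0.9 per sub-step,
    which keeps the explicit update positive for arbitrary valid
    parameter sets.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    state.validate(params)
    L = DEFAULT_GEOMETRY.segment_length_mm
    if c1_init is None:
        c1_init = params.c1_init_molecules()

    # positivity guard: worst-case per-day outflow fractions
    v_now = isf_velocity(state.t, phys, params)
    frac_par = (v_now / L + max(params.k7a, params.k9)) * dt
    frac_pvs = (params.k6 + params.k_exit + max(params.k7, params.k9a)) * dt
    n_sub = max(1, math.ceil(max(frac_par, frac_pvs) / 0.9))
    h = dt / n_sub

    # daily survival factors for the cell pools (annual rates compound
    # geometrically; k12 is already per-day)
    s_n_base = (1.0 - annual_to_daily(params.d)) ** h
    s_n_trig = (1.0 - annual_to_daily(min(params.d + params.k1, 1.0 - 1e-12))) ** h
    s_m = (1.0 - params.k12) ** h
    s_ec = (1.0 - annual_to_daily(params.k2)) ** h
    s_lrp = (1.0 - annual_to_daily(params.k10)) ** h

    t = state.t
    N, M, EC, LRP = state.N, state.M, state.EC, state.LRP
    C1, C4, C2, C5 = state.C1, state.C4, state.C2, state.C5
    C3, C6, C9, C10 = state.C3, state.C6, state.C9, state.C10
    tot = [0.0] * 14  # accumulated fluxes, order of FLUX_NAMES

    for _ in range(n_sub):
        v = isf_velocity(t, phys, params)
        ell = lrp_fraction(LRP, params.LRP0)
        triggered = C1 > params.theta_k1 * c1_init

        gen40, gen42 = generation_flux(N, params, gen_multiplier)
        gen40 *= h
        gen42 *= h
        glym40 = glymphatic_flux(C1, v, L) * h
        glym42 = glymphatic_flux(C4, v, L) * h
        depb40 = params.k7a * C1 * h
        depb42 = params.k9 * C4 * h
        avail40 = C1 + gen40 - glym40 - depb40
        avail42 = C4 + gen42 - glym42 - depb42
        upt40 = min(params.k5 * M * h, avail40)
        upt42 = min(params.k11 * M * h, avail42)
        lrp40 = lrp_flux(C2, ell, params.k6) * h
        lrp42 = lrp_flux(C5, ell, params.k6) * h
        exit40 = params.k_exit * C2 * h
        exit42 = params.k_exit * C5 * h
        depv40 = params.k7 * C2 * h
        depv42 = params.k9a * C5 * h

        # written as avail - uptake so a fully clamped pool lands on 0.0
        # exactly rather than a rounding-level negative
        C1 = avail40 - upt40
        C4 = avail42 - upt42
        C2 += glym40 - lrp40 - exit40 - depv40
        C5 += glym42 - lrp42 - exit42 - depv42
        C9 += depb40
        C10 += depb42
        C3 += depv40
        C6 += depv42

        N *= s_n_trig if triggered else s_n_base
        M *= s_m
        EC *= s_ec
        LRP *= s_lrp
        t += h

        for i, x in enumerate((gen40, gen42, upt40, upt42, glym40, glym42,
                               lrp40, lrp42, exit40, exit42,
                               depb40, depb42, depv40, depv42)):
            tot[i] += x

    new = ModelState(t=state.t + dt, N=N, M=M, EC=EC, LRP=LRP,
                     C1=C1, C4=C4, C2=C2, C5=C5,
                     C3=C3, C6=C6, C9=C9, C10=C10)
    new.validate(params)
    return new, StepFluxes(*tot)
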