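"""Simulation engine: 50-year daily-step runs, the cumulative-flux ledger,
a fine-step reference integrator, and the two calibration routines.

The engine is fully deterministic — there is no random number generator
anywhere in the model — so identical configurations produce bit-identical
trajectories.

Two model parameters are not measurable directly and are fitted once
against endpoint anchors:

* ``v0`` (baseline ISF velocity) against the 50-year normal-aging
  parenchymal Aβ40 deposit, by bisection inside the literature velocity
  range; the parenchymal deposit is strictly decreasing in ``v0``.
* ``k_exit`` (perivascular exit to the cervical lymph nodes) against the
  ApoE4-to-baseline vessel Aβ40 deposit ratio; the ratio is strictly
  decreasing in ``k_exit``.

``v0`` is calibrated first because the parenchymal compartment is
upstream of the perivascular space and independent of ``k_exit``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dynamics import (FLUX_NAMES, ModelState, initial_state, step)
from .errors import InvariantError, ParameterError
from .params import (CALIBRATION_ANCHORS, DEFAULT_GEOMETRY, ModelParams,
                     V0_BOUNDS)
from .physiology import Physiology, isf_velocity, lrp_fraction

log = logging.getLogger(__name__)

#: Column order of Trajectory.states
STATE_COLUMNS = ("N", "M", "EC", "LRP", "C1", "C4", "C2", "C5",
                 "C3", "C6", "C9", "C10")
#: Column order of Trajectory.ledger (cumulative fluxes)
LEDGER_COLUMNS = FLUX_NAMES

#: Exact header of the trajectory CSV export.
CSV_COLUMNS = (
    "t_days", "N", "M", "EC", "LRP", "C1", "C4", "C2", "C5",
    "C3", "C6", "C9", "C10",
    "cum_gen40", "cum_gen42", "cum_upt40", "cum_upt42",
    "cum_lrp40", "cum_lrp42", "cum_exit40", "cum_exit42",
)

_CSV_LEDGER = ("gen40", "gen42", "upt40", "upt42",
               "lrp40", "lrp42", "exit40", "exit42")


@dataclass
class Trajectory:
    """Time-indexed record of a run plus its cumulative-flux ledger."""

    times: np.ndarray                 # (n,) days, uniform spacing
    states: np.ndarray                # (n, 12), columns STATE_COLUMNS
    ledger: np.ndarray | None         # (n, 14), columns LEDGER_COLUMNS
    scenario_name: str
    params_used: ModelParams

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise InvariantError("times and states length mismatch")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9):
                raise InvariantError("times must increase with uniform spacing")

    # -- accessors ---------------------------------------------------------
    def state_at(self, i: int) -> ModelState:
        row = self.states[i]
        return ModelState(self.times[i], *row)

    @property
    def final_state(self) -> ModelState:
        return self.state_at(len(self.times) - 1)

    def endpoint(self, name: str) -> float:
        """Final value of one state column, e.g. ``endpoint("C9")``."""
        return float(self.states[-1, STATE_COLUMNS.index(name)])

    def endpoints(self) -> dict[str, float]:
        return {c: float(x) for c, x in zip(STATE_COLUMNS, self.states[-1])}

    def ledger_totals(self) -> dict[str, float]:
        if self.ledger is None:
            return {}
        return {c: float(x) for c, x in zip(LEDGER_COLUMNS, self.ledger[-1])}

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a DataFrame with the fixed CSV column set."""
        if self.ledger is None:
            raise InvariantError("trajectory has no ledger to export")
        data = {"t_days": self.times}
        for j, c in enumerate(STATE_COLUMNS):
            data[c] = self.states[:, j]
        for c in _CSV_LEDGER:
            data[f"cum_{c}"] = self.ledger[:, LEDGER_COLUMNS.index(c)]
        return pd.DataFrame(data, columns=CSV_COLUMNS)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of fitting one free parameter to an endpoint anchor."""

    parameter: str
    fitted_value: float
    anchor: float
    residual: float          # |achieved - anchor| / anchor
    at_bound: bool = False
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Running
# ---------------------------------------------------------------------------

def run_simulation(scenario=None, years: float = 50.0, dt: float = 1.0,
                   params: ModelParams | None = None,
                   phys: Physiology | None = None,
                   record_stride: float = 1.0,
                   pvs_init_scale: float = 1.0,
                   gen_multiplier: float = 1.0) -> Trajectory:
    """Run a scenario (or an explicit params/physiology pair) for ``years``
    years of ``dt``-day steps and return the recorded trajectory.

    A full default run is 18,250 daily steps (50 years), recorded at every
    step, so the trajectory holds 18,251 points including t=0.
    """
    if years <= 0:
        raise ParameterError("years must be > 0")
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    if record_stride < dt:
        raise ParameterError("record_stride must be >= dt")

    name = "custom"
    if scenario is not None:
        name = scenario.name
        if params is None:
            params = scenario.build_params()
        if phys is None:
            phys = scenario.build_physiology()
    if params is None:
        params = ModelParams()
    if phys is None:
        phys = Physiology()
    params.validate()
    if gen_multiplier <= 0:
        raise ParameterError("gen_multiplier must be > 0")

    n_steps = int(round(years * 365.0 / dt))
    every = max(1, int(round(record_stride / dt)))
    n_rec = n_steps // every + 1

    state = initial_state(params, pvs_init_scale=pvs_init_scale)
    c1_init = params.c1_init_molecules()

    times = np.empty(n_rec)
    states = np.empty((n_rec, 12))
    ledger = np.empty((n_rec, 14))
    cum = [0.0] * 14

    def record(k: int, s: ModelState) -> None:
        times[k] = s.t
        states[k] = (s.N, s.M, s.EC, s.LRP, s.C1, s.C4, s.C2, s.C5,
                     s.C3, s.C6, s.C9, s.C10)
        ledger[k] = cum

    record(0, state)
    k = 1
    for i in range(1, n_steps + 1):
        state, fluxes = step(state, params, phys, dt=dt,
                             gen_multiplier=gen_multiplier, c1_init=c1_init)
        for j, fname in enumerate(FLUX_NAMES):
            cum[j] += getattr(fluxes, fname)
        if i % every == 0:
            record(k, state)
            k += 1

    traj = Trajectory(times=times[:k], states=states[:k], ledger=ledger[:k],
                      scenario_name=name, params_used=params)
    # internal closure gate; the tolerance is scaled also by the initial
    # dissolved stock so that zero-generation runs are judged relative to
    # the mass actually circulating, not in absolute molecules
    abs_resid, generated = _mass_balance_arrays(traj)
    stock0 = float(np.sum(traj.states[0, 4:8]))
    if np.max(abs_resid) > 1e-9 * max(1.0, generated[-1], stock0):
        raise InvariantError(
            f"mass-balance ledger failed to close: {np.max(abs_resid):.3e} "
            "molecules")
    return traj


def _mass_balance_arrays(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Absolute mass-balance residual and cumulative generation, per
    recorded step."""
    if traj.ledger is None or len(traj.times) == 0:
        raise ParameterError("trajectory must be non-empty and carry a ledger")
    idx = [STATE_COLUMNS.index(c) for c in
           ("C1", "C4", "C2", "C5", "C3", "C6", "C9", "C10")]
    stocks = traj.states[:, idx].sum(axis=1)
    d_stocks = stocks - stocks[0]
    led = {c: traj.ledger[:, LEDGER_COLUMNS.index(c)] for c in LEDGER_COLUMNS}
    generated = led["gen40"] + led["gen42"]
    removed = (led["upt40"] + led["upt42"] + led["lrp40"] + led["lrp42"]
               + led["exit40"] + led["exit42"])
    return np.abs(generated - d_stocks - removed), generated


def mass_balance_residual(traj: Trajectory) -> float:
    """Largest relative mass-balance error over the recorded trajectory.

    At every recorded time the Aβ generated so far must equal the change
    in dissolved stocks plus deposits plus everything removed (uptake,
    LRP-1 transport, lymphatic exit).  The ledger is exact bookkeeping,
    so any residual beyond float rounding indicates a wiring bug.
    """
    resid, generated = _mass_balance_arrays(traj)
    return float(np.max(resid / np.maximum(1.0, generated)))


# ---------------------------------------------------------------------------
# Fine-step reference integrator (tests only)
# ---------------------------------------------------------------------------

def reference_integrate(scenario=None, years: float = 50.0,
                        fine_dt: float = 0.25,
                        params: ModelParams | None = None,
                        phys: Physiology | None = None,
                        pvs_init_scale: float = 1.0,
                        gen_multiplier: float = 1.0) -> Trajectory:
    """Classical fixed-step 4th-order Runge-Kutta integration of the
    continuous-rate counterpart of the daily map.

    Annual loss fractions become continuous hazards −ln(1−r)/365 per day,
    so the cell pools match the discrete geometric decay exactly at day
    boundaries.  Microglial uptake is applied unclamped (the dissolved
    pools stay far from zero in every scenario this oracle is used for).
    Serves as an independent accuracy oracle in the test suite; the
    returned trajectory has no flux ledger.
    """
    if fine_dt > 0.25:
        raise ParameterError("fine_dt must be <= 0.25 day")
    if scenario is not None:
        if params is None:
            params = scenario.build_params()
        if phys is None:
            phys = scenario.build_physiology()
    if params is None:
        params = ModelParams()
    if phys is None:
        phys = Physiology()

    L = DEFAULT_GEOMETRY.segment_length_mm
    c1_init = params.c1_init_molecules()
    lam_n_base = -math.log(1.0 - params.d) / 365.0
    lam_n_trig = -math.log(1.0 - min(params.d + params.k1, 1 - 1e-12)) / 365.0
    lam_m = -math.log(1.0 - params.k12)
    lam_ec = -math.log(1.0 - params.k2) / 365.0
    lam_lrp = -math.log(1.0 - params.k10) / 365.0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        N, M, EC, LRP, C1, C4, C2, C5, C3, C6, C9, C10 = y
        v = isf_velocity(t, phys, params)
        ell = lrp_fraction(min(LRP, params.LRP0), params.LRP0)
        lam_n = lam_n_trig if C1 > params.theta_k1 * c1_init else lam_n_base
        gen40 = params.k3 * params.k4 * gen_multiplier * N
        gen42 = params.k8 * params.k4 * gen_multiplier * N
        upt40 = params.k5 * M
        upt42 = params.k11 * M
        glym40 = (v / L) * C1
        glym42 = (v / L) * C4
        return np.array([
            -lam_n * N, -lam_m * M, -lam_ec * EC, -lam_lrp * LRP,
            gen40 - upt40 - glym40 - params.k7a * C1,
            gen42 - upt42 - glym42 - params.k9 * C4,
            glym40 - (params.k6 * ell + params.k_exit + params.k7) * C2,
            glym42 - (params.k6 * ell + params.k_exit + params.k9a) * C5,
            params.k7 * C2, params.k9a * C5,
            params.k7a * C1, params.k9 * C4,
        ])

    n_steps = int(round(years * 365.0 / fine_dt))
    rec_every = max(1, int(round(1.0 / fine_dt)))
    s0 = initial_state(params, pvs_init_scale=pvs_init_scale)
    y = np.array([s0.N, s0.M, s0.EC, s0.LRP, s0.C1, s0.C4, s0.C2, s0.C5,
                  s0.C3, s0.C6, s0.C9, s0.C10])
    t = 0.0
    times = [0.0]
    states = [y.copy()]
    h = fine_dt
    for i in range(1, n_steps + 1):
        k1_ = rhs(t, y)
        k2_ = rhs(t + h / 2, y + h / 2 * k1_)
        k3_ = rhs(t + h / 2, y + h / 2 * k2_)
        k4_ = rhs(t + h, y + h * k3_)
        y = y + h / 6 * (k1_ + 2 * k2_ + 2 * k3_ + k4_)
        t = i * fine_dt
        if i % rec_every == 0:
            times.append(t)
            states.append(y.copy())
    name = scenario.name if scenario is not None else "custom"
    return Trajectory(times=np.array(times), states=np.array(states),
                      ledger=None, scenario_name=f"{name}:reference",
                      params_used=params)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def _bisect_monotone(f: Callable[[float], float], lo: float, hi: float,
                     decreasing: bool) -> tuple[float, float, bool]:
    """Root of a monotone objective on [lo, hi]; returns (x, f(x), at_bound).

    If the root lies outside the interval, the nearer bound is returned
    with its residual and the at_bound flag set.
    """
    f_lo, f_hi = f(lo), f(hi)
    # for a decreasing objective f(lo) >= 0 >= f(hi) brackets a root
    if decreasing:
        if f_lo < 0:
            return lo, f_lo, True
        if f_hi > 0:
            return hi, f_hi, True
    else:
        if f_lo > 0:
            return lo, f_lo, True
        if f_hi < 0:
            return hi, f_hi, True
    x = brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16)
    return x, f(x), False


def calibrate_v0(params: ModelParams, anchor_value: float | None = None,
                 years: float = 50.0) -> CalibrationResult:
    """Fit the baseline ISF velocity to the normal-aging parenchymal Aβ40
    deposit anchor by bisection inside the literature velocity range.

    The deposit is strictly decreasing in ``v0`` (faster flow flushes Aβ
    out of the parenchyma before it can deposit), so the objective is
    monotone and the solution unique when reachable.
    """
    if anchor_value is None:
        anchor_value = CALIBRATION_ANCHORS["parenchymal_ab40_deposit"]
    if anchor_value <= 0:
        raise ParameterError("anchor_value must be > 0")
    lo, hi = V0_BOUNDS

    def objective(v0: float) -> float:
        p = replace(params, v0=v0)
        traj = run_simulation(params=p, years=years)
        return traj.endpoint("C9") - anchor_value

    x, fx, at_bound = _bisect_monotone(objective, lo, hi, decreasing=True)
    resid = abs(fx) / anchor_value
    if at_bound:
        log.warning("v0 calibration hit bound %.4g (residual %.3g)", x, resid)
    else:
        log.info("calibrated v0 = %.6g mm/day (residual %.3g)", x, resid)
    return CalibrationResult("v0", x, anchor_value, resid, at_bound)


def calibrate_k_exit(params: ModelParams, anchor_ratio: float | None = None,
                     years: float = 50.0,
                     apoe4_k6: float = 0.12) -> CalibrationResult:
    """Fit the perivascular exit rate so that slowing LRP-1 transport to
    its ApoE4 value multiplies the 50-year vessel Aβ40 deposit by the
    anchor ratio.

    The larger ``k_exit`` is, the smaller the share of perivascular Aβ
    that LRP-1 handles, and the weaker the effect of slowing LRP-1 — so
    the ratio is strictly decreasing in ``k_exit``.
    """
    if anchor_ratio is None:
        anchor_ratio = CALIBRATION_ANCHORS["apoe4_vessel_ab40_ratio"]
    if anchor_ratio <= 1.0:
        raise ParameterError("anchor_ratio must be > 1")

    def ratio(k_exit: float) -> float:
        base = run_simulation(params=replace(params, k_exit=k_exit),
                              years=years)
        apoe4 = run_simulation(
            params=replace(params, k_exit=k_exit, k6=apoe4_k6), years=years)
        return apoe4.endpoint("C3") / base.endpoint("C3")

    def objective(k_exit: float) -> float:
        return ratio(k_exit) - anchor_ratio

    x, fx, at_bound = _bisect_monotone(objective, 0.0, 2.0, decreasing=True)
    resid = abs(fx) / anchor_ratio

    # realized clearance shares at the fitted value, for the record
    base = run_simulation(params=replace(params, k_exit=x), years=years)
    tot = base.ledger_totals()
    pvs_out = tot["lrp40"] + tot["exit40"] + base.endpoint("C3")
    details = {
        "lrp_share_of_pvs_outflow": tot["lrp40"] / pvs_out if pvs_out else 0.0,
        "exit_share_of_pvs_outflow": tot["exit40"] / pvs_out if pvs_out else 0.0,
    }
    if at_bound:
        log.warning("k_exit calibration hit bound %.4g (residual %.3g)", x, resid)
    else:
        log.info("calibrated k_exit = %.6g /day (residual %.3g); "
                 "LRP share of PVS outflow %.2f", x, resid,
                 details["lrp_share_of_pvs_outflow"])
    return CalibrationResult("k_exit", x, anchor_ratio, resid, at_bound, details)
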