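"""The unclamped, coupled intraciliary Ca2+ / membrane-potential system.

With the clamp removed, the Ca2+ and K+ currents themselves move the
membrane potential.  Channel conductances relax much faster than either u
or psi, so they are taken at their voltage steady states, and the indirect
gate is taken at its Ca2+ steady state c(u).  The base system is

    du/deta  = s   * ( -b*(c(u)*nu(psi) + nuCa_st) * (psi - 0.5*ln(uout/u))
                       - u/(kA+u) )
    dpsi/deta = rho * ( I_Ca(u,psi) + I_K(u,psi) + I0 )

with I_Ca = -b*(c(u)*nu(psi)+nuCa_st)*(psi - 0.5*ln(uout/u)) (inward,
depolarising), I_K = -b1*(nuK(psi)+nuK_st)*(psi - psiK) (repolarising above
psiK) and I0 a prescribed inward-current drive.  psi is the fast variable
(rho >> s), u the slow one: an excitable system of the relaxation-oscillator
family whose psi-nullcline is N-shaped.

Variants:

* ``hyper`` adds the hyperpolarisation-activated Ca2+ conductance
  -vCah*nu_h(psi) to the Ca branch of the psi equation and an optional
  Ca2+-dependent K+ conductance vKca*nuK(psi)*u/(1+u) to the K branch;
* ``full`` further adds the cilium-to-body leak
  vCat*nu_t(psi)*(psi_tr - 0.5*ln(u/ut)) to the u equation.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .conductances import (
    CA_CONDUCTANCE,
    H_CONDUCTANCE,
    K_CONDUCTANCE,
    T_CONDUCTANCE,
    SigmoidConductanceParams,
    sigmoid_conductance,
)
from .gating import LOG_FLOOR, IndirectGatingParams, indirect_open_fraction_ss
from .clamp import StiffnessError, Trajectory

__all__ = [
    "Variant",
    "CoupledModelParams",
    "CurrentSchedule",
    "coupled_rhs",
    "free_currents",
    "simulate_free",
    "iv_characteristic",
]


_log = logging.getLogger("ciliadyn")


class Variant(str, enum.Enum):
    BASE = "base"
    HYPER = "hyper"
    FULL = "full"


@dataclass(frozen=True)
class CoupledModelParams:
    """Parameter set of the coupled (u, psi) system.

    Defaults are the printed coupled-system values: b=8, cac0=20, rho=10,
    s=0.5, background conductances nuCa_st = nuK_st = 0.01, kA=1,
    uout=1000.  vCah (hyperpolarisation-activated Ca2+ scale), vKca
    (Ca2+-dependent K+ scale) and vCat (cilium-to-body scale) activate the
    hyper / full variants; all default to 0.
    """

    s: float = 0.5
    b: float = 8.0
    b1: float = 1.0
    rho: float = 10.0
    kA: float = 1.0
    uout: float = 1000.0
    ut: float = 0.025
    #: K+ reversal. -1.8 (45 mV hyperpolarised of zero) places the I0=0 rest
    #: at psi ~ -1.24, the stated resting potential; a K+ reversal above rest
    #: would leave the coupled system without a low-Ca2+ rest state.
    psiK: float = -1.8
    nuCa_st: float = 0.01
    nuK_st: float = 0.01
    vCah: float = 0.0
    vKca: float = 0.0
    vCat: float = 0.0
    psi_tr: float = 0.0
    I0: float = 0.0
    gating: IndirectGatingParams = field(default_factory=IndirectGatingParams)
    ca_cond: SigmoidConductanceParams = field(default=CA_CONDUCTANCE)
    k_cond: SigmoidConductanceParams = field(default=K_CONDUCTANCE)
    h_cond: SigmoidConductanceParams = field(default=H_CONDUCTANCE)
    t_cond: SigmoidConductanceParams = field(default=T_CONDUCTANCE)
    #: if True, the psi-equation Ca2+ log term uses ln(uout/ut) (the printed
    #: composite form) instead of the self-consistent ln(uout/u)
    psi_log_uses_ut: bool = False
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        for name in ("s", "b", "b1", "rho", "uout", "ut"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("nuCa_st", "nuK_st", "vCah", "vKca", "vCat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CurrentSchedule:
    """Piecewise-constant inward-current programme I0(eta).

    ``segments`` is a sequence of (start_eta, value) pairs with strictly
    increasing start times; the value of the last segment whose start time
    is <= eta applies.  Before the first segment the baseline I0 applies.
    """

    segments: tuple[tuple[float, float], ...] = ()
    baseline: float = 0.0

    def __post_init__(self) -> None:
        starts = [s for s, _ in self.segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("schedule segments must have strictly increasing start times")

    def __call__(self, eta: float) -> float:
        value = self.baseline
        for start, v in self.segments:
            if eta >= start:
                value = v
            else:
                break
        return value

    @classmethod
    def constant(cls, I0: float) -> "CurrentSchedule":
        return cls(segments=(), baseline=I0)


def free_currents(u, psi, params: CoupledModelParams, variant: Variant | str = Variant.BASE):
    """Component currents (i_ca, i_k, i_hyper, i_body) at a state (u, psi)."""
    variant = Variant(variant)
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("coupled system requires u > 0")
    uu = np.maximum(u, LOG_FLOOR)
    c = indirect_open_fraction_ss(u, params.gating)
    nu = sigmoid_conductance(psi, params.ca_cond)
    drive = psi - 0.5 * np.log(params.uout / uu)
    i_ca = -params.b * (c * nu + params.nuCa_st) * drive

    nuK = sigmoid_conductance(psi, params.k_cond)
    gK = nuK + params.nuK_st
    if variant in (Variant.HYPER, Variant.FULL):
        gK = gK + params.vKca * nuK * u / (1.0 + u)
    i_k = -params.b1 * gK * (psi - params.psiK)

    i_hyper = 0.0
    if variant in (Variant.HYPER, Variant.FULL):
        if params.psi_log_uses_ut:
            drive_h = psi - 0.5 * np.log(params.uout / params.ut)
        else:
            drive_h = drive
        i_hyper = -params.vCah * sigmoid_conductance(psi, params.h_cond) * drive_h

    i_body = 0.0
    if variant == Variant.FULL:
        i_body = params.vCat * sigmoid_conductance(psi, params.t_cond) * (
            params.psi_tr - 0.5 * np.log(uu / params.ut)
        )
    return i_ca, i_k, i_hyper, i_body


def coupled_rhs(
    state,
    params: CoupledModelParams,
    variant: Variant | str = Variant.BASE,
    I0: float | None = None,
):
    """(du/deta, dpsi/deta) of the selected variant at ``state = (u, psi)``.

    The hyper terms enter only the psi equation; the cilium-to-body leak
    only the u equation.  With vCah = vKca = vCat = 0 every variant reduces
    exactly to the base right-hand side.
    """
    u, psi = state
    if I0 is None:
        I0 = params.I0
    i_ca, i_k, i_hyper, i_body = free_currents(u, psi, params, variant)
    pump = np.asarray(u, dtype=float) / (params.kA + np.asarray(u, dtype=float))
    du = params.s * (i_ca - pump + i_body)
    dpsi = params.rho * (i_ca + i_hyper + i_k + I0)
    return du, dpsi


def simulate_free(
    params: CoupledModelParams,
    schedule: CurrentSchedule | float | None = None,
    init: tuple[float, float] | None = None,
    duration: float = 200.0,
    variant: Variant | str = Variant.BASE,
    n_points: int = 4000,
) -> Trajectory:
    """Integrate the free-membrane system under an inward-current schedule.

    ``init`` defaults to the resting fixed point at the schedule's baseline
    current (found by the phase-portrait root solver).  The returned
    Trajectory carries psi in place of the clamp's fixed potential and the
    quasi-steady gate c(u).
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    variant = Variant(variant)
    if schedule is None:
        schedule = CurrentSchedule.constant(params.I0)
    elif not isinstance(schedule, CurrentSchedule):
        schedule = CurrentSchedule.constant(float(schedule))

    if init is None:
        from .phase import resting_state

        init = resting_state(params, variant, I0=schedule.baseline)

    def rhs(eta, y):
        u = max(y[0], LOG_FLOOR)
        return coupled_rhs((u, y[1]), params, variant, I0=schedule(eta))

    breaks = [s for s, _ in schedule.segments if 0.0 < s < duration]
    edges = [0.0, *breaks, duration]
    etas, us, psis = [], [], []
    y0 = list(init)
    for t0, t1 in zip(edges[:-1], edges[1:]):
        sol = solve_ivp(
            rhs,
            (t0, t1),
            y0,
            method="LSODA",
            rtol=params.rtol,
            atol=params.atol,
            dense_output=True,
        )
        if not sol.success:
            raise StiffnessError(f"free-membrane integration failed: {sol.message}")
        n_seg = max(16, int(round(n_points * (t1 - t0) / duration)))
        eta = np.linspace(t0, t1, n_seg)
        u, psi = sol.sol(eta)
        etas.append(eta)
        us.append(u)
        psis.append(psi)
        y0 = sol.y[:, -1]

    eta = np.concatenate(etas)
    u = np.concatenate(us)
    psi = np.concatenate(psis)
    _log.info(
        "free %s duration=%.4g segments=%d baseline_I0=%.4g points=%d",
        variant.value, duration, len(schedule.segments), schedule.baseline, eta.size,
    )
    I0_arr = np.array([schedule(t) for t in eta])
    i_ca, i_k, i_hyper, i_body = free_currents(np.maximum(u, LOG_FLOOR), psi, params, variant)
    i_full = i_ca + np.asarray(i_hyper) + i_k + I0_arr
    gate = indirect_open_fraction_ss(np.maximum(u, 0.0), params.gating)
    return Trajectory(eta=eta, u=u, gate=gate, i_ca=np.asarray(i_ca), i_k=np.asarray(i_k), i_full=i_full, psi=psi)


def iv_characteristic(
    params: CoupledModelParams,
    psi_step_grid,
    variant: Variant | str = Variant.BASE,
    duration: float = 60.0,
) -> pd.DataFrame:
    """Voltage-current characteristic from free-membrane transients.

    Each row displaces the membrane potential from rest to a grid value
    (Ca2+ left at rest), lets the system run free, and reports the transient
    current-amplitude extrema plus the stationary full current.
    """
    from .phase import resting_state

    u_rest, psi_rest = resting_state(params, variant, I0=params.I0)
    rows = []
    for psi_step in np.asarray(psi_step_grid, dtype=float):
        traj = simulate_free(
            params,
            schedule=CurrentSchedule.constant(params.I0),
            init=(u_rest, psi_step),
            duration=duration,
            variant=variant,
        )

        def amp(x):
            return float(np.max(x) - np.min(x))

        rows.append(
            {
                "psi_step": psi_step,
                "peak_i_ca": amp(traj.i_ca),
                "peak_i_k": amp(traj.i_k),
                "peak_i_full": amp(traj.i_full),
                "stationary_i_full": float(traj.i_full[-1]),
            }
        )
    return pd.DataFrame(rows)
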