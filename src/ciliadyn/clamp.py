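"""Voltage-clamp simulation of the intraciliary Ca2+ / gate system.

Under voltage clamp the membrane potential is stepped from a holding value
psi0 to psi1 at eta = 0 while the intraciliary Ca2+ level u and the channel
gate (n for the direct mechanism, c for the indirect one) evolve:

    du/deta = S * ( -b * gate * nu_rel(eta) * (psi - 0.5*ln(u_out/u))
                    - u/(kA + u) [ + cilium-to-body leak ] )

with nu_rel the exponentially relaxing Ca2+ conductance between its psi0
and psi1 steady values, and S the flux scale (s for the direct model, a for
the indirect one).  The bracket is the signed non-dimensional Ca2+ current
i_Ca reported in trajectories; the optional K+ contribution is
i_K = -b1 * nuK_rel(eta) * (psi - psi_K) and i_full = i_Ca + i_K.

A depolarising step opens the conductance within tau0, producing a fast
inward current phase that the Ca2+-dependent gate then relaxes away — the
biphasic clamp current.  Whether intraciliary Ca2+ itself overshoots (a
spike) or rises monotonically to its new steady level depends on the flux
scale: u must outrun the gate (roughly flux_scale * |i_Ca| > 1 + k*u) for
an interior maximum to form.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .conductances import (
    CA_CONDUCTANCE,
    K_CONDUCTANCE,
    RelaxationSpec,
    SigmoidConductanceParams,
    relaxed_conductance,
    sigmoid_conductance,
)
from .gating import (
    LOG_FLOOR,
    CiliumBodyParams,
    DirectGatingParams,
    IndirectGatingParams,
    direct_gate_rhs,
    direct_open_fraction_ss,
    indirect_gate_rhs,
    indirect_open_fraction_ss,
    pump_flux,
    PumpParams,
    cilium_body_current,
)

__all__ = [
    "Mechanism",
    "ClampProtocol",
    "ClampModelParams",
    "Trajectory",
    "SpikeMetrics",
    "InitialisationError",
    "StiffnessError",
    "clamp_initial_state",
    "simulate_clamp",
    "simulate_direct_clamp",
    "simulate_indirect_clamp",
    "clamp_full_current",
    "steady_state_u_of_psi",
    "spike_metrics",
    "scan_spike_amplitude",
]


_log = logging.getLogger("ciliadyn")


class Mechanism(str, enum.Enum):
    DIRECT = "direct"
    INDIRECT = "indirect"


class InitialisationError(RuntimeError):
    """No clamp fixed point found in the search bracket."""


class StiffnessError(RuntimeError):
    """Integrator failure; try tighter tolerances or a shorter step."""


@dataclass(frozen=True)
class ClampProtocol:
    """Holding/step potentials and relaxation times of one clamp run."""

    psi0: float = -1.2
    psi1: float = 0.5
    tau0: float = 0.02
    tauK: float = 0.02
    duration: float = 30.0
    mechanism: Mechanism = Mechanism.DIRECT
    include_K: bool = False

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not self.tau0 > 0 or not self.tauK > 0:
            raise ValueError("relaxation time constants must be > 0")


@dataclass(frozen=True)
class ClampModelParams:
    """Non-dimensional parameter set of the clamp model.

    s / a are the flux scales of the direct / indirect u-equations, b the
    maximal Ca2+ conductance group, b1 the K+ conductance group, kA the
    pump half-saturation, u_out the extracellular Ca2+ level and psi_K the
    K+ equilibrium potential (default −0.4 = 10 mV: the full steady clamp
    current crosses zero exactly there).
    """

    s: float = 0.5
    a: float = 4.0
    b: float = 2.0
    b1: float = 1.0
    kA: float = 1.0
    uout: float = 1000.0
    psiK: float = -0.4
    direct: DirectGatingParams = field(default_factory=DirectGatingParams)
    indirect: IndirectGatingParams = field(default_factory=IndirectGatingParams)
    ca_cond: SigmoidConductanceParams = field(default=CA_CONDUCTANCE)
    k_cond: SigmoidConductanceParams = field(default=K_CONDUCTANCE)
    cb: CiliumBodyParams = field(default_factory=CiliumBodyParams)
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        for name in ("s", "a", "b", "b1", "uout"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def pump(self) -> PumpParams:
        return PumpParams(kA=self.kA)


@dataclass
class Trajectory:
    """Time grid with state variables and derived currents."""

    eta: np.ndarray
    u: np.ndarray
    gate: np.ndarray
    i_ca: np.ndarray
    i_k: np.ndarray
    i_full: np.ndarray
    psi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eta": self.eta,
                "u": self.u,
                "gate": self.gate,
                "i_ca": self.i_ca,
                "i_k": self.i_k,
                "i_full": self.i_full,
                "psi": self.psi,
            }
        )


@dataclass(frozen=True)
class SpikeMetrics:
    """Peak/amplitude summary of one post-step transient."""

    baseline: float
    peak: float
    amplitude: float
    peak_time: float
    final_ss: float
    n_extrema: int


def _gate_ss(u: float, params: ClampModelParams, mechanism: Mechanism) -> float:
    if mechanism == Mechanism.DIRECT:
        return float(direct_open_fraction_ss(u, params.direct))
    return float(indirect_open_fraction_ss(u, params.indirect))


def _ca_current(u, gate, nu, psi, params: ClampModelParams):
    """Signed non-dimensional Ca2+ current (passive influx minus pump)."""
    drive = psi - 0.5 * np.log(params.uout / np.maximum(u, LOG_FLOOR))
    i = -params.b * gate * nu * drive - pump_flux(np.maximum(u, 0.0), params.pump)
    if params.cb.nu_t != 0.0:
        i = i + cilium_body_current(np.maximum(u, LOG_FLOOR), params.cb, psi)
    return i


def clamp_initial_state(
    params: ClampModelParams,
    psi0: float,
    mechanism: Mechanism = Mechanism.DIRECT,
) -> tuple[float, float]:
    """Resting state (u0, gate0) of the clamp system held at psi0.

    Solves the quasi-steady balance influx = pump with the gate at its
    steady-state value; the returned state zeroes the clamp RHS to better
    than 1e-10.
    """
    nu0 = sigmoid_conductance(psi0, params.ca_cond)

    def residual(u: float) -> float:
        return float(_ca_current(u, _gate_ss(u, params, mechanism), nu0, psi0, params))

    lo = 1e-10
    hi = params.uout * np.exp(-2.0 * psi0)  # Nernst level: influx term vanishes
    if residual(lo) < 0 or residual(hi) > 0:
        raise InitialisationError(
            f"no clamp fixed point bracketed in [{lo:g}, {hi:g}] at psi0={psi0}: "
            f"residuals ({residual(lo):g}, {residual(hi):g})"
        )
    u0 = brentq(residual, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    # Newton polish for the spec'd residual level
    for _ in range(3):
        r = residual(u0)
        if abs(r) < 1e-12:
            break
        h = max(1e-9 * u0, 1e-12)
        dr = (residual(u0 + h) - residual(u0 - h)) / (2 * h)
        if dr == 0:
            break
        u0 = u0 - r / dr
    return float(u0), _gate_ss(u0, params, mechanism)


def simulate_clamp(
    protocol: ClampProtocol,
    params: ClampModelParams,
    n_points: int = 2000,
) -> Trajectory:
    """Integrate one voltage-clamp run and return a resampled trajectory."""
    mech = Mechanism(protocol.mechanism)
    flux_scale = params.s if mech == Mechanism.DIRECT else params.a
    relax = RelaxationSpec(protocol.psi0, protocol.psi1, protocol.tau0)
    u0, gate0 = clamp_initial_state(params, protocol.psi0, mech)

    def rhs(eta, y):
        u, gate = y
        nu = relaxed_conductance(eta, relax, params.ca_cond)
        du = flux_scale * _ca_current(u, gate, nu, protocol.psi1, params)
        if mech == Mechanism.DIRECT:
            dg = direct_gate_rhs(gate, max(u, 0.0), params.direct)
        else:
            dg = indirect_gate_rhs(gate, max(u, 0.0), params.indirect)
        return (du, dg)

    sol = solve_ivp(
        rhs,
        (0.0, protocol.duration),
        (u0, gate0),
        method="LSODA",
        rtol=params.rtol,
        atol=params.atol,
        dense_output=True,
    )
    if not sol.success:
        raise StiffnessError(
            f"clamp integration failed: {sol.message}; try tighter tolerances"
        )
    _log.info(
        "clamp %s psi %.4g->%.4g duration=%.4g steps=%d nfev=%d",
        mech.value, protocol.psi0, protocol.psi1, protocol.duration, sol.t.size, sol.nfev,
    )
    eta = np.linspace(0.0, protocol.duration, max(n_points, 2000))
    u, gate = sol.sol(eta)
    nu = relaxed_conductance(eta, relax, params.ca_cond)
    i_ca = _ca_current(u, gate, nu, protocol.psi1, params)
    if protocol.include_K:
        nuK = relaxed_conductance(eta, RelaxationSpec(protocol.psi0, protocol.psi1, protocol.tauK), params.k_cond)
        i_k = -params.b1 * nuK * (protocol.psi1 - params.psiK)
        i_k = np.broadcast_to(np.asarray(i_k, dtype=float), eta.shape).copy()
    else:
        i_k = np.zeros_like(eta)
    psi = np.full_like(eta, protocol.psi1)
    return Trajectory(eta=eta, u=u, gate=gate, i_ca=i_ca, i_k=i_k, i_full=i_ca + i_k, psi=psi)


def simulate_direct_clamp(protocol: ClampProtocol, params: ClampModelParams, **kw) -> Trajectory:
    """Clamp run under the direct Ca2+-binding inhibition mechanism."""
    return simulate_clamp(replace(protocol, mechanism=Mechanism.DIRECT), params, **kw)


def simulate_indirect_clamp(protocol: ClampProtocol, params: ClampModelParams, **kw) -> Trajectory:
    """Clamp run under the sensor-protein (indirect) inhibition mechanism."""
    return simulate_clamp(replace(protocol, mechanism=Mechanism.INDIRECT), params, **kw)


def clamp_full_current(
    trajectory: Trajectory,
    params: ClampModelParams,
    protocol: ClampProtocol,
) -> np.ndarray:
    """Full (Ca2+ + K+) clamp current recomputed from a stored trajectory."""
    relax = RelaxationSpec(protocol.psi0, protocol.psi1, protocol.tau0)
    nu = relaxed_conductance(trajectory.eta, relax, params.ca_cond)
    i_ca = _ca_current(trajectory.u, trajectory.gate, nu, protocol.psi1, params)
    nuK = relaxed_conductance(
        trajectory.eta, RelaxationSpec(protocol.psi0, protocol.psi1, protocol.tauK), params.k_cond
    )
    i_k = -params.b1 * nuK * (protocol.psi1 - params.psiK)
    return i_ca + i_k


def steady_state_u_of_psi(
    params: ClampModelParams,
    psi_grid: np.ndarray,
    mechanism: Mechanism = Mechanism.DIRECT,
) -> pd.DataFrame:
    """Clamp fixed point u(psi) along a potential grid.

    For the printed parameter sets the curve is bell-shaped over the
    depolarisation range: steady Ca2+ first rises with psi as the channels
    open, then falls as Ca2+-dependent inhibition and the shrinking driving
    force take over.
    """
    rows = []
    for psi in np.asarray(psi_grid, dtype=float):
        try:
            u, gate = clamp_initial_state(params, psi, mechanism)
            rows.append({"psi": psi, "u": u, "gate": gate, "ok": True})
        except InitialisationError:
            rows.append({"psi": psi, "u": np.nan, "gate": np.nan, "ok": False})
    return pd.DataFrame(rows)


def spike_metrics(trajectory: Trajectory, rel_prominence: float = 1e-4) -> SpikeMetrics:
    """Deterministic peak extraction from a post-step transient.

    Interior maxima are counted with a prominence filter of
    ``rel_prominence * (max-min)`` so integrator-level wiggle is ignored.
    """
    from scipy.signal import find_peaks

    u = trajectory.u
    baseline = float(u[0])
    peak_idx = int(np.argmax(u))
    peak = float(u[peak_idx])
    final = float(u[-1])
    span = float(np.max(u) - np.min(u))
    flat = span <= 1e-9 * max(abs(peak), 1e-30)
    if flat:
        n_extrema = 0
    else:
        peaks, _ = find_peaks(u, prominence=rel_prominence * span)
        n_extrema = int(len(peaks))
    amplitude = 0.0 if flat else max(peak - final, 0.0)
    return SpikeMetrics(
        baseline=baseline,
        peak=peak,
        amplitude=amplitude,
        peak_time=float(trajectory.eta[peak_idx]),
        final_ss=final,
        n_extrema=n_extrema,
    )


def scan_spike_amplitude(
    params: ClampModelParams,
    protocol: ClampProtocol,
    vary: str,
    grid: np.ndarray,
) -> pd.DataFrame:
    """Spike metrics along a grid of psi1, psi0 or uout values.

    ``vary`` is one of {"psi1", "psi0", "uout"}; all other protocol and
    model parameters are held fixed.
    """
    if vary not in {"psi1", "psi0", "uout"}:
        raise ValueError(f"vary must be psi1, psi0 or uout, got {vary!r}")
    rows = []
    for value in np.asarray(grid, dtype=float):
        p, proto = params, protocol
        if vary == "uout":
            p = replace(params, uout=float(value))
        else:
            proto = replace(protocol, **{vary: float(value)})
        try:
            m = spike_metrics(simulate_clamp(proto, p))
            rows.append(
                {
                    vary: value,
                    "baseline": m.baseline,
                    "peak": m.peak,
                    "amplitude": m.amplitude,
                    "peak_time": m.peak_time,
                    "final_ss": m.final_ss,
                    "n_extrema": m.n_extrema,
                    "ok": True,
                }
            )
        except (InitialisationError, StiffnessError) as exc:
            rows.append({vary: value, "ok": False, "error": str(exc)})
    return pd.DataFrame(rows)
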