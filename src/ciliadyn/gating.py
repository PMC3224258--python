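"""Ca2+-dependent channel gating, the extrusion pump and the cilium-to-body leak.

Two inhibition mechanisms close the ciliary Ca2+ channel as intraciliary
Ca2+ (u) rises:

* **direct** — Ca2+ binds the channel itself; the open fraction n obeys
  ``dn/deta = -k*n*u + (1-n)`` with steady state ``n = 1/(1+k*u)``
  (equivalently kC/(kC+u) with kC = 1/k).  Full inhibition at high u.
* **indirect** — Ca2+ first loads a sensor protein (abundance cac0 relative
  to its channel-binding constant) which then closes the channel; the open
  fraction c obeys ``dc/deta = -c*cac0*u/(kC+u) + (1-c)`` with steady state
  ``c = (kC+u)/(kC+(cac0+1)*u)``.  Inhibition saturates at the floor
  ``1/(cac0+1)`` — high Ca2+ never closes all channels.

Ca2+ is extruded by a saturating active-transport pump (Michaelis form
``u/(kA+u)``; an optional kinetic mode integrates the pump-cycle occupancy)
and can also leak from the cilium into the cell body down its Nernst
gradient through a voltage-gated base conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conductances import T_CONDUCTANCE, SigmoidConductanceParams, sigmoid_conductance

__all__ = [
    "DirectGatingParams",
    "IndirectGatingParams",
    "PumpParams",
    "CiliumBodyParams",
    "direct_open_fraction_ss",
    "direct_gate_rhs",
    "indirect_open_fraction_ss",
    "indirect_gate_rhs",
    "indirect_gate_analytic",
    "gate_time_constant",
    "pump_flux",
    "pump_cycle_rhs",
    "cilium_body_current",
    "LOG_FLOOR",
]

#: floor applied inside logarithm arguments only (never to the state itself)
LOG_FLOOR = 1e-12


def _check_u(u) -> None:
    if np.any(np.asarray(u) < 0):
        raise ValueError("non-dimensional Ca2+ u must be >= 0")


@dataclass(frozen=True)
class DirectGatingParams:
    """Direct inhibition: k = K_CaM / K_C, the association ratio."""

    k: float = 2.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"k must be > 0, got {self.k}")


@dataclass(frozen=True)
class IndirectGatingParams:
    """Indirect inhibition via a Ca2+-sensor protein.

    kC is the sensor/Ca2+ dissociation ratio (K_C / K_CaM); cac0 the sensor
    abundance relative to its channel dissociation constant (CaC0 / K_CC).
    """

    kC: float = 1.0
    cac0: float = 20.0

    def __post_init__(self) -> None:
        if not self.kC > 0:
            raise ValueError(f"kC must be > 0, got {self.kC}")
        if self.cac0 < 0:
            raise ValueError(f"cac0 must be >= 0, got {self.cac0}")


@dataclass(frozen=True)
class PumpParams:
    """Active Ca2+ extrusion.  kA is the half-saturation level; (ka, kb) the
    optional pump-cycle association/turnover rates for the kinetic mode."""

    kA: float = 1.0
    ka: float | None = None
    kb: float | None = None

    def __post_init__(self) -> None:
        if not self.kA > 0:
            raise ValueError(f"kA must be > 0, got {self.kA}")


@dataclass(frozen=True)
class CiliumBodyParams:
    """Cilium-to-cell-body Ca2+ leak.

    nu_t scales the base conductance (beta1/beta); psi_tr is the cilium-to-
    body potential difference (no printed value; default 0); ut the
    non-dimensional intracellular Ca2+ (default 0.025 = 0.1 uM, about one
    order of magnitude below typical intraciliary levels).
    """

    nu_t: float = 0.0
    psi_tr: float = 0.0
    ut: float = 0.025
    cond: SigmoidConductanceParams = field(default=T_CONDUCTANCE)

    def __post_init__(self) -> None:
        if not self.ut > 0:
            raise ValueError(f"ut must be > 0, got {self.ut}")


# ---------------------------------------------------------------------------
# direct mechanism

def direct_open_fraction_ss(u, p: DirectGatingParams):
    """Steady-state open fraction n(u) = 1 / (1 + k*u)."""
    _check_u(u)
    return 1.0 / (1.0 + p.k * np.asarray(u, dtype=float))


def direct_gate_rhs(n, u, p: DirectGatingParams):
    """dn/deta = -k*n*u + (1 - n); fixed point is direct_open_fraction_ss."""
    _check_u(u)
    return -p.k * n * np.asarray(u, dtype=float) + (1.0 - n)


# ---------------------------------------------------------------------------
# indirect mechanism

def indirect_open_fraction_ss(u, p: IndirectGatingParams):
    """Steady-state open fraction c(u) = (kC+u) / (kC + (cac0+1)*u)."""
    _check_u(u)
    u = np.asarray(u, dtype=float)
    return (p.kC + u) / (p.kC + (p.cac0 + 1.0) * u)


def indirect_gate_rhs(c, u, p: IndirectGatingParams):
    """dc/deta = -c*cac0*u/(kC+u) + (1 - c)."""
    _check_u(u)
    u = np.asarray(u, dtype=float)
    return -c * p.cac0 * u / (p.kC + u) + (1.0 - c)


def gate_time_constant(u1, p: IndirectGatingParams):
    """Relaxation time of the indirect gate after a Ca2+ step to u1.

    tau = (kC + u1) / (kC + (cac0+1)*u1); for cac0 >> 1 and u1 >> kC it
    approaches 1/(cac0+1) ~ 1/cac0.
    """
    _check_u(u1)
    u1 = np.asarray(u1, dtype=float)
    return (p.kC + u1) / (p.kC + (p.cac0 + 1.0) * u1)


def indirect_gate_analytic(eta, u0, u1, p: IndirectGatingParams):
    """Closed-form gate response to a Ca2+ step u0 -> u1 at eta = 0.

    c(eta) = c_inf - (c_inf - c_0) * exp(-eta/tau) with c_0, c_inf the
    steady fractions at u0, u1 and tau = gate_time_constant(u1).
    """
    c0 = indirect_open_fraction_ss(u0, p)
    cinf = indirect_open_fraction_ss(u1, p)
    tau = gate_time_constant(u1, p)
    return cinf - (cinf - c0) * np.exp(-np.asarray(eta, dtype=float) / tau)


# ---------------------------------------------------------------------------
# pump and leak

def pump_flux(u, p: PumpParams):
    """Quasi-steady pump extrusion flux u / (kA + u)."""
    _check_u(u)
    u = np.asarray(u, dtype=float)
    out = u / (p.kA + u)
    return float(out) if out.ndim == 0 else out


def pump_cycle_rhs(omega, u, p: PumpParams):
    """Kinetic pump mode: occupancy dynamics d(omega)/deta = ka*u*(1-omega) - kb*omega."""
    if p.ka is None or p.kb is None:
        raise ValueError("kinetic pump mode requires ka and kb")
    _check_u(u)
    return p.ka * np.asarray(u, dtype=float) * (1.0 - omega) - p.kb * omega


def cilium_body_current(u, p: CiliumBodyParams, psi, cond: SigmoidConductanceParams | None = None):
    """Ca2+ leak from the cilium into the cell body.

    nu_t * nu_t(psi) * (psi_tr - 0.5*ln(u/ut)): vanishes exactly at the
    Nernst balance psi_tr = 0.5*ln(u/ut).  u must be positive (log
    singularity at zero).
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("cilium-to-body current requires u > 0")
    if cond is None:
        cond = p.cond
    gate = sigmoid_conductance(psi, cond)
    out = p.nu_t * gate * (p.psi_tr - 0.5 * np.log(u / p.ut))
    return float(out) if np.ndim(out) == 0 else out
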