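"""Voltage-dependent channel conductances.

Every channel family in the model (Ca2+, K+, hyperpolarisation-activated,
cilium-to-body) shares one normalised steady-state conductance shape,

    nu(psi) = exp(alpha * (psi + d)) / (lambda + exp(alpha * (psi + d))),

a bounded sigmoid in the non-dimensional potential psi.  ``alpha`` sets the
steepness and orientation (alpha > 0: activated by depolarisation, alpha < 0:
activated by hyperpolarisation), ``d`` shifts the midpoint and ``lambda``
scales the half-activation level.

Under a voltage-clamp step psi0 -> psi1 the conductance does not jump but
relaxes exponentially between its two steady values with a characteristic
time tau (tau0 for the Ca2+ family, tauK for K+).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SigmoidConductanceParams",
    "RelaxationSpec",
    "sigmoid_conductance",
    "relaxed_conductance",
    "CA_CONDUCTANCE",
    "K_CONDUCTANCE",
    "H_CONDUCTANCE",
    "T_CONDUCTANCE",
]

# beyond this the exponential saturates at double precision anyway
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class SigmoidConductanceParams:
    """(alpha, d, lambda) triple defining one channel family's voltage curve."""

    alpha: float
    d: float
    lam: float

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lambda must be > 0 for a bounded sigmoid, got {self.lam}")


@dataclass(frozen=True)
class RelaxationSpec:
    """Exponential conductance relaxation between two clamp levels.

    psi0/psi1 are the holding and step potentials; tau is the relaxation
    time constant in non-dimensional time.
    """

    psi0: float
    psi1: float
    tau: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"relaxation time constant must be > 0, got {self.tau}")


def sigmoid_conductance(psi, p: SigmoidConductanceParams):
    """Normalised steady-state conductance nu(psi) in (0, 1).

    Overflow-guarded: for very large |alpha*(psi+d)| the exact asymptote
    (0 or 1) is returned rather than NaN.
    """
    x = np.clip(p.alpha * (np.asarray(psi, dtype=float) + p.d), -_EXP_CLIP, _EXP_CLIP)
    # compute in the numerically stable branch of the logistic form
    out = np.where(
        x > 0,
        1.0 / (1.0 + p.lam * np.exp(-x)),
        np.exp(x) / (p.lam + np.exp(x)),
    )
    if np.isscalar(psi) or np.ndim(psi) == 0:
        return float(out)
    return out


def relaxed_conductance(eta, r: RelaxationSpec, p: SigmoidConductanceParams):
    """Conductance at time eta after a clamp step psi0 -> psi1.

    nu(psi1) - (nu(psi1) - nu(psi0)) * exp(-eta / tau): starts at the
    psi0 steady value and relaxes exponentially to the psi1 value.
    """
    nu0 = sigmoid_conductance(r.psi0, p)
    nu1 = sigmoid_conductance(r.psi1, p)
    out = nu1 - (nu1 - nu0) * np.exp(-np.asarray(eta, dtype=float) / r.tau)
    if np.isscalar(eta) or np.ndim(eta) == 0:
        return float(out)
    return out


#: Ca2+ channel conductance vs psi (Paramecium voltage-clamp fit).
CA_CONDUCTANCE = SigmoidConductanceParams(alpha=4.0, d=0.4, lam=0.5)

#: K+ channel conductance vs psi (fit to the fast depolarised-branch current).
K_CONDUCTANCE = SigmoidConductanceParams(alpha=0.5, d=0.5, lam=0.005)

#: Hyperpolarisation-activated conductance.  The printed steepness magnitude
#: is 4; the negative sign encodes the hyperpolarisation orientation under
#: this package's psi convention (depolarisation = increasing psi).
H_CONDUCTANCE = SigmoidConductanceParams(alpha=-4.0, d=1.0, lam=5.0)

#: Cilium-to-body conductance; no printed triple, mirrors the
#: hyperpolarisation family (opens as the membrane hyperpolarises).
T_CONDUCTANCE = SigmoidConductanceParams(alpha=-4.0, d=1.0, lam=5.0)
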