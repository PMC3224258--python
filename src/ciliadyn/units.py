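"""Conversion between dimensional and non-dimensional model variables.

The model is formulated entirely in non-dimensional variables:

* ``u = [Ca2+] / K_CaM`` — intraciliary calcium scaled by the calmodulin
  dissociation constant (K_CaM = 4 uM by default), and
* ``psi = F * V / (R*T)`` — membrane potential scaled by the thermal
  voltage.  The conversion constant is carried as the ratio R*T/F and is
  *negative* (−0.025 V) in the convention adopted here, so that the resting
  potential V0 = 30 mV maps to psi0 = −1.2 and depolarisation corresponds
  to *increasing* psi.

All simulator internals are non-dimensional; these helpers are used only at
I/O boundaries (CLI flags, config files, reporting).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PhysicalConstants",
    "InvalidConstantsError",
    "nondim_potential",
    "dim_potential",
    "nondim_calcium",
    "dim_calcium",
]


class InvalidConstantsError(ValueError):
    """Raised when a conversion constant makes the mapping singular."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants linking dimensional and non-dimensional quantities.

    Parameters
    ----------
    K_CaM : float
        Calmodulin Ca2+ dissociation constant in uM; the concentration
        scale of ``u``.  Must be positive.
    RT_over_F : float
        Thermal voltage R*T/F in volts.  The default −0.025 V is the only
        sign that maps the printed (psi, V) pairs onto each other
        consistently.  Must be non-zero.
    z : int
        Ion charge; 2 for Ca2+.
    """

    K_CaM: float = 4.0
    RT_over_F: float = -0.025
    z: int = 2

    def __post_init__(self) -> None:
        if not self.K_CaM > 0:
            raise InvalidConstantsError(f"K_CaM must be > 0, got {self.K_CaM}")
        if self.RT_over_F == 0:
            raise InvalidConstantsError("RT_over_F must be non-zero")

    @property
    def rt_over_f_mV(self) -> float:
        return self.RT_over_F * 1000.0


DEFAULT_CONSTANTS = PhysicalConstants()


def nondim_potential(V_mV: float, c: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Membrane potential in mV -> non-dimensional psi = V / (RT/F)."""
    return V_mV / c.rt_over_f_mV


def dim_potential(psi: float, c: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Non-dimensional psi -> membrane potential in mV (inverse of above)."""
    return psi * c.rt_over_f_mV


def nondim_calcium(ca_uM: float, c: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Ca2+ concentration in uM -> non-dimensional u = Ca / K_CaM."""
    if ca_uM < 0:
        raise ValueError(f"Ca2+ concentration must be >= 0, got {ca_uM}")
    return ca_uM / c.K_CaM


def dim_calcium(u: float, c: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Non-dimensional u -> Ca2+ concentration in uM."""
    if u < 0:
        raise ValueError(f"non-dimensional Ca2+ must be >= 0, got {u}")
    return u * c.K_CaM
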