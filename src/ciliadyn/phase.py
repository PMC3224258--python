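"""Phase-plane analysis of the coupled Ca2+ / membrane-potential system.

Tools to trace nullclines, locate fixed points with their linear stability,
detect limit cycles, and classify the dynamic regime of the free-membrane
model as the inward current I0 varies:

* ``single_spike`` — a unique stable rest state on the left (low-u) branch
  of the N-shaped psi-nullcline; switching the current on elicits one
  Ca2+/potential pulse followed by a return to rest;
* ``oscillation`` — the nullclines intersect on the unstable middle branch
  and a limit cycle carries sustained Ca2+ and potential oscillations;
* ``switch`` — the intersection has moved to the right (high-u) branch:
  the system steps to an elevated steady Ca2+ / potential level;
* ``multivibrator`` — with the hyperpolarisation-activated current active,
  the rest state is unique and stable at every inward current, and every
  step of I0 (of either sign) elicits exactly one spike.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root
from scipy.signal import find_peaks

from .free_membrane import (
    CoupledModelParams,
    CurrentSchedule,
    Variant,
    coupled_rhs,
    simulate_free,
)

__all__ = [
    "Stability",
    "RegimeMode",
    "Nullclines",
    "FixedPoint",
    "LimitCycle",
    "RegimeReport",
    "DEFAULT_WINDOW",
    "compute_nullclines",
    "find_fixed_points",
    "resting_state",
    "detect_limit_cycle",
    "classify_regime",
    "regime_scan",
]

#: default analysis window: u in [0.01, 10] (0.04-40 uM), psi in [-2, 1]
DEFAULT_WINDOW = ((0.01, 10.0), (-2.0, 1.0))


class Stability(str, enum.Enum):
    STABLE_NODE = "stable_node"
    STABLE_FOCUS = "stable_focus"
    UNSTABLE_FOCUS = "unstable_focus"
    UNSTABLE_NODE = "unstable_node"
    SADDLE = "saddle"

    @property
    def is_stable(self) -> bool:
        return self in (Stability.STABLE_NODE, Stability.STABLE_FOCUS)


class RegimeMode(str, enum.Enum):
    SINGLE_SPIKE = "single_spike"
    OSCILLATION = "oscillation"
    SWITCH = "switch"
    MULTIVIBRATOR = "multivibrator"
    INDETERMINATE = "indeterminate"


@dataclass
class Nullclines:
    """Sampled du/deta = 0 and dpsi/deta = 0 zero sets.

    Curves are (u, psi) point arrays; ``psi_turning_points`` are the
    interior extrema of u along the psi-nullcline (the folds of the N);
    ``gaps`` record grid lines with no zero crossing.
    """

    u_nullcline: np.ndarray
    psi_nullcline: np.ndarray
    window: tuple[tuple[float, float], tuple[float, float]]
    psi_turning_points: np.ndarray
    gaps: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FixedPoint:
    u: float
    psi: float
    eigenvalues: tuple[complex, complex]
    stability: Stability


@dataclass(frozen=True)
class LimitCycle:
    period: float
    u_amplitude: float
    psi_amplitude: float


@dataclass
class RegimeReport:
    mode: RegimeMode
    fixed_points: list[FixedPoint]
    limit_cycle: LimitCycle | None = None
    diagnostics: dict = field(default_factory=dict)


def _rhs_parts(params: CoupledModelParams, variant, I0):
    def f_u(u, psi):
        return coupled_rhs((u, psi), params, variant, I0=I0)[0]

    def f_psi(u, psi):
        return coupled_rhs((u, psi), params, variant, I0=I0)[1]

    return f_u, f_psi


def _scan_roots(f, grid, n_sub=801):
    """All roots of a 1-D function along ``grid`` by sign scan + bisection."""
    vals = f(grid)
    roots = []
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    for i in idx:
        roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-13, rtol=8.9e-16))
    for i in np.nonzero(vals == 0.0)[0]:
        roots.append(float(grid[i]))
    return sorted(roots)


def compute_nullclines(
    params: CoupledModelParams,
    variant: Variant | str = Variant.BASE,
    window=DEFAULT_WINDOW,
    resolution: int = 241,
    I0: float | None = None,
    turning_prominence: float = 0.01,
) -> Nullclines:
    """Trace both nullclines by per-grid-line root finding.

    The u-nullcline is solved for psi on each of ``resolution`` u-lines
    (log-spaced); the psi-nullcline for u on each psi-line.  Lines without
    a zero crossing are recorded under ``gaps``, never interpolated.
    """
    if I0 is None:
        I0 = params.I0
    variant = Variant(variant)
    (u_lo, u_hi), (psi_lo, psi_hi) = window
    f_u, f_psi = _rhs_parts(params, variant, I0)

    u_lines = np.geomspace(u_lo, u_hi, resolution)
    psi_dense = np.linspace(psi_lo, psi_hi, 4 * resolution)
    pts_u, gaps_u = [], []
    for u in u_lines:
        roots = _scan_roots(lambda p, _u=u: f_u(_u, p), psi_dense)
        if roots:
            pts_u.extend((u, p) for p in roots)
        else:
            gaps_u.append(u)

    psi_lines = np.linspace(psi_lo, psi_hi, resolution)
    lnu_dense = np.log(np.geomspace(u_lo, u_hi, 4 * resolution))
    pts_psi, gaps_psi = [], []
    primary_u = np.full(resolution, np.nan)
    for j, psi in enumerate(psi_lines):
        roots = _scan_roots(lambda x, _p=psi: f_psi(np.exp(x), _p), lnu_dense)
        if roots:
            us = [float(np.exp(r)) for r in roots]
            pts_psi.extend((uu, psi) for uu in us)
            primary_u[j] = us[0]
        else:
            gaps_psi.append(psi)

    # folds of the N: interior extrema of u along the psi-nullcline
    turning = []
    valid = ~np.isnan(primary_u)
    if valid.sum() >= 5:
        pv = psi_lines[valid]
        uv = np.log(primary_u[valid])  # extrema in log-u: scale-free prominence
        span = float(uv.max() - uv.min())
        if span > 0:
            prom = turning_prominence * span
            for arr, s in ((uv, 1.0), (-uv, -1.0)):
                pk, _ = find_peaks(arr, prominence=prom)
                turning.extend((float(np.exp(s * arr[i] if s > 0 else -arr[i])), float(pv[i])) for i in pk)
    turning.sort(key=lambda t: t[1])

    return Nullclines(
        u_nullcline=np.array(pts_u) if pts_u else np.empty((0, 2)),
        psi_nullcline=np.array(pts_psi) if pts_psi else np.empty((0, 2)),
        window=window,
        psi_turning_points=np.array(turning) if turning else np.empty((0, 2)),
        gaps={"u_nullcline": gaps_u, "psi_nullcline": gaps_psi},
    )


def _jacobian(params, variant, I0, u, psi):
    hu = 1e-7 * max(u, 1e-3)
    hp = 1e-7 * max(abs(psi), 1.0)
    J = np.empty((2, 2))
    for col, (du_, dp_) in enumerate(((hu, 0.0), (0.0, hp))):
        fp = coupled_rhs((u + du_, psi + dp_), params, variant, I0=I0)
        fm = coupled_rhs((u - du_, psi - dp_), params, variant, I0=I0)
        h = hu if col == 0 else hp
        J[0, col] = (fp[0] - fm[0]) / (2 * h)
        J[1, col] = (fp[1] - fm[1]) / (2 * h)
    return J


def _classify_eigs(eigs) -> Stability:
    if np.real(eigs[0]) * np.real(eigs[1]) < 0 and np.all(np.isreal(eigs)):
        return Stability.SADDLE
    stable = max(np.real(eigs)) < 0
    focus = np.any(np.abs(np.imag(eigs)) > 1e-12)
    if stable:
        return Stability.STABLE_FOCUS if focus else Stability.STABLE_NODE
    return Stability.UNSTABLE_FOCUS if focus else Stability.UNSTABLE_NODE


def find_fixed_points(
    params: CoupledModelParams,
    variant: Variant | str = Variant.BASE,
    window=DEFAULT_WINDOW,
    I0: float | None = None,
    grid: int = 200,
    residual_tol: float = 1e-10,
) -> list[FixedPoint]:
    """All roots of the coupled RHS inside ``window``, with stability labels.

    Candidate cells come from a sign-change scan of both RHS components on
    a ``grid`` x ``grid`` mesh (log-spaced in u); each candidate seeds a
    Newton-type root solve in (ln u, psi), and converged roots are
    deduplicated and classified by the eigenvalues of the numerical
    Jacobian.
    """
    if I0 is None:
        I0 = params.I0
    variant = Variant(variant)
    (u_lo, u_hi), (psi_lo, psi_hi) = window
    uu = np.geomspace(u_lo, u_hi, grid)
    pp = np.linspace(psi_lo, psi_hi, grid)
    U, P = np.meshgrid(uu, pp, indexing="ij")
    FU, FP = coupled_rhs((U, P), params, variant, I0=I0)
    su, sp = np.sign(FU), np.sign(FP)

    def cell_changes(s):
        c = np.zeros((grid - 1, grid - 1), dtype=bool)
        corners = (s[:-1, :-1], s[1:, :-1], s[:-1, 1:], s[1:, 1:])
        mn = np.minimum.reduce(corners)
        mx = np.maximum.reduce(corners)
        c |= mn < mx
        return c

    cand = cell_changes(su) & cell_changes(sp)
    ci, cj = np.nonzero(cand)

    def G(x):
        return np.array(coupled_rhs((np.exp(x[0]), x[1]), params, variant, I0=I0))

    found: list[FixedPoint] = []
    for i, j in zip(ci, cj):
        x0 = np.array([np.log(np.sqrt(uu[i] * uu[i + 1])), 0.5 * (pp[j] + pp[j + 1])])
        sol = root(G, x0, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        u_r, psi_r = float(np.exp(sol.x[0])), float(sol.x[1])
        res = np.max(np.abs(G(sol.x)))
        if res > residual_tol:
            continue
        if not (u_lo * 0.99 <= u_r <= u_hi * 1.01 and psi_lo - 0.01 <= psi_r <= psi_hi + 0.01):
            continue
        if any(
            abs(np.log(u_r / f.u)) < 1e-6 and abs(psi_r - f.psi) < 1e-6 for f in found
        ):
            continue
        eigs = np.linalg.eigvals(_jacobian(params, variant, I0, u_r, psi_r))
        found.append(
            FixedPoint(u=u_r, psi=psi_r, eigenvalues=(complex(eigs[0]), complex(eigs[1])), stability=_classify_eigs(eigs))
        )
    found.sort(key=lambda f: f.u)
    return found


def resting_state(
    params: CoupledModelParams,
    variant: Variant | str = Variant.BASE,
    I0: float = 0.0,
    window=((1e-4, 50.0), (-3.0, 1.5)),
) -> tuple[float, float]:
    """Resting fixed point at the given inward current.

    Prefers a stable fixed point (lowest u); falls back to the lowest-u
    fixed point when none is stable (the oscillatory regime).
    """
    fps = find_fixed_points(params, variant, window=window, I0=I0)
    if not fps:
        raise RuntimeError(f"no fixed point found in {window} at I0={I0}")
    stable = [f for f in fps if f.stability.is_stable]
    pick = stable[0] if stable else fps[0]
    return pick.u, pick.psi


def detect_limit_cycle(
    params: CoupledModelParams,
    variant: Variant | str = Variant.BASE,
    init: tuple[float, float] | None = None,
    horizon: float = 400.0,
    I0: float | None = None,
    transient_fraction: float = 0.5,
    period_rtol: float = 0.01,
    min_amplitude: float = 1e-3,
) -> LimitCycle | None:
    """Detect sustained oscillation by successive-peak comparison.

    Integrates for ``horizon``, discards the transient fraction, and
    requires at least three u-peaks whose last two inter-peak intervals and
    heights agree to ``period_rtol``; returns the period and the u/psi
    amplitudes of the final cycle, or None.
    """
    if I0 is None:
        I0 = params.I0
    traj = simulate_free(
        params,
        schedule=CurrentSchedule.constant(I0),
        init=init,
        duration=horizon,
        variant=variant,
        n_points=8000,
    )
    n0 = int(len(traj.eta) * transient_fraction)
    eta, u, psi = traj.eta[n0:], traj.u[n0:], traj.psi[n0:]
    span = float(np.max(u) - np.min(u))
    if span < min_amplitude:
        return None
    peaks, _ = find_peaks(u, prominence=0.05 * span)
    troughs, _ = find_peaks(-u, prominence=0.05 * span)
    if len(peaks) < 3 or len(troughs) < 2:
        return None
    periods = np.diff(eta[peaks])
    if len(periods) < 2:
        return None
    p1, p2 = periods[-2], periods[-1]
    if abs(p2 - p1) > period_rtol * p2:
        return None
    h1, h2 = u[peaks[-2]], u[peaks[-1]]
    amp = float(u[peaks[-1]] - np.min(u[troughs[-2]:]))
    if amp < min_amplitude:
        return None
    if abs(h2 - h1) > period_rtol * max(amp, abs(h2)):
        return None
    last = eta >= eta[peaks[-2]]
    psi_amp = float(np.max(psi[last]) - np.min(psi[last]))
    return LimitCycle(period=float(p2), u_amplitude=amp, psi_amplitude=psi_amp)


def _branch_of(fp: FixedPoint, nc: Nullclines) -> str:
    """left / middle / right branch of the N-shaped psi-nullcline."""
    tp = nc.psi_turning_points
    if len(tp) < 2:
        return "unbranched"
    psi_folds = np.sort(tp[:, 1])
    lo, hi = psi_folds[0], psi_folds[-1]
    if fp.psi < lo:
        return "left"
    if fp.psi > hi:
        return "right"
    return "middle"


def _count_pulses(traj, baseline_u, fp_u, spike_factor=3.0, return_band=0.05):
    """Pulses: u exceeds baseline by spike_factor, then returns near the fixed point."""
    u = traj.u
    span = float(np.max(u) - np.min(u))
    if span <= 0:
        return 0, True
    peaks, _ = find_peaks(u, prominence=0.1 * span)
    thresh = spike_factor * baseline_u
    big = [p for p in peaks if u[p] >= thresh]
    if np.max(u) >= thresh and len(big) == 0 and np.argmax(u) in (0, len(u) - 1):
        big = [int(np.argmax(u))]
    returned = abs(u[-1] - fp_u) <= return_band * max(fp_u, 1e-12)
    return len(big), returned


#: wider state-space window used when classifying regimes: fixed points of
#: the switch mode sit above the nullcline-plot window
ANALYSIS_WINDOW = ((1e-4, 100.0), (-4.0, 2.0))


def classify_regime(
    params: CoupledModelParams,
    variant: Variant | str = Variant.BASE,
    I0: float = 0.0,
    window=ANALYSIS_WINDOW,
    horizon: float = 400.0,
    probe_steps=(-1.0, -0.3, 0.3, 1.0),
    spike_factor: float = 3.0,
    return_band: float = 0.05,
    switch_ratio: float = 3.0,
) -> RegimeReport:
    """Classify the dynamic regime of the system run at inward current I0.

    The reference experiment matches the switch-on protocol: the system
    rests at I0 = 0, the current is stepped to I0, and the transient plus
    the phase-plane geometry decide the mode.  For the hyper/full variants
    a probe set of additional I0 steps (both signs) tests the monostable-
    multivibrator property.
    """
    variant = Variant(variant)
    fps = find_fixed_points(params, variant, window=window, I0=I0)
    nc = compute_nullclines(params, variant, window=window, I0=I0, resolution=161)
    stable = [f for f in fps if f.stability.is_stable]
    diagnostics: dict = {
        "I0": I0,
        "n_fixed_points": len(fps),
        "n_stable": len(stable),
        "branches": [_branch_of(f, nc) for f in fps],
    }

    try:
        rest0 = resting_state(params, variant, I0=0.0)
    except RuntimeError:
        rest0 = None

    lc = None
    if not stable or any(_branch_of(f, nc) == "middle" for f in fps):
        lc = detect_limit_cycle(params, variant, init=rest0, horizon=horizon, I0=I0)
    if lc is not None:
        return RegimeReport(RegimeMode.OSCILLATION, fps, lc, diagnostics)

    if not stable:
        diagnostics["reason"] = "no stable fixed point and no limit cycle detected"
        return RegimeReport(RegimeMode.INDETERMINATE, fps, None, diagnostics)

    target = stable[0]
    if variant in (Variant.HYPER, Variant.FULL):
        ok = len(fps) == 1 and target.stability.is_stable
        pulse_counts = []
        if ok:
            for delta in probe_steps:
                fps_d = find_fixed_points(params, variant, window=window, I0=I0 + delta)
                stable_d = [f for f in fps_d if f.stability.is_stable]
                if len(fps_d) != 1 or not stable_d:
                    ok = False
                    break
                traj = simulate_free(
                    params,
                    schedule=CurrentSchedule.constant(I0 + delta),
                    init=(target.u, target.psi),
                    duration=horizon,
                    variant=variant,
                )
                n_p, returned = _count_pulses(
                    traj, target.u, stable_d[0].u, spike_factor, return_band
                )
                pulse_counts.append(n_p)
                if n_p != 1 or not returned:
                    ok = False
                    break
        diagnostics["probe_pulse_counts"] = pulse_counts
        if ok:
            return RegimeReport(RegimeMode.MULTIVIBRATOR, fps, None, diagnostics)

    branch = _branch_of(target, nc)
    u_ratio = target.u / rest0[0] if rest0 is not None else np.inf
    diagnostics["u_ratio_vs_rest"] = u_ratio
    if branch == "right" or u_ratio >= switch_ratio:
        return RegimeReport(RegimeMode.SWITCH, fps, None, diagnostics)
    if rest0 is not None:
        traj = simulate_free(
            params,
            schedule=CurrentSchedule.constant(I0),
            init=rest0,
            duration=horizon,
            variant=variant,
        )
        n_p, returned = _count_pulses(traj, rest0[0], target.u, spike_factor, return_band)
        diagnostics["switch_on_pulses"] = n_p
        diagnostics["returned"] = returned
        if returned:
            return RegimeReport(RegimeMode.SINGLE_SPIKE, fps, None, diagnostics)
    diagnostics["reason"] = f"stable point on {branch} branch without clean return"
    return RegimeReport(RegimeMode.INDETERMINATE, fps, None, diagnostics)


def regime_scan(
    params: CoupledModelParams,
    variant: Variant | str = Variant.BASE,
    I0_grid=np.linspace(0.0, 1.2, 13),
    **kw,
) -> pd.DataFrame:
    """Regime classification along an ordered inward-current grid."""
    rows = []
    for I0 in np.asarray(I0_grid, dtype=float):
        rep = classify_regime(params, variant, I0=I0, **kw)
        stable = [f for f in rep.fixed_points if f.stability.is_stable]
        pick = stable[0] if stable else (rep.fixed_points[0] if rep.fixed_points else None)
        rows.append(
            {
                "I0": I0,
                "mode": rep.mode.value,
                "n_fixed_points": len(rep.fixed_points),
                "u_ss": pick.u if pick else np.nan,
                "psi_ss": pick.psi if pick else np.nan,
                "period": rep.limit_cycle.period if rep.limit_cycle else np.nan,
            }
        )
    return pd.DataFrame(rows)
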