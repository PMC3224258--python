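# Methods

## The model

`ciliadyn` simulates the electro-chemical excitability of a motile cilium:
the interplay between intraciliary free calcium, voltage-gated Ca²⁺ and K⁺
currents across the ciliary membrane, an active Ca²⁺ extrusion pump, and the
membrane potential itself. The cilium is treated as a well-mixed compartment
separate from the cell body, with its own Ca²⁺ level and membrane potential.

All computation is non-dimensional. Calcium is scaled by the calmodulin
dissociation constant, `u = [Ca²⁺]/K_CaM` with `K_CaM = 4 µM`; potential by
the thermal voltage, `ψ = F·V/(R·T)` with `R·T/F = −0.025 V`. The negative
conversion constant is deliberate: it is the only sign that maps the
published (ψ, V) value pairs onto each other consistently (ψ₀ = −1.2 ↔
V₀ = 30 mV). Under this convention depolarisation means *increasing* ψ.
Conversion happens only at I/O boundaries (`units` module, CLI flags).

### Channel conductances

Every channel family shares one normalised voltage dependence,

    ν(ψ) = exp(α(ψ+d)) / (λ + exp(α(ψ+d))),

a bounded sigmoid: α sets steepness and orientation, d the midpoint shift, λ
the half-activation scale. Defaults: Ca²⁺ (4, 0.4, 0.5); K⁺ (0.5, 0.5,
0.005) — effectively fully open everywhere above ψ ≈ −10, so the K⁺ current
is nearly ohmic in the physiological window; hyperpolarisation-activated and
cilium-to-body families (−4, 1, 5). The published steepness magnitude for
the hyperpolarisation family is 4; the negative sign is this package's
encoding of its stated orientation ("activated by hyperpolarisation") under
the ψ-increases-with-depolarisation convention — with α = +4 the conductance
would open on depolarisation, contradicting both its name and its dynamical
role. Evaluation is overflow-guarded (asymptote returned beyond |x| = 700).

Under a voltage-clamp step ψ₀→ψ₁ a conductance relaxes exponentially between
its steady values with time constant τ₀ (Ca²⁺, default 0.02) or τ_K (K⁺,
default 0.02; no published value — taken equal to τ₀ since both currents are
described as activating on the same fast, ~10 ms, timescale).

### Ca²⁺-dependent channel inhibition

Two mechanisms close the Ca²⁺ channel as `u` rises:

* **direct** (Ca²⁺ binds the channel): `dn/dη = −k·n·u + (1−n)`,
  steady state `n = 1/(1+k·u)`, complete inhibition at high Ca²⁺; `k = 2`.
* **indirect** (via a Ca²⁺-sensor protein of relative abundance `cac0`):
  `dc/dη = −c·cac0·u/(kC+u) + (1−c)`, steady state
  `c = (kC+u)/(kC+(cac0+1)·u)` with floor `1/(cac0+1)` — high Ca²⁺ never
  closes every channel; `kC = 1`, `cac0 ∈ {5,…,100}` (clamp figures) or 20
  (coupled system). The step response is exactly exponential with time
  constant `(kC+u₁)/(kC+(cac0+1)·u₁)`; the closed form is verified against
  direct ODE integration in the tests.

Extrusion is a saturating pump `u/(kA+u)` (`kA = 1`), used quasi-statically;
a kinetic pump-cycle mode (`dω/dη = ka·u(1−ω) − kb·ω`) is available but off
by default, matching the assumption that pump kinetics are fast.

### Voltage clamp

With ψ held, the state is (u, gate):

    du/dη = S·( −b·gate·ν_rel(η)·(ψ₁ − 0.5·ln(u_out/u)) − u/(kA+u) ),

S = s = 0.5 (direct) or a = 4 (indirect), b = 2, u_out = 1000 (4 mM
external Ca²⁺). The bracket is the reported signed Ca²⁺ current; the
optional K⁺ term is `−b₁·ν_K-rel·(ψ₁ − ψ_K)` with b₁ = 1 and ψ_K = −0.4
(10 mV): because the Ca²⁺ current vanishes identically at any clamp steady
state, the full steady current then crosses zero exactly at 10 mV, the
reported zero-crossing of the measured current. Initial conditions are the
clamp fixed point at ψ₀, found by bracketed root solving (bracket
(0, u_out·e^(−2ψ₀)], residual < 1e−10 after a Newton polish).

A depolarising step produces a biphasic current: a fast inward surge as the
conductance relaxes (τ₀), then decay as Ca²⁺-dependent inhibition builds.
Whether *u itself* overshoots (a Ca²⁺ spike) depends on a timescale race: an
interior maximum requires u to outrun the gate, roughly
`S·|i_Ca| > 1 + k·u`. At the published S values the gate is the faster
variable and u rises monotonically to its new steady level; spikes appear
for S ≳ 5. The test suite asserts the spike phenomenology at the published
values and therefore documents this discrepancy rather than hiding it (see
Known limitations).

The steady-state curve u(ψ) is bell-shaped over the depolarisation range:
steady Ca²⁺ first rises as channels open, then falls as inhibition deepens
and the driving force shrinks.

### Free membrane

Without the clamp, conductances and the indirect gate are taken quasi-steady
(they relax much faster than u or ψ) and the system reduces to two coupled
ODEs:

    du/dη = s·( I_Ca(u,ψ) − u/(kA+u) ),
    dψ/dη = ρ·( I_Ca(u,ψ) + I_K(u,ψ) + I₀ ),

    I_Ca = −b·(c(u)·ν(ψ) + ν_Ca_st)·(ψ − 0.5·ln(u_out/u)),
    I_K  = −b₁·(ν_K(ψ) + ν_K_st)·(ψ − ψ_K),

with b = 8, cac0 = 20, ρ = 10, s = 0.5, background conductances
ν_Ca_st = ν_K_st = 0.01, and I₀ a prescribed inward current. Signs are
normalised so that (a) depolarisation activates the Ca²⁺/K⁺ conductances,
(b) I_Ca is inward/depolarising, I_K repolarising above ψ_K, and (c) larger
I₀ raises the ψ fixed point — the only orientation that yields the
documented regime sequence. ψ is the fast variable (ρ/s = 20): a
relaxation-oscillator structure with an N-shaped ψ-nullcline and a monotone
u-nullcline.

**K⁺ reversal in the coupled system.** The clamp-derived ψ_K = −0.4 cannot
be used here: below ψ = −0.4 both currents would be depolarising, leaving no
low-Ca²⁺ rest state (the unique fixed point sits at u ≈ 9.5, ψ ≈ +0.5, with
no excitable geometry). The coupled system instead defaults to ψ_K = −1.8
(45 mV hyperpolarised of zero — a physiological K⁺ reversal below rest),
which places the I₀ = 0 rest at ψ ≈ −1.24, i.e. at the published resting
potential, and reproduces the full documented phase-plane story: the
ψ-nullcline is N-shaped with folds at ψ ≈ −1.11 and −0.38, and as I₀ grows
the intersection moves from the left descending branch (stable; single
spike) through the middle ascending branch (unstable; limit cycle) to the
right descending branch (stable again; switch to an elevated level). The two
ψ_K defaults are both config-exposed; the tension between the 10 mV
zero-crossing statement and the coupled-system behaviour is inherent to the
source material.

Variants: `hyper` adds the hyperpolarisation-activated Ca²⁺ conductance
−v_Cah·ν_h(ψ) to the Ca²⁺ branch of the ψ equation and (optionally) a
Ca²⁺-dependent K⁺ conductance v_Kca·ν_K(ψ)·u/(1+u) — the latter has no
published functional form, so a first-order saturating Ca²⁺ activation was
chosen; `full` adds the cilium-to-body leak
v_Cat·ν_t(ψ)·(ψ_tr − 0.5·ln(u/u_t)) to the u equation. Each variant reduces
bitwise to the previous one when its scale is zero. The intracellular level
u_t defaults to 0.025 (0.1 µM, an order of magnitude below typical
intraciliary levels); ψ_tr defaults to 0. The ψ-equation log term uses
ln(u_out/u) in both equations for self-consistency; a config flag
(`psi_log_uses_ut`) restores the printed composite form ln(u_out/u_t).

### Phase-plane analysis

Nullclines are traced by per-grid-line sign-scan plus Brent root finding
(never interpolated across gaps; lines without a crossing are recorded as
gaps). Turning points of the ψ-nullcline (the folds of the N) are interior
extrema of log-u along the curve with a 1% relative prominence filter.
Fixed points come from sign-change candidate cells on a 200×200 mesh
(log-spaced in u) refined by a Newton-type solver in (ln u, ψ), deduplicated,
residual-checked (< 1e−10) and classified by the eigenvalues of a central
finite-difference Jacobian (saddle ⇔ negative determinant; focus ⇔ complex
pair). Limit cycles are detected by successive-peak comparison after
discarding a transient fraction (default 50%): at least three u-peaks whose
last two periods and heights agree to 1% and whose amplitude exceeds 1e−3.

Regime classification runs the switch-on experiment (rest at I₀ = 0, step to
the probe I₀): oscillation if a limit cycle is found; switch if the stable
fixed point sits on the right branch or its u exceeds 3× the reference rest;
single spike if the trajectory returns to a left/middle-branch stable point
(within 5%); multivibrator (hyper/full variants) if the fixed point is
unique and stable at the probe I₀ and at every probe step, and each step of
either sign elicits exactly one pulse (pulse: u exceeds baseline 3× and
returns to within 5% of the fixed point). Unclassifiable cases return
`indeterminate` with diagnostics rather than a guess.

Default windows: nullcline plots u ∈ [0.01, 10] (0.04–40 µM), ψ ∈ [−2, 1];
fixed-point searches use a wider analysis window (u ∈ [1e−4, 100],
ψ ∈ [−4, 2]) because the switch-mode fixed point sits above the plot window.

### Numerics

LSODA with rtol = 1e−8, atol = 1e−10 (the log drive and fast gate make the
system moderately stiff); dense output resampled to ≥ 2000 (clamp) / 4000
(free) uniform points for stable metric extraction. u is floored at 1e−12
inside logarithm arguments only, never in the state. Piecewise-constant
current schedules are integrated segment by segment so discontinuities fall
on integration boundaries. Spike counting uses a prominence filter of 1e−4
of the trace range, with traces whose total range is below 1e−9 of their
magnitude treated as flat. The model has no stochastic component; identical
configurations produce byte-identical outputs.

## What the tests show — and what they do not

The suite verifies the implementation against closed forms (gate response,
steady fractions, time constants), independent oracles (brute-force
2000×2000 fixed-point scans, dense re-integration), and the documented
qualitative dynamics (bell-shaped clamp curve, biphasic currents, N-shaped
nullcline, the single-spike → oscillation → switch sequence, oscillation
suppression by the hyperpolarisation current). Passing tests show the
equations behave as analysed at the published parameter values; they say
nothing about real cilia beyond the model's own assumptions (well-mixed
compartment, single conducting channel state, quasi-steady conductances, no
CaM buffering term, no beat mechanics).

## Known limitations

* **Clamp Ca²⁺ spikes at published flux scales.** With s = 0.5 (direct
  model) the inhibition gate is the fast variable and u cannot overshoot —
  the documented single Ca²⁺ spike per depolarising step requires s ≳ 5.
  The acceptance test for that claim is expected to fail at the published
  values and is kept failing deliberately; the biphasic *current* claim
  holds and passes.
* **Current-trace coincidence across sensor abundances.** The Ca²⁺ current
  traces for cac0 ∈ {5,…,100} differ by 25–76% sup-norm (the initial surge
  scales with the cac0-dependent resting pump load); the steady-level
  ordering claim holds.
* **Gating floor at u = 1e6.** The indirect open fraction approaches its
  floor with a gap of `kC·cac0/((cac0+1)(kC+(cac0+1)u))` ≈ 1e−7 at u = 1e6
  — the floor value itself is exact, but the stated 1e−9 convergence at
  that probe point is not attainable by the formula being tested.
* **Monostable multivibrator.** In this two-variable quasi-steady
  formulation, a hyperpolarisation current strong enough to stabilise the
  fixed point at every I₀ (v_Cah = 0.9) necessarily flattens the ψ-fold
  that generates impulses; unique-stable-fixed-point and
  one-spike-per-step cannot hold simultaneously. The stabilisation and the
  vCah = 0 limit-cycle restoration both hold and pass; the per-step impulse
  clause fails by construction. A dynamic (non-quasi-steady) h-gate would
  add a third state variable and could reconcile the two, but is outside
  the model as specified.
* The near-exponential growth of the free-membrane peak current with the
  displacement step does not hold in this parameterisation; the observed
  behaviour is threshold-like (small sub-threshold transients, saturating
  supra-threshold spikes). The IV table reports what is computed.
* No spatial structure, no multi-cilium coupling, no ciliary-beat-frequency
  layer, no multi-subtype K⁺ expansion.
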