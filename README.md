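# ciliadyn

An excitable-system model of ciliary regulation: coupled intraciliary Ca²⁺
concentration and membrane potential, with voltage-clamp and free-membrane
simulators and a phase-plane analysis layer.

Motile cilia (in ciliates such as *Paramecium* and in human airway, sperm
and ependymal cells) steer their beat through intraciliary Ca²⁺, which is in
turn set by voltage-gated Ca²⁺ channels, Ca²⁺-dependent channel inhibition,
K⁺ currents, an active extrusion pump and a leak into the cell body. This
package implements that circuit as a pair of non-dimensional ODE systems and
the analysis tools needed to characterise its dynamic modes — single Ca²⁺
spike, sustained oscillation, switch to an elevated steady state, and the
monostable-multivibrator behaviour induced by hyperpolarisation-activated
currents. It is aimed at systems biologists and biophysicists who want a
tested, scriptable implementation of this class of ciliary excitability
models.

## The model in brief

Non-dimensional variables: `u = [Ca²⁺]/K_CaM` (K_CaM = 4 µM) and
`ψ = F·V/(R·T)` (R·T/F = −0.025 V, so depolarisation increases ψ; rest
ψ₀ = −1.2 ↔ 30 mV). Channel conductances follow the bounded sigmoid
`ν(ψ) = e^{α(ψ+d)}/(λ + e^{α(ψ+d)})`. Under clamp, Ca²⁺ and a gate variable
(direct Ca²⁺ binding `n`, or sensor-mediated `c`) evolve as

    du/dη = S·( −b·gate·ν_rel(η)·(ψ − ½·ln(u_out/u)) − u/(kA+u) )
    dn/dη = −k·n·u + (1−n)        (direct)
    dc/dη = −c·cac0·u/(kC+u) + (1−c)   (indirect)

With the clamp removed, ψ becomes the fast dynamical variable:

    du/dη = s·( I_Ca − u/(kA+u) ),    dψ/dη = ρ·( I_Ca + I_K + I₀ ),

an excitable relaxation-oscillator whose ψ-nullcline is N-shaped. The
inward current I₀ selects the regime: single spike → limit-cycle
oscillation → switch. See `docs/methods.md` for the full formulation,
parameter table, sign conventions and known limitations.

## Worked example

Clamp step from the resting potential (30 mV, ψ₀ = −1.2) to −12.5 mV
(ψ₁ = 0.5), direct inhibition mechanism, published parameter values:

```
$ ciliadyn clamp --psi0 30 --psi1 -12.5 --unit mv --out clamp.csv
clamp direct psi -1.2 -> 0.5: peak u = 2.77288, amplitude = 0, extrema = 0 -> clamp.csv
```

Intraciliary Ca²⁺ climbs from its rest level u ≈ 0.551 (2.2 µM) to a new
steady level u ≈ 2.773 (11.1 µM): the depolarisation opens the Ca²⁺
conductance and the Ca²⁺-dependent gate then throttles the influx. The CSV
holds the full trajectory (`eta,u,gate,i_ca,i_k,i_full,psi`); the Ca²⁺
current column shows the biphasic response — a fast inward surge (peak
≈ +2.7 within η < 0.3) decaying as inhibition builds.

Regime scan of the coupled free-membrane system (b = 8, cac0 = 20, ρ = 10,
s = 0.5) over the inward current:

```
$ ciliadyn phase regime-scan --i0-max 0.6 --i0-steps 7 --out regimes.csv
 I0         mode  n_fixed_points      u_ss    psi_ss    period
0.0 single_spike               1  1.271217 -1.241859       NaN
0.1 single_spike               1  1.793801 -1.060469       NaN
0.2  oscillation               1  3.216321 -0.841110 23.302913
0.3  oscillation               1  6.032772 -0.647546 19.552444
0.4       switch               1  9.447097 -0.502234       NaN
0.5       switch               1 12.493439 -0.381641       NaN
0.6       switch               1 14.570039 -0.272713       NaN
```

Reading it: at rest (I₀ = 0) the system sits at u ≈ 1.27, ψ ≈ −1.24
(≈ 31 mV) and answers a small current step with one Ca²⁺/potential pulse;
at intermediate drive the fixed point destabilises and a limit cycle with
period ≈ 20 η-units carries sustained Ca²⁺ oscillations; at high drive the
system switches to a stable elevated Ca²⁺ level. These are the three
physiological modes the model proposes for ciliary beat control.

Other entry points: `ciliadyn free` (current schedules, hyperpolarisation
variants), `ciliadyn phase nullclines|fixed-points`, `ciliadyn scan`
(spike-amplitude grids), `ciliadyn convert` (mV/µM ↔ non-dimensional),
`ciliadyn preset --list` (per-figure parameter bundles, fig2–fig14). The
same functionality is available as a library (`import ciliadyn`).

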