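"""Voltage-clamp simulator: fixed points, transients, currents, metrics."""

from dataclasses import replace

import numpy as np
import pytest

from ciliadyn.clamp import (
    ClampModelParams,
    ClampProtocol,
    InitialisationError,
    Mechanism,
    clamp_full_current,
    clamp_initial_state,
    scan_spike_amplitude,
    simulate_clamp,
    simulate_direct_clamp,
    simulate_indirect_clamp,
    spike_metrics,
    steady_state_u_of_psi,
)
from ciliadyn.conductances import RelaxationSpec, relaxed_conductance, sigmoid_conductance
from ciliadyn.gating import (
    DirectGatingParams,
    IndirectGatingParams,
    direct_open_fraction_ss,
    indirect_open_fraction_ss,
    pump_flux,
)


@pytest.fixture(scope="module")
def params():
    return ClampModelParams()


class TestInitialState:
    @pytest.mark.parametrize("mech", [Mechanism.DIRECT, Mechanism.INDIRECT])
    def test_residual_below_tolerance(self, params, mech):
        u0, g0 = clamp_initial_state(params, -1.2, mech)
        nu = sigmoid_conductance(-1.2, params.ca_cond)
        drive = -1.2 - 0.5 * np.log(params.uout / u0)
        res = -params.b * g0 * nu * drive - pump_flux(u0, params.pump)
        assert abs(res) < 1e-10
        assert u0 > 0

    def test_gate_consistent_with_steady_formula(self, params):
        u0, n0 = clamp_initial_state(params, -1.2, Mechanism.DIRECT)
        assert n0 == pytest.approx(float(direct_open_fraction_ss(u0, params.direct)), rel=1e-12)
        u0, c0 = clamp_initial_state(params, -1.2, Mechanism.INDIRECT)
        assert c0 == pytest.approx(float(indirect_open_fraction_ss(u0, params.indirect)), rel=1e-12)

    def test_vanishing_influx_limit(self, params):
        """As the conductance group b shrinks, the rest level collapses toward 0."""
        rests = [
            clamp_initial_state(replace(params, b=b), -1.2)[0] for b in (2.0, 0.2, 0.02, 0.002)
        ]
        assert all(b > a for a, b in zip(rests[1:], rests[:-1]))
        assert rests[-1] < 1e-2

    def test_jacobian_stable_at_fixed_point(self, params):
        """The clamp fixed point is unique in the bracket and linearly stable."""
        for psi in (-1.2, -0.5, 0.5):
            u0, n0 = clamp_initial_state(params, psi, Mechanism.DIRECT)

            def rhs(y):
                u, n = y
                nu = sigmoid_conductance(psi, params.ca_cond)
                du = params.s * (
                    -params.b * n * nu * (psi - 0.5 * np.log(params.uout / u))
                    - pump_flux(u, params.pump)
                )
                dn = -params.direct.k * n * u + (1 - n)
                return np.array([du, dn])

            J = np.zeros((2, 2))
            y0 = np.array([u0, n0])
            for c in range(2):
                h = 1e-7 * max(abs(y0[c]), 1e-3)
                yp, ym = y0.copy(), y0.copy()
                yp[c] += h
                ym[c] -= h
                J[:, c] = (rhs(yp) - rhs(ym)) / (2 * h)
            assert max(np.linalg.eigvals(J).real) < 0


class TestClampRuns:
    def test_no_stimulus_stays_at_rest(self, params):
        proto = ClampProtocol(psi0=-1.2, psi1=-1.2, duration=20)
        traj = simulate_direct_clamp(proto, params)
        assert np.max(np.abs(traj.u - traj.u[0])) < 1e-6 * traj.u[0]
        m = spike_metrics(traj)
        assert m.amplitude == 0.0 and m.n_extrema == 0

    def test_depolarising_step_raises_calcium(self, params):
        traj = simulate_direct_clamp(ClampProtocol(psi1=0.5, duration=30), params)
        assert traj.u[-1] > 2 * traj.u[0]
        assert np.all(traj.u > 0)

    def test_current_biphasic_fast_inward_then_relaxation(self, params):
        """The Ca2+ current jumps within the conductance relaxation time then decays."""
        traj = simulate_direct_clamp(ClampProtocol(psi1=0.5, duration=30), params)
        i = traj.i_ca
        peak_idx = int(np.argmax(i))
        assert traj.eta[peak_idx] < 1.0  # fast activation phase
        assert i[peak_idx] > 10 * abs(i[0])
        # monotone-ish relaxation over the tail
        tail = i[int(0.5 * len(i)):]
        assert abs(tail[-1]) < 0.2 * i[peak_idx]

    def test_currents_recomputable_from_state(self, params):
        proto = ClampProtocol(psi1=0.2, duration=20)
        traj = simulate_direct_clamp(proto, params)
        relax = RelaxationSpec(proto.psi0, proto.psi1, proto.tau0)
        nu = relaxed_conductance(traj.eta, relax, params.ca_cond)
        drive = proto.psi1 - 0.5 * np.log(params.uout / traj.u)
        i = -params.b * traj.gate * nu * drive - pump_flux(traj.u, params.pump)
        assert np.max(np.abs(i - traj.i_ca)) < 1e-9

    def test_indirect_disabled_sensor_keeps_gate_open(self, params):
        p = replace(params, indirect=IndirectGatingParams(kC=1.0, cac0=0.0))
        traj = simulate_indirect_clamp(ClampProtocol(psi1=0.0, duration=10), p)
        assert np.max(np.abs(traj.gate - 1.0)) < 1e-7

    def test_indirect_steady_level_falls_with_sensor_abundance(self, params):
        finals = []
        for cac0 in (5.0, 10.0, 50.0, 100.0):
            p = replace(params, indirect=IndirectGatingParams(kC=1.0, cac0=cac0))
            traj = simulate_indirect_clamp(ClampProtocol(psi1=0.5, duration=30), p)
            finals.append(traj.u[-1])
        assert all(b < a for a, b in zip(finals, finals[1:]))


class TestFullCurrent:
    def test_k_free_limit_matches_ca_only(self, params):
        proto = ClampProtocol(psi1=0.3, duration=15, include_K=True)
        traj = simulate_direct_clamp(proto, params)
        p0 = replace(params, b1=1e-300)
        full = clamp_full_current(traj, p0, proto)
        assert np.max(np.abs(full - traj.i_ca)) < 1e-12

    def test_zero_k_contribution_at_reversal(self, params):
        proto = ClampProtocol(psi1=params.psiK, duration=15, include_K=True)
        traj = simulate_direct_clamp(proto, params)
        assert np.max(np.abs(traj.i_k)) < 1e-14
        assert np.max(np.abs(traj.i_full - traj.i_ca)) < 1e-14

    def test_k_term_preserves_spike_count(self, params):
        proto = ClampProtocol(psi1=0.5, duration=30)
        m_no_k = spike_metrics(simulate_direct_clamp(proto, params))
        m_k = spike_metrics(
            simulate_direct_clamp(replace(proto, include_K=True), params)
        )
        assert m_no_k.n_extrema == m_k.n_extrema


class TestSteadyCurve:
    def test_bell_shape_over_depolarisation_range(self, params):
        """Steady Ca2+ rises with depolarisation then falls again (bell)."""
        grid = np.linspace(-1.2, 1.0, 23)
        df = steady_state_u_of_psi(params, grid)
        assert df["ok"].all()
        u = df["u"].to_numpy()
        k = int(np.argmax(u))
        assert 0 < k < len(u) - 1
        assert np.all(np.diff(u[: k + 1]) > 0)
        assert np.all(np.diff(u[k:]) < 0)

    def test_direct_and_indirect_coincide_at_low_calcium(self, params):
        """Both gates approach 1 as u -> 0, so the hyperpolarised ends agree."""
        psi = np.array([-2.8])
        ud = steady_state_u_of_psi(params, psi, Mechanism.DIRECT)["u"].iloc[0]
        ui = steady_state_u_of_psi(params, psi, Mechanism.INDIRECT)["u"].iloc[0]
        assert ud == pytest.approx(ui, rel=0.05)
        assert ud < 0.05

    def test_collapse_without_influx(self, params):
        df = steady_state_u_of_psi(replace(params, b=1e-6), np.array([-1.2, 0.0]))
        assert (df["u"] < 1e-5).all()


class TestSpikeMetricsAndScan:
    def test_flat_trajectory_metrics(self, params):
        traj = simulate_direct_clamp(ClampProtocol(psi1=-1.2, duration=5), params)
        m = spike_metrics(traj)
        assert m.amplitude == 0.0
        assert m.n_extrema == 0
        assert m.baseline == pytest.approx(m.final_ss, rel=1e-6)

    def test_single_spike_regime_counts_one_extremum(self, params):
        """With a fast Ca2+ flux scale the gate lags and u overshoots once."""
        p = replace(params, s=5.0)
        traj = simulate_direct_clamp(ClampProtocol(psi1=0.5, duration=30), p)
        m = spike_metrics(traj)
        assert m.n_extrema == 1
        assert m.peak > m.final_ss > m.baseline
        assert m.amplitude == pytest.approx(m.peak - m.final_ss)

    def test_amplitude_against_dense_reintegration(self, params):
        p = replace(params, s=5.0)
        proto = ClampProtocol(psi1=0.5, duration=30)
        m1 = spike_metrics(simulate_clamp(proto, p, n_points=2000))
        m2 = spike_metrics(simulate_clamp(proto, p, n_points=8000))
        assert m1.amplitude == pytest.approx(m2.amplitude, rel=1e-3)
        assert m1.peak_time == pytest.approx(m2.peak_time, abs=0.02)

    def test_amplitude_grows_with_external_calcium(self, params):
        """More extracellular Ca2+ -> larger depolarisation-induced response."""
        p = replace(params, s=5.0)
        proto = ClampProtocol(psi1=0.2, duration=30)
        df = scan_spike_amplitude(p, proto, "uout", np.array([300.0, 1000.0, 3000.0]))
        rise = (df["peak"] - df["baseline"]).to_numpy()
        assert np.all(np.diff(rise) > 0)

    def test_amplitude_vanishes_at_calcium_equilibrium(self, params):
        """Stepping to the Ca2+ Nernst level of the rest state gives ~no response."""
        u0, _ = clamp_initial_state(params, -1.2)
        psi_eq = 0.5 * np.log(params.uout / u0)
        surge_eq = simulate_direct_clamp(ClampProtocol(psi1=psi_eq, duration=20), params).i_ca.max()
        surge_depol = simulate_direct_clamp(ClampProtocol(psi1=0.2, duration=20), params).i_ca.max()
        assert surge_eq < 1e-3 * surge_depol

    def test_scan_rejects_unknown_axis(self, params):
        with pytest.raises(ValueError):
            scan_spike_amplitude(params, ClampProtocol(), "tau0", np.array([0.1]))


def test_initialisation_error_is_diagnostic():
    p = ClampModelParams()
    with pytest.raises(InitialisationError):
        # beyond the Nernst level of the bracket upper end the search fails loudly
        clamp_initial_state(replace(p, uout=1e-12), 5.0)
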