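import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from golgisim import membrane
from golgisim.membrane import (CalciumShellSpec, CalciumShellState,
                               HHGateSpec, MarkovChannelSpec, RateSpec,
                               calcium_step, channel_current, gate_advance,
                               load_channel_registry, markov_advance,
                               q10_factor)


@pytest.fixture(scope="module")
def registry():
    return load_channel_registry()


class TestGateAdvance:
    def test_fixed_point_at_constant_voltage(self):
        g = HHGateSpec(kind="v", vhalf=-40.0, k=5.0, tau_min=2.0)
        m = 0.1
        minf = float(g.minf(-50.0))
        tau = float(g.tau(-50.0))
        for _ in range(20000):
            m = gate_advance(m, minf, tau, 0.1)
        assert m == pytest.approx(minf, abs=1e-9)

    def test_one_tau_step_moves_1_minus_1_over_e(self):
        m0, minf, tau = 0.0, 1.0, 7.3
        m1 = gate_advance(m0, minf, tau, dt=tau)
        assert m1 == pytest.approx(1.0 - np.exp(-1.0))
        # temperature factor rescales the effective time constant
        m2 = gate_advance(m0, minf, tau, dt=tau / 2.0, temp_factor=2.0)
        assert m2 == pytest.approx(m1)

    def test_trajectory_matches_fine_ode_for_arbitrary_voltage(self):
        # oracle: dense ODE integration of dm/dt = (minf(V(t)) - m)/tau(V(t))
        g = HHGateSpec(kind="v", vhalf=-35.0, k=6.0, tau_min=1.0,
                       tau_amp=5.0, tau_vhalf=-40.0, tau_k=15.0)

        def volt(t):
            return -60.0 + 30.0 * np.sin(2 * np.pi * t / 17.0)

        def rhs(t, y):
            v = volt(t)
            return [(g.minf(v) - y[0]) / g.tau(v)]

        sol = solve_ivp(rhs, (0.0, 50.0), [0.2], max_step=1e-2,
                        dense_output=True, rtol=1e-10, atol=1e-12)
        m = 0.2
        dt = 1e-4
        for i in range(int(50.0 / dt)):
            v = volt(i * dt)
            m = gate_advance(m, float(g.minf(v)), float(g.tau(v)), dt)
        assert abs(m - sol.y[0, -1]) < 1e-4


class TestMarkovAdvance:
    def test_zero_generator_is_identity(self):
        spec = MarkovChannelSpec(
            "null", ["A", "B"], ["B"],
            [("A", "B", RateSpec("const", 0.0))], e_rev=0.0)
        p = markov_advance(spec, [0.3, 0.7], v=-20.0, dt=5.0)
        assert p == pytest.approx([0.3, 0.7])

    def test_two_state_analytic_relaxation(self):
        a, b = 0.7, 0.4
        spec = MarkovChannelSpec(
            "two", ["C", "O"], ["O"],
            [("C", "O", RateSpec("const", a)), ("O", "C", RateSpec("const", b))],
            e_rev=0.0)
        p = np.array([1.0, 0.0])
        t = 3.0
        for _ in range(300):
            p = markov_advance(spec, p, v=0.0, dt=t / 300)
        p_inf = a / (a + b)
        expect = p_inf - (p_inf - 0.0) * np.exp(-(a + b) * t)
        assert p[1] == pytest.approx(expect, abs=1e-6)

    def test_six_state_matches_matrix_exponential(self):
        # oracle: scipy expm of the generator over 10 ms at fixed (V, Ca)
        rng = np.random.default_rng(42)
        states = list("ABCDEF")
        trans = []
        for i in range(5):
            trans.append((states[i], states[i + 1],
                          RateSpec("const", float(rng.uniform(0.1, 2.0)))))
            trans.append((states[i + 1], states[i],
                          RateSpec("const", float(rng.uniform(0.1, 2.0)))))
        spec = MarkovChannelSpec("six", states, ["F"], trans, e_rev=0.0)
        q = spec.rate_matrix(0.0)
        p0 = np.zeros(6)
        p0[0] = 1.0
        oracle = expm(q.T * 10.0) @ p0
        p = p0.copy()
        for _ in range(400):
            p = markov_advance(spec, p, v=0.0, dt=10.0 / 400)
        assert np.abs(p - oracle).max() < 1e-5

    def test_probabilities_conserved_and_nonnegative(self, registry):
        channels, *_ = registry
        nav = channels["Nav1.6"]
        rng = np.random.default_rng(0)
        p = nav.equilibrium(-70.0)
        for _ in range(500):
            v = float(rng.uniform(-90, 30))
            p = markov_advance(nav, p, v=v, dt=0.025)
            assert p.min() >= 0.0
            assert p.sum() == pytest.approx(1.0, abs=1e-9)


class TestChannelCurrent:
    def test_zero_at_reversal(self, registry):
        channels, *_ = registry
        for spec in channels.values():
            assert channel_current(0.1, 0.5, spec.e_rev, spec.e_rev) == 0.0

    def test_fully_open_sodium_arithmetic(self):
        # soma Nav density, fully open, V = -10 mV, E = +60 mV
        i = channel_current(0.149, 1.0, -10.0, 60.0)
        assert i == pytest.approx(0.149 * (-70.0))
        assert i == pytest.approx(-10.43, abs=0.01)

    def test_closed_channel_carries_nothing(self):
        assert channel_current(0.5, 0.0, 40.0, -80.0) == 0.0


class TestQ10:
    @pytest.mark.parametrize("q10,temp,ref,expect", [
        (3.0, 42.0, 32.0, 3.0),
        (3.0, 32.0, 32.0, 1.0),
        (2.4, 32.0, 22.0, 2.4),
    ])
    def test_values(self, q10, temp, ref, expect):
        assert q10_factor(q10, temp, ref) == pytest.approx(expect)


class TestCalciumShell:
    def test_resting_state_is_equilibrium(self):
        spec = CalciumShellSpec()
        st = CalciumShellState.resting(spec)
        st2 = calcium_step(spec, st, 0.0, 1e-6, 10.0)
        assert st2.ca == pytest.approx(st.ca, rel=1e-6)
        assert st2.buf_bound == pytest.approx(st.buf_bound, rel=1e-6)

    def test_pulse_then_return_to_rest(self):
        spec = CalciumShellSpec(pump_density=5e-9, pump_turnover=1.0)
        st = CalciumShellState.resting(spec)
        for _ in range(50):
            st = calcium_step(spec, st, -0.01, 1e-7, 0.1)  # 10 pA inward
        assert st.ca > 2 * spec.ca_rest
        # effective decay is slowed by the buffer capacity ratio
        kappa = spec.buffer_total / (spec.koff / spec.kon)
        tau_eff = (1.0 + kappa) / spec.pump_rate_per_ms()
        for _ in range(int(20 * tau_eff / 0.5)):  # many decay constants
            st = calcium_step(spec, st, 0.0, 1e-7, 0.5)
        assert st.ca == pytest.approx(spec.ca_rest, rel=0.05)

    def test_step_response_matches_fine_ode(self):
        # oracle: solve_ivp of the shell ODEs under constant influx
        spec = CalciumShellSpec(pump_density=5e-9, pump_turnover=1.0)
        area = 1e-7
        i_ca = -0.005
        jin = -i_ca * spec.influx_factor(area)
        kp = spec.pump_rate_per_ms()

        def rhs(t, y):
            ca, b = y
            dbdt = spec.kon * ca * (spec.buffer_total - b) - spec.koff * b
            return [jin - dbdt - kp * (ca - spec.ca_rest), dbdt]

        st0 = CalciumShellState.resting(spec)
        sol = solve_ivp(rhs, (0, 20.0), [st0.ca, st0.buf_bound],
                        rtol=1e-10, atol=1e-14)
        st = st0
        for _ in range(200):
            st = calcium_step(spec, st, i_ca, area, 0.1, max_sub_dt=1e-4)
        assert st.ca == pytest.approx(sol.y[0, -1], rel=1e-3)

    def test_calcium_stays_positive_under_outward_artifact(self):
        spec = CalciumShellSpec()
        st = CalciumShellState.resting(spec)
        st = calcium_step(spec, st, +1.0, 1e-7, 5.0)  # nonphysical outward
        assert st.ca > 0


class TestRegistry:
    def test_registry_has_no_synaptic_receptors(self, registry):
        channels, placements, _, _ = registry
        names = {p.channel for p in placements} | set(channels)
        assert not any(n.upper().startswith(("AMPA", "NMDA", "GABA"))
                       for n in names)

    def test_published_placement_map(self, registry):
        _, placements, _, _ = registry
        by_channel = {}
        for p in placements:
            by_channel.setdefault(p.channel, {})[p.section] = p
        # Cav2.3 only in apical dendrites at the printed density
        assert set(by_channel["Cav2.3"]) == {"apical_dendrite"}
        assert by_channel["Cav2.3"]["apical_dendrite"].g_max == pytest.approx(0.0012)
        # Kv7.x in the AIS at the printed default
        assert set(by_channel["Kv7.x"]) == {"AIS"}
        assert by_channel["Kv7.x"]["AIS"].g_max == pytest.approx(0.0002)
        # Nav1.6 everywhere, density graded per the printed table
        nav = {s: p.g_max for s, p in by_channel["Nav1.6"].items()}
        assert set(nav) == {"soma", "AIS", "axon", "basal_dendrite",
                            "apical_dendrite"}
        assert nav["AIS"] > nav["soma"] > nav["axon"] \
            > nav["basal_dendrite"] > nav["apical_dendrite"]

    def test_reversal_potentials(self, registry):
        channels, *_ = registry
        assert channels["Nav1.6"].e_rev == 60.0
        assert channels["Kv3.4"].e_rev == -80.0
        assert channels["HCN1"].e_rev == -20.0
        assert channels["Cav2.2"].e_rev == 137.5

    def test_pump_densities_follow_text_values(self, registry):
        calcium = registry[2]
        assert calcium["apical_dendrite"].pump_density == pytest.approx(2e-9)
        assert calcium["basal_dendrite"].pump_density == pytest.approx(5e-9)
        assert calcium["soma"].pump_density == pytest.approx(1e-7)
        assert calcium["AIS"].pump_density == pytest.approx(1e-8)

    def test_gmax_defaults_within_or_at_bounds_margin(self, registry):
        _, placements, _, _ = registry
        for p in placements:
            lo, hi = p.bounds
            assert lo < hi
            # defaults sit in or near the printed optimization range
            assert p.g_max <= hi * 1.05
            assert p.g_max >= lo * 0.85
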