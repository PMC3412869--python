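"""Generic Markov machinery: generators, stationary solutions, clamp
propagation, and lockstep between the introspectable schemes and the
compiled kernels used by the whole-cell model."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mouseap import cell, rates
from mouseap.channels import build_scheme, build_iktof_scheme, load_rate_vector
from mouseap.markov import (
    MarkovScheme,
    SchemeError,
    Transition,
    occupancy_derivative,
    simulate_piecewise_clamp,
    steady_state_occupancy,
    transition_matrix,
)

CHANNELS = ("iktof", "iktos", "ikur", "iks")
V_GRID = (-120.0, -80.0, -40.0, 0.0, 30.0, 60.0)


def two_state(alpha, beta):
    return MarkovScheme(
        name="toy",
        states=("C", "O"),
        transitions=(
            Transition("C", "O", lambda V, c: alpha),
            Transition("O", "C", lambda V, c: beta),
        ),
        conducting_states=frozenset({"O"}),
    )


class TestTransitionMatrix:
    def test_two_state_matrix_is_definitional(self):
        Q = transition_matrix(two_state(2.0, 0.5), 0.0)
        assert np.allclose(Q, [[-2.0, 0.5], [2.0, -0.5]])

    @pytest.mark.parametrize("channel", CHANNELS)
    @pytest.mark.parametrize("V", V_GRID)
    def test_columns_sum_to_zero_and_rates_valid(self, channel, V):
        scheme = build_scheme(channel)
        Q = transition_matrix(scheme, V)
        assert np.abs(Q.sum(axis=0)).max() < 1e-12
        off = Q - np.diag(np.diag(Q))
        assert np.all(off >= 0)
        assert np.all(np.isfinite(Q))

    def test_unknown_state_rejected_at_construction(self):
        with pytest.raises(SchemeError, match="unknown state"):
            MarkovScheme(
                name="bad", states=("C", "O"),
                transitions=(Transition("C", "X", lambda V, c: 1.0),),
                conducting_states=frozenset({"O"}),
            )

    def test_disconnected_graph_rejected(self):
        with pytest.raises(SchemeError, match="not connected"):
            MarkovScheme(
                name="bad", states=("A", "B", "C"),
                transitions=(Transition("A", "B", lambda V, c: 1.0),
                             Transition("B", "A", lambda V, c: 1.0)),
                conducting_states=frozenset({"A"}),
            )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(build_scheme("iktof"), 0.0, drug_conc=-1.0)

    def test_scheme1_entries_match_hand_evaluated_rates(self):
        # Rate laws evaluated independently with a scalar calculator at +50 mV:
        # alpha_a = 0.18064*exp(0.03577*80), beta_a = 0.3956*exp(-0.06237*80),
        # k_OI = 0.002 + 0.030/(1+exp(-65/8)), k_IO = 0.030*exp(-120/25).
        aa = 3.15930106577958
        ba = 0.0026933980168900445
        koi = 0.031991121286594607
        kio = 0.0002468924114706009
        s = build_iktof_scheme()
        Q = transition_matrix(s, 50.0)
        i = {name: s.index(name) for name in s.states}
        assert Q[i["C2"], i["C1"]] == pytest.approx(3 * aa, rel=1e-12)
        assert Q[i["C1"], i["C2"]] == pytest.approx(ba, rel=1e-12)
        assert Q[i["C3"], i["C2"]] == pytest.approx(2 * aa, rel=1e-12)
        assert Q[i["O"], i["C3"]] == pytest.approx(aa, rel=1e-12)
        assert Q[i["C3"], i["O"]] == pytest.approx(3 * ba, rel=1e-12)
        assert Q[i["I1"], i["O"]] == pytest.approx(koi, rel=1e-12)
        assert Q[i["O"], i["I1"]] == pytest.approx(kio, rel=1e-12)
        # frozen parameter-file constants
        p = load_rate_vector("iktof")
        assert Q[i["I1"], i["C3"]] == pytest.approx(p[11], rel=1e-12)
        assert Q[i["I2"], i["I1"]] == pytest.approx(p[13], rel=1e-12)


class TestStationary:
    def test_two_state_symmetry(self):
        p = steady_state_occupancy(two_state(1.0, 1.0), 0.0)
        assert np.allclose(p, [0.5, 0.5])

    def test_two_state_detailed_balance(self):
        p = steady_state_occupancy(two_state(2.0, 1.0), 0.0)
        assert np.allclose(p, [1 / 3, 2 / 3])

    @pytest.mark.parametrize("channel", CHANNELS)
    def test_stationary_is_nullspace_and_simplex(self, channel):
        scheme = build_scheme(channel)
        for V in (-70.0, 0.0):
            p = steady_state_occupancy(scheme, V)
            assert p.min() >= 0
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.abs(transition_matrix(scheme, V) @ p).max() < 1e-9

    def test_ikur_stationary_matches_long_time_integration(self):
        """Forward ODE integration at fixed V converges to the nullspace."""
        scheme = build_scheme("ikur")
        V = -70.0
        Q = transition_matrix(scheme, V)
        p0 = np.zeros(scheme.n_states)
        p0[0] = 1.0
        sol = solve_ivp(lambda t, p: Q @ p, (0, 200000.0), p0, rtol=1e-10, atol=1e-12)
        assert np.allclose(sol.y[:, -1], steady_state_occupancy(scheme, V), atol=1e-6)


class TestDynamics:
    def test_derivative_conservation_and_stationarity(self):
        scheme = build_scheme("iktos")
        p = steady_state_occupancy(scheme, -40.0)
        d = occupancy_derivative(scheme, p, -40.0)
        assert abs(d.sum()) < 1e-12
        assert np.abs(d).max() < 1e-9
        rng = np.random.default_rng(0)
        q = rng.dirichlet(np.ones(scheme.n_states))
        assert abs(occupancy_derivative(scheme, q, 10.0).sum()) < 1e-12

    def test_derivative_dimension_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            occupancy_derivative(build_scheme("ikur"), np.ones(3), 0.0)

    def test_clamp_propagation_matches_ode_oracle(self):
        """Step from -100 to +50 mV: expm propagation vs an independent
        adaptive-ODE solve of dp/dt = Q p at fixed voltage."""
        scheme = build_scheme("iktos")
        p0 = steady_state_occupancy(scheme, -100.0)
        t, V, occ = simulate_piecewise_clamp(
            scheme, [(500.0, 50.0)], dt_out=0.5, p0=p0
        )
        Q = transition_matrix(scheme, 50.0)
        io = scheme.index("O")
        for t_probe in (10.0, 100.0, 400.0):
            sol = solve_ivp(lambda tt, p: Q @ p, (0, t_probe), p0,
                            rtol=1e-10, atol=1e-12)
            k = np.argmin(np.abs(t - t_probe))
            assert occ[k, io] == pytest.approx(sol.y[io, -1], abs=1e-8)
        # transient-outward style: open occupancy rises then decays
        o = occ[:, io]
        assert o.argmax() > 0
        assert o[-1] < 0.5 * o.max()

    def test_occupancy_stays_on_simplex_along_trajectory(self):
        scheme = build_scheme("iktof")
        t, V, occ = simulate_piecewise_clamp(
            scheme, [(20.0, -80.0), (500.0, 40.0), (200.0, -80.0)], dt_out=0.5
        )
        assert occ.min() >= -1e-9
        assert np.abs(occ.sum(axis=1) - 1).max() < 1e-6


class TestCompiledKernelLockstep:
    """The hand-expanded in-place kernels must equal generator @ occupancy."""

    def test_iktof_apply_matches_generator(self):
        p = load_rate_vector("iktof")
        rng = np.random.default_rng(1)
        y = np.zeros(50)
        dy = np.zeros(50)
        occ = rng.dirichlet(np.ones(10))
        for V in (-80.0, 0.0, 40.0):
            y[5:15] = occ
            args = (V, 0.5, p, 0.0032, 0.008, 4.0, 0.002, 0.01)
            rates.iktof_apply(*args, y, dy, 5)
            Q = rates.iktof_generator(*args)
            assert np.allclose(dy[5:15], Q @ occ, atol=1e-14)

    @pytest.mark.parametrize("channel,n", [("iktos", 9), ("ikur", 6), ("iks", 17)])
    def test_k_channel_apply_matches_generator(self, channel, n):
        p = load_rate_vector(channel)
        gen = getattr(rates, f"{channel}_generator")
        apply_ = getattr(rates, f"{channel}_apply")
        rng = np.random.default_rng(2)
        occ = rng.dirichlet(np.ones(n))
        y = np.zeros(n + 7)
        dy = np.zeros(n + 7)
        for V in (-90.0, -30.0, 20.0):
            y[7:] = occ
            apply_(V, p, y, dy, 7)
            assert np.allclose(dy[7:], gen(V, p) @ occ, atol=1e-14)
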