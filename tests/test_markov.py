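"""Generator construction, matrix-method propagation and stationary solves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navlti.markov import (
    KineticScheme,
    RateConstant,
    VoltageProtocol,
    build_generator,
    eval_rate,
    load_rate_table,
    propagate,
    run_protocol,
    stationary_distribution,
)

from conftest import random_scheme


class TestEvalRate:
    @pytest.mark.parametrize(
        "k0,k1,V,expected",
        [
            (400.8, -0.011, 0.0, 400.8),  # O->S entry rate at 0 mV
            (0.207, -0.031, 0.0, 0.207),  # S->O exit rate at 0 mV
            (7.5, 0.0, -123.0, 7.5),  # voltage-independent rate
        ],
    )
    def test_eyring_values(self, k0, k1, V, expected):
        assert eval_rate(RateConstant(k0, k1), V) == pytest.approx(expected)

    def test_voltage_dependence_is_exponential(self):
        rc = RateConstant(2.0, -0.03)
        assert eval_rate(rc, -80.0) == pytest.approx(2.0 * np.exp(0.03 * 80))

    def test_extreme_exponent_signalled(self):
        with pytest.raises(OverflowError):
            eval_rate(RateConstant(1.0, 1.0), 1e6)

    def test_invalid_rate_constant(self):
        with pytest.raises(ValueError):
            RateConstant(-1.0, 0.0)
        with pytest.raises(ValueError):
            RateConstant(1.0, float("nan"))


class TestBuildGenerator:
    def test_two_state_definition(self, two_state):
        Q = build_generator(two_state, 0.0)
        assert np.allclose(Q, [[-0.4, 0.4], [0.1, -0.1]])

    def test_rows_sum_to_zero_13_state(self, lti_model):
        Q = build_generator(lti_model.scheme, -37.5)
        assert Q.shape == (13, 13)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        off = Q - np.diag(np.diag(Q))
        assert (off >= 0).all()

    def test_duplicate_transition_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            KineticScheme(
                ["A", "B"],
                {"B": True},
                [
                    ("A", "B", RateConstant(1.0)),
                    ("A", "B", RateConstant(2.0)),
                    ("B", "A", RateConstant(1.0)),
                ],
            )

    def test_disconnected_scheme_rejected(self):
        with pytest.raises(ValueError, match="not connected"):
            KineticScheme(
                ["A", "B", "C", "D"],
                {"A": True},
                [("A", "B", RateConstant(1.0)), ("C", "D", RateConstant(1.0))],
            )


class TestPropagate:
    def test_zero_dt_is_identity(self, two_state):
        P0 = np.array([0.3, 0.7])
        Q = two_state.generator(0.0)
        assert np.array_equal(propagate(P0, Q, 0.0), P0)

    def test_two_state_closed_form(self, two_state):
        # analytic relaxation: P_A(t) = b/(a+b) + a/(a+b) e^{-(a+b)t}
        a, b = 0.4, 0.1
        Q = two_state.generator(0.0)
        for dt in (0.1, 1.0, 7.3, 50.0):
            P = propagate(np.array([1.0, 0.0]), Q, dt)
            expected = b / (a + b) + a / (a + b) * np.exp(-(a + b) * dt)
            assert P[0] == pytest.approx(expected, abs=1e-12)

    @given(
        seed=st.integers(0, 1000),
        n=st.integers(3, 5),
        dt=st.floats(0.01, 20.0),
        V=st.floats(-90.0, 30.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_probability_conserved_and_nonnegative(self, seed, n, dt, V):
        rng = np.random.default_rng(seed)
        scheme = random_scheme(rng, n)
        P0 = rng.dirichlet(np.ones(n))
        P = propagate(P0, scheme.generator(V), dt)
        assert abs(P.sum() - 1.0) < 1e-9
        assert (P >= -1e-12).all()

    @pytest.mark.parametrize("seed", [1, 7, 42])
    def test_matches_fine_euler_oracle(self, seed):
        """Matrix exponential agrees with a fine-step forward-Euler oracle."""
        rng = np.random.default_rng(seed)
        scheme = random_scheme(rng, 3)
        Q = scheme.generator(-20.0)
        P0 = rng.dirichlet(np.ones(3))
        t_end, h = 1.0, 1e-5
        P_euler = P0.copy()
        M = np.eye(3) + Q * h  # forward Euler step
        for _ in range(int(t_end / h)):
            P_euler = P_euler @ M
        P_exact = propagate(P0, Q, t_end)
        assert np.abs(P_exact - P_euler).max() < 1e-6

    def test_nonfinite_generator_rejected(self):
        Q = np.array([[np.nan, np.nan], [1.0, -1.0]])
        with pytest.raises(ValueError):
            propagate(np.array([1.0, 0.0]), Q, 1.0)


class TestStationary:
    def test_two_state_closed_form(self, two_state):
        P = stationary_distribution(two_state.generator(0.0))
        assert np.allclose(P, [0.1 / 0.5, 0.4 / 0.5])

    def test_symmetric_rates_give_uniform(self):
        scheme = KineticScheme(
            ["A", "B"], {"B": True},
            [("A", "B", RateConstant(0.7)), ("B", "A", RateConstant(0.7))],
        )
        assert np.allclose(stationary_distribution(scheme.generator(0.0)), [0.5, 0.5])

    def test_lti_equilibrium_s_occupancy(self, lti_model):
        """Sustained depolarization drives ~70% of channels into S13."""
        P = stationary_distribution(lti_model.scheme.generator(0.0))
        assert P[lti_model.scheme.index("S13")] == pytest.approx(0.7, abs=0.02)

    def test_reducible_chain_rejected(self):
        Q = np.array(
            [[-1.0, 1.0, 0.0, 0.0],
             [2.0, -2.0, 0.0, 0.0],
             [0.0, 0.0, -0.5, 0.5],
             [0.0, 0.0, 0.3, -0.3]]
        )
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(Q)


class TestRunProtocol:
    def test_stationary_start_stays_constant(self, two_state):
        P0 = stationary_distribution(two_state.generator(-10.0))
        traj = run_protocol(two_state, VoltageProtocol(((50.0, -10.0),)), P0, 1.0)
        assert np.abs(traj.P - P0).max() < 1e-9

    def test_brief_depolarization_splits_80_20(self, lti_model):
        """5 ms at 0 mV from rest: ~80% normal inactivation, ~20% LTI."""
        scheme = lti_model.scheme
        P0 = stationary_distribution(scheme.generator(-80.0))
        traj = run_protocol(scheme, VoltageProtocol(((5.0, 0.0),)), P0, 0.05)
        p_i = traj.occupancy([f"I{i}" for i in range(7, 13)])[-1]
        p_s = traj.occupancy("S13")[-1]
        assert p_i == pytest.approx(0.8, abs=0.03)
        assert p_s == pytest.approx(0.2, abs=0.02)

    def test_time_step_invariance(self, lti_model):
        """Matrix-method propagation is exact: dt and dt/10 agree."""
        scheme = lti_model.scheme
        P0 = stationary_distribution(scheme.generator(-80.0))
        proto = VoltageProtocol(((5.0, 0.0), (20.0, -80.0)))
        coarse = run_protocol(scheme, proto, P0, 0.5)
        fine = run_protocol(scheme, proto, P0, 0.05)
        idx = np.arange(coarse.times.size) * 10
        assert np.abs(fine.times[idx] - coarse.times).max() < 1e-8
        assert np.abs(fine.P[idx] - coarse.P).max() < 1e-9

    def test_long_hold_converges_to_stationary(self, two_state):
        Q = two_state.generator(5.0)
        P_inf = stationary_distribution(Q)
        P0 = np.array([1.0, 0.0])
        traj = run_protocol(two_state, VoltageProtocol(((200.0, 5.0),)), P0, 5.0)
        assert np.abs(traj.P[-1] - P_inf).max() < 1e-6

    def test_conservation_along_trajectory(self, lti_model):
        scheme = lti_model.scheme
        P0 = stationary_distribution(scheme.generator(-80.0))
        proto = VoltageProtocol(((5.0, 0.0), (45.0, -80.0), (5.0, 0.0)))
        traj = run_protocol(scheme, proto, P0, 0.1)
        assert np.abs(traj.P.sum(axis=1) - 1.0).max() < 1e-9
        assert traj.P.min() > -1e-12

    def test_invalid_dt_rejected(self, two_state):
        with pytest.raises(ValueError):
            run_protocol(two_state, VoltageProtocol(((1.0, 0.0),)), np.array([1.0, 0.0]), 0.0)


class TestRateTable:
    def test_per_s_units_converted(self, tmp_path):
        p = tmp_path / "rates.csv"
        p.write_text("# units: per_s\nfrom,to,k0,k1\nA,B,1000,0.01\nB,A,500,0\n")
        df = load_rate_table(p)
        assert df.attrs["units"] == "per_s"
        assert df["k0"].tolist() == [1.0, 0.5]

    def test_default_units_per_ms(self, tmp_path):
        p = tmp_path / "rates.csv"
        p.write_text("from,to,k0,k1\nA,B,2.0,0\nB,A,1.0,0\n")
        assert load_rate_table(p)["k0"].tolist() == [2.0, 1.0]

    def test_unknown_units_rejected(self, tmp_path):
        p = tmp_path / "rates.csv"
        p.write_text("# units: per_hour\nfrom,to,k0,k1\nA,B,1,0\n")
        with pytest.raises(ValueError, match="unknown rate units"):
            load_rate_table(p)
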