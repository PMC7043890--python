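"""Leaky-integrator recursions: limits, bounds, and channel comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from navlti.integrator import (
    LeakyIntegratorParams,
    Signal,
    compare_ps_vs_integrator,
    integrate_continuous,
    integrate_discrete,
    integrate_saturating,
    pulse_train_input,
)


def _uniform_signal(values, dt=0.05):
    values = np.asarray(values, dtype=float)
    return Signal(times=np.arange(values.size) * dt, values=values)


class TestContinuous:
    def test_pure_decay_reaches_e_fold_at_tau(self):
        tau = 50.0
        x = _uniform_signal(np.zeros(1001), dt=tau / 1000)
        y = integrate_continuous(x, tau, y0=1.0)
        assert y.values[-1] == pytest.approx(math.exp(-1.0), rel=1e-9)

    def test_constant_input_fixed_point(self):
        tau, c = 20.0, 0.3
        x = _uniform_signal(np.full(4001, c), dt=0.25)
        y = integrate_continuous(x, tau)
        assert y.values[-1] == pytest.approx(c * tau, rel=1e-6)

    def test_discrete_converges_to_continuous(self):
        """Eq.-2-style recursion approaches the exact solution as dt -> 0."""
        tau = 30.0
        errors = []
        for dt in (0.5, 0.05):
            n = int(100.0 / dt) + 1
            x = Signal(times=np.arange(n) * dt, values=np.ones(n) * 0.1)
            exact = integrate_continuous(x, tau)
            approx = integrate_discrete(x, LeakyIntegratorParams(tau_leak=tau, dt=dt))
            errors.append(np.abs(exact.values - approx.values).max())
        assert errors[1] < errors[0] / 5  # O(dt) refinement


class TestDiscrete:
    def test_infinite_tau_reduces_to_summation(self):
        rng = np.random.default_rng(0)
        x = _uniform_signal(rng.uniform(0, 1, 200), dt=0.1)
        y = integrate_discrete(x, LeakyIntegratorParams(tau_leak=1e12, dt=0.1))
        expected = np.concatenate([[0.0], np.cumsum(x.values[1:] * 0.1)])
        assert np.allclose(y.values, expected, atol=1e-6)

    def test_zero_tau_gives_scaled_copy(self):
        rng = np.random.default_rng(1)
        x = _uniform_signal(rng.uniform(0, 1, 100), dt=0.1)
        y = integrate_discrete(x, LeakyIntegratorParams(tau_leak=1e-9, dt=0.1))
        assert np.allclose(y.values[1:], x.values[1:] * 0.1)

    def test_impulse_response_decays_exponentially(self):
        dt, tau = 0.1, 5.0
        x = np.zeros(100)
        x[10] = 1.0
        y = integrate_discrete(_uniform_signal(x, dt), LeakyIntegratorParams(tau, dt=dt))
        post = y.values[10:]
        expected = x[10] * dt * np.exp(-np.arange(post.size) * dt / tau)
        assert np.allclose(post, expected, atol=1e-12)

    def test_superposition_holds_for_linear_form(self):
        rng = np.random.default_rng(2)
        params = LeakyIntegratorParams(tau_leak=12.0, dt=0.1)
        x1 = rng.uniform(0, 1, 150)
        x2 = rng.uniform(0, 1, 150)
        y1 = integrate_discrete(_uniform_signal(x1, 0.1), params).values
        y2 = integrate_discrete(_uniform_signal(x2, 0.1), params).values
        y12 = integrate_discrete(_uniform_signal(x1 + x2, 0.1), params).values
        assert np.allclose(y12, y1 + y2, atol=1e-12)


class TestSaturating:
    def test_single_pulse_increments_by_y_inc(self):
        """One t_p-long pulse from y=0 with tau >> t_p raises y by ~y_inc
        (the 20% per-action-potential LTI share)."""
        params = LeakyIntegratorParams(tau_leak=1e6, dt=0.05, y_inc=0.2, t_p=5.0)
        x = pulse_train_input(1.0, 5.0, 5.0, 0.05)
        y = integrate_saturating(x, params)
        # the increment self-attenuates within the pulse: exact limit is
        # 1 - exp(-y_inc) ~ 0.181, i.e. "approximately 20%"
        assert y.values[-1] == pytest.approx(0.2, abs=0.025)
        assert y.values[-1] == pytest.approx(1.0 - math.exp(-0.2), abs=0.005)

    def test_single_step_pulse_is_exact(self):
        params = LeakyIntegratorParams(tau_leak=435.0, dt=5.0, y_inc=0.2, t_p=5.0)
        x = Signal(times=np.array([0.0, 5.0]), values=np.array([0.0, 1.0]))
        y = integrate_saturating(x, params)
        assert y.values[-1] == pytest.approx(0.2, abs=1e-12)

    def test_sustained_input_rises_to_fixed_point(self):
        """Under continuous input the output climbs monotonically to the
        recursion's fixed point y* = g / (1 - d(1-g)), just below 1."""
        params = LeakyIntegratorParams(tau_leak=435.0, dt=0.5, y_inc=0.2, t_p=5.0)
        x = _uniform_signal(np.ones(40000), dt=0.5)
        y = integrate_saturating(x, params)
        assert (np.diff(y.values) >= -1e-12).all()
        d = math.exp(-params.dt / params.tau_leak)
        g = params.y_inc * params.dt / params.t_p
        y_star = g / (1.0 - d * (1.0 - g))
        assert y.values[-1] == pytest.approx(y_star, abs=1e-6)
        assert y_star > 0.9

    @given(seed=st.integers(0, 500), tau=st.floats(5.0, 2000.0), y0=st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_output_bounded_for_adversarial_digital_input(self, seed, tau, y0):
        rng = np.random.default_rng(seed)
        x = _uniform_signal(rng.integers(0, 2, 400).astype(float), dt=0.5)
        params = LeakyIntegratorParams(tau_leak=tau, dt=0.5, y_inc=0.2, t_p=5.0)
        y = integrate_saturating(x, params, y0=y0)
        assert (y.values >= 0.0).all() and (y.values <= 1.0).all()

    def test_superposition_violated_by_saturation(self):
        params = LeakyIntegratorParams(tau_leak=435.0, dt=5.0, y_inc=0.2, t_p=5.0)
        x = _uniform_signal(np.ones(200), dt=5.0)
        y1 = integrate_saturating(x, params).values
        # "doubling" the input is impossible digitally; instead verify the
        # response to a pulse pair differs from the sum of single responses
        xa = np.zeros(200)
        xa[10] = 1.0
        xb = np.zeros(200)
        xb[11] = 1.0
        ya = integrate_saturating(_uniform_signal(xa, 5.0), params).values
        yb = integrate_saturating(_uniform_signal(xb, 5.0), params).values
        yab = integrate_saturating(_uniform_signal(xa + xb, 5.0), params).values
        assert not np.allclose(yab, ya + yb, atol=1e-6)
        del y1

    def test_non_digital_input_rejected(self):
        params = LeakyIntegratorParams(tau_leak=435.0, dt=0.5)
        with pytest.raises(ValueError, match="digital"):
            integrate_saturating(_uniform_signal([0.0, 0.5, 1.0], 0.5), params)

    def test_dt_exceeding_pulse_rejected(self):
        params = LeakyIntegratorParams(tau_leak=435.0, dt=10.0, t_p=5.0)
        with pytest.raises(ValueError, match="t_p"):
            integrate_saturating(_uniform_signal([0.0, 1.0], 10.0), params)


class TestComparison:
    def test_steady_level_matches_brute_force_recursion(self):
        """The reported steady integrator stats agree with directly running
        the recursion for a long time (independent oracle)."""
        import pandas as pd

        params = LeakyIntegratorParams(tau_leak=435.0, dt=0.05, y_inc=0.2, t_p=5.0)
        model_stub = pd.DataFrame(
            {"freq_hz": [10.0], "ps_min": [0.5], "ps_max": [0.6], "ps_mean": [0.55]}
        )
        table = compare_ps_vs_integrator(model_stub, params)
        x = pulse_train_input(10.0, 5.0, 12000.0, 0.05)
        y = integrate_saturating(x, params)
        last_cycle = y.values[y.times >= 11900.0]
        assert table["y_max"].iloc[0] == pytest.approx(last_cycle.max(), abs=1e-3)
        assert table["y_min"].iloc[0] == pytest.approx(last_cycle.min(), abs=1e-3)

    def test_monotone_steady_level_in_frequency(self):
        import pandas as pd

        params = LeakyIntegratorParams(tau_leak=435.0, dt=0.1, y_inc=0.2, t_p=5.0)
        stub = pd.DataFrame(
            {"freq_hz": [2.0, 10.0, 50.0], "ps_min": 0.0, "ps_max": 0.0, "ps_mean": 0.0}
        )
        table = compare_ps_vs_integrator(stub, params)
        assert table["y_mean"].is_monotonic_increasing

    def test_identical_signals_give_zero_deviation(self, lti_model):
        """Feeding the model's own response as both sides yields zero diff."""
        import pandas as pd

        resp = pd.DataFrame(
            {"freq_hz": [0.0], "ps_min": [0.0], "ps_max": [0.0], "ps_mean": [0.0]}
        )
        params = LeakyIntegratorParams(tau_leak=435.0, dt=0.1)
        table = compare_ps_vs_integrator(resp, params)
        assert table["mean_diff"].abs().max() == 0.0
        assert table.attrs["rms"] == 0.0
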