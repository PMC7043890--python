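"""Leaky-integrator mathematics mirrored by the LTI state occupancy.

Three forms are implemented:

continuous
    ``dy/dt = x(t) - y(t)/tau_leak`` for piecewise-constant input, solved
    exactly per segment.

discrete (linear)
    ``y[t+dt] = y[t] * exp(-dt/tau_leak) + x[t+dt] * dt`` - a leak step
    followed by accumulation of the incoming sample.  With tau_leak >> dt
    this degenerates to a plain running sum (an event counter for digital
    pulses); with tau_leak << dt the output is just a scaled copy of the
    input.

saturating (digital input)
    The channel-like variant where a 0/1 input can only increment the
    output by a capped per-pulse amount ``y_inc`` of the remaining headroom,
    spread over the pulse duration ``t_p``:

        y[t+dt] = y[t] * exp(-dt/tau) + x[t+dt] * f[t+dt]
        f[t+dt] = y_inc * (dt/t_p) * (1 - y[t] * exp(-dt/tau))

    which keeps y in [0, 1], exactly as P_S can only grow by ~20% of the
    currently available channel fraction per action potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LeakyIntegratorParams",
    "Signal",
    "integrate_continuous",
    "integrate_discrete",
    "integrate_saturating",
    "pulse_train_input",
    "compare_ps_vs_integrator",
]


@dataclass(frozen=True)
class LeakyIntegratorParams:
    """Parameters of the discrete saturating integrator.

    tau_leak : ms      leak time constant
    dt : ms            sampling interval (default 0.05 ms)
    y_inc : (0, 1]     maximum per-pulse increment (0.2 = the 20% LTI share)
    t_p : ms           pulse duration over which the increment is spread
    """

    tau_leak: float
    dt: float = 0.05
    y_inc: float = 0.2
    t_p: float = 5.0

    def __post_init__(self) -> None:
        if not (self.tau_leak > 0 and self.dt > 0 and self.t_p > 0):
            raise ValueError("tau_leak, dt and t_p must be positive")
        if not (0 < self.y_inc <= 1):
            raise ValueError("y_inc must lie in (0, 1]")


@dataclass
class Signal:
    """Uniformly (or piecewise) sampled scalar signal."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def dt(self) -> float:
        steps = np.diff(self.times)
        if steps.size == 0:
            raise ValueError("signal has fewer than two samples")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("signal is not uniformly sampled")
        return float(steps[0])


def integrate_continuous(x: Signal, tau_leak: float, y0: float = 0.0) -> Signal:
    """Exact solution of ``dy/dt = x - y/tau`` for piecewise-constant input.

    Each sample of ``x`` is held constant until the next sample time; on a
    segment with constant input c the solution relaxes exponentially toward
    the fixed point ``c * tau``.
    """
    if tau_leak <= 0:
        raise ValueError("tau_leak must be positive")
    t = x.times
    y = np.empty_like(t)
    y_prev = float(y0)
    y[0] = y_prev
    for i in range(1, t.size):
        h = t[i] - t[i - 1]
        c = x.values[i - 1]
        decay = math.exp(-h / tau_leak)
        y_prev = c * tau_leak + (y_prev - c * tau_leak) * decay
        y[i] = y_prev
    return Signal(times=t.copy(), values=y)


def integrate_discrete(x: Signal, params: LeakyIntegratorParams, y0: float = 0.0) -> Signal:
    """Linear discrete leaky integration, the recursion applied verbatim."""
    dt = x.dt
    decay = math.exp(-dt / params.tau_leak)
    y = np.empty_like(x.values)
    y_prev = float(y0)
    y[0] = y_prev
    for i in range(1, y.size):
        y_prev = y_prev * decay + x.values[i] * dt
        y[i] = y_prev
    return Signal(times=x.times.copy(), values=y)


def integrate_saturating(x: Signal, params: LeakyIntegratorParams, y0: float = 0.0) -> Signal:
    """Saturating leaky integration of a digital (0/1) input.

    The per-step increment is ``y_inc * (dt/t_p)`` of the headroom left
    after the leak, so a full pulse of duration t_p from y = 0 raises the
    output by about ``y_inc``, and y stays in [0, 1] for any input.
    """
    vals = x.values
    if not np.all((vals == 0.0) | (vals == 1.0)):
        raise ValueError("saturating integrator expects a digital 0/1 input")
    dt = x.dt
    if dt > params.t_p + 1e-12:
        raise ValueError("dt must not exceed the pulse duration t_p")
    if not (0.0 <= y0 <= 1.0):
        raise ValueError("y0 must lie in [0, 1]")
    decay = math.exp(-dt / params.tau_leak)
    gain = params.y_inc * dt / params.t_p
    y = np.empty_like(vals)
    y_prev = float(y0)
    y[0] = y_prev
    for i in range(1, y.size):
        leaked = y_prev * decay
        y_prev = leaked + vals[i] * gain * (1.0 - leaked)
        y[i] = y_prev
    return Signal(times=x.times.copy(), values=y)


def pulse_train_input(
    freq: float,
    pulse_ms: float,
    duration: float,
    dt: float,
) -> Signal:
    """Digital pulse-train input: 1 during pulses, 0 in between."""
    if freq < 0:
        raise ValueError("freq must be non-negative")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    x = np.zeros(n)
    if freq > 0:
        period = 1000.0 / freq
        if pulse_ms > period + 1e-9:
            raise ValueError("pulse does not fit the period")
        phase = np.mod(t, period)
        x[phase < pulse_ms - 1e-9] = 1.0
    return Signal(times=t, values=x)


def compare_ps_vs_integrator(
    model_response: pd.DataFrame,
    params: LeakyIntegratorParams,
    pulse_ms: float = 5.0,
    settle_ms: float | None = None,
) -> pd.DataFrame:
    """Steady-level comparison of the channel's P_S with the integrator.

    ``model_response`` is the output of
    :func:`navlti.analysis.frequency_response` (per-frequency steady P_S
    min/max/mean).  For each frequency the saturating integrator is run to
    steady state on the same digital pulse train and its steady cycle
    statistics are recorded next to the model's, with the mean difference
    per frequency and the overall RMS deviation in ``df.attrs["rms"]``.
    """
    rows = []
    for _, rec in model_response.iterrows():
        f = float(rec["freq_hz"])
        if f == 0.0:
            y_min = y_max = y_mean = 0.0
        else:
            period = 1000.0 / f
            if pulse_ms >= period - 1e-9:
                # continuous input: closed-form fixed point of the recursion
                decay = math.exp(-params.dt / params.tau_leak)
                g = params.y_inc * params.dt / params.t_p
                y_star = g / (1.0 - decay * (1.0 - g))
                y_min = y_max = y_mean = y_star
            else:
                # settle for >> tau_leak so the steady cycle is reached
                duration = settle_ms or max(12.0 * params.tau_leak, 10.0 * period)
                duration = math.ceil(duration / period) * period
                x = pulse_train_input(f, pulse_ms, duration, params.dt)
                y = integrate_saturating(x, params)
                last = y.times >= duration - period
                y_min = float(y.values[last].min())
                y_max = float(y.values[last].max())
                y_mean = float(np.mean(y.values[last]))
        rows.append(
            (f, rec["ps_min"], rec["ps_max"], rec["ps_mean"],
             y_min, y_max, y_mean, rec["ps_mean"] - y_mean)
        )
    out = pd.DataFrame(
        rows,
        columns=["freq_hz", "ps_min", "ps_max", "ps_mean",
                 "y_min", "y_max", "y_mean", "mean_diff"],
    )
    out.attrs["rms"] = float(np.sqrt(np.mean(out["mean_diff"] ** 2)))
    return out
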