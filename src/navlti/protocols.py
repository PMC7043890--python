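"""Voltage-clamp protocol builders and macroscopic current simulation.

Protocols are piecewise-constant command-voltage sequences: pulse trains
(availability decay), two-pulse recovery (bi-exponential recovery from
inactivation), and simple steps.  Macroscopic current is ohmic from the
open-state occupancy: ``I(t) = G_Na * P_O(t) * (V(t) - E_Na)``, negative
(inward) for V below the Na+ reversal potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import VoltageProtocol, run_protocol
from .models import NavModelSpec, rested_state

__all__ = [
    "CurrentSimSettings",
    "CurrentTrace",
    "pulse_train_protocol",
    "recovery_protocol",
    "simulate_current",
]


@dataclass(frozen=True)
class CurrentSimSettings:
    """Conductance and reversal for current simulation.

    ``G_Na`` is the total Nav conductance in nS, or a density in nS/pF when
    ``C_m`` (pF) is given, matching the dynamic-clamp axis convention.
    ``E_Na`` defaults to +60 mV (physiological convention); inward current
    is negative.
    """

    G_Na: float
    E_Na: float = 60.0
    C_m: float | None = None

    def __post_init__(self) -> None:
        if not (self.G_Na > 0):
            raise ValueError("G_Na must be positive")
        if self.C_m is not None and not (self.C_m > 0):
            raise ValueError("C_m must be positive when given")

    @property
    def total_conductance(self) -> float:
        """Total conductance in nS (density scaled by C_m if applicable)."""
        return self.G_Na * self.C_m if self.C_m is not None else self.G_Na


@dataclass
class CurrentTrace:
    """Simulated (or synthetic) whole-cell current trace.

    times in ms, I in pA, voltage in mV, all equal length.
    """

    times: np.ndarray
    I: np.ndarray
    voltage: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if not (self.times.size == self.I.size == self.voltage.size):
            raise ValueError("times, I and voltage must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.times, "voltage_mV": self.voltage, "current_pA": self.I}
        )


def pulse_train_protocol(
    V_hold: float,
    V_pulse: float,
    pulse_ms: float,
    freq: float,
    n_pulses: int,
) -> VoltageProtocol:
    """Train of depolarizing pulses at a given repetition rate.

    Each cycle is ``pulse_ms`` at ``V_pulse`` followed by an inter-pulse
    interval of ``1000/freq - pulse_ms`` at ``V_hold`` (e.g. 195, 95 and
    45 ms for 5 ms pulses at 5, 10 and 20 Hz).  ``pulse_ms`` exactly equal
    to the period degenerates to one constant depolarization.
    """
    if freq <= 0 or pulse_ms <= 0 or n_pulses < 1:
        raise ValueError("freq, pulse_ms and n_pulses must be positive")
    period = 1000.0 / freq
    gap = period - pulse_ms
    if gap < -1e-9:
        raise ValueError(
            f"pulse_ms = {pulse_ms} exceeds the period {period:.3f} ms at {freq} Hz"
        )
    label = f"train {freq:g} Hz, {pulse_ms:g} ms at {V_pulse:g} mV"
    if abs(gap) <= 1e-9:  # continuous-depolarization limit
        return VoltageProtocol(((n_pulses * pulse_ms, V_pulse),), label=label)
    segments: list[tuple[float, float]] = []
    for _ in range(n_pulses):
        segments.append((pulse_ms, V_pulse))
        segments.append((gap, V_hold))
    return VoltageProtocol(tuple(segments), label=label)


def recovery_protocol(
    V_hold: float,
    V_pulse: float,
    pulse_ms: float,
    delays: list[float],
) -> list[VoltageProtocol]:
    """Two-pulse recovery protocols, one per recovery delay.

    The first pulse inactivates the channels; after ``delay`` ms at
    ``V_hold`` the identical test pulse probes availability.
    """
    if len(delays) == 0:
        raise ValueError("at least one recovery delay is required")
    delays = list(delays)
    if any(d <= 0 for d in delays):
        raise ValueError("delays must be positive")
    if sorted(delays) != delays:
        raise ValueError("delays must be sorted ascending")
    protocols = []
    for d in delays:
        protocols.append(
            VoltageProtocol(
                ((pulse_ms, V_pulse), (d, V_hold), (pulse_ms, V_pulse)),
                label=f"recovery delay {d:g} ms",
            )
        )
    return protocols


def simulate_current(
    model: NavModelSpec,
    protocol: VoltageProtocol,
    settings: CurrentSimSettings,
    dt_out: float = 0.01,
    P0: np.ndarray | None = None,
    V_rest: float | None = None,
) -> CurrentTrace:
    """Simulate the macroscopic Na+ current under a voltage protocol.

    The initial occupancy defaults to the rested (stationary) state at
    ``V_rest``; if not given, the holding potential is taken as the most
    hyperpolarized level in the protocol (sweeps begin from holding, even
    when the first segment is a pulse).  Default sampling is 0.01 ms
    (100 kHz), matching voltage-clamp digitization.
    """
    if P0 is None:
        if V_rest is None:
            V_rest = min(level for _, level in protocol.segments)
        P0 = rested_state(model, V_rest)
    traj = run_protocol(model.scheme, protocol, P0, dt_out)
    P_open = traj.P[:, model.scheme.conducting].sum(axis=1)
    g = settings.total_conductance  # nS
    current = g * P_open * (traj.voltage - settings.E_Na)  # nS*mV = pA
    return CurrentTrace(times=traj.times, I=current, voltage=traj.voltage)
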