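"""Synthetic voltage-clamp datasets with the statistical structure of
whole-cell Na+ current recordings.

Recovery-from-inactivation datasets are generated from built-in
bi-exponential ground-truth parameter sets (neonatal brainstem-slice and
acutely dissociated mature neurons, each at -80 and -100 mV), with
additive Gaussian noise on the normalized availability - the quantity
actually measured - and optional cell-to-cell parameter jitter
reconstructed from the reported standard errors (sd ~ SE * sqrt(n)).  The
jitter is an emulation of cohort variability, not a reconstruction of any
per-cell values.  Every generator is a pure function of (parameters,
seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import biexp_availability
from .protocols import CurrentSimSettings, CurrentTrace, pulse_train_protocol, simulate_current

__all__ = [
    "RecoveryGroundTruth",
    "NoiseModel",
    "builtin_param_sets",
    "synth_recovery_dataset",
    "synth_pulse_train_trace",
]


@dataclass(frozen=True)
class RecoveryGroundTruth:
    """Bi-exponential recovery parameters of one preparation/voltage.

    Amplitudes are fractional and sum to ~1; time constants in ms.  The
    reported standard errors and cell count are retained as metadata for
    jitter emulation.
    """

    preparation: str
    voltage: float
    a_fast: float
    tau_fast: float
    a_slow: float
    tau_slow: float
    se: dict[str, float] = field(default_factory=dict)
    n_cells: int = 0

    def __post_init__(self) -> None:
        if not (self.tau_fast < self.tau_slow):
            raise ValueError("tau_fast must be smaller than tau_slow")
        if not (0.95 <= self.a_fast + self.a_slow <= 1.05):
            raise ValueError("fractional amplitudes must sum to ~1")

    def curve(self, delays: np.ndarray) -> np.ndarray:
        return biexp_availability(delays, self.a_fast, self.tau_fast, self.a_slow, self.tau_slow)


def builtin_param_sets() -> list[RecoveryGroundTruth]:
    """The four reported recovery parameter sets (means, SEs, cell counts)."""
    return [
        RecoveryGroundTruth(
            "neonatal_slice", -80.0, 0.786, 3.14, 0.212, 612.0,
            se={"a_fast": 0.013, "tau_fast": 0.126, "a_slow": 0.007, "tau_slow": 76.0},
            n_cells=18,
        ),
        RecoveryGroundTruth(
            "neonatal_slice", -100.0, 0.775, 1.45, 0.199, 209.0,
            se={"a_fast": 0.017, "tau_fast": 0.07, "a_slow": 0.01, "tau_slow": 39.0},
            n_cells=6,
        ),
        RecoveryGroundTruth(
            "mature_dissociated", -80.0, 0.81, 8.54, 0.187, 517.0,
            se={"a_fast": 0.022, "tau_fast": 0.59, "a_slow": 0.017, "tau_slow": 126.0},
            n_cells=6,
        ),
        RecoveryGroundTruth(
            "mature_dissociated", -100.0, 0.74, 5.25, 0.252, 247.0,
            se={"a_fast": 0.042, "tau_fast": 0.69, "a_slow": 0.033, "tau_slow": 84.0},
            n_cells=5,
        ),
    ]


def get_param_set(preparation: str, voltage: float) -> RecoveryGroundTruth:
    for truth in builtin_param_sets():
        if truth.preparation == preparation and truth.voltage == voltage:
            return truth
    raise KeyError(f"no built-in parameter set for {preparation!r} at {voltage} mV")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise settings for synthetic data.

    ``sd_availability`` acts on the normalized availability ratio;
    ``sd_current_pA`` acts on raw current samples (train generator).  The
    seed is recorded in every dataset's metadata.
    """

    sd_availability: float = 0.02
    sd_current_pA: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_availability < 0 or self.sd_current_pA < 0:
            raise ValueError("noise standard deviations must be non-negative")


def _jittered_params(
    truth: RecoveryGroundTruth, rng: np.random.Generator
) -> tuple[float, float, float, float]:
    """Draw one cell's parameters.

    Cell-level sd is reconstructed as SE * sqrt(n).  Time constants are
    drawn log-normally (median at the reported mean) so large fractional
    spreads cannot produce non-positive values; amplitudes are normal,
    floored at a small positive value.
    """
    n = max(truth.n_cells, 1)
    root_n = np.sqrt(n)

    def log_normal(mean: float, se: float) -> float:
        # mean-preserving lognormal so cohort averages stay unbiased
        cv = se * root_n / mean
        sigma = np.sqrt(np.log1p(cv**2))
        return float(mean * np.exp(rng.normal(-0.5 * sigma**2, sigma)))

    a_f = max(float(rng.normal(truth.a_fast, truth.se.get("a_fast", 0.0) * root_n)), 0.05)
    a_s = max(float(rng.normal(truth.a_slow, truth.se.get("a_slow", 0.0) * root_n)), 0.01)
    t_f = log_normal(truth.tau_fast, truth.se.get("tau_fast", 0.0))
    t_s = log_normal(truth.tau_slow, truth.se.get("tau_slow", 0.0))
    if t_s <= 3.0 * t_f:  # keep the two components separable
        t_s = 3.0 * t_f
    return a_f, t_f, a_s, t_s


def synth_recovery_dataset(
    truth: RecoveryGroundTruth,
    delays: np.ndarray,
    n_cells: int,
    noise: NoiseModel,
    cell_jitter: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Generate a multi-cell recovery-from-inactivation dataset.

    Per cell: availability = biexp(truth or jittered params, delay) +
    Gaussian noise, clipped to [0, 1.05].  Returns the long-format
    DataFrame (``delay_ms, availability, replicate``) and a metadata dict
    with seed, ground truth and noise settings.  Identical inputs give
    bit-identical output.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    delays = np.asarray(delays, dtype=float)
    span = delays.max() / delays.min()
    if span < 100:
        import warnings

        warnings.warn(
            "recovery delays span less than two decades; both time scales "
            "may not be constrained", stacklevel=2,
        )
    rng = np.random.default_rng(noise.seed)
    frames = []
    cell_params = []
    for cell in range(n_cells):
        if cell_jitter:
            a_f, t_f, a_s, t_s = _jittered_params(truth, rng)
        else:
            a_f, t_f, a_s, t_s = truth.a_fast, truth.tau_fast, truth.a_slow, truth.tau_slow
        cell_params.append({"a_fast": a_f, "tau_fast": t_f, "a_slow": a_s, "tau_slow": t_s})
        clean = biexp_availability(delays, a_f, t_f, a_s, t_s)
        noisy = clean + rng.normal(0.0, noise.sd_availability, size=delays.size)
        frames.append(
            pd.DataFrame(
                {
                    "delay_ms": delays,
                    "availability": np.clip(noisy, 0.0, 1.05),
                    "replicate": cell,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    meta = {
        "seed": noise.seed,
        "sd_availability": noise.sd_availability,
        "cell_jitter": cell_jitter,
        "n_cells": n_cells,
        "truth": {
            "preparation": truth.preparation,
            "voltage": truth.voltage,
            "a_fast": truth.a_fast,
            "tau_fast": truth.tau_fast,
            "a_slow": truth.a_slow,
            "tau_slow": truth.tau_slow,
        },
        "cell_params": cell_params,
    }
    return data, meta


def synth_pulse_train_trace(
    model,
    freq: float,
    settings: CurrentSimSettings,
    noise: NoiseModel,
    V_hold: float = -80.0,
    V_pulse: float = -15.0,
    pulse_ms: float = 5.0,
    n_pulses: int = 10,
    dt_out: float = 0.02,
) -> CurrentTrace:
    """Simulated pulse-train current sweep with additive current noise.

    Exercises peak extraction on imperfect data; with zero noise this
    reduces exactly to :func:`navlti.protocols.simulate_current`.
    """
    protocol = pulse_train_protocol(V_hold, V_pulse, pulse_ms, freq, n_pulses)
    trace = simulate_current(model, protocol, settings, dt_out=dt_out)
    if noise.sd_current_pA > 0:
        rng = np.random.default_rng(noise.seed)
        trace = CurrentTrace(
            times=trace.times,
            I=trace.I + rng.normal(0.0, noise.sd_current_pA, size=trace.I.size),
            voltage=trace.voltage,
        )
    return trace
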