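"""In-silico dynamic clamp: a surrogate pacemaker neuron driven by
model-generated Na+ current.

The host neuron stands in for the live serotonergic raphe neurons used in
the dynamic-clamp experiments: a minimal conductance-based pacemaker with
a leak, a delayed-rectifier K+ conductance, and a slow spike-triggered
adaptation conductance, calibrated once to the documented phenotype (slow
regular spiking at a few Hz, broad action potentials) and then frozen in a
versioned parameter file.  Everything derived from it is therefore
qualitative - orderings, slopes' signs, adaptation directions - never a
numeric match to any live-cell value.

The hybrid loop mirrors a real-time dynamic-clamp cycle at 50 kHz: the Nav
occupancies advance by the matrix method (an exact matrix-exponential
propagator per voltage, cached on a 0.05 mV grid), the Nav current
``I_Na = G_Na * C_m * P_O * (V - E_Na)`` is computed, and the host
membrane equation advances one Euler step.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .models import NavModelSpec, rested_state

__all__ = [
    "HostNeuronSpec",
    "HybridSimResult",
    "default_host",
    "simulate_hybrid",
    "detect_spikes",
    "instantaneous_frequency",
    "steady_frequency",
    "frequency_vs_gna",
    "frequency_vs_iinj",
]

V_MIN, V_MAX = -120.0, 60.0
_V_QUANTUM = 0.05  # mV grid for cached Nav propagators


@dataclass(frozen=True)
class HostNeuronSpec:
    """Parameters of the surrogate pacemaker host neuron.

    Conductances in nS, potentials in mV, capacitance in pF, time
    constants in ms.  The delayed rectifier uses a single activation gate
    raised to the fourth power.  Slow adaptation is spike-triggered: each
    action potential increments a gating variable z by ``z_inc * (1 - z)``
    and z decays with time constant ``tau_z``, driving a K+-reversal
    adaptation current.  The stereotyped (spike-shape-independent)
    increment makes the pacing depend on spike COUNT, so differences
    between Nav variants express themselves through the sodium current's
    effect on the interspike trajectory, not through spike-amplitude side
    effects on the adaptation machinery.
    """

    C_m: float = 20.0
    g_leak: float = 1.0
    E_leak: float = -40.0
    g_K: float = 40.0
    E_K: float = -90.0
    n_vhalf: float = -25.0
    n_slope: float = 9.0
    tau_n: float = 4.0
    g_adapt: float = 3.0
    tau_z: float = 100.0
    z_inc: float = 0.35
    spike_thresh: float = -20.0
    E_Na: float = 60.0
    V_init: float = -65.0

    @classmethod
    def from_json(cls, path) -> "HostNeuronSpec":
        return cls(**json.loads(open(path).read()))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    def n_inf(self, V: float) -> float:
        return 1.0 / (1.0 + math.exp(-(V - self.n_vhalf) / self.n_slope))


def default_host() -> HostNeuronSpec:
    """The packaged, calibrated host parameter set."""
    with resources.files("navlti").joinpath("data/host_neuron.json").open() as fh:
        return HostNeuronSpec(**json.load(fh))


@dataclass
class HybridSimResult:
    """Output of a hybrid (virtual dynamic-clamp) simulation.

    ``times``/``V``/``I_Na`` are sampled every ``record_every`` steps;
    ``occ_times``/``occupancy`` are a coarser occupancy trajectory for the
    (first) Nav model; ``spikes`` are spike times in ms.
    """

    times: np.ndarray
    V: np.ndarray
    I_Na: np.ndarray
    occ_times: np.ndarray
    occupancy: np.ndarray
    state_names: list[str]
    spikes: np.ndarray
    dt: float


class _PropagatorGrid:
    """Per-(scheme, dt) cache of matrix-exponential propagators on a
    voltage grid, so the hybrid loop never recomputes an expm."""

    def __init__(self, scheme, dt: float) -> None:
        self.scheme = scheme
        self.dt = dt
        self._cache: dict[int, np.ndarray] = {}

    def __call__(self, V: float) -> np.ndarray:
        idx = int(round((V - V_MIN) / _V_QUANTUM))
        M = self._cache.get(idx)
        if M is None:
            Vq = V_MIN + idx * _V_QUANTUM
            M = expm(self.scheme.generator(Vq) * self.dt)
            self._cache[idx] = M
        return M


def _iinj_array(I_inj, n_steps: int, dt: float) -> np.ndarray:
    """Expand a constant or piecewise (duration_ms, pA) spec to per-step pA."""
    if np.isscalar(I_inj):
        return np.full(n_steps, float(I_inj))
    out = np.zeros(n_steps)
    i = 0
    for dur, amp in I_inj:
        n = int(round(dur / dt))
        out[i : i + n] = amp
        i += n
    if i < n_steps:
        out[i:] = out[i - 1] if i > 0 else 0.0
    return out


def simulate_hybrid(
    host: HostNeuronSpec,
    nav: NavModelSpec | dict[str, NavModelSpec],
    G_Na: float,
    I_inj=0.0,
    duration: float = 5000.0,
    dt: float = 0.02,
    active_schedule: list[tuple[float, str]] | None = None,
    record_every: int = 25,
    occ_every: int = 250,
) -> HybridSimResult:
    """Run the virtual dynamic-clamp loop.

    ``G_Na`` is a conductance density in nS/pF, scaled by the host's C_m.
    ``nav`` may be a single model or a dict of named variants; with a dict,
    ``active_schedule`` (list of ``(duration_ms, name)``) selects which
    variant injects current at each moment while every variant's
    occupancies are integrated throughout - exactly the alternation used
    to swap models mid-protocol.  ``I_inj`` is a constant bias (pA) or a
    list of ``(duration_ms, pA)`` segments.

    Raises if the membrane potential leaves [-120, +60] mV (numerical
    failure) rather than returning garbage.
    """
    if isinstance(nav, NavModelSpec):
        navs = {"model": nav}
        active_schedule = [(duration, "model")]
    else:
        navs = dict(nav)
        if active_schedule is None:
            raise ValueError("active_schedule is required with multiple Nav models")

    n_steps = int(round(duration / dt))
    iinj = _iinj_array(I_inj, n_steps, dt)

    # per-step active-model index
    names = list(navs)
    active_idx = np.zeros(n_steps, dtype=int)
    pos = 0
    for seg_dur, name in active_schedule:
        n = int(round(seg_dur / dt))
        active_idx[pos : pos + n] = names.index(name)
        pos += n
    if pos < n_steps:
        active_idx[pos:] = active_idx[pos - 1]

    grids = [_PropagatorGrid(navs[name].scheme, dt) for name in names]
    occs = [rested_state(navs[name], host.V_init) for name in names]
    open_masks = [navs[name].scheme.conducting for name in names]
    g_total = G_Na * host.C_m  # nS

    V = host.V_init
    n_gate = host.n_inf(V)
    z_gate = 0.0
    above_thresh = False
    last_spike_step = -10**9

    n_rec = n_steps // record_every + 1
    rec_t = np.empty(n_rec)
    rec_v = np.empty(n_rec)
    rec_i = np.empty(n_rec)
    n_occ = n_steps // occ_every + 1
    occ_t = np.empty(n_occ)
    occ_p = np.empty((n_occ, occs[0].size))
    r = q = 0

    cons_check = max(n_steps // 100, 1)
    for step in range(n_steps):
        t = step * dt
        # Nav occupancies: exact matrix-method step at the present voltage
        for k in range(len(names)):
            occs[k] = occs[k] @ grids[k](V)
        if step % cons_check == 0:
            for k, P in enumerate(occs):
                tot = P.sum()
                if abs(tot - 1.0) > 1e-8:
                    raise ArithmeticError(
                        f"occupancy conservation lost ({names[k]}) at t={t:.2f} ms"
                    )
        a = active_idx[step]
        P_open = float(occs[a][open_masks[a]].sum())
        i_na = g_total * P_open * (V - host.E_Na)  # pA

        if step % record_every == 0:
            rec_t[r], rec_v[r], rec_i[r] = t, V, i_na
            r += 1
        if step % occ_every == 0:
            occ_t[q] = t
            occ_p[q] = occs[0]
            q += 1

        # host gates (Euler; time constants >> dt)
        n_gate += dt * (host.n_inf(V) - n_gate) / host.tau_n
        z_gate -= dt * z_gate / host.tau_z
        if V >= host.spike_thresh:
            if not above_thresh and (step - last_spike_step) * dt >= 5.0:
                z_gate += host.z_inc * (1.0 - z_gate)  # one increment per spike
                last_spike_step = step
            above_thresh = True
        else:
            above_thresh = False

        i_leak = host.g_leak * (V - host.E_leak)
        i_k = host.g_K * n_gate**4 * (V - host.E_K)
        i_adapt = host.g_adapt * z_gate * (V - host.E_K)
        dv = (-i_leak - i_k - i_adapt - i_na + iinj[step]) / host.C_m
        V = V + dt * dv
        if not (V_MIN <= V <= V_MAX):
            raise ArithmeticError(f"membrane potential diverged at t={t:.2f} ms: V={V:.1f}")

    times = rec_t[:r]
    v_arr = rec_v[:r]
    spikes = detect_spikes(v_arr, times)
    return HybridSimResult(
        times=times, V=v_arr, I_Na=rec_i[:r],
        occ_times=occ_t[:q], occupancy=occ_p[:q],
        state_names=navs[names[0]].scheme.state_names,
        spikes=spikes, dt=dt,
    )


def detect_spikes(
    V: np.ndarray,
    times: np.ndarray,
    threshold: float = -20.0,
    min_isi: float = 5.0,
) -> np.ndarray:
    """Spike times from upward threshold crossings, refractory-filtered.

    A spike is timestamped at the local voltage maximum following each
    upward crossing; crossings closer than ``min_isi`` to the previous
    accepted spike are ignored.
    """
    V = np.asarray(V, dtype=float)
    times = np.asarray(times, dtype=float)
    above = V >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    spikes: list[float] = []
    for c in crossings:
        # local maximum while above threshold
        j = c
        while j + 1 < V.size and V[j + 1] >= threshold:
            j += 1
        peak = c + int(np.argmax(V[c : j + 1]))
        t_spike = times[peak]
        if spikes and t_spike - spikes[-1] < min_isi:
            continue
        spikes.append(t_spike)
    return np.asarray(spikes)


def instantaneous_frequency(spikes: np.ndarray) -> pd.DataFrame:
    """Per-interval firing frequency, timestamped at the later spike."""
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size < 2:
        return pd.DataFrame({"time_ms": [], "freq_hz": []})
    isi = np.diff(spikes)
    return pd.DataFrame({"time_ms": spikes[1:], "freq_hz": 1000.0 / isi})


def steady_frequency(spikes: np.ndarray, window: tuple[float, float]) -> float:
    """Mean instantaneous frequency over the second half of a step window."""
    t0, t1 = window
    half = (t0 + t1) / 2.0
    f = instantaneous_frequency(spikes)
    sel = (f["time_ms"] >= half) & (f["time_ms"] <= t1)
    if not sel.any():
        return 0.0
    return float(f.loc[sel, "freq_hz"].mean())


def spike_width(result: HybridSimResult, threshold: float = -20.0) -> float:
    """Median time spent above ``threshold`` per spike (action-potential width)."""
    above = result.V >= threshold
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    n = min(starts.size, ends.size)
    if n == 0:
        return float("nan")
    widths = result.times[ends[:n]] - result.times[starts[:n]]
    return float(np.median(widths[widths > 0]))


def frequency_vs_gna(
    host: HostNeuronSpec,
    nav_variants: dict[str, NavModelSpec],
    gna_list: np.ndarray,
    duration: float = 5000.0,
    dt: float = 0.02,
    discard_ms: float = 1000.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Free-firing frequency versus Nav conductance density, per variant.

    Frequency is the steady firing rate after ``discard_ms`` of settling.
    Returns the curve and a least-squares line (slope, intercept) per
    variant.
    """
    rows = []
    for name, model in nav_variants.items():
        for gna in np.asarray(gna_list, dtype=float):
            res = simulate_hybrid(host, model, gna, duration=duration, dt=dt)
            freq = steady_frequency(res.spikes, (discard_ms, duration))
            rows.append((name, gna, freq))
    curve = pd.DataFrame(rows, columns=["variant", "gna_ns_per_pf", "freq_hz"])
    fits = []
    for name, grp in curve.groupby("variant"):
        slope, intercept = np.polyfit(grp["gna_ns_per_pf"], grp["freq_hz"], 1)
        fits.append((name, slope, intercept))
    return curve, pd.DataFrame(fits, columns=["variant", "slope", "intercept"])


def frequency_vs_iinj(
    host: HostNeuronSpec,
    nav_variants: dict[str, NavModelSpec],
    iinj_steps: np.ndarray,
    G_Na: float = 10.0,
    step_ms: float = 4000.0,
    dt: float = 0.02,
    alternate: bool = False,
    order: tuple[str, ...] | None = None,
    rest_ms: float = 0.0,
    rest_level_pA: float = 0.0,
) -> pd.DataFrame:
    """Steady firing frequency and adaptation depth per depolarizing step.

    Two protocol families are supported.  With ``alternate=False`` each
    variant runs the full staircase of ``iinj_steps`` separately (with an
    optional rest period of ``rest_ms`` before every step).  With
    ``alternate=True`` both variants are integrated continuously through a
    single staircase and each step is split between them in ``order``
    (either alternation direction), mirroring a model-swap protocol.

    Depolarizing bias beyond 40 pA is refused (depolarization block).
    Adaptation depth is (initial - steady) / initial instantaneous
    frequency within the portion of the step a variant was active.
    """
    iinj_steps = np.asarray(iinj_steps, dtype=float)
    if np.any(iinj_steps > 40.0):
        raise ValueError("I_inj above 40 pA is not supported (depolarization block)")

    rows = []
    if not alternate:
        for name, model in nav_variants.items():
            segments: list[tuple[float, float]] = []
            windows = []
            t = 0.0
            for amp in iinj_steps:
                if rest_ms > 0:
                    segments.append((rest_ms, rest_level_pA))
                    t += rest_ms
                segments.append((step_ms, amp))
                windows.append((amp, t, t + step_ms))
                t += step_ms
            res = simulate_hybrid(host, model, G_Na, I_inj=segments, duration=t, dt=dt)
            for amp, t0, t1 in windows:
                rows.append(_step_metrics(name, amp, res.spikes, t0, t1))
    else:
        order = order or tuple(nav_variants)
        segments = []
        schedule: list[tuple[float, str]] = []
        windows = []
        t = 0.0
        part = step_ms / len(order)
        for amp in iinj_steps:
            segments.append((step_ms, amp))
            for name in order:
                schedule.append((part, name))
                windows.append((name, amp, t, t + part))
                t += part
        res = simulate_hybrid(
            host, nav_variants, G_Na, I_inj=segments, duration=t, dt=dt,
            active_schedule=schedule,
        )
        for name, amp, t0, t1 in windows:
            rows.append(_step_metrics(name, amp, res.spikes, t0, t1))
    return pd.DataFrame(
        rows,
        columns=["variant", "iinj_pA", "steady_freq_hz", "initial_freq_hz", "adaptation_depth"],
    )


def _step_metrics(name: str, amp: float, spikes: np.ndarray, t0: float, t1: float):
    in_win = spikes[(spikes >= t0) & (spikes <= t1)]
    steady = steady_frequency(in_win, (t0, t1))
    f = instantaneous_frequency(in_win)
    initial = float(f["freq_hz"].iloc[0]) if len(f) else 0.0
    depth = (initial - steady) / initial if initial > 0 else 0.0
    return (name, amp, steady, initial, depth)
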