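"""Continuous-time Markov machinery for ion-channel kinetic schemes.

A gating scheme is a directed graph of states connected by voltage-dependent
rate constants of Eyring form ``k(V) = k0 * exp(k1 * V)``.  Occupancy
probabilities are propagated with the matrix method: within any interval of
constant membrane potential the occupancy row vector obeys ``dP/dt = P @ Q``
with generator matrix ``Q``, so ``P(t) = P(0) @ expm(Q t)`` exactly.

Units are milliseconds for time, millivolts for voltage, and ms^-1 for rates
throughout the in-memory representation; rate tables on disk may declare
``per_s`` and are converted on load.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "RateConstant",
    "KineticScheme",
    "VoltageProtocol",
    "OccupancyTrajectory",
    "eval_rate",
    "build_generator",
    "propagate",
    "stationary_distribution",
    "run_protocol",
    "load_rate_table",
]

#: |k1 * V| beyond which the Eyring exponent is considered out of range.
_MAX_EXPONENT = 500.0

#: probability-conservation tolerance for occupancy vectors
CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class RateConstant:
    """Eyring rate constant ``k(V) = k0 * exp(k1 * V)``.

    ``k0`` is the pre-exponential factor (same unit as the rate itself);
    ``k1`` is the exponential voltage factor in 1/mV (zero for a
    voltage-independent rate, negative for rates accelerated by
    hyperpolarization).
    """

    k0: float
    k1: float = 0.0

    def __post_init__(self) -> None:
        if not (self.k0 > 0):
            raise ValueError(f"k0 must be positive, got {self.k0}")
        if not math.isfinite(self.k1):
            raise ValueError(f"k1 must be finite, got {self.k1}")

    def __call__(self, V: float) -> float:
        return eval_rate(self, V)

    def scaled(self, factor: float) -> "RateConstant":
        """Return a copy with ``k0`` multiplied by ``factor`` (unit change)."""
        return RateConstant(self.k0 * factor, self.k1)


def eval_rate(rc: RateConstant, V: float) -> float:
    """Evaluate an Eyring rate constant at membrane potential ``V`` (mV)."""
    if not math.isfinite(V):
        raise ValueError(f"voltage must be finite, got {V}")
    exponent = rc.k1 * V
    if abs(exponent) > _MAX_EXPONENT:
        raise OverflowError(
            f"rate exponent k1*V = {exponent:.3g} out of range at V = {V} mV"
        )
    return rc.k0 * math.exp(exponent)


class KineticScheme:
    """A named-state kinetic scheme with voltage-dependent transition rates.

    Parameters
    ----------
    state_names
        Ordered, unique state labels (e.g. ``C1..C5, O6, I7..I12, S13``).
    conducting
        Mapping or iterable of flags marking which states carry current.
    transitions
        Directed ``(from_state, to_state, RateConstant)`` triples, rates in
        ms^-1.  Duplicate directed pairs are rejected.
    """

    def __init__(
        self,
        state_names: list[str],
        conducting: dict[str, bool] | list[bool],
        transitions: list[tuple[str, str, RateConstant]],
        name: str = "scheme",
    ) -> None:
        if len(set(state_names)) != len(state_names):
            raise ValueError("state labels must be unique")
        self.state_names = list(state_names)
        self.name = name
        self._index = {s: i for i, s in enumerate(self.state_names)}
        if isinstance(conducting, dict):
            unknown = set(conducting) - set(state_names)
            if unknown:
                raise ValueError(f"conducting flags for unknown states: {unknown}")
            self.conducting = np.array(
                [bool(conducting.get(s, False)) for s in state_names]
            )
        else:
            if len(conducting) != len(state_names):
                raise ValueError("conducting flags must match state count")
            self.conducting = np.asarray(conducting, dtype=bool)

        seen: set[tuple[str, str]] = set()
        for src, dst, rc in transitions:
            if src not in self._index or dst not in self._index:
                raise ValueError(f"transition {src}->{dst} references unknown state")
            if src == dst:
                raise ValueError(f"self-transition {src}->{src} not allowed")
            if (src, dst) in seen:
                raise ValueError(f"duplicate directed transition {src}->{dst}")
            if not isinstance(rc, RateConstant):
                raise TypeError("transition rates must be RateConstant instances")
            seen.add((src, dst))
        self.transitions = list(transitions)
        self._check_connected()
        # caches keyed by voltage (and step size for propagators)
        self._q_cache: dict[float, np.ndarray] = {}
        self._prop_cache: dict[tuple[float, float], np.ndarray] = {}

    # ------------------------------------------------------------------
    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def index(self, state: str) -> int:
        return self._index[state]

    def _check_connected(self) -> None:
        """Reject schemes whose undirected transition graph is disconnected."""
        n = self.n_states
        if n == 0:
            raise ValueError("scheme has no states")
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for src, dst, _ in self.transitions:
            i, j = self._index[src], self._index[dst]
            adj[i].add(j)
            adj[j].add(i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if len(seen) != n:
            orphans = [self.state_names[i] for i in range(n) if i not in seen]
            raise ValueError(f"scheme graph is not connected; unreachable: {orphans}")

    # ------------------------------------------------------------------
    def generator(self, V: float) -> np.ndarray:
        """Generator matrix Q at voltage ``V`` (row convention dP/dt = P Q)."""
        Q = self._q_cache.get(V)
        if Q is None:
            Q = build_generator(self, V)
            self._q_cache[V] = Q
        return Q

    def propagator(self, V: float, dt: float) -> np.ndarray:
        """``expm(Q(V) * dt)``, cached per (V, dt)."""
        key = (V, dt)
        M = self._prop_cache.get(key)
        if M is None:
            M = expm(self.generator(V) * dt)
            self._prop_cache[key] = M
        return M


def build_generator(scheme: KineticScheme, V: float) -> np.ndarray:
    """Build the generator matrix of ``scheme`` at voltage ``V``.

    Off-diagonal entries are the directed transition rates in ms^-1;
    diagonal entries are minus the row sums, so each row sums to zero.
    """
    n = scheme.n_states
    Q = np.zeros((n, n))
    for src, dst, rc in scheme.transitions:
        Q[scheme.index(src), scheme.index(dst)] = eval_rate(rc, V)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _check_occupancy(P: np.ndarray, n: int) -> np.ndarray:
    P = np.asarray(P, dtype=float).ravel()
    if P.shape != (n,):
        raise ValueError(f"occupancy vector must have length {n}")
    if np.any(P < -1e-12) or np.any(P > 1 + 1e-12):
        raise ValueError("occupancy entries must lie in [0, 1]")
    if abs(P.sum() - 1.0) > 1e-6:
        raise ValueError(f"occupancy must sum to 1, got {P.sum():.9f}")
    return P


def propagate(P0: np.ndarray, Q: np.ndarray, dt: float) -> np.ndarray:
    """Advance occupancy ``P0`` by ``dt`` ms under generator ``Q``.

    Uses the matrix exponential (scaling-and-squaring), which is exact for
    piecewise-constant voltage.  Probability is conserved to 1e-9 and the
    result is cleaned of tiny negative round-off.
    """
    Q = np.asarray(Q, dtype=float)
    if not np.all(np.isfinite(Q)):
        raise ValueError("generator matrix contains non-finite entries")
    if dt < 0:
        raise ValueError("dt must be non-negative")
    P0 = _check_occupancy(P0, Q.shape[0])
    if dt == 0:
        return P0.copy()
    P = P0 @ expm(Q * dt)
    total = P.sum()
    if abs(total - 1.0) > CONSERVATION_TOL:
        raise ArithmeticError(f"probability not conserved: sum = {total:.12f}")
    np.clip(P, 0.0, None, out=P)
    return P / P.sum()


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary occupancy P satisfying ``P @ Q = 0`` with ``sum(P) = 1``.

    Solved via the null space of ``Q.T`` (smallest singular vector),
    renormalized.  Schemes with absorbing subsets (reducible chains) yield a
    degenerate null space and are rejected.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    _, s, Vt = np.linalg.svd(Q.T)
    # null-space dimension > 1 signals a reducible chain
    tol = max(Q.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    if Q.shape[0] > 1 and s[-2] < max(tol, 1e-12 * s[0]):
        raise ValueError("reducible scheme: stationary distribution not unique")
    p = Vt[-1, :]
    p = np.abs(p)  # null vector sign is arbitrary
    total = p.sum()
    if total <= 0:
        raise ValueError("degenerate null space")
    p = p / total
    resid = np.abs(p @ Q).max()
    scale = np.abs(Q).max() or 1.0
    if resid > 1e-8 * scale:
        raise ArithmeticError(f"stationary solve residual too large: {resid:.3g}")
    return p


@dataclass(frozen=True)
class VoltageProtocol:
    """Piecewise-constant command-voltage sequence.

    ``segments`` is an ordered tuple of ``(duration_ms, level_mV)`` pairs.
    Ramps are deliberately unsupported: every protocol in this package is a
    step or a pulse train, which keeps matrix-exponential propagation exact.
    """

    segments: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        for dur, level in self.segments:
            if not (dur > 0) or not math.isfinite(dur):
                raise ValueError(f"segment durations must be positive, got {dur}")
            if not math.isfinite(level):
                raise ValueError("segment levels must be finite")

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def voltage_at(self, t: float) -> float:
        """Command voltage at time ``t`` (ms from protocol start)."""
        acc = 0.0
        for dur, level in self.segments:
            acc += dur
            if t < acc:
                return level
        return self.segments[-1][1]


@dataclass
class OccupancyTrajectory:
    """State-occupancy time series under a voltage protocol.

    ``P`` has one row per time point, columns ordered as the scheme's states.
    """

    times: np.ndarray
    P: np.ndarray
    voltage: np.ndarray
    state_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.P.shape[0] != self.times.size or self.voltage.size != self.times.size:
            raise ValueError("times, P and voltage must have matching lengths")

    def occupancy(self, states: list[str] | str) -> np.ndarray:
        """Summed occupancy over a state subset (e.g. ``["I7", ..., "I12"]``)."""
        if isinstance(states, str):
            states = [states]
        idx = [self.state_names.index(s) for s in states]
        return self.P[:, idx].sum(axis=1)


def run_protocol(
    scheme: KineticScheme,
    protocol: VoltageProtocol,
    P0: np.ndarray,
    dt_out: float,
) -> OccupancyTrajectory:
    """Propagate a scheme through a piecewise-constant voltage protocol.

    Within each segment the occupancy is advanced exactly with the cached
    matrix exponential at the segment step ``dt_out``; segment boundaries are
    always sampled (a final partial step closes each segment), so output
    times include every voltage transition.
    """
    if not (dt_out > 0):
        raise ValueError("dt_out must be positive")
    P = _check_occupancy(P0, scheme.n_states)

    times = [0.0]
    rows = [P.copy()]
    volts = [protocol.segments[0][1]]
    t = 0.0
    for dur, level in protocol.segments:
        M = scheme.propagator(level, dt_out)
        n_full = int(math.floor(dur / dt_out + 1e-9))
        remainder = dur - n_full * dt_out
        if remainder < 1e-9 * max(dur, dt_out):
            remainder = 0.0
        for _ in range(n_full):
            P = P @ M
            t += dt_out
            times.append(t)
            rows.append(P)
            volts.append(level)
        if remainder > 0.0:
            P = P @ scheme.propagator(level, remainder)
            t += remainder
            times.append(t)
            rows.append(P)
            volts.append(level)
        total = P.sum()
        if abs(total - 1.0) > CONSERVATION_TOL:
            raise ArithmeticError(f"probability not conserved at t={t}: {total:.12f}")
        P = np.clip(P, 0.0, None)
        P = P / P.sum()

    return OccupancyTrajectory(
        times=np.array(times),
        P=np.vstack(rows),
        voltage=np.array(volts),
        state_names=scheme.state_names,
    )


# ----------------------------------------------------------------------
# rate-table I/O


def load_rate_table(source: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read a rate table: CSV with header ``from,to,k0,k1``.

    An optional metadata comment line ``# units: per_ms`` or ``# units:
    per_s`` declares the unit of ``k0``; ``per_s`` values are converted to
    ms^-1.  Returns a DataFrame with columns ``from, to, k0, k1`` (k0 in
    ms^-1) carrying the declared unit in ``df.attrs["units"]``.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    units = "per_ms"
    body_lines = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("#"):
            content = stripped.lstrip("#").strip()
            if content.lower().startswith("units:"):
                units = content.split(":", 1)[1].strip().lower()
            continue
        if stripped:
            body_lines.append(line)
    if units not in ("per_ms", "per_s"):
        raise ValueError(f"unknown rate units declaration: {units!r}")
    df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    expected = {"from", "to", "k0", "k1"}
    if not expected.issubset(df.columns):
        raise ValueError(f"rate table must have columns {sorted(expected)}")
    df = df[["from", "to", "k0", "k1"]].copy()
    if (df["k0"] <= 0).any():
        raise ValueError("all k0 values must be positive")
    if units == "per_s":
        df["k0"] = df["k0"] / 1000.0
    df.attrs["units"] = units
    return df


def scheme_from_table(
    table: pd.DataFrame,
    conducting: dict[str, bool],
    name: str = "scheme",
) -> KineticScheme:
    """Build a KineticScheme from a loaded rate table (k0 already in ms^-1)."""
    states: list[str] = []
    for col in ("from", "to"):
        for s in table[col]:
            if s not in states:
                states.append(s)
    transitions = [
        (row["from"], row["to"], RateConstant(row["k0"], row["k1"]))
        for _, row in table.iterrows()
    ]
    return KineticScheme(states, conducting, transitions, name=name)
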