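"""LTI and non-LTI Nav channel models and their emergent leak properties.

The long-term-inactivation (LTI) model is a 13-state scheme: an activation
ladder of five closed states (C1..C5), one open state (O6), a mirrored
ladder of six fast-inactivated states (I7..I12), and one long-term
inactivated state (S13) attached to the open state.  S13 represents the
open channel blocked by an FHF auxiliary factor: entry is fast (ms, during
a spike) and exit is slow (hundreds of ms at hyperpolarized potentials),
which turns P_S into the retained output of a molecular leaky integrator.

The non-LTI variant is the same scheme without S13, used as the control in
every comparison.  Two published parameter sets for the O6-S13 pair are
built in; all other rates are shared between them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .markov import (
    KineticScheme,
    RateConstant,
    VoltageProtocol,
    load_rate_table,
    run_protocol,
    scheme_from_table,
    stationary_distribution,
)

__all__ = [
    "NavModelSpec",
    "LeakProperties",
    "OS_PARAM_SETS",
    "builtin_rate_table",
    "make_lti_model",
    "make_non_lti_model",
    "derive_leak_properties",
]

OPEN_STATE = "O6"
LTI_STATE = "S13"
I_STATES = [f"I{i}" for i in range(7, 13)]
C_STATES = [f"C{i}" for i in range(1, 6)]

#: published O6-S13 rate pairs (k0 in s^-1 as printed, k1 in 1/mV).
#: set1: tau_leak ~ 435 ms, 80/20 normal-inactivation/LTI split;
#: set2: tau_leak ~ 820 ms, 90/10 split.  Both give P_S_inf ~ 0.7.
OS_PARAM_SETS: dict[str, dict[str, tuple[float, float]]] = {
    "set1": {"k_os": (400.8, -0.011), "k_so": (0.207, -0.031)},
    "set2": {"k_os": (205.7, -0.011), "k_so": (0.106, -0.031)},
}


@dataclass(frozen=True)
class NavModelSpec:
    """A concrete Nav model: a kinetic scheme plus its variant label.

    ``os_rates`` holds the O6->S13 and S13->O6 RateConstant pair in the rate
    table's native printed unit (s^-1 here); it is ``None`` for the non-LTI
    variant.
    """

    scheme: KineticScheme
    variant: str  # "lti" | "non_lti"
    os_rates: tuple[RateConstant, RateConstant] | None = None

    @property
    def is_lti(self) -> bool:
        return self.variant == "lti"


@dataclass(frozen=True)
class LeakProperties:
    """Emergent integrator constants of the LTI model.

    tau_leak : ms
        Observed decay constant of P_S at the holding potential after a
        brief pulse (single-exponential fit to the tail).
    lti_fraction : dimensionless
        P_S at the end of a single pulse from the rested state: the
        per-pulse LTI share (complement of the normal-inactivation share).
    ps_inf : dimensionless
        Stationary S13 occupancy under sustained depolarization.
    """

    tau_leak: float
    lti_fraction: float
    ps_inf: float

    def __post_init__(self) -> None:
        if not (self.tau_leak > 0 and 0 < self.lti_fraction < 1 and 0 < self.ps_inf <= 1):
            raise ValueError(f"invalid leak properties: {self}")


def builtin_rate_table(os_set: str = "set1") -> pd.DataFrame:
    """The packaged 13-state rate table with a chosen O6-S13 parameter set.

    Returns k0 in ms^-1 (converted from the table's declared s^-1).
    """
    with resources.files("navlti").joinpath("data/nav_lti_rates.csv").open() as fh:
        table = load_rate_table(fh)
    if os_set != "set1":
        table = swap_os_rates(table, os_set)
    return table


def swap_os_rates(table: pd.DataFrame, os_set: str) -> pd.DataFrame:
    """Replace the O6-S13 rate pair in a loaded table (k0 in ms^-1)."""
    if os_set not in OS_PARAM_SETS:
        raise KeyError(f"unknown O6-S13 parameter set {os_set!r}")
    pair = OS_PARAM_SETS[os_set]
    table = table.copy()
    for (src, dst), key in ((("O6", "S13"), "k_os"), (("S13", "O6"), "k_so")):
        mask = (table["from"] == src) & (table["to"] == dst)
        if not mask.any():
            raise ValueError(f"table lacks the {src}->{dst} transition")
        k0_s, k1 = pair[key]
        table.loc[mask, "k0"] = k0_s / 1000.0  # printed values are s^-1
        table.loc[mask, "k1"] = k1
    return table


def _os_pair(table: pd.DataFrame) -> tuple[RateConstant, RateConstant]:
    out = []
    for src, dst in (("O6", "S13"), ("S13", "O6")):
        row = table[(table["from"] == src) & (table["to"] == dst)]
        if row.empty:
            raise ValueError(f"rate table lacks the {src}->{dst} transition")
        # report back in the printed s^-1 convention
        out.append(RateConstant(float(row["k0"].iloc[0]) * 1000.0, float(row["k1"].iloc[0])))
    return out[0], out[1]


def make_lti_model(rate_table: pd.DataFrame | None = None, os_set: str = "set1") -> NavModelSpec:
    """Build the 13-state LTI model from a rate table (k0 in ms^-1).

    The table must contain all 13 states including S13 and both O6-S13
    transitions; O6 is the only conducting state.
    """
    table = builtin_rate_table(os_set) if rate_table is None else rate_table
    states = set(table["from"]) | set(table["to"])
    if LTI_STATE not in states:
        raise ValueError("LTI model requires the S13 state in the rate table")
    missing = ({OPEN_STATE} | set(C_STATES) | set(I_STATES)) - states
    if missing:
        raise ValueError(f"rate table missing states: {sorted(missing)}")
    scheme = scheme_from_table(table, conducting={OPEN_STATE: True}, name="Nav-LTI")
    return NavModelSpec(scheme=scheme, variant="lti", os_rates=_os_pair(table))


def make_non_lti_model(rate_table: pd.DataFrame | None = None) -> NavModelSpec:
    """Build the 12-state control model: same rates, no S13 state."""
    table = builtin_rate_table() if rate_table is None else rate_table
    table = table[(table["from"] != LTI_STATE) & (table["to"] != LTI_STATE)]
    scheme = scheme_from_table(table, conducting={OPEN_STATE: True}, name="Nav-nonLTI")
    return NavModelSpec(scheme=scheme, variant="non_lti", os_rates=None)


def rested_state(model: NavModelSpec, V_rest: float) -> np.ndarray:
    """Fully rested occupancy: the stationary distribution at ``V_rest``.

    Matches a >= 6 s intersweep hold, long enough for complete recovery.
    """
    return stationary_distribution(model.scheme.generator(V_rest))


def derive_leak_properties(
    model: NavModelSpec,
    V_rest: float = -80.0,
    V_pulse: float = 0.0,
    pulse_ms: float = 5.0,
    tail_start_ms: float = 50.0,
    tail_ms: float = 3000.0,
) -> LeakProperties:
    """Measure tau_leak, the per-pulse LTI fraction, and P_S_inf.

    A single ``pulse_ms`` pulse from the rested state at ``V_rest`` to
    ``V_pulse`` is simulated; ``lti_fraction`` is P_S at pulse end.  The
    subsequent P_S decay at ``V_rest`` is fit with a single exponential on
    the tail beyond ``tail_start_ms`` (past the fast recovery component),
    giving ``tau_leak`` as an observed decay constant rather than an
    eigenvalue.  ``ps_inf`` is the stationary S13 occupancy at ``V_pulse``.
    """
    if not model.is_lti:
        raise ValueError("leak properties are defined for the LTI variant only")
    scheme = model.scheme
    s_idx = scheme.index(LTI_STATE)

    P0 = rested_state(model, V_rest)
    pulse = VoltageProtocol(((pulse_ms, V_pulse),), label="single pulse")
    end = run_protocol(scheme, pulse, P0, dt_out=0.05).P[-1]
    lti_fraction = float(end[s_idx])

    recover = VoltageProtocol(((tail_ms, V_rest),), label="post-pulse hold")
    traj = run_protocol(scheme, recover, end, dt_out=1.0)
    ps = traj.P[:, s_idx]
    mask = traj.times >= tail_start_ms
    t = traj.times[mask]
    y = ps[mask]
    if np.any(y <= 0):
        raise ArithmeticError("P_S tail reached zero; cannot fit exponential")
    # log-linear least squares: exact for a single-exponential tail
    slope, _ = np.polyfit(t, np.log(y), 1)
    if slope >= 0:
        raise ArithmeticError("P_S tail is not decaying")
    tau_leak = -1.0 / slope

    ps_inf = float(stationary_distribution(scheme.generator(V_pulse))[s_idx])
    return LeakProperties(tau_leak=tau_leak, lti_fraction=lti_fraction, ps_inf=ps_inf)
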