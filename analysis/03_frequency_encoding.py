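"""Frequency encoding: steady P_S versus pulse rate, model vs integrator.

Drives both O6-S13 parameter sets with 5 ms pulse trains (0 mV from
-80 mV) at 2-100 Hz plus constant depolarization, records the steady
P_S oscillation band, and compares the set-1 response with the discrete
saturating leaky integrator (tau_leak = 435 ms, y_inc = 0.2).

Writes results/frequency_encoding.csv.
"""

from pathlib import Path

import pandas as pd

from navlti.analysis import frequency_response
from navlti.integrator import LeakyIntegratorParams, compare_ps_vs_integrator
from navlti.models import make_lti_model

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
FREQS = [0.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0]  # 200 Hz = constant 0 mV

frames = []
for os_set, tau in (("set1", 435.0), ("set2", 820.0)):
    resp = frequency_response(make_lti_model(os_set=os_set), FREQS)
    resp.insert(0, "os_set", os_set)
    frames.append(resp)
    print(f"{os_set}: steady mean P_S " +
          " ".join(f"{f:g}Hz={m:.3f}" for f, m in zip(resp["freq_hz"], resp["ps_mean"])))

params = LeakyIntegratorParams(tau_leak=435.0, dt=0.05, y_inc=0.2, t_p=5.0)
table = compare_ps_vs_integrator(frames[0].drop(columns="os_set"), params)
table.insert(0, "os_set", "set1")
merged = pd.concat(frames, ignore_index=True).merge(
    table[["os_set", "freq_hz", "y_min", "y_max", "y_mean", "mean_diff"]],
    on=["os_set", "freq_hz"], how="left",
)
merged.to_csv(OUT / "frequency_encoding.csv", index=False)

hi = table[table["freq_hz"] == 100.0].iloc[0]
const = table[table["freq_hz"] == 200.0].iloc[0]
print(f"\nAt 100 Hz the model's P_S oscillates in [{hi['ps_min']:.3f}, {hi['ps_max']:.3f}] "
      f"while the integrator sits at {hi['y_mean']:.3f}.")
print(f"Under constant input the integrator plateaus at {const['y_mean']:.3f} whereas the "
      f"model relaxes to its equilibrium occupancy {const['ps_mean']:.3f} — the mathematical "
      "form tracks the channel at low rates and departs at saturation, "
      f"overall RMS deviation {table.attrs['rms']:.3f}.")
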