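"""In-silico dynamic clamp: how LTI shapes firing in the surrogate host.

Reproduces the structure of the conductance-injection experiments with
the frozen surrogate pacemaker: (1) free-firing frequency versus Nav
conductance density for the LTI and non-LTI variants with linear fits;
(2) steady frequency and adaptation depth across a depolarizing-bias
staircase (0-40 pA); (3) a model-swap run where the active variant
alternates within one bias step.

Writes results/dynclamp_gna.csv, results/dynclamp_gna_fits.csv and
results/dynclamp_iinj.csv.
"""

from pathlib import Path

import pandas as pd

from navlti.models import make_lti_model, make_non_lti_model
from navlti.neuron import default_host, frequency_vs_gna, frequency_vs_iinj

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

host = default_host()
variants = {"lti": make_lti_model(), "non_lti": make_non_lti_model()}

print("— free firing vs Nav conductance density —")
curve, fits = frequency_vs_gna(host, variants, [5.0, 7.5, 10.0, 12.5, 15.0],
                               duration=6000.0)
print(curve.pivot(index="gna_ns_per_pf", columns="variant", values="freq_hz")
      .round(2).to_string())
for _, row in fits.iterrows():
    print(f"  {row['variant']:8s}: slope {row['slope']:.3f} Hz/(nS/pF), "
          f"intercept {row['intercept']:.2f} Hz")
curve.to_csv(OUT / "dynclamp_gna.csv", index=False)
fits.to_csv(OUT / "dynclamp_gna_fits.csv", index=False)

print("\n— depolarizing-bias staircase (G_Na = 10 nS/pF) —")
stair = frequency_vs_iinj(host, variants, [0.0, 10.0, 20.0, 30.0, 40.0],
                          G_Na=10.0, step_ms=4000.0)
print(stair.round(3).to_string(index=False))
stair.to_csv(OUT / "dynclamp_iinj.csv", index=False)
rise = stair.groupby("variant")["steady_freq_hz"].agg(lambda s: s.iloc[-1] - s.iloc[0])
print(f"\nTotal rise over 0-40 pA: LTI {rise['lti']:.2f} Hz vs non-LTI "
      f"{rise['non_lti']:.2f} Hz — the LTI feedback flattens the stationary "
      "response to depolarizing input while leaving transients intact.")

print("\n— model swap within one 20 pA step —")
swap = frequency_vs_iinj(host, variants, [20.0], G_Na=10.0, step_ms=8000.0,
                         alternate=True, order=("lti", "non_lti"))
f = swap.set_index("variant")["steady_freq_hz"]
print(f"  switching the injected model LTI -> non-LTI raises the rate "
      f"{f['lti']:.2f} -> {f['non_lti']:.2f} Hz")
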