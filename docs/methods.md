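# Methods

## The kinetic model

The Nav channel is modelled as a continuous-time Markov chain over 13
states: five closed states (C1–C5, the activation ladder, with
statistical factors 4α, 3α, 2α, α on the forward rates), one open state
(O6, the only conducting state), six fast-inactivated states (I7–I12, a
mirrored ladder entered mainly from the open state), and one long-term
inactivated state (S13) connected to the open state. S13 represents the
open channel blocked by an FHF auxiliary factor; its defining feature is
the three-orders-of-magnitude asymmetry between entry (fast, at
depolarized potentials) and exit (slow, at rest). Every rate is an
Eyring expression `k(V) = k₀·e^(k₁·V)` with `k₀` a pre-exponential
factor and `k₁` a voltage factor in 1/mV. The non-LTI control model is
the same scheme with S13 and its two transitions removed.

Occupancies evolve as `dP/dt = P·Q` (row-vector convention) with the
generator matrix `Q(V)` assembled from the rate table. All command
voltages in this package are piecewise constant (steps and pulse
trains; no ramps), so propagation is *exact*: within each segment
`P(t+Δ) = P(t)·expm(Q·Δ)`, computed by scaling-and-squaring and cached
per (voltage, step). Probability conservation is enforced to 1e-9 at
every step, and stationary distributions are obtained from the null
space of `Qᵀ` (smallest singular vector, renormalized), with reducible
generators rejected.

### Units of the rate table

Rate tables are CSV (`from,to,k0,k1`) with a declared unit
(`# units: per_s` or `per_ms`); the engine works in ms⁻¹ and mV. The
shipped table is declared in s⁻¹: with the published O6–S13 pair on that
scale, 1/k₁₃,₆(−80 mV) ≈ 404 ms, which together with a ~7 % probability
of re-entering S13 through the open state reproduces the observed
τ_leak ≈ 435 ms — and the second published pair then lands on ≈ 820 ms
with no further freedom. On a ms⁻¹ reading the same numbers would give a
0.4 ms leak, inconsistent with every other constraint, so the s⁻¹
interpretation is adopted throughout.

### Rate-table construction and calibration

The O6–S13 pair is fixed at its published values (two sets: set 1,
k₆,₁₃ = 400.8·e^(−0.011V) / k₁₃,₆ = 0.207·e^(−0.031V); set 2,
205.7·e^(−0.011V) / 0.106·e^(−0.031V), both s⁻¹). The remaining rates of
the base scheme were parameterized in the classic allosteric-ladder
style and calibrated **once**, before any downstream analysis, against
four anchor behaviours measured by full simulation:

1. fitted fast recovery time constant at −80 mV ≈ 3.14 ms;
2. P_S after a single 5 ms pulse from −80 to 0 mV ≈ 0.20 (the 80/20
   split between normal inactivation and LTI);
3. single-exponential decay constant of the post-pulse P_S tail at
   −80 mV ≈ 435 ms (τ_leak, set 1);
4. stationary S13 occupancy at 0 mV ≈ 0.70.

Six scalars (the I-ladder deactivation and its O6-side step, the
closed↔inactivated vertical exit rate, O6→C5 deactivation, and the
O6↔I12 pair) were adjusted by least squares on these anchors; the result
is frozen in `src/navlti/data/nav_lti_rates.csv`. Everything else the
package reports about the model — the ≈ 820 ms leak of set 2, the
stationary 0.70/0.30 S-versus-I split at 0 mV for both sets, the ~20 %
slow amplitude of simulated two-pulse recovery, the 100 Hz steady P_S
oscillation band near 0.93 — is *emergent*, not fitted.

Closed-state inactivation is present (C–I rungs with small rates) but
deliberately weak; the model's steady-state availability curve was not a
calibration target and should not be quoted from this package.

### Peak open probability of the two variants

Because entry into S13 competes with fast inactivation already during
the rising phase of a pulse, the LTI model's first-pulse peak open
probability sits a few percent below the non-LTI control (≈ 8 % with the
calibrated activation speed; the gap shrinks only as activation is made
unphysically fast). Both variants start a first pulse from identical
availability — S13 is empty at rest — and the within-model availability
ratio I^p/I^0 is unaffected, since the same proportional loss applies to
every pulse.

## Protocols, currents and analysis

Macroscopic current is ohmic: `I = G_Na·P_O·(V − E_Na)`, with G_Na given
either as total conductance (nS) or density (nS/pF, scaled by C_m). The
reversal defaults to +60 mV and is configurable; inward current is
negative. Default sampling is 0.01 ms (100 kHz) for voltage-clamp
simulation. Sweep initial conditions are the stationary state at the
most hyperpolarized protocol level (the holding potential), which
corresponds to a ≥ 6 s inter-sweep hold.

Per-pulse peaks are the extremum of |I| restricted to each pulse window;
availability is the signed peak divided by the first, and the LTI-state
estimate is `P_S = 1 − I^p/I^0`, clipped to [0,1]. This estimator is
valid when the inter-pulse interval is long enough to clear fast
inactivation (≈ 10·τ_fast); the test suite checks it against the model's
true inter-pulse P_S at 5 Hz (195 ms gaps), where agreement is within
0.05.

Two-pulse recovery is fit with
`A(t) = a_fast·(1 − e^(−t/τ_fast)) + a_slow·(1 − e^(−t/τ_slow))`
by least squares in log-τ coordinates with analytic gradients
(initialized by a two-segment log-linear split at the geometric-mean
delay; components sorted fast-first after the fit). On noiseless
self-generated data the fitter recovers parameters to 1e-6 relative. A
time-constant ratio below 3 or a component amplitude below 1 % of the
total flags the split as degenerate (mono-exponential data); the non-LTI
model's recovery is flagged this way, as expected.

Frequency response iterates the pulse-train cycle with exact per-segment
propagators until the cycle-to-cycle P_S drift falls below 1e-7 (well
past 10·τ_leak for every tested rate), then samples one steady cycle at
0.05 ms for min/max/time-weighted mean.

## The leaky-integrator forms

Three forms are implemented exactly as recursions/solutions of
`dy/dt = x − y/τ_leak`: the exact piecewise-constant solution, the
linear discrete form `y_{t+δt} = y_t·e^(−δt/τ) + x_{t+δt}·δt`, and the
saturating digital form in which the per-step gain is
`y_inc·(δt/t_p)·(1 − y_t·e^(−δt/τ))`. Defaults: δt = 0.05 ms, t_p = 5 ms,
y_inc = 0.2, τ_leak = 435 ms. Two consequences of the saturating
recursion worth noting (both verified by the tests): a single t_p-long
pulse from y = 0 raises the output by `1 − e^(−y_inc)` ≈ 0.181 — the
increment self-attenuates within the pulse, so "≈ y_inc" is approximate —
and under sustained input the fixed point is
`y* = g/(1 − d(1−g))` with `d = e^(−δt/τ)`, `g = y_inc·δt/t_p`, slightly
below 1 because the leak never stops. The channel model differs from the
mathematical form exactly where expected: at saturating rates and under
constant input, where P_S relaxes to P_S∞ ≈ 0.7 while the integrator
stays near its ceiling.

## The surrogate dynamic-clamp host

The conductance-injection experiments were performed on live neurons; in
silico they require a host. The host here is a deliberately minimal
conductance-based pacemaker — **an invented surrogate, calibrated once
and frozen** (`src/navlti/data/host_neuron.json`), and every conclusion
drawn from it is qualitative (orderings, slopes' signs, adaptation
directions), never a numeric match to live-cell values:

- membrane: C_m = 20 pF; leak g_L = 1 nS toward E_L = −40 mV (the
  depolarizing drive that makes the cell fire spontaneously);
- delayed rectifier: g_K = 40 nS, single gate n⁴,
  n∞ = 1/(1+e^(−(V+25)/9)), τ_n = 4 ms (slow enough for 3–4 ms spikes);
- adaptation: **spike-triggered** — each detected spike (upward −20 mV
  crossing, 5 ms refractory) increments a gate by z ← z + 0.35·(1−z),
  which decays with τ_z = 100 ms and drives g_adapt·z·(V−E_K) with
  g_adapt = 3 nS. The increment is independent of spike amplitude and
  width by construction, so differences between Nav variants act on the
  pacing only through the sodium current itself; with a voltage-gated
  adaptation conductance, the non-LTI variant's larger spikes charge the
  adaptation more and can invert the frequency ordering — an artifact of
  the surrogate, not a property of the channel.

The hybrid loop mirrors a 50 kHz real-time dynamic clamp: per 0.02 ms
step the Nav occupancies advance by the matrix method using propagators
cached on a 0.05 mV voltage grid (quantization perturbs rates by < 0.3 %;
halving the time step changes steady firing by < 0.1 %), the model
current `G_Na·C_m·P_O·(V−E_Na)` is computed, and the membrane equation
takes one Euler step. Occupancy conservation is asserted during the run,
and the simulation aborts loudly if V leaves [−120, +60] mV.

Calibration targets (checked, then frozen): non-LTI at 10 nS/pF fires
regularly at ≈ 3.9 Hz with ≈ 4 ms spikes; the LTI variant is strictly
slower at equal conductance. Known surrogate limits: the LTI/non-LTI
free-firing curves converge by ≈ 15 nS/pF (as live cells also do at high
conductance), so ordering properties are exercised over 5–12.5 nS/pF;
depolarizing bias is capped at 40 pA (larger values caused
depolarization block in the original preparation and are refused here).

## Synthetic data

Recovery datasets are generated from four built-in bi-exponential
ground-truth parameter sets (neonatal slice and mature dissociated
preparations, each at −80 and −100 mV, with their reported SEs and cell
counts). Per cell, availability = biexp(params, delay) + Gaussian noise
(default sd 0.02 on the normalized ratio — the measured quantity),
clipped to [0, 1.05]. Optional cell-level parameter jitter reconstructs
cohort spread as sd ≈ SE·√n, with mean-preserving lognormal draws for
time constants (so cohort averages stay unbiased and τ stays positive)
and a floor keeping τ_slow ≥ 3·τ_fast (separable components). This is an
*emulation* of cohort variability, not a reconstruction of any real
cells; `scripts/acceptance.py` generates its 18-cell cohort without
jitter, since its purpose is refitting the printed mean curve under
measurement noise. All generators are pure functions of (parameters,
seed). What passing these tests shows is that the estimation pipeline is
unbiased under the stated noise model; real sweeps add capacitive
artifacts, leak-subtraction residuals and series-resistance errors that
are deliberately out of scope.

## Problem sizes

Simulated spans were chosen so every driver and the full test suite run
comfortably on one CPU: recovery delays 1 ms–6 s (24 log-spaced points),
frequency responses iterated to a 1e-7 steady-cycle drift (a few seconds
of simulated time per rate), hybrid simulations 4–6 s per condition at
50 kHz, bias staircases 3–4 s per step. Longer runs change none of the
reported quantities (steady-state criteria, not durations, terminate the
iterations).
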