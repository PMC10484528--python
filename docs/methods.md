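# Methods

## Model and backends

The package simulates one point neuron in two arithmetically different
ways and treats their disagreement as the object of study.

**Reference backend.** A leaky integrate-and-fire neuron
`C dV/dt = -(V - E_L)/R + I_e` with `tau_v = R C`, integrated by forward
Euler at step `dt`.  Euler is a deliberate choice, not a simplification:
the fixed-point backend's update rule is itself a forward-Euler-form
recursion, so a higher-order reference scheme would introduce a spurious
O(dt) disagreement between the backends that no voltage scale could remove.
The resistance is always the derived ratio `tau_v / C`; it is never an
independent degree of freedom.

**Emulated fixed-point backend.** An integer state
`v(t+1) = v(t) - trunc(v * delta_v / 2^12) + b + u(t)` with reset to 0
above an integer threshold.  The decay is applied as
`v - trunc(v * delta_v / 2^12)` rather than `trunc(v * (1 - delta_v/2^12))`;
the forms agree in exact arithmetic but only the first keeps every
intermediate product integral.  Truncation toward zero is used everywhere
an integer is produced from a ratio — it is the unique rounding mode
consistent with the bias-precision table (1175 -> 587 at exponent 1) and
with the decay integer 184 arising from 4096/22.2 = 184.5.  State is an
unbounded Python integer with an overflow check at 2^23 by default; the
check exists to surface a mis-chosen voltage scale, not to model a specific
register width, and is configurable.

**Mapping.** `v = trunc((V - V_r)/Vs)`, `delta_v = trunc((dt/tau_v) 2^12)`,
integer bias `b = trunc(dt I_e / (C Vs))` encoded as a bounded mantissa
(|m| <= 4096) times `2^exponent` (exponent in 0..7), spike weights scaled
by `1/Vs`, and — when the resting and reset potentials differ — a constant
per-step leak increment `trunc(dt (E_L - V_r)/(tau_v Vs))`.  The default
voltage scale is calibrated from the one integer anchor the protocol
provides: 200 pA into 170 pF at dt = 1 ms must map to the integer bias
1175, giving `Vs = (dt I_e / C)/1175 ≈ 1.00125e-3` mV/unit.  The naive
1e-3 mV/unit would give 1176 instead; `Vs` remains fully configurable.

## Cost function

Backends are compared on the forward finite differences of their voltage
traces (mV/ms), not the voltages themselves: the residual algebra of the
analytic treatment is written in derivative form, and the derivative
removes constant-offset freedom.  Samples whose interval straddles a spike
or reset in *either* trace are excluded, with a one-step guard window on
each side by default, so spike-timing jitter cannot leak into the
subthreshold cost.  A raw-voltage RMSE and the subthreshold Pearson
correlation are reported alongside.

The closed-form (analytic) version of the cost factors the residual as
`r_i = [(V_i - E_L)/tau_v - I_e/C] / (Vs - 1)` and evaluates
`sqrt(mean(e_i)) / |Vs - 1|` with `e_i` the squared bracket.  Two
numerical notes: the absolute value `|Vs - 1|` replaces the signed factor
(with Vs ~ 1e-3 a signed denominator would make the RMSE negative), and
`e_i` is computed as the factored square rather than the expanded
three-term sum, which loses half the significant digits to cancellation
near the residual root.  The partial derivatives of `e` with respect to
`C`, `tau_v` and `E_L` are closed-form; the `E_L` partial is affine in
`E_L`, which is the analytic reason the resting potential dominates the
empirical sensitivity ranking when the cost stays below 1 mV/ms.

## Sensitivity scans

OAT scans perturb one parameter per grid point in one backend and restore
it afterwards; TAT scans perturb ordered pairs over the Cartesian product
of two grids.  Conventions that matter:

* **Capacitance rule.** A lone `C_m` perturbation holds `R` at its base
  ratio, so `tau_v = R C_m` moves with it — without this, `C_m` would drop
  out of the spike-driven dynamics entirely.  When `C_m` and `tau_v` are
  perturbed together both are set directly and `R` follows.  Consequently
  the TAT `{C_m, tau_v}` slice at base `tau_v` is *not* the `C_m` OAT
  curve (they agree only at the base point); slices through pairs
  involving `E_L` do reduce exactly to the corresponding OAT curves.
* **State vs parameter.** The initial condition stays at the base resting
  potential in both backends; a perturbation changes the parameter, never
  the state.  (If the initial state tracked the perturbed `E_L`, the
  reference-side `E_L` scan would be exactly flat, because the dynamics of
  `V - E_L` do not depend on `E_L`.)
* **Emulator-side quantization.** Perturbing the emulator re-runs the
  full mapping per point, so `delta_v` and the bias are re-quantized; the
  resulting staircase structure in emulator-side curves is the physics of
  the integer substrate, not numerical noise.
* **Minima and profiles.** Grid minima break ties toward the declared base
  value, then lexicographically.  Relative-change profiles report
  `(RMSE - min)/min` per point; a zero minimum degenerates to absolute
  increases.
* Scan points are evaluated independently; results are invariant to
  evaluation order (asserted by a shuffled-order test).

Preset grids: `C_m` [160, 180] pF step 1.0 (spike drive) and
[169, 171.5] step 0.2 (bias drive); `tau_v` [21.0, 23.6] ms step 0.2
(spike) and [24.0, 26.2] (bias); `E_L` [-71, -69] mV step 0.1 (both).
The bias-drive `tau_v` preset deliberately brackets a region above the
base value; its minimum therefore sits on the grid boundary nearest the
base.  All presets are overridable.

## Study conditions and the stimulus generator

Defaults define the validation conditions: C = 170 pF, tau_v = 22.2 ms,
E_L = V_r = -70 mV, Theta = -50 mV, dt = 1 ms, 500 ms runs, bias drive
200 pA, spike drive from a frozen set of five sources with eleven spikes
over 500 ms.  `V_r = E_L` makes the emulator's constant leak term vanish
at base parameters; Theta and V_r are not dictated by the mapping itself
and are configurable.

Fresh stimuli are drawn as homogeneous Poisson sources at a 5 Hz maximum
rate, snapped to the dt grid by truncation and frozen by seed; a flag
draws heterogeneous per-source rates in (0, 5] Hz instead.  The
delta-kernel spike weight defaults to 0.5 mV — a typical cortical unitary
EPSP amplitude — which keeps the spike-driven runs subthreshold, matching
the regime in which the subthreshold cost is meaningful.  An exponential
current kernel is available in the reference backend only; the emulator
implements the delta kernel (a synaptic current decay integer is outside
the present mapping).

What the generator does *not* emulate: biological rate heterogeneity
beyond the optional uniform draw, refractoriness, synaptic depression,
conductance-based synapses, and correlated inputs.  Passing tests
therefore demonstrate fidelity of the integer mapping under simple,
frozen, low-rate drive — not robustness of the mapping for arbitrary
in-vivo-like input statistics.

## Numerical choices

* Truncation toward zero everywhere, with one guard: a float within 1e-9
  relative of an integer is snapped to it before truncating.  Quantities
  that are integers by construction (the calibrated bias 1175, decay
  round trips) can otherwise land one ULP below an integer and truncate to
  its neighbour.
* The emulator's integer arithmetic uses exact integer truncating division
  (`//` with sign handling), never floats.
* Degenerate inputs fail loudly: over-masked comparisons, constant traces
  in the correlation, `tau_v < dt` in the decay map, unencodable biases,
  and non-finite states (with the offending step index) all raise typed
  errors; per-point scan failures are recorded in the grid rather than
  aborting the scan.
* Fine-limit diagnostics: with the decay unquantized and the bias
  unencoded, per-step truncation of the integer state (< 2 units) passes
  through the geometric decay sum to a steady error of at most
  `2 tau_v/dt` integer units.  The equivalence check therefore runs at
  Vs = 1e-6 mV/unit against a fixed physical budget of 1e-3 mV (one unit
  at the coarsest scale of interest); exact one-unit agreement is not
  attainable for any truncating integer recursion.

## Problem sizes

Default runs are 500 steps.  The full preset scan battery (OAT and TAT,
both stimuli, both directions) evaluates 3,624 grid points, each a fresh
500-step simulation of the perturbed backend against a cached fixed trace;
it completes in seconds on one CPU.  The acceptance script reruns exactly
this battery plus the default validation run.

## Known limitations

* The voltage scale is calibrated from a single integer anchor; no
  automatic optimal-Vs search is provided.
* Only the voltage-decay integer is modelled; synaptic current decay,
  refractory periods, learning rules, dendritic compartments and synaptic
  delays of real neuromorphic silicon are out of scope, as is
  cycle-accurate replication of any particular chip.
* Spike-timing-based cost functions are not implemented; the cost is
  blind to timing by construction (masked subthreshold samples only).
* The E/I network builder is a demo fixture for stimulus generation, not
  a network simulator; runtime/energy benchmarking of hardware is out of
  scope.
* Global sensitivity methods (Sobol, Morris) are not implemented; the
  scanners are local (OAT/TAT) by design.
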