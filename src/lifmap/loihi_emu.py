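"""Software emulator of the fixed-point neuromorphic LIF update rule.

The on-chip membrane state is a bounded integer v that evolves as

    v(t+1) = v(t) - trunc(v(t) * delta_v / 2^12) + b + u(t),
    v(t)  <- 0   if v(t) > theta,

where ``delta_v`` is the 12-bit integer voltage-decay parameter, ``b`` the
constant bias reconstructed from its mantissa/exponent encoding and ``u(t)``
the integer synaptic/leak input of the step.  The decay is applied as
``v - trunc(v*delta_v/2^12)`` rather than ``trunc(v*(1 - delta_v/2^12))``:
the two agree in exact arithmetic, but the first form keeps every
intermediate product integral, which is what the hardware does.

State is emulated as an unbounded Python integer with a configurable
overflow check (default 2^23) that exists to surface a mis-scaled voltage
scale early rather than to replicate a specific silicon register width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from ._numeric import int_trunc_div, trunc_toward_zero
from .errors import EncodingError, SimulationError

__all__ = [
    "MANTISSA_LIMIT",
    "EXPONENT_RANGE",
    "LoihiNeuronConfig",
    "IntTrace",
    "BiasEncoding",
    "encode_bias",
    "bias_precision_sweep",
    "simulate_emulator",
    "decay_sweep",
]

#: Bias mantissa range is [-2^12, 2^12]; the exponent occupies 3 bits.
MANTISSA_LIMIT = 4096
EXPONENT_RANGE = (0, 7)
_DECAY_SCALE_BITS = 12


@dataclass(frozen=True)
class BiasEncoding:
    """Mantissa/exponent representation of an integer bias current."""

    mantissa: int
    exponent: int
    reconstructed: int

    def __post_init__(self):
        assert self.reconstructed == self.mantissa * 2 ** self.exponent


def encode_bias(base_bias: int, exponent: int) -> BiasEncoding:
    """Encode an integer bias as mantissa * 2^exponent with a truncated mantissa.

    The mantissa is ``base_bias / 2^exponent`` truncated toward zero, so the
    reconstructed bias never exceeds the original in magnitude and degrades
    monotonically as the exponent grows.
    """
    lo, hi = EXPONENT_RANGE
    if not lo <= exponent <= hi:
        raise EncodingError(f"bias exponent {exponent} outside [{lo}, {hi}]")
    mantissa = int_trunc_div(int(base_bias), 2 ** exponent)
    if abs(mantissa) > MANTISSA_LIMIT:
        raise EncodingError(
            f"bias mantissa {mantissa} outside [-{MANTISSA_LIMIT}, {MANTISSA_LIMIT}]")
    return BiasEncoding(mantissa=mantissa, exponent=exponent,
                        reconstructed=mantissa * 2 ** exponent)


def bias_precision_sweep(base_bias: int) -> list[BiasEncoding]:
    """Encode ``base_bias`` at every allowed exponent (coarsening precision)."""
    return [encode_bias(base_bias, e) for e in range(EXPONENT_RANGE[0], EXPONENT_RANGE[1] + 1)]


@dataclass(frozen=True)
class LoihiNeuronConfig:
    """Integer-domain neuron configuration.

    ``theta_int`` may be ``None`` for a non-firing (threshold-free) neuron.
    ``reset_int`` is fixed at zero: the hardware reset rule clamps the state
    to 0, with physical offsets carried by the voltage-scale transform.
    ``weights_int`` records the per-source integer synaptic weights used to
    build the stimulus (informational; the per-step input array carries them).
    """

    delta_v: int
    bias_mantissa: int = 0
    bias_exponent: int = 0
    theta_int: int | None = None
    reset_int: int = 0
    weights_int: tuple[int, ...] = ()

    def __post_init__(self):
        if not 0 <= self.delta_v <= 2 ** _DECAY_SCALE_BITS:
            raise ValueError(f"delta_v {self.delta_v} outside [0, 4096]")
        if abs(self.bias_mantissa) > MANTISSA_LIMIT:
            raise ValueError("bias mantissa out of range")
        lo, hi = EXPONENT_RANGE
        if not lo <= self.bias_exponent <= hi:
            raise ValueError("bias exponent out of range")
        if self.reset_int != 0:
            raise ValueError("reset value is fixed at 0")

    @property
    def bias(self) -> int:
        """Reconstructed integer bias, mantissa * 2^exponent."""
        return self.bias_mantissa * 2 ** self.bias_exponent


@dataclass(frozen=True)
class IntTrace:
    """Integer membrane-state time series with recorded spike steps."""

    steps: int
    values: np.ndarray = field(repr=False)
    spike_steps: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values)
        if not np.issubdtype(values.dtype, np.integer):
            raise ValueError("IntTrace values must be integers")
        if values.size != self.steps + 1:
            raise ValueError("values length must equal steps + 1")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spike_steps",
                           np.asarray(self.spike_steps, dtype=int))

    def to_trace(self, Vr: float, Vs: float, dt: float):
        """Map back to a physical-unit trace: V = Vr + v * Vs."""
        from .model_core import Trace

        return Trace(
            dt=dt,
            values=Vr + self.values.astype(float) * Vs,
            spike_times=self.spike_steps.astype(float) * dt,
            duration=self.steps * dt,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame({"step": np.arange(self.steps + 1), "value": self.values}).to_csv(
            path, index=False)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=np.arange(self.steps + 1))
            f.create_dataset("voltage", data=self.values)
            f.create_dataset("spike_times", data=self.spike_steps)


def simulate_emulator(
    cfg: LoihiNeuronConfig,
    u_steps: np.ndarray | None = None,
    n_steps: int | None = None,
    v0: int = 0,
    state_bits: int = 23,
    delta_override: float | None = None,
    bias_override: int | None = None,
) -> IntTrace:
    """Iterate the fixed-point update rule for ``n_steps`` steps.

    ``u_steps`` is the per-step integer input (synaptic weights plus any
    constant leak increment).  Two diagnostic hooks support fine-limit
    comparisons against the continuous reference: ``delta_override``
    substitutes an unquantized real-valued decay parameter, and
    ``bias_override`` an unencoded integer bias beyond the mantissa range;
    the state stays integral either way.  Exceeding ``2**state_bits`` in
    magnitude raises :class:`SimulationError` — almost always a sign that
    the voltage scale Vs is too fine for the dynamic range of the run.
    """
    if u_steps is not None:
        u_steps = np.asarray(u_steps)
        if not np.issubdtype(u_steps.dtype, np.integer):
            raise ValueError("u_steps must be integer-valued")
        if n_steps is None:
            n_steps = int(u_steps.size)
        elif n_steps != u_steps.size:
            raise ValueError("n_steps disagrees with len(u_steps)")
    if n_steps is None or n_steps < 1:
        raise ValueError("n_steps must be at least 1")

    limit = 1 << state_bits
    scale = 1 << _DECAY_SCALE_BITS
    b = cfg.bias if bias_override is None else int(bias_override)
    theta = cfg.theta_int
    v = int(v0)
    values = np.empty(n_steps + 1, dtype=np.int64)
    values[0] = v
    spike_steps: list[int] = []
    for i in range(n_steps):
        if theta is not None and v > theta:
            v = cfg.reset_int
            spike_steps.append(i)
        else:
            if delta_override is None:
                decay = int_trunc_div(v * cfg.delta_v, scale)
            else:
                decay = trunc_toward_zero(v * delta_override / scale)
            v = v - decay + b + (int(u_steps[i]) if u_steps is not None else 0)
        if abs(v) > limit:
            raise SimulationError(
                f"integer state overflow |v| > 2^{state_bits} at step {i + 1}; "
                "the voltage scale Vs is mis-scaled for this run", step=i + 1)
        values[i + 1] = v
    return IntTrace(steps=n_steps, values=values,
                    spike_steps=np.array(spike_steps, dtype=int))


def decay_sweep(
    cfg: LoihiNeuronConfig,
    base_delta: int,
    half_width: int,
    reference,
    mapping,
    Vr: float = -70.0,
    u_steps: np.ndarray | None = None,
    v0: int = 0,
    guard: int = 1,
):
    """RMSE of the emulator against a fixed reference over a decay-integer grid.

    Runs the emulator for every integer ``delta_v`` in
    ``[base_delta - half_width, base_delta + half_width]`` with every other
    setting of ``cfg`` unchanged and scores the masked derivative RMSE
    against ``reference`` (a physical-unit trace).  Per-point failures are
    recorded (value NaN) without aborting the sweep.
    """
    from .cost import rmse, subthreshold_mask
    from .model_core import derivative_trace
    from .sensitivity import ParamGrid, SensitivityGrid

    if base_delta - half_width < 0:
        raise ValueError("decay grid extends below 0")
    deltas = np.arange(base_delta - half_width, base_delta + half_width + 1)
    n_steps = reference.n_samples - 1
    values = np.empty(deltas.size)
    failures: dict[int, str] = {}
    y_ref = derivative_trace(reference)
    for k, d in enumerate(deltas):
        try:
            sub = LoihiNeuronConfig(
                delta_v=int(d),
                bias_mantissa=cfg.bias_mantissa,
                bias_exponent=cfg.bias_exponent,
                theta_int=cfg.theta_int,
                weights_int=cfg.weights_int,
            )
            emu = simulate_emulator(sub, u_steps=u_steps, n_steps=n_steps, v0=v0)
            emu_mv = emu.to_trace(Vr=Vr, Vs=mapping.Vs, dt=mapping.dt)
            mask = subthreshold_mask(reference, emu_mv, guard=guard)
            values[k] = rmse(y_ref, derivative_trace(emu_mv), mask)
        except Exception as exc:  # noqa: BLE001 - per-point failure is data
            values[k] = np.nan
            failures[int(d)] = f"delta_v={int(d)}: {exc}"
    grid = ParamGrid(name="delta_v", values=deltas.astype(float), base=float(base_delta))
    return SensitivityGrid(axes=(grid,), direction="emulator",
                           rmse_values=values, failures=failures)
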