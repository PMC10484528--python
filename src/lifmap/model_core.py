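"""Continuous (floating-point) leaky integrate-and-fire reference simulator.

The membrane potential of a point neuron obeys

    C dV/dt = -(V - E_L)/R + I_e,        tau_v = R C,

integrated with forward Euler at a fixed step ``dt``.  Whenever V exceeds the
firing threshold Theta at a step, the spike time is recorded and V is set to
the reset potential V_r at the next step.  Forward Euler is used deliberately:
the fixed-point emulator's update rule is itself a forward-Euler-form
recursion, so any higher-order scheme would break the cross-backend
equivalence that the validation metric relies on.

Units follow the usual point-neuron convention: capacitance in pF, time in
ms, voltages in mV, currents in pA (pA·ms/pF = mV, so no unit conversion
factors appear in the update).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import h5py
import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SimulationError
from .stimulus import SpikeTrainSet

__all__ = [
    "LIFParams",
    "StimulusSpec",
    "Trace",
    "DEFAULT_PARAMS",
    "simulate_reference",
    "derivative_trace",
]


@dataclass(frozen=True)
class LIFParams:
    """Physical-unit LIF parameters.

    The membrane resistance R (GΩ) is always derived as ``tau_v / C`` and is
    never set independently, so the constraint tau_v = R C holds exactly.
    """

    C: float  # membrane capacitance, pF
    tau_v: float  # membrane time constant, ms
    EL: float  # resting potential, mV
    Vr: float = -70.0  # reset potential, mV
    theta: float = -50.0  # firing threshold, mV (may be +inf)

    def __post_init__(self):
        if not self.C > 0:
            raise ValueError("C must be positive")
        if not self.tau_v > 0:
            raise ValueError("tau_v must be positive")
        if not self.theta > self.Vr:
            raise ValueError("theta must exceed Vr")

    @property
    def R(self) -> float:
        """Membrane resistance tau_v / C (GΩ), derived."""
        return self.tau_v / self.C

    def replace(self, **kwargs) -> "LIFParams":
        return replace(self, **kwargs)


#: Base neuron of the validation study: 170 pF, 22.2 ms, resting at -70 mV.
DEFAULT_PARAMS = LIFParams(C=170.0, tau_v=22.2, EL=-70.0, Vr=-70.0, theta=-50.0)


@dataclass(frozen=True)
class StimulusSpec:
    """Constant bias current or weighted external spike trains — exactly one.

    For spike mode, ``weight`` (mV) is the instantaneous membrane-potential
    increment per spike (delta kernel, the default synaptic response); a
    mapping ``{source_id: weight}`` assigns per-source weights.  An
    exponential current kernel with time constant ``tau_syn`` is available in
    the reference backend only.
    """

    mode: Literal["bias", "spikes"]
    Ie: float = 0.0  # pA, bias mode
    spike_trains: SpikeTrainSet | None = None
    weight: float | Mapping[int, float] = 0.5  # mV per spike
    kernel: Literal["delta", "exp"] = "delta"
    tau_syn: float = 2.0  # ms, exp kernel only

    def __post_init__(self):
        if self.mode == "bias":
            if self.spike_trains is not None:
                raise ValueError("bias stimulus must not carry spike trains")
            if not math.isfinite(self.Ie):
                raise ValueError("Ie must be finite")
        elif self.mode == "spikes":
            if self.spike_trains is None:
                raise ValueError("spike stimulus requires spike trains")
            if self.Ie != 0.0:
                raise ValueError("spike stimulus must have Ie = 0")
        else:
            raise ValueError(f"unknown stimulus mode {self.mode!r}")

    @classmethod
    def bias(cls, Ie: float) -> "StimulusSpec":
        return cls(mode="bias", Ie=Ie)

    @classmethod
    def spikes(cls, trains: SpikeTrainSet, weight: float | Mapping[int, float] = 0.5,
               kernel: Literal["delta", "exp"] = "delta", tau_syn: float = 2.0) -> "StimulusSpec":
        return cls(mode="spikes", spike_trains=trains, weight=weight,
                   kernel=kernel, tau_syn=tau_syn)

    def weight_of(self, source_id: int) -> float:
        if isinstance(self.weight, Mapping):
            return float(self.weight[source_id])
        return float(self.weight)

    def step_increments(self, dt: float, n_steps: int) -> np.ndarray:
        """Summed spike weights (mV) landing on each step of a dt grid."""
        inc = np.zeros(n_steps, dtype=float)
        if self.spike_trains is None:
            return inc
        for src, steps in self.spike_trains.steps(dt).items():
            w = self.weight_of(src)
            if not math.isfinite(w):
                raise ValueError(f"non-finite weight for source {src}")
            for s in steps:
                if 0 <= s < n_steps:
                    inc[s] += w
        return inc


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled membrane-potential time series (mV) with spike times.

    ``values`` has ``floor(duration/dt) + 1`` samples; spike times are the
    times of the suprathreshold samples, each a multiple of ``dt``.
    """

    dt: float
    values: np.ndarray = field(repr=False)
    spike_times: np.ndarray = field(repr=False)
    duration: float

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        spikes = np.asarray(self.spike_times, dtype=float)
        if values.size != math.floor(self.duration / self.dt) + 1:
            raise ValueError("values length must equal floor(duration/dt) + 1")
        for t in spikes:
            if not (0 <= t <= self.duration):
                raise ValueError("spike time outside trace duration")
            if abs(t / self.dt - round(t / self.dt)) > 1e-9:
                raise ValueError("spike times must be multiples of dt")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spike_times", spikes)

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    @property
    def spike_steps(self) -> np.ndarray:
        return np.round(self.spike_times / self.dt).astype(int)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ms": self.time, "value": self.values}).to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=self.time)
            f.create_dataset("voltage", data=self.values)
            f.create_dataset("spike_times", data=self.spike_times)
            f.attrs["dt"] = self.dt
            f.attrs["duration"] = self.duration

    @classmethod
    def from_hdf5(cls, path) -> "Trace":
        with h5py.File(path, "r") as f:
            return cls(
                dt=float(f.attrs["dt"]),
                values=f["voltage"][()],
                spike_times=f["spike_times"][()],
                duration=float(f.attrs["duration"]),
            )


def simulate_reference(
    params: LIFParams,
    stim: StimulusSpec,
    dt: float = 1.0,
    duration: float = 500.0,
    v0: float | None = None,
) -> Trace:
    """Forward-Euler integration of the continuous LIF model.

    ``v0`` defaults to the resting potential.  When the membrane potential
    exceeds ``params.theta`` at a step, the step time is recorded as a spike
    and the potential is set to ``params.Vr`` at the next step (inputs landing
    on the reset step are discarded, matching the emulator's reset rule).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least dt")
    n = math.floor(duration / dt)
    inc = stim.step_increments(dt, n) if stim.mode == "spikes" else np.zeros(n)
    values = np.empty(n + 1)
    v = params.EL if v0 is None else float(v0)
    values[0] = v
    spike_steps: list[int] = []
    syn = 0.0  # exp-kernel synaptic drive (mV/ms)
    syn_decay = math.exp(-dt / stim.tau_syn) if stim.kernel == "exp" else 0.0
    for i in range(n):
        if v > params.theta:
            v = params.Vr
            spike_steps.append(i)
        else:
            dv = dt * (-(v - params.EL) / params.tau_v + stim.Ie / params.C)
            if stim.kernel == "exp":
                syn = syn * syn_decay + inc[i] / stim.tau_syn
                dv += dt * syn
                v = v + dv
            else:
                v = v + dv + inc[i]
        if not math.isfinite(v):
            raise SimulationError(
                f"non-finite membrane potential at step {i + 1}; "
                "check parameters and step size", step=i + 1)
        values[i + 1] = v
    return Trace(
        dt=dt,
        values=values,
        spike_times=np.array(spike_steps, dtype=float) * dt,
        duration=duration,
    )


def derivative_trace(trace: Trace) -> np.ndarray:
    """Forward finite differences of the trace, in mV/ms.

    Returns ``(values[i+1] - values[i]) / dt`` with one fewer sample than the
    trace.  Samples straddling a spike/reset carry the reset jump and are
    meant to be excluded downstream (see ``cost.subthreshold_mask``).
    """
    if trace.n_samples < 2:
        raise InsufficientDataError("derivative needs at least 2 samples")
    return np.diff(trace.values) / trace.dt
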