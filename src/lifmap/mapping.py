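"""Bidirectional transform between physical units and the integer emulator domain.

State rescaling uses a voltage scale Vs (mV per integer unit):

    v = trunc((V - V_r) / Vs),            V = V_r + v * Vs,

and time is discretized at the shared step dt.  The membrane time constant
maps to the 12-bit decay integer delta_v = trunc((dt/tau_v) * 2^12) and a
bias current I_e maps to the per-step integer increment
b = trunc(dt * I_e / (C * Vs)) (pA·ms/pF = mV, divided by Vs).  The default
Vs is calibrated so the study's base drive (200 pA into 170 pF at dt = 1 ms)
maps to the integer bias 1175 — the one printed anchor available for the
scale — and remains fully configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._numeric import trunc_toward_zero
from .errors import DecayRangeError, ScalingError
from .loihi_emu import EXPONENT_RANGE, LoihiNeuronConfig, encode_bias
from .model_core import LIFParams, StimulusSpec

__all__ = [
    "DEFAULT_VS",
    "MappingConfig",
    "rescale_state",
    "inverse_rescale",
    "compute_decay",
    "invert_decay",
    "map_lif_to_loihi",
]

#: Calibrated voltage scale: (dt * Ie / C) / 1175 for the base drive, about
#: 1.00125e-3 mV per integer unit.  The naive 1e-3 would map 200 pA to 1176.
DEFAULT_VS = (1.0 * 200.0 / 170.0) / 1175.0


@dataclass(frozen=True)
class MappingConfig:
    """Cross-platform transform: voltage scale, timestep, precision, rounding."""

    Vs: float = DEFAULT_VS  # mV per integer unit
    dt: float = 1.0  # ms
    precision_bits: int = 12
    rounding: str = "truncate"

    def __post_init__(self):
        if not self.Vs > 0:
            raise ValueError("Vs must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.precision_bits < 1:
            raise ValueError("precision_bits must be at least 1")
        if self.rounding != "truncate":
            raise ValueError("only truncation rounding is supported")


def rescale_state(V: float, Vr: float, mapping: MappingConfig) -> int:
    """Physical potential (mV) to integer state: trunc((V - Vr) / Vs)."""
    if not math.isfinite(V):
        raise ValueError("cannot rescale non-finite potential")
    return trunc_toward_zero((V - Vr) / mapping.Vs)


def inverse_rescale(v_int: int, Vr: float, mapping: MappingConfig) -> float:
    """Integer state back to mV: Vr + v * Vs (identity on exact multiples of Vs)."""
    return Vr + v_int * mapping.Vs


def compute_decay(tau_v: float, dt: float = 1.0, precision_bits: int = 12) -> int:
    """Integer voltage-decay parameter trunc((dt / tau_v) * 2^precision_bits)."""
    if tau_v < dt:
        raise DecayRangeError(
            f"tau_v = {tau_v} ms below dt = {dt} ms: decay would exceed 2^{precision_bits}")
    return trunc_toward_zero((dt / tau_v) * 2 ** precision_bits)


def invert_decay(delta_v: int, dt: float = 1.0, precision_bits: int = 12) -> float:
    """Membrane time constant (ms) recovered from the decay integer.

    Returns ``dt * 2^precision_bits / delta_v`` at full precision; display
    contexts conventionally round it to one decimal.
    """
    if delta_v < 1:
        raise DecayRangeError("delta_v = 0 is not invertible")
    return dt * 2 ** precision_bits / delta_v


def map_lif_to_loihi(
    params: LIFParams,
    stim: StimulusSpec,
    mapping: MappingConfig,
    duration: float = 500.0,
) -> tuple[LoihiNeuronConfig, np.ndarray]:
    """Map a physical neuron + stimulus onto the integer emulator domain.

    Returns the neuron configuration and the per-step integer input array
    ``u_steps`` of length ``floor(duration/dt)``.  The bias current becomes
    the mantissa/exponent-encoded constant b; when the resting potential
    differs from the reset potential, the constant leak drive
    ``dt * (EL - Vr) / (tau_v * Vs)`` is truncated to an integer and added to
    every step's input.  Spike weights are scaled by 1/Vs and truncated.
    """
    if stim.mode == "spikes" and stim.kernel != "delta":
        raise ScalingError("only the delta synaptic kernel maps to the emulator")
    dt, Vs = mapping.dt, mapping.Vs
    n_steps = math.floor(duration / dt)

    delta_v = compute_decay(params.tau_v, dt, mapping.precision_bits)

    bias_int = trunc_toward_zero(dt * stim.Ie / (params.C * Vs))
    enc = None
    for exponent in range(EXPONENT_RANGE[0], EXPONENT_RANGE[1] + 1):
        try:
            enc = encode_bias(bias_int, exponent)
            break
        except Exception:
            continue
    if enc is None:
        raise ScalingError(
            f"integer bias {bias_int} unencodable at any exponent; Vs = {Vs} is too fine")

    theta_int = None if math.isinf(params.theta) else rescale_state(
        params.theta, params.Vr, mapping)

    u_steps = np.zeros(n_steps, dtype=np.int64)
    if params.EL != params.Vr:
        u_steps += trunc_toward_zero(dt * (params.EL - params.Vr) / (params.tau_v * Vs))

    weights_int: tuple[int, ...] = ()
    if stim.mode == "spikes" and stim.spike_trains is not None:
        weights_int = tuple(
            trunc_toward_zero(stim.weight_of(src) / Vs)
            for src in range(stim.spike_trains.n_sources)
        )
        for src, steps in stim.spike_trains.steps(dt).items():
            for s in steps:
                if 0 <= s < n_steps:
                    u_steps[s] += weights_int[src]

    cfg = LoihiNeuronConfig(
        delta_v=delta_v,
        bias_mantissa=enc.mantissa,
        bias_exponent=enc.exponent,
        theta_int=theta_int,
        weights_int=weights_int,
    )
    return cfg, u_steps
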