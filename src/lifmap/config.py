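"""Run configuration: TOML loading, validation, manifest writing."""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .errors import ConfigError
from .mapping import DEFAULT_VS, MappingConfig
from .model_core import DEFAULT_PARAMS, LIFParams, StimulusSpec
from .stimulus import SpikeTrainSet, frozen_table1, poisson_spikes

__all__ = ["RunConfig", "load_config", "write_manifest"]


@dataclass(frozen=True)
class RunConfig:
    """A complete, validated run configuration (fail-fast)."""

    params: LIFParams = DEFAULT_PARAMS
    mapping: MappingConfig = MappingConfig()
    stimulus: StimulusSpec = StimulusSpec.bias(200.0)
    duration: float = 500.0
    seed: int | None = None
    out_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.duration < self.mapping.dt:
            raise ConfigError("run.duration_ms: must be at least mapping.dt")
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"run.log_level: unknown level {self.log_level!r}")

    def manifest(self) -> dict:
        stim = dataclasses.asdict(self.stimulus) if self.stimulus.mode == "bias" else {
            "mode": "spikes",
            "n_sources": self.stimulus.spike_trains.n_sources,
            "n_spikes": self.stimulus.spike_trains.n_spikes,
            "weight_mV": self.stimulus.weight,
            "kernel": self.stimulus.kernel,
        }
        return {
            "toolkit_version": __version__,
            "neuron": dataclasses.asdict(self.params) | {"R_GOhm": self.params.R},
            "mapping": dataclasses.asdict(self.mapping),
            "stimulus": stim,
            "duration_ms": self.duration,
            "seed": self.seed,
        }


def _get(section: dict, key: str, default, section_name: str):
    value = section.get(key, default)
    if value is None:
        raise ConfigError(f"{section_name}.{key}: required key missing")
    return value


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration.

    Recognised sections/keys::

        [neuron]    C_pF, tau_ms, EL_mV, Vr_mV, theta_mV
        [mapping]   Vs, dt, precision_bits, rounding
        [stimulus]  mode ("bias"|"spikes"), Ie_pA | spikes_csv, weight_mV
        [run]       duration_ms, seed, out_dir, log_level

    Validation failures raise :class:`ConfigError` naming the offending key.
    """
    try:
        with open(path, "rb") as f:
            raw = tomllib.load(f)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"malformed TOML in {path}: {exc}") from exc

    known = {"neuron", "mapping", "stimulus", "run"}
    for section in raw:
        if section not in known:
            raise ConfigError(f"{section}: unknown section")

    neuron = raw.get("neuron", {})
    try:
        params = LIFParams(
            C=float(_get(neuron, "C_pF", DEFAULT_PARAMS.C, "neuron")),
            tau_v=float(_get(neuron, "tau_ms", DEFAULT_PARAMS.tau_v, "neuron")),
            EL=float(_get(neuron, "EL_mV", DEFAULT_PARAMS.EL, "neuron")),
            Vr=float(_get(neuron, "Vr_mV", DEFAULT_PARAMS.Vr, "neuron")),
            theta=float(_get(neuron, "theta_mV", DEFAULT_PARAMS.theta, "neuron")),
        )
    except ValueError as exc:
        raise ConfigError(f"neuron: {exc}") from exc

    mcfg = raw.get("mapping", {})
    try:
        mapping = MappingConfig(
            Vs=float(_get(mcfg, "Vs", DEFAULT_VS, "mapping")),
            dt=float(_get(mcfg, "dt", 1.0, "mapping")),
            precision_bits=int(_get(mcfg, "precision_bits", 12, "mapping")),
            rounding=str(_get(mcfg, "rounding", "truncate", "mapping")),
        )
    except ValueError as exc:
        raise ConfigError(f"mapping: {exc}") from exc

    run = raw.get("run", {})
    seed = run.get("seed")
    duration = float(run.get("duration_ms", 500.0))

    scfg = raw.get("stimulus", {})
    mode = scfg.get("mode", "bias")
    try:
        if mode == "bias":
            stim = StimulusSpec.bias(float(_get(scfg, "Ie_pA", 200.0, "stimulus")))
        elif mode == "spikes":
            source = scfg.get("spikes_csv", "table1")
            if source == "table1":
                trains = frozen_table1()
            elif source == "poisson":
                trains = poisson_spikes(
                    n_sources=int(scfg.get("n_sources", 5)),
                    max_rate=float(scfg.get("max_rate_hz", 5.0)),
                    duration=duration, seed=seed, dt=mapping.dt)
            else:
                trains = SpikeTrainSet.from_csv(source)
            stim = StimulusSpec.spikes(trains, weight=float(scfg.get("weight_mV", 0.5)))
        else:
            raise ConfigError(f"stimulus.mode: unknown mode {mode!r}")
    except (ValueError, OSError) as exc:
        raise ConfigError(f"stimulus: {exc}") from exc

    return RunConfig(
        params=params,
        mapping=mapping,
        stimulus=stim,
        duration=duration,
        seed=seed,
        out_dir=str(run.get("out_dir", "results")),
        log_level=str(run.get("log_level", "INFO")),
    )


def write_manifest(config: RunConfig, path: str | Path, extra: dict | None = None) -> None:
    """Write the effective configuration (plus seed and version) as JSON."""
    manifest = config.manifest()
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
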