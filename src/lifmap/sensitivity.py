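"""One-at-a-time (OAT) and two-at-a-time (TAT) sensitivity scanners.

A scan perturbs the membrane capacitance Cm, time constant tau_v or resting
potential EL of exactly one backend over a grid while the other backend
stays fixed at its validated base configuration, and records the masked
subthreshold derivative RMSE at every grid point.  Directionality lives in
which side is perturbed ("reference" or "emulator"); the metric itself is
symmetric.  TAT scans evaluate the full Cartesian product of two grids with
both parameters perturbed simultaneously.

Perturbation semantics follow the cross-platform analysis convention:

* Cm alone is varied with the membrane resistance R held at its base ratio,
  so tau_v = R * Cm is re-derived (Cm enters the dynamics through the decay
  even for pure-spike drive);
* tau_v alone is varied directly (R re-derived);
* when Cm and tau_v are varied together, both are set directly and R follows;
* EL perturbations move the leak target only — the initial state and the
  reset potential stay at their base values (a perturbation changes the
  parameter, not the state).

Perturbing the emulator side re-runs the physical-to-integer mapping per
grid point, so the integer quantization of the decay and bias is re-applied;
this is what makes emulator-side curves less smooth than reference-side
ones, and it is intended behaviour, not noise to be filtered.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cost import rmse, subthreshold_mask
from .errors import GridError
from .loihi_emu import simulate_emulator
from .mapping import MappingConfig, map_lif_to_loihi, rescale_state
from .model_core import LIFParams, StimulusSpec, Trace, derivative_trace, simulate_reference

__all__ = [
    "SCAN_PARAMETERS",
    "PRESET_RANGES",
    "ParamGrid",
    "SensitivityGrid",
    "preset_grid",
    "apply_perturbation",
    "evaluate_point",
    "oat_scan",
    "tat_scan",
    "locate_minimum",
    "relative_change_profile",
    "first_step_relative_change",
    "run_preset_scans",
]

SCAN_PARAMETERS = ("Cm", "tau_v", "EL")

#: Scan presets, per stimulus mode: (min, max, step).  The bias-stimulus
#: ranges are narrower to resolve the sharper minima under constant drive.
PRESET_RANGES: dict[str, dict[str, tuple[float, float, float]]] = {
    "spike": {
        "Cm": (160.0, 180.0, 1.0),
        "tau_v": (21.0, 23.6, 0.2),
        "EL": (-71.0, -69.0, 0.1),
    },
    "bias": {
        "Cm": (169.0, 171.5, 0.2),
        "tau_v": (24.0, 26.2, 0.2),
        "EL": (-71.0, -69.0, 0.1),
    },
}


@dataclass(frozen=True)
class ParamGrid:
    """Ordered scan values for one parameter, with its declared base value.

    The base value need not lie inside the range (some presets deliberately
    bracket a shifted minimum); operations that require an interior base
    check for it themselves.
    """

    name: str
    values: np.ndarray = field(repr=False)
    base: float = math.nan

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise GridError("grid must be a non-empty 1-D sequence")
        if values.size > 1 and not np.all(np.diff(values) > 0):
            raise GridError("grid values must be strictly increasing")
        object.__setattr__(self, "values", values)

    @classmethod
    def from_range(cls, name: str, lo: float, hi: float, step: float,
                   base: float = math.nan) -> "ParamGrid":
        if step <= 0 or hi < lo:
            raise GridError("invalid grid range")
        n = int(math.floor((hi - lo) / step + 1e-9))
        values = np.round(lo + step * np.arange(n + 1), 10)
        return cls(name=name, values=values, base=base)

    @property
    def size(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class SensitivityGrid:
    """RMSE values over a 1-D or 2-D parameter grid.

    ``rmse_values`` has one axis per grid, indexed like the grids; failed
    points hold NaN with the reason in ``failures``.
    """

    axes: tuple[ParamGrid, ...]
    direction: str  # "reference" or "emulator"
    rmse_values: np.ndarray = field(repr=False)
    failures: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        shape = tuple(g.size for g in self.axes)
        if tuple(np.shape(self.rmse_values)) != shape:
            raise GridError("rmse_values shape must match the grid axes")
        if self.direction not in ("reference", "emulator"):
            raise GridError("direction must be 'reference' or 'emulator'")

    @property
    def argmin(self) -> tuple[int, ...]:
        return locate_minimum(self)[0]

    @property
    def min_rmse(self) -> float:
        return locate_minimum(self)[1]

    def argmin_values(self) -> tuple[float, ...]:
        idx = self.argmin
        return tuple(float(g.values[i]) for g, i in zip(self.axes, idx))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per grid point."""
        rows = []
        for idx in itertools.product(*(range(g.size) for g in self.axes)):
            row = {}
            for k, (g, i) in enumerate(zip(self.axes, idx), start=1):
                row[f"param_{k}"] = g.name
                row[f"value_{k}"] = g.values[i]
            row["direction"] = self.direction
            row["rmse"] = self.rmse_values[idx]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        idx, value = locate_minimum(self)
        out = {
            "direction": self.direction,
            "parameters": [g.name for g in self.axes],
            "argmin": {g.name: float(g.values[i]) for g, i in zip(self.axes, idx)},
            "min_rmse": value,
            "max_rmse": float(np.nanmax(self.rmse_values)),
            "n_points": int(np.size(self.rmse_values)),
            "n_failures": len(self.failures),
        }
        if len(self.axes) == 1:
            try:
                out["relative_change_profile"] = relative_change_profile(self).tolist()
            except GridError:
                pass
        return out


def preset_grid(stimulus_mode: str, name: str, base_params: LIFParams) -> ParamGrid:
    """Build the named preset grid for a stimulus mode ('spike' or 'bias')."""
    try:
        lo, hi, step = PRESET_RANGES[stimulus_mode][name]
    except KeyError as exc:
        raise GridError(f"no preset grid for {stimulus_mode!r}/{name!r}") from exc
    base = {"Cm": base_params.C, "tau_v": base_params.tau_v, "EL": base_params.EL}[name]
    return ParamGrid.from_range(name, lo, hi, step, base=base)


def apply_perturbation(base: LIFParams, updates: dict[str, float]) -> LIFParams:
    """Return base parameters with the scan perturbations applied.

    Implements the R-held-fixed rule for a lone Cm perturbation (see module
    docstring); Vr, theta and the initial condition are never touched.
    """
    unknown = set(updates) - set(SCAN_PARAMETERS)
    if unknown:
        raise GridError(f"unknown scan parameter(s): {sorted(unknown)}")
    kwargs = {}
    if "Cm" in updates and "tau_v" in updates:
        kwargs["C"] = updates["Cm"]
        kwargs["tau_v"] = updates["tau_v"]
    elif "Cm" in updates:
        kwargs["C"] = updates["Cm"]
        kwargs["tau_v"] = base.R * updates["Cm"]  # R fixed at base ratio
    elif "tau_v" in updates:
        kwargs["tau_v"] = updates["tau_v"]
    if "EL" in updates:
        kwargs["EL"] = updates["EL"]
    return base.replace(**kwargs)


def evaluate_point(
    base_params: LIFParams,
    stim: StimulusSpec,
    mapping: MappingConfig,
    updates: dict[str, float],
    direction: str = "reference",
    duration: float = 500.0,
    guard: int = 1,
    fixed_trace: Trace | None = None,
) -> float:
    """Masked derivative RMSE with ``updates`` applied to one backend.

    ``fixed_trace`` optionally supplies the unperturbed side's precomputed
    trace (it is identical for every point of a scan).  Evaluations are
    independent of one another, so results do not depend on scan order.
    """
    perturbed = apply_perturbation(base_params, updates)
    v0 = base_params.EL  # initial state pinned to the base configuration
    if direction == "reference":
        moved = simulate_reference(perturbed, stim, mapping.dt, duration, v0=v0)
        fixed = fixed_trace if fixed_trace is not None else _emulator_trace(
            base_params, stim, mapping, duration, v0)
    elif direction == "emulator":
        moved = _emulator_trace(perturbed, stim, mapping, duration, v0,
                                vr_base=base_params.Vr)
        fixed = fixed_trace if fixed_trace is not None else simulate_reference(
            base_params, stim, mapping.dt, duration, v0=v0)
    else:
        raise GridError("direction must be 'reference' or 'emulator'")
    mask = subthreshold_mask(moved, fixed, guard=guard)
    return rmse(derivative_trace(moved), derivative_trace(fixed), mask)


def _emulator_trace(params: LIFParams, stim: StimulusSpec, mapping: MappingConfig,
                    duration: float, v0_mv: float,
                    vr_base: float | None = None) -> Trace:
    """Map, run and rescale the emulator back to a physical-unit trace."""
    vr = params.Vr if vr_base is None else vr_base
    cfg, u_steps = map_lif_to_loihi(params, stim, mapping, duration)
    emu = simulate_emulator(cfg, u_steps=u_steps,
                            v0=rescale_state(v0_mv, vr, mapping))
    return emu.to_trace(Vr=vr, Vs=mapping.Vs, dt=mapping.dt)


def _fixed_side(base_params, stim, mapping, duration, direction):
    v0 = base_params.EL
    if direction == "reference":  # emulator side stays fixed
        return _emulator_trace(base_params, stim, mapping, duration, v0)
    return simulate_reference(base_params, stim, mapping.dt, duration, v0=v0)


def oat_scan(
    base_params: LIFParams,
    stim: StimulusSpec,
    mapping: MappingConfig,
    grid: ParamGrid,
    direction: str = "reference",
    duration: float = 500.0,
    guard: int = 1,
) -> SensitivityGrid:
    """One-at-a-time scan: one parameter perturbed per point, base restored after."""
    fixed = _fixed_side(base_params, stim, mapping, duration, direction)
    values = np.empty(grid.size)
    failures: dict = {}
    for i, x in enumerate(grid.values):
        try:
            values[i] = evaluate_point(base_params, stim, mapping, {grid.name: x},
                                       direction, duration, guard, fixed_trace=fixed)
        except Exception as exc:  # noqa: BLE001 - per-point failure is data
            values[i] = np.nan
            failures[(i,)] = f"{grid.name}={x}: {exc}"
    return SensitivityGrid(axes=(grid,), direction=direction,
                           rmse_values=values, failures=failures)


def tat_scan(
    base_params: LIFParams,
    stim: StimulusSpec,
    mapping: MappingConfig,
    grid_a: ParamGrid,
    grid_b: ParamGrid,
    direction: str = "reference",
    duration: float = 500.0,
    guard: int = 1,
) -> SensitivityGrid:
    """Two-at-a-time scan over the Cartesian product of two parameter grids."""
    if grid_a.name == grid_b.name:
        raise GridError("TAT grids must cover distinct parameters")
    fixed = _fixed_side(base_params, stim, mapping, duration, direction)
    values = np.empty((grid_a.size, grid_b.size))
    failures: dict = {}
    for i, a in enumerate(grid_a.values):
        for j, b in enumerate(grid_b.values):
            try:
                values[i, j] = evaluate_point(
                    base_params, stim, mapping,
                    {grid_a.name: a, grid_b.name: b},
                    direction, duration, guard, fixed_trace=fixed)
            except Exception as exc:  # noqa: BLE001
                values[i, j] = np.nan
                failures[(i, j)] = f"{grid_a.name}={a},{grid_b.name}={b}: {exc}"
    return SensitivityGrid(axes=(grid_a, grid_b), direction=direction,
                           rmse_values=values, failures=failures)


def locate_minimum(grid: SensitivityGrid) -> tuple[tuple[int, ...], float]:
    """Coordinates and value of the smallest RMSE.

    Ties are broken toward the declared base value (smallest total distance),
    then lexicographically by index.
    """
    values = grid.rmse_values
    if np.all(np.isnan(values)):
        raise GridError("all grid points failed; no minimum")
    vmin = np.nanmin(values)
    candidates = [tuple(int(i) for i in idx) for idx in np.argwhere(values == vmin)]

    def tie_key(idx):
        dist = 0.0
        for g, i in zip(grid.axes, idx):
            if math.isfinite(g.base):
                dist += abs(g.values[i] - g.base)
        return (dist, idx)

    return min(candidates, key=tie_key), float(vmin)


def relative_change_profile(grid: SensitivityGrid) -> np.ndarray:
    """Per-point fractional RMSE increase from the minimum, (RMSE - min)/min.

    Defined for 1-D grids.  A zero minimum (identical traces) degenerates
    the fractional form; absolute increases are returned instead.
    """
    if len(grid.axes) != 1:
        raise GridError("relative-change profile is defined for 1-D grids")
    _, vmin = locate_minimum(grid)
    if vmin == 0.0:
        return grid.rmse_values.copy()
    return (grid.rmse_values - vmin) / vmin


def first_step_relative_change(grid: SensitivityGrid) -> float:
    """Largest fractional RMSE increase one grid step away from the minimum."""
    profile = relative_change_profile(grid)
    (idx,), _ = locate_minimum(grid)
    neighbours = [profile[j] for j in (idx - 1, idx + 1) if 0 <= j < profile.size]
    if not neighbours:
        raise GridError("single-point grid has no neighbouring step")
    return float(max(neighbours))


def run_preset_scans(
    base_params: LIFParams,
    mapping: MappingConfig,
    spike_stim: StimulusSpec,
    bias_stim: StimulusSpec,
    duration: float = 500.0,
    directions: tuple[str, ...] = ("reference", "emulator"),
    include_tat: bool = True,
):
    """Run every preset OAT scan (and optionally the three TAT pairings)
    for both stimuli and the requested directions.

    Yields ``(label, SensitivityGrid)`` pairs, with labels like
    ``"spike/reference/oat/EL"`` or ``"bias/emulator/tat/Cm-tau_v"``.
    """
    stimuli = {"spike": spike_stim, "bias": bias_stim}
    for mode, stim in stimuli.items():
        grids = {name: preset_grid(mode, name, base_params) for name in SCAN_PARAMETERS}
        for direction in directions:
            for name in SCAN_PARAMETERS:
                yield (f"{mode}/{direction}/oat/{name}",
                       oat_scan(base_params, stim, mapping, grids[name],
                                direction, duration))
            if include_tat:
                for a, b in itertools.combinations(SCAN_PARAMETERS, 2):
                    yield (f"{mode}/{direction}/tat/{a}-{b}",
                           tat_scan(base_params, stim, mapping, grids[a], grids[b],
                                    direction, duration))
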