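"""Stimulus fixtures and generators.

The toolkit's validation protocol drives a single neuron either with a
constant bias current or with a small set of external spike sources.  The
canonical spike stimulus is a frozen set of eleven spikes from five sources
(:func:`frozen_table1`); new stimuli of the same character are produced by
:func:`poisson_spikes` (homogeneous Poisson sources, frozen by seed).  A
small random excitatory/inhibitory network builder is included for demos.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridError

__all__ = [
    "SpikeTrainSet",
    "NetworkSpec",
    "frozen_table1",
    "poisson_spikes",
    "random_ei_network",
]

#: The frozen five-source stimulus: ``{source_id: spike times (ms)}``.
_TABLE1_TIMES = {
    0: (446.0,),
    1: (355.0,),
    2: (53.0, 258.0, 300.0, 424.0, 457.0),
    3: (88.0, 466.0),
    4: (100.0, 212.0),
}


@dataclass(frozen=True)
class SpikeTrainSet:
    """Spike times of ``n_sources`` independent sources over ``duration`` ms.

    ``times`` holds one strictly-increasing array of spike times per source.
    """

    n_sources: int
    times: tuple[np.ndarray, ...]
    duration: float

    def __post_init__(self):
        if self.n_sources != len(self.times):
            raise ValueError("times must hold one array per source")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        clean = []
        for src, t in enumerate(self.times):
            t = np.asarray(t, dtype=float)
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise ValueError(f"source {src}: spike time outside [0, duration]")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"source {src}: spike times must be strictly increasing")
            clean.append(t)
        object.__setattr__(self, "times", tuple(clean))

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.times))

    def records(self) -> list[tuple[int, float]]:
        """All spikes as ``(source_id, time_ms)`` pairs, sorted by time."""
        recs = [(src, float(t)) for src, ts in enumerate(self.times) for t in ts]
        return sorted(recs, key=lambda r: (r[1], r[0]))

    def steps(self, dt: float) -> dict[int, list[int]]:
        """Spike step indices per source on a ``dt`` grid (times truncated)."""
        return {src: [int(t // dt) for t in ts] for src, ts in enumerate(self.times)}

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.records(), columns=["source_id", "time_ms"])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_sources: int | None = None, duration: float | None = None) -> "SpikeTrainSet":
        df = pd.read_csv(path)
        if list(df.columns) != ["source_id", "time_ms"]:
            raise ValueError("spike CSV must have header 'source_id,time_ms'")
        if n_sources is None:
            n_sources = int(df["source_id"].max()) + 1 if len(df) else 0
        if duration is None:
            duration = float(df["time_ms"].max()) if len(df) else 0.0
        times = tuple(
            np.sort(df.loc[df["source_id"] == src, "time_ms"].to_numpy(dtype=float))
            for src in range(n_sources)
        )
        return cls(n_sources=n_sources, times=times, duration=duration)


def frozen_table1() -> SpikeTrainSet:
    """The frozen five-source, eleven-spike external stimulus (500 ms)."""
    times = tuple(np.array(_TABLE1_TIMES[src], dtype=float) for src in range(5))
    return SpikeTrainSet(n_sources=5, times=times, duration=500.0)


def poisson_spikes(
    n_sources: int,
    max_rate: float,
    duration: float,
    seed: int | None = None,
    dt: float = 1.0,
    heterogeneous_rates: bool = False,
) -> SpikeTrainSet:
    """Homogeneous Poisson spike sources, frozen by ``seed``.

    Each source fires at ``max_rate`` (Hz); with ``heterogeneous_rates`` each
    source's rate is drawn uniformly from ``(0, max_rate]`` instead.  Spike
    times are snapped to the ``dt`` grid by truncation (the toolkit-wide
    rounding convention) and deduplicated so per-source times stay strictly
    increasing.
    """
    if max_rate <= 0:
        raise ValueError("max_rate must be positive")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = np.random.default_rng(seed)
    times = []
    for _ in range(n_sources):
        rate = max_rate * rng.uniform() if heterogeneous_rates else max_rate
        rate_per_ms = rate / 1000.0
        ts: list[float] = []
        t = 0.0
        while True:
            t += rng.exponential(1.0 / rate_per_ms) if rate_per_ms > 0 else np.inf
            if t > duration:
                break
            ts.append((t // dt) * dt)
        times.append(np.unique(np.asarray(ts, dtype=float)))
    return SpikeTrainSet(n_sources=n_sources, times=tuple(times), duration=duration)


@dataclass(frozen=True)
class NetworkSpec:
    """A random directed E/I network: edge list with signed weights."""

    n_neurons: int
    ei_ratio: str
    connection_probability: float
    edges: np.ndarray = field(repr=False)  # shape (m, 3): src, dst, weight
    seed: int | None = None

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.edges, columns=["src", "dst", "weight"])
        df["src"] = df["src"].astype(int)
        df["dst"] = df["dst"].astype(int)
        df.to_csv(path, index=False)


def random_ei_network(
    n: int,
    ei_ratio: str = "1:1",
    p: float = 0.1,
    seed: int | None = None,
    w_exc: float = 0.5,
    w_inh: float = -0.5,
) -> NetworkSpec:
    """Independent Bernoulli(``p``) directed edges, no self-edges.

    The first ``n_exc`` neurons (per ``ei_ratio``, e.g. ``"1:1"``) are
    excitatory with weight ``w_exc``; the rest inhibitory with ``w_inh``.
    """
    if n < 2:
        raise GridError("network needs at least 2 neurons")
    if not 0.0 <= p <= 1.0:
        raise GridError("connection probability must lie in [0, 1]")
    try:
        e_part, i_part = (int(x) for x in ei_ratio.split(":"))
    except Exception as exc:
        raise GridError(f"cannot parse ei_ratio {ei_ratio!r}") from exc
    n_exc = round(n * e_part / (e_part + i_part))
    rng = np.random.default_rng(seed)
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    src, dst = np.nonzero(mask)
    weight = np.where(src < n_exc, w_exc, w_inh)
    edges = np.column_stack([src.astype(float), dst.astype(float), weight])
    return NetworkSpec(
        n_neurons=n,
        ei_ratio=ei_ratio,
        connection_probability=p,
        edges=edges,
        seed=seed,
    )
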