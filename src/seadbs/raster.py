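"""Spike rasters: per-neuron event lists over a time window."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SpikeRaster"]


@dataclass
class SpikeRaster:
    """Per-neuron ordered spike times (ms) within a half-open window [t0, t1).

    Parameters
    ----------
    spikes : list of ndarray
        One strictly increasing array of spike times per neuron.
    t0, t1 : float
        Window bounds in ms; every spike time lies in ``[t0, t1)``.
    """

    spikes: list = field(default_factory=list)
    t0: float = 0.0
    t1: float = 0.0

    def __post_init__(self) -> None:
        if self.t1 < self.t0:
            raise ValueError(f"window bounds reversed: [{self.t0}, {self.t1})")
        clean = []
        for i, s in enumerate(self.spikes):
            s = np.asarray(s, dtype=float)
            if s.size and (np.any(np.diff(s) <= 0)):
                raise ValueError(f"spike times not strictly increasing for neuron {i}")
            if s.size and (s[0] < self.t0 or s[-1] >= self.t1):
                raise ValueError(
                    f"neuron {i} has spikes outside [{self.t0}, {self.t1})"
                )
            clean.append(s)
        self.spikes = clean

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    @property
    def duration(self) -> float:
        return self.t1 - self.t0

    @property
    def n_spikes(self) -> int:
        return int(sum(s.size for s in self.spikes))

    def concat(self, other: "SpikeRaster") -> "SpikeRaster":
        """Append a raster that starts exactly where this one ends."""
        if other.n_neurons != self.n_neurons:
            raise ValueError("neuron counts differ")
        if not np.isclose(other.t0, self.t1):
            raise ValueError(f"rasters not contiguous: {self.t1} vs {other.t0}")
        spikes = [
            np.concatenate([a, b]) for a, b in zip(self.spikes, other.spikes)
        ]
        return SpikeRaster(spikes, self.t0, other.t1)

    def between(self, t0: float, t1: float) -> "SpikeRaster":
        """Restrict to the sub-window [t0, t1) (must lie within bounds)."""
        if t0 < self.t0 - 1e-9 or t1 > self.t1 + 1e-9:
            raise ValueError(f"[{t0}, {t1}) not inside [{self.t0}, {self.t1})")
        spikes = [s[(s >= t0) & (s < t1)] for s in self.spikes]
        return SpikeRaster(spikes, t0, t1)

    def tail(self, duration: float) -> "SpikeRaster":
        """The trailing ``duration`` ms of the raster (at most the full window)."""
        t0 = max(self.t0, self.t1 - duration)
        spikes = [s[s >= t0] for s in self.spikes]
        return SpikeRaster(spikes, t0, self.t1)

    def to_text(self, path: str | Path) -> None:
        """Write a two-column event list: neuron id, spike time (ms)."""
        with open(path, "w") as fh:
            fh.write(f"# window {self.t0} {self.t1} ms\n")
            for i, s in enumerate(self.spikes):
                for t in s:
                    fh.write(f"{i}\t{t:.4f}\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "SpikeRaster":
        with open(path) as fh:
            header = fh.readline().split()
            t0, t1 = float(header[2]), float(header[3])
            events: dict[int, list[float]] = {}
            n_max = -1
            for line in fh:
                i_s, t_s = line.split()
                i = int(i_s)
                events.setdefault(i, []).append(float(t_s))
                n_max = max(n_max, i)
        spikes = [np.array(events.get(i, []), dtype=float) for i in range(n_max + 1)]
        return cls(spikes, t0, t1)
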