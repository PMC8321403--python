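"""Frames and trajectories (nm / ns, orthorhombic boxes only)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .topology import ParticleTopology

__all__ = ["Frame", "Trajectory"]


@dataclass
class Frame:
    """One snapshot: N x 3 coordinates (nm), box edges (nm), time (ns)."""

    coordinates: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (N, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be 3 positive edge lengths (orthorhombic)")

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[0]


class Trajectory:
    """Ordered frames over a fixed topology.

    Stores coordinates as a dense (n_frames, N, 3) array for vectorized
    per-frame analysis; :meth:`frames` iterates lightweight Frame views.
    """

    def __init__(self, topology: ParticleTopology, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        n = topology.n_particles
        for i, fr in enumerate(frames):
            if fr.n_particles != n:
                raise ValueError(
                    f"frame {i} has {fr.n_particles} particles, topology has {n}")
        times = np.array([fr.time for fr in frames], dtype=float)
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        self.topology = topology
        self.coordinates = np.stack([fr.coordinates for fr in frames])
        self.boxes = np.stack([fr.box for fr in frames])
        self.times = times

    # ------------------------------------------------------------------
    @classmethod
    def from_arrays(cls, topology: ParticleTopology, coordinates: np.ndarray,
                    boxes: np.ndarray, times: np.ndarray) -> "Trajectory":
        traj = cls.__new__(cls)
        coordinates = np.asarray(coordinates, dtype=float)
        boxes = np.asarray(boxes, dtype=float)
        times = np.asarray(times, dtype=float)
        if coordinates.ndim != 3 or coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, N, 3)")
        if coordinates.shape[1] != topology.n_particles:
            raise ValueError("particle count mismatch with topology")
        if boxes.shape != (coordinates.shape[0], 3):
            raise ValueError("boxes must have shape (n_frames, 3)")
        if len(times) > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        traj.topology = topology
        traj.coordinates = coordinates
        traj.boxes = boxes
        traj.times = times
        return traj

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    @property
    def frame_interval(self) -> float:
        """Time between frames in ns (from the first pair; 0 if single-frame)."""
        return float(self.times[1] - self.times[0]) if self.n_frames > 1 else 0.0

    def frame(self, i: int) -> Frame:
        return Frame(self.coordinates[i], self.boxes[i], float(self.times[i]))

    def frames(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def strided(self, stride: int) -> "Trajectory":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        if stride >= self.n_frames:
            raise ValueError(f"stride {stride} >= frame count {self.n_frames}")
        return Trajectory.from_arrays(self.topology, self.coordinates[::stride],
                                      self.boxes[::stride], self.times[::stride])
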