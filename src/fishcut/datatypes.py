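"""Core in-memory containers for laser-scan data.

A scan of one fish is a :class:`PointCloud`: an ordered sequence of
:class:`RadialProfile` frames, one per laser line, each holding the lateral
positions ``y`` (mm) and surface heights ``z`` (mm) measured at conveyor
position ``x`` (mm).  All coordinates follow the rig convention: ``x`` along
belt travel (increasing toward the fish head), ``y`` lateral along the laser
line, ``z`` vertical height in the sensor frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["RadialProfile", "PointCloud"]


@dataclass
class RadialProfile:
    """One laser frame: heights ``z`` sampled at lateral positions ``y``.

    Parameters
    ----------
    x : float
        Conveyor position of the frame, mm.
    y : array-like
        Lateral positions, mm, strictly increasing.
    z : array-like
        Heights, mm, same length as ``y``.
    belt_level : float, optional
        Estimated belt-surface height for this frame (set by preprocessing
        from the flanking belt regions); mm.
    """

    x: float
    y: np.ndarray
    z: np.ndarray
    belt_level: float | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.y.ndim != 1 or self.z.ndim != 1:
            raise InvalidArgumentError("profile y and z must be 1-D")
        if self.y.shape != self.z.shape:
            raise InvalidArgumentError(
                f"profile y and z lengths differ: {self.y.size} vs {self.z.size}"
            )
        if self.y.size > 1 and not np.all(np.diff(self.y) > 0):
            raise InvalidArgumentError("profile y must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.y.size)

    def __len__(self) -> int:
        return self.n_points


@dataclass
class PointCloud:
    """Ordered sequence of radial profiles for one fish pass.

    ``frame_spacing`` is the belt travel between consecutive sampled frames
    (mm).  ``belt_height`` is the nominal belt-plane height in the sensor
    frame (mm) when known (the simulator records it; preprocessing estimates
    it for measured data).
    """

    frames: list[RadialProfile]
    frame_spacing: float
    belt_height: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = list(self.frames)
        if self.frame_spacing <= 0:
            raise InvalidArgumentError("frame_spacing must be > 0")
        xs = [f.x for f in self.frames]
        if xs != sorted(xs):
            self.frames.sort(key=lambda f: f.x)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_positions(self) -> np.ndarray:
        return np.array([f.x for f in self.frames], dtype=float)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self) -> Iterator[RadialProfile]:
        return iter(self.frames)

    def __getitem__(self, k: int) -> RadialProfile:
        return self.frames[k]


def as_point_cloud(frames: Sequence[RadialProfile], frame_spacing: float,
                   belt_height: float | None = None, **metadata) -> PointCloud:
    """Convenience constructor used by the simulator and readers."""
    return PointCloud(list(frames), frame_spacing, belt_height, dict(metadata))
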