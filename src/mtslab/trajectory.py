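"""In-memory trajectory container shared by the driver and the analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Topology


@dataclass
class Trajectory:
    """Frames of positions/boxes at saved times, tied to one topology."""

    topology: Topology
    times: list[float] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)
    boxes: list[np.ndarray] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def append(self, time: float, positions: np.ndarray,
               box: np.ndarray) -> None:
        self.times.append(float(time))
        self.positions.append(np.array(positions, copy=True))
        self.boxes.append(np.array(box, copy=True))

    def frame_period(self) -> float:
        """Sampling period in ps (requires uniform saving)."""
        if self.n_frames < 2:
            raise ValueError("need >= 2 frames to infer the frame period")
        dts = np.diff(self.times)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("frames are not uniformly spaced")
        return float(dts[0])

    def subset(self, frame_indices) -> "Trajectory":
        out = Trajectory(self.topology)
        for k in frame_indices:
            out.append(self.times[k], self.positions[k], self.boxes[k])
        return out
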