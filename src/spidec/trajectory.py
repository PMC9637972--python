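"""In-memory trajectory container shared by the engines and the analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .configuration import Box

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """A stack of saved frames from one run.

    Attributes
    ----------
    positions : (n_frames, N, 3) array
        Wrapped coordinates.
    steps : (n_frames,) int array
        Global step (MD time step or MC sweep) of each frame.
    box : Box
    species : list of str
        Per-particle type labels (H/P/LJ/C/PATCH).
    molecule_index : (N,) int array
    orientations : (n_frames, N, 3, 3) array or None
        Patchy-particle orientations, when present.
    time_per_step : float
        Physical time per step in tau (MD: dt; MC: 1 sweep).
    """

    positions: np.ndarray
    steps: np.ndarray
    box: Box
    species: list[str]
    molecule_index: np.ndarray
    orientations: np.ndarray | None = None
    time_per_step: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.steps = np.asarray(self.steps, dtype=np.int64)
        if self.positions.ndim != 3:
            raise ValueError("positions must be (n_frames, N, 3)")
        if len(self.steps) != self.n_frames:
            raise ValueError("steps must match the number of frames")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.steps * self.time_per_step

    def window(self, start: int, stop: int | None = None) -> "Trajectory":
        """Sub-trajectory by frame index (half-open)."""
        sl = slice(start, stop)
        return Trajectory(
            self.positions[sl],
            self.steps[sl],
            self.box,
            self.species,
            self.molecule_index,
            None if self.orientations is None else self.orientations[sl],
            self.time_per_step,
        )

    def second_half(self) -> "Trajectory":
        return self.window(self.n_frames // 2)
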