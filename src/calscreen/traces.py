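"""Per-cell fluorescence time courses.

A :class:`TraceSeries` is the atomic unit of the analysis: one cell's
fluo-4 intensity sampled at a fixed rate (nominally 380 frames at 2 Hz,
i.e. 190 s of recording following agonist addition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TraceSeries"]


@dataclass
class TraceSeries:
    """One cell's fluorescence time course.

    Parameters
    ----------
    well_id : str
        Identifier of the well the cell was imaged in.
    cell_id : int
        Identifier of the cell within its well.
    values : ndarray of float
        Fluorescence per frame, arbitrary units. Must be finite and hold
        at least two samples.
    sampling_rate : float
        Frames per second; must be positive. Default 2.0 Hz.
    """

    well_id: str
    cell_id: int
    values: np.ndarray
    sampling_rate: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace needs at least 2 samples in a 1-d array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def time(self) -> np.ndarray:
        """Time of each frame in seconds (frame_index / sampling_rate)."""
        return np.arange(self.values.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        """Total recorded time span in seconds."""
        return (self.values.size - 1) / self.sampling_rate
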