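"""Time-lapse image stack container.

An :class:`ImageStack` is the universal currency of the toolkit: a 3-D
array of non-negative intensities indexed ``(frame, row, col)`` together
with the frame interval ``dt`` in seconds (one frame per bleach/acquire
cycle in a FLIP experiment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack:
    """A grayscale time-lapse stack.

    Parameters
    ----------
    data
        Array of shape ``(n_frames, height, width)``. Stored as float64.
    dt
        Frame interval in seconds; frame ``n`` is acquired at ``t = n * dt``.
    """

    data: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValueError(
                f"stack data must be 3-D (frames, height, width); got shape {arr.shape}"
            )
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ValueError(f"dt must be a positive number of seconds; got {self.dt}")
        self.data = arr

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Acquisition times in seconds, ``t_n = n * dt``."""
        return np.arange(self.n_frames) * self.dt

    def __getitem__(self, n) -> np.ndarray:
        return self.data[n]
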