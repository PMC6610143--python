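"""In-memory movie container with physical calibration metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Movie:
    """A calibrated fluorescence movie.

    Pixel data are stored in a fixed five-axis order ``(T, C, Z, Y, X)``;
    missing axes have extent 1.  Physical calibration (pixel size and frame
    interval) travels with the array so every downstream table can report
    both pixel and micrometre coordinates.

    Attributes
    ----------
    data
        Camera counts, shape ``(T, C, Z, Y, X)``, floating point.
    pixel_size_um
        Lateral pixel size in micrometres per pixel.
    frame_interval_s
        Time between consecutive frames in seconds.
    channel_names
        One name per channel axis entry.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 2:
            arr = arr[None, None, None]
        elif arr.ndim == 3:  # (T, Y, X)
            arr = arr[:, None, None]
        elif arr.ndim == 4:  # (T, C, Y, X)
            arr = arr[:, :, None]
        elif arr.ndim != 5:
            raise ValueError(f"movie array must have 2-5 axes, got {arr.ndim}")
        self.data = arr
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        if not (self.frame_interval_s > 0):
            raise ValueError("frame_interval_s must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match channel axis")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_z(self) -> int:
        return self.data.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]

    def frame(self, t: int, channel: int = 0, z_policy: str = "max_project") -> np.ndarray:
        """Return one 2-D frame; z collapsed by max projection by default."""
        stack = self.data[t, channel]
        if self.n_z == 1:
            return stack[0]
        if z_policy == "max_project":
            return stack.max(axis=0)
        raise ValueError(f"unknown z_policy {z_policy!r}")

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s
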