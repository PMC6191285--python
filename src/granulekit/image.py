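"""The in-memory image container used throughout granulekit.

All images are carried as 5-D arrays in the fixed axis order ``(t, z, c, y, x)``
(time, axial plane, channel, row, column).  Missing axes are inserted with
length 1, so a plain 2-D micrograph becomes ``(1, 1, 1, Y, X)``.  Pixel indices
are 0-based and pixel centers sit at integer coordinates; physical distances
are obtained via ``pixel_size_nm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

AXES = "TZCYX"


@dataclass
class ImageStack:
    """An n-dimensional fluorescence image with physical calibration.

    Parameters
    ----------
    data
        Intensity array of shape ``(t, z, c, y, x)``.
    pixel_size_nm
        Lateral pixel size in nanometers per pixel (> 0).
    frame_interval_s
        Time between consecutive frames in seconds (> 0).
    """

    data: np.ndarray
    pixel_size_nm: float = 100.0
    frame_interval_s: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ParameterError(
                f"ImageStack data must be 5-D (t, z, c, y, x); got {self.data.ndim}-D"
            )
        if not (self.pixel_size_nm > 0):
            raise ParameterError("pixel_size_nm must be > 0")
        if not (self.frame_interval_s > 0):
            raise ParameterError("frame_interval_s must be > 0")

    @classmethod
    def from_array(cls, arr, axes: str | None = None, **kwargs) -> "ImageStack":
        """Wrap an array, inserting missing axes.

        ``axes`` names the existing dimensions with characters from ``TZCYX``
        (in order).  When omitted, trailing dimensions are taken as ``(y, x)``
        and remaining leading dimensions, if any, as ``t`` then ``z``.
        """
        arr = np.asarray(arr)
        if axes is None:
            if arr.ndim == 2:
                axes = "YX"
            elif arr.ndim == 3:
                axes = "TYX"
            elif arr.ndim == 4:
                axes = "TZYX"
            elif arr.ndim == 5:
                axes = AXES
            else:
                raise ParameterError(f"cannot infer axes for {arr.ndim}-D array")
        axes = axes.upper()
        if len(axes) != arr.ndim:
            raise ParameterError(f"axes {axes!r} do not match {arr.ndim}-D array")
        unknown = set(axes) - set(AXES)
        if unknown:
            raise ParameterError(f"unknown axis labels {sorted(unknown)}")
        if sorted(axes, key=AXES.index) != list(axes):
            order = sorted(range(arr.ndim), key=lambda i: AXES.index(axes[i]))
            arr = arr.transpose(order)
            axes = "".join(axes[i] for i in order)
        for pos, ax in enumerate(AXES):
            if ax not in axes:
                arr = np.expand_dims(arr, pos)
        return cls(arr, **kwargs)

    # -- convenience accessors -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def shape_yx(self) -> tuple:
        return self.data.shape[3:]

    def plane(self, t: int = 0, z: int = 0, c: int = 0) -> np.ndarray:
        """Return one 2-D plane."""
        return self.data[t, z, c]

    def volume(self, t: int = 0, c: int = 0) -> np.ndarray:
        """Return one 3-D (z, y, x) volume."""
        return self.data[t, :, c]

    @property
    def pixel_area_nm2(self) -> float:
        return self.pixel_size_nm**2
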