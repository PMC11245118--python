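"""Calibrated multi-channel time-lapse container and TIFF round-trip.

A :class:`TimelapseStack` is the universal input of every analysis stage:
a ``(frames, channels, rows, cols)`` array of nonnegative intensities plus
the two pieces of calibration every downstream number depends on — the
pixel size in micrometres and the frame interval in seconds.

Stacks are written as multi-page TIFF with the calibration embedded as a
JSON blob in the image description, so a stack written by this package
round-trips bit-identically.  Foreign TIFFs without calibration metadata
are accepted only when the caller supplies the calibration explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

_DESC_KEY = "orgdyn_stack"


@dataclass
class TimelapseStack:
    """Calibrated image sequence: ``data[t, c, y, x]``.

    Parameters
    ----------
    data:
        Nonnegative intensities, shape ``(n_frames, n_channels, rows, cols)``.
    pixel_size_um:
        Physical size of one pixel edge, micrometres (> 0).
    frame_interval_s:
        Time between consecutive frames, seconds (> 0).
    channel_names:
        One name per channel, e.g. ``["organelle", "acer"]``.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:  # single channel convenience
            self.data = self.data[:, None, :, :]
        if self.data.ndim != 4:
            raise ValueError("data must be (frames, channels, rows, cols)")
        if self.data.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel count")
        if np.any(np.asarray(self.data) < 0):
            raise ValueError("intensities must be nonnegative")

    # -- accessors ---------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name: str) -> np.ndarray:
        """Return the ``(frames, rows, cols)`` view of a named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; have {self.channel_names}"
            ) from None
        return self.data[:, idx]

    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, seconds from the first frame."""
        return np.arange(self.n_frames) * self.frame_interval_s

    # -- IO ----------------------------------------------------------------
    def save(self, path) -> None:
        """Write an interleaved multi-page TIFF with calibration metadata."""
        meta = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "channel_names": self.channel_names,
            "axes": "TCYX",
        }
        tifffile.imwrite(
            path,
            self.data,
            description=json.dumps({_DESC_KEY: meta}),
            photometric="minisblack",
        )


def read_timelapse(
    path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    channel_names: list[str] | None = None,
) -> TimelapseStack:
    """Read a multi-page TIFF into a :class:`TimelapseStack`.

    Calibration is taken from the embedded sidecar metadata when present;
    otherwise it must be supplied through the keyword arguments, and a
    ``ValueError`` is raised when it is missing from both places.
    Arrays of 2 or 3 dimensions are promoted to single-frame/-channel.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    meta = {}
    if _DESC_KEY in desc:
        try:
            meta = json.loads(desc)[_DESC_KEY]
        except (json.JSONDecodeError, KeyError):
            meta = {}
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = (
        frame_interval_s
        if frame_interval_s is not None
        else meta.get("frame_interval_s")
    )
    if px is None:
        raise ValueError(f"{path}: pixel size missing; pass pixel_size_um")
    if dt is None:
        raise ValueError(f"{path}: frame interval missing; pass frame_interval_s")
    names = channel_names if channel_names is not None else meta.get("channel_names")
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[:, None]
    if data.ndim != 4:
        raise ValueError(f"{path}: cannot interpret array of shape {data.shape}")
    if names is not None and len(names) != data.shape[1]:
        raise ValueError(
            f"{path}: {len(names)} channel names for {data.shape[1]} channels"
        )
    return TimelapseStack(
        data=data,
        pixel_size_um=float(px),
        frame_interval_s=float(dt),
        channel_names=list(names) if names else [],
    )
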