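"""Stage 1 of the margination pipeline: channel isolation and thresholding.

ICG emission leaks predominantly into a single channel of a colour sensor,
so "grayscale conversion" here means isolating that channel, not luma
mixing (mixing would dilute the NIR signal with channels that carry none).
Thresholding a per-pixel temporal statistic then discards the image
background and areas of non-dynamic fluorescence, leaving the foreground
pixels whose intensity time-series the later stages cluster and correlate.

All operations are pure: input arrays are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from icgmargin.exceptions import DomainError, EmptyForegroundError, ValidationError
from icgmargin.video_io import BinaryMask, VideoStack

#: Fraction of the dtype range used as the default foreground threshold.
DEFAULT_THRESHOLD_FRACTION = 0.2

ChannelStrategy = Literal["auto", "fixed"]
ThresholdStatistic = Literal["max", "mean", "ptp"]


@dataclass
class PixelTimeSeriesMatrix:
    """Foreground pixel coordinates paired with their intensity traces.

    ``coords`` is an (N, 2) array of (row, col) positions in row-major
    order; ``traces[i]`` is the length-T floating-point intensity
    time-series of ``coords[i]``.
    """

    coords: np.ndarray
    traces: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        self.traces = np.asarray(self.traces)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must be an (N, 2) array")
        if self.traces.ndim != 2 or self.traces.shape[0] != self.coords.shape[0]:
            raise ValidationError("traces must be (N, T) aligned with coords")
        if len(np.unique(self.coords[:, 0].astype(np.int64) * (self.coords[:, 1].max() + 1 if self.coords.size else 1) + self.coords[:, 1])) != self.coords.shape[0]:
            raise ValidationError("duplicate pixel coordinates")
        if not np.issubdtype(self.traces.dtype, np.floating):
            self.traces = self.traces.astype(np.float32)

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) / self.frame_rate

    def to_map(self, frame_shape: tuple[int, int], values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter one value per pixel back onto an H×W map (others = ``fill``)."""
        values = np.asarray(values)
        if values.shape[0] != self.n_pixels:
            raise ValidationError("one value per foreground pixel required")
        out = np.full(frame_shape, fill, dtype=float)
        out[self.coords[:, 0], self.coords[:, 1]] = values
        return out


def isolate_fluorescence_channel(
    stack: VideoStack,
    strategy: ChannelStrategy = "auto",
    channel: int | None = None,
) -> VideoStack:
    """Reduce a colour video to the channel carrying the fluorescence signal.

    ``strategy='auto'`` picks the channel with the largest summed per-pixel
    temporal variance — the dynamic ICG bolus dominates the variance of
    whichever channel the NIR emission leaks into.  ``strategy='fixed'``
    takes ``channel`` verbatim.  Single-channel input is returned as-is.
    """
    if stack.n_channels == 1:
        return stack
    if strategy == "fixed":
        if channel is None or not 0 <= channel < stack.n_channels:
            raise DomainError(f"fixed strategy needs a channel in [0, {stack.n_channels})")
        idx = channel
    elif strategy == "auto":
        # accumulate per-channel temporal variance without materialising floats
        f = stack.frames
        t = f.shape[0]
        mean = f.mean(axis=0, dtype=np.float64)
        sq = np.zeros_like(mean)
        for i in range(t):  # frame-wise to bound memory
            d = f[i].astype(np.float64) - mean
            sq += d * d
        total_var = sq.sum(axis=(0, 1)) / (t - 1)
        idx = int(np.argmax(total_var))
    else:
        raise DomainError(f"unknown channel strategy {strategy!r}")
    return VideoStack(stack.frames[..., idx], stack.frame_rate)


def _temporal_statistic(frames: np.ndarray, statistic: ThresholdStatistic) -> np.ndarray:
    if statistic == "max":
        return frames.max(axis=0)
    if statistic == "mean":
        return frames.mean(axis=0)
    if statistic == "ptp":
        return frames.max(axis=0).astype(np.int64) - frames.min(axis=0)
    raise DomainError(f"unknown threshold statistic {statistic!r}")


def threshold_foreground(
    stack: VideoStack,
    threshold: float | None = None,
    statistic: ThresholdStatistic = "max",
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> BinaryMask:
    """Foreground mask: pixels whose temporal ``statistic`` strictly exceeds a threshold.

    The default statistic is the per-pixel maximum over time, which keeps
    pixels whose wash-in arrives late.  When ``threshold`` is None it is
    ``fraction`` of the dtype range (e.g. 0.2·255 for 8-bit video), making
    the default bit-depth independent.
    """
    if stack.n_channels != 1:
        raise ValidationError("threshold_foreground expects a single-channel stack")
    if threshold is None:
        info = np.iinfo(stack.frames.dtype) if np.issubdtype(stack.frames.dtype, np.integer) else None
        full_range = (info.max - info.min) if info else 1.0
        threshold = fraction * full_range
    stat = _temporal_statistic(stack.frames, statistic)
    grid = (stat > threshold).astype(np.uint8)
    if grid.sum() == 0:
        raise EmptyForegroundError(
            f"threshold {threshold} on statistic {statistic!r} leaves no foreground"
        )
    return BinaryMask(grid, label="foreground")


def extract_timeseries(stack: VideoStack, mask: BinaryMask) -> PixelTimeSeriesMatrix:
    """Gather the intensity trace of every mask-1 pixel, row-major.

    Traces are cast to float32; coordinates enumerate mask pixels in
    row-major (C) order so the matrix can be scattered back losslessly.
    """
    if stack.n_channels != 1:
        raise ValidationError("extract_timeseries expects a single-channel stack")
    if mask.grid.shape != stack.frame_shape:
        raise ValidationError(
            f"mask shape {mask.grid.shape} != frame shape {stack.frame_shape}"
        )
    coords = np.argwhere(mask.grid == 1)  # row-major by construction
    if coords.shape[0] == 0:
        raise EmptyForegroundError("mask selects no pixels")
    traces = stack.frames[:, coords[:, 0], coords[:, 1]].T.astype(np.float32)
    return PixelTimeSeriesMatrix(coords=coords, traces=traces, frame_rate=stack.frame_rate)
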