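"""Readers and writers for fluorescence video, masks, ROIs and time-series.

Supported containers:

* multi-page TIFF (lossless, the preferred interchange format),
* a directory of numbered PNG frames (``f_000.png`` ...),
* AVI/MP4 through :mod:`imageio` when a codec plugin is available in the
  running environment (lossy; raises :class:`FormatError` otherwise).

Masks travel as PNG (0/255 on disk, {0,1} in memory) or as plain-text 0/1
matrices.  Time-series are CSV with ``frame_index,time_s,value`` columns.
Coordinates are 0-based (row, col) with the origin at the top-left;
rectangles are half-open.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from icgmargin.exceptions import FormatError, IntegrityError, ValidationError

#: Working resolution of the flexible-scope captures (rows, cols).
DEFAULT_FRAME_SHAPE = (480, 640)
#: Capture frame rate of the scope camera, frames per second.
DEFAULT_FRAME_RATE = 30.0


@dataclass
class VideoStack:
    """An ordered stack of video frames with a frame rate.

    Parameters
    ----------
    frames
        ``T×H×W`` (single-channel) or ``T×H×W×C`` array of unsigned-integer
        intensities, ``C`` in {1, 3}.  Single-channel stacks are stored as
        ``T×H×W``.
    frame_rate
        Frames per second, > 0.  Frame ``i`` is at time ``i / frame_rate``.
    """

    frames: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim == 4 and f.shape[-1] == 1:
            f = f[..., 0]
        if f.ndim not in (3, 4):
            raise ValidationError(f"frames must be T×H×W[×C], got shape {f.shape}")
        if f.ndim == 4 and f.shape[-1] != 3:
            raise ValidationError(f"channel count must be 1 or 3, got {f.shape[-1]}")
        if f.shape[0] < 2:
            raise ValidationError("a video needs at least 2 frames")
        if f.shape[1] < 8 or f.shape[2] < 8:
            raise ValidationError("frames must be at least 8×8 pixels")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def n_channels(self) -> int:
        return 1 if self.frames.ndim == 3 else self.frames.shape[3]

    @property
    def times(self) -> np.ndarray:
        """Timestamp of each frame in seconds (index / frame_rate)."""
        return np.arange(self.n_frames, dtype=float) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass
class BinaryMask:
    """H×W grid over {0, 1} naming a pixel region."""

    grid: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got shape {g.shape}")
        vals = np.unique(g)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("mask values must be strictly in {0, 1}")
        self.grid = g.astype(np.uint8)

    @property
    def n_pixels(self) -> int:
        return int(self.grid.sum())

    def coords(self) -> np.ndarray:
        """Row-major (row, col) coordinates of the 1-pixels, shape (n, 2)."""
        return np.argwhere(self.grid == 1)


@dataclass
class RoiSpec:
    """A region of interest: an axis-aligned rectangle or a polygon.

    Rectangles are ``(row0, col0, row1, col1)`` half-open; polygons are a
    vertex list of (row, col) pairs.  All coordinates 0-based pixels.
    """

    shape: str  # "rectangle" | "polygon"
    rectangle: tuple[int, int, int, int] | None = None
    polygon: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.shape == "rectangle":
            if self.rectangle is None:
                raise ValidationError("rectangle ROI needs (row0, col0, row1, col1)")
            r0, c0, r1, c1 = self.rectangle
            if r1 <= r0 or c1 <= c0:
                raise ValidationError("rectangle must have non-empty interior")
        elif self.shape == "polygon":
            if len(self.polygon) < 3:
                raise ValidationError("polygon ROI needs at least 3 vertices")
        else:
            raise ValidationError(f"unknown ROI shape {self.shape!r}")

    def to_mask(self, frame_shape: tuple[int, int]) -> BinaryMask:
        """Rasterize onto a frame of the given (H, W)."""
        h, w = frame_shape
        grid = np.zeros((h, w), dtype=np.uint8)
        if self.shape == "rectangle":
            r0, c0, r1, c1 = self.rectangle  # type: ignore[misc]
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                raise ValidationError("rectangle ROI outside frame bounds")
            grid[r0:r1, c0:c1] = 1
        else:
            from skimage.draw import polygon as sk_polygon

            rows = [p[0] for p in self.polygon]
            cols = [p[1] for p in self.polygon]
            if min(rows) < 0 or min(cols) < 0 or max(rows) > h or max(cols) > w:
                raise ValidationError("polygon ROI outside frame bounds")
            rr, cc = sk_polygon(rows, cols, shape=(h, w))
            grid[rr, cc] = 1
        if grid.sum() == 0:
            raise ValidationError("ROI rasterizes to an empty pixel set")
        return BinaryMask(grid, label="roi")

    def to_json(self, path: str | Path) -> None:
        payload: dict = {"shape": self.shape}
        if self.shape == "rectangle":
            payload["rectangle"] = list(self.rectangle)  # type: ignore[arg-type]
        else:
            payload["polygon"] = [list(p) for p in self.polygon]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RoiSpec":
        payload = json.loads(Path(path).read_text())
        if payload.get("shape") == "rectangle":
            return cls(shape="rectangle", rectangle=tuple(payload["rectangle"]))
        return cls(
            shape="polygon",
            polygon=[tuple(p) for p in payload.get("polygon", [])],
        )


# ---------------------------------------------------------------------------
# video


_NUM_SUFFIX = re.compile(r"(\d+)\D*$")


def _numeric_key(p: Path) -> tuple[int, str]:
    m = _NUM_SUFFIX.search(p.stem)
    return (int(m.group(1)) if m else -1, p.name)


def _iter_frame_files(directory: Path) -> Iterator[Path]:
    files = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")),
        key=_numeric_key,
    )
    yield from files


def read_video(
    path: str | Path,
    frame_rate: float | None = None,
) -> VideoStack:
    """Read a video from TIFF stack, PNG frame directory, or AVI/MP4 container.

    ``frame_rate`` overrides container metadata; it is required for formats
    that carry none (TIFF, PNG directories default to 30 fps).
    """
    path = Path(path)
    if path.is_dir():
        frames = []
        for p in _iter_frame_files(path):
            frames.append(np.asarray(Image.open(p)))
        if len(frames) < 2:
            raise FormatError(f"no frame sequence found in directory {path}")
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise IntegrityError(f"inconsistent frame shapes in {path}: {shapes}")
        return VideoStack(np.stack(frames), frame_rate or DEFAULT_FRAME_RATE)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        return VideoStack(np.asarray(arr), frame_rate or DEFAULT_FRAME_RATE)
    if suffix in (".avi", ".mp4", ".mov", ".mkv"):
        try:
            import imageio.v3 as iio

            frames = np.asarray(iio.imread(path, plugin="pyav"))
            meta = iio.immeta(path, plugin="pyav")
            fps = frame_rate or float(meta.get("fps", DEFAULT_FRAME_RATE))
        except Exception as exc:  # no codec plugin in this environment
            raise FormatError(
                f"cannot decode {path}: no video codec plugin available ({exc})"
            ) from exc
        return VideoStack(frames, fps)
    raise FormatError(f"unsupported video format: {path}")


def write_video(stack: VideoStack, path: str | Path, fmt: str | None = None) -> None:
    """Write a video as multi-page TIFF, PNG frame directory, or container.

    ``fmt`` defaults from the path suffix ('tiff', 'png_dir', 'mp4'/'avi').
    TIFF and PNG directories round-trip losslessly.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        if suffix in (".tif", ".tiff"):
            fmt = "tiff"
        elif suffix in (".mp4", ".avi"):
            fmt = suffix[1:]
        else:
            fmt = "png_dir"
    if fmt == "tiff":
        tifffile.imwrite(path, stack.frames)
    elif fmt == "png_dir":
        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(stack.n_frames - 1)))
        for i in range(stack.n_frames):
            Image.fromarray(stack.frames[i]).save(path / f"f_{i:0{width}d}.png")
    elif fmt in ("mp4", "avi"):
        try:
            import imageio.v3 as iio

            iio.imwrite(path, stack.frames, plugin="pyav", fps=int(round(stack.frame_rate)))
        except Exception as exc:
            raise FormatError(
                f"cannot encode {path}: no video codec plugin available ({exc})"
            ) from exc
    else:
        raise FormatError(f"unsupported output format {fmt!r}")


# ---------------------------------------------------------------------------
# masks


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as PNG (0/255) or plain-text 0/1 matrix (.txt)."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        Image.fromarray((mask.grid * 255).astype(np.uint8)).save(path)
    elif path.suffix.lower() in (".txt", ".dat"):
        np.savetxt(path, mask.grid, fmt="%d")
    else:
        raise FormatError(f"unsupported mask format: {path}")


def read_mask(path: str | Path, label: str = "") -> BinaryMask:
    """Read a mask from PNG (nonzero -> 1) or plain-text 0/1 matrix."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() == ".png":
        arr = np.asarray(Image.open(path).convert("L"))
        bad = np.setdiff1d(np.unique(arr), (0, 255))
        if bad.size:
            raise ValidationError(f"mask PNG has values other than 0/255: {bad[:5]}")
        grid = (arr == 255).astype(np.uint8)
    elif path.suffix.lower() in (".txt", ".dat"):
        grid = np.loadtxt(path, dtype=int)
        if grid.ndim == 1:
            grid = grid[None, :]
    else:
        raise FormatError(f"unsupported mask format: {path}")
    return BinaryMask(grid, label=label or path.stem)


# ---------------------------------------------------------------------------
# time-series tables


def write_timeseries(
    path: str | Path,
    values: Sequence[float] | np.ndarray,
    frame_rate: float,
    column: str = "value",
) -> None:
    """Write a per-frame trace as CSV with frame_index, time_s, value columns."""
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        {
            "frame_index": np.arange(values.size),
            "time_s": np.arange(values.size) / frame_rate,
            column: values,
        }
    )
    df.to_csv(path, index=False)


def read_timeseries(path: str | Path, column: str = "value") -> tuple[np.ndarray, np.ndarray]:
    """Read (times, values) from a CSV written by :func:`write_timeseries`."""
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(), df[column].to_numpy()
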