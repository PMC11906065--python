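"""Synthetic dual-chamber perfusion phantom video generator.

Emulates a bench flow model in which a pump circulates an ICG bolus through
two transparent flow chambers whose inlet/outlet orifice sizes (0.8 mm vs
1.2 mm in the bench rig) set different flow rates, producing distinct
wash-in/wash-out fluorescence profiles.  Each chamber's intensity follows a
rise-times-decay bolus curve

    I(t) = A · (1 − exp(−k_in·τ)) · exp(−k_out·τ),   τ = t − t_arrival

(zero before arrival): the rapid uptrend models first arrival of the bolus
and the exponential tail its clearance.  The curve peaks at
τ* = ln((k_in + k_out)/k_out) / k_in and decays to zero.

The rendered video injects the fluorescence signal predominantly into one
colour channel (mimicking NIR leakage into a single-colour-sensor channel),
adds seeded Gaussian read noise and optional Poisson shot noise, and is
returned together with ground-truth chamber masks and noiseless curves —
the ground truth the physical bench model lacks.

Each chamber renders a bright core plus a dimmer rim band along the chamber
wall: the optical path through a fluid channel is shorter near the wall, so
wall-adjacent pixels carry a scaled-down copy of the same kinetic curve.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from icgmargin.exceptions import DomainError, ValidationError
from icgmargin.video_io import BinaryMask, VideoStack

#: Frames rendered per noise-drawing chunk; fixed so that a given seed
#: yields bit-identical output regardless of available memory.
_CHUNK = 64


@dataclass(frozen=True)
class ChamberKinetics:
    """Bolus kinetics of one chamber.

    Parameters
    ----------
    t_arrival
        First arrival of the bolus at the chamber, seconds.
    k_in
        Wash-in rate, 1/s.  Larger = faster filling (wider inlet).
    k_out
        Wash-out decay rate, 1/s; must be < k_in (filling is faster than
        clearance in the bench rig).
    amplitude
        Peak intensity gain as a fraction of the dynamic range, in (0, 1].
    """

    t_arrival: float
    k_in: float
    k_out: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.t_arrival < 0:
            raise DomainError("t_arrival must be >= 0")
        if self.k_in <= 0 or self.k_out <= 0:
            raise DomainError("k_in and k_out must be positive")
        if self.k_out >= self.k_in:
            raise DomainError("require k_out < k_in")
        if not 0 < self.amplitude <= 1:
            raise DomainError("amplitude must be in (0, 1]")

    @property
    def peak_time(self) -> float:
        """Time of the curve maximum: t_arrival + ln((k_in+k_out)/k_out)/k_in."""
        return self.t_arrival + math.log((self.k_in + self.k_out) / self.k_out) / self.k_in


@dataclass(frozen=True)
class ChamberGeometry:
    """Chamber footprint in pixel coordinates: rectangle or ellipse.

    Rectangle: (row0, col0, row1, col1), half-open.  Ellipse: (center_row,
    center_col, semi_axis_rows, semi_axis_cols).
    """

    kind: str  # "rectangle" | "ellipse"
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("rectangle", "ellipse"):
            raise ValidationError(f"unknown geometry kind {self.kind!r}")
        if len(self.params) != 4:
            raise ValidationError("geometry needs exactly 4 parameters")

    def mask(self, frame_shape: tuple[int, int], shrink: float = 0.0) -> np.ndarray:
        """Boolean footprint; ``shrink`` erodes the boundary by that many pixels."""
        h, w = frame_shape
        if self.kind == "rectangle":
            r0, c0, r1, c1 = self.params
            r0, c0, r1, c1 = r0 + shrink, c0 + shrink, r1 - shrink, c1 - shrink
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValidationError(f"rectangle {self.params} outside {frame_shape}")
            out = np.zeros((h, w), dtype=bool)
            out[int(math.ceil(r0)) : int(math.ceil(r1)), int(math.ceil(c0)) : int(math.ceil(c1))] = True
            return out
        cr, cc, ar, ac = self.params
        ar, ac = ar - shrink, ac - shrink
        if ar <= 0 or ac <= 0:
            return np.zeros((h, w), dtype=bool)
        rr = (np.arange(h) - cr)[:, None] / ar
        cc_ = (np.arange(w) - cc)[None, :] / ac
        return rr * rr + cc_ * cc_ <= 1.0


@dataclass
class PhantomConfig:
    """Complete description of a synthetic phantom video.

    ``rim_width``/``rim_gain`` control the dim wall band of each chamber
    (rim pixels carry ``rim_gain`` times the core amplitude); ``noise_sd``
    is Gaussian read noise in 8-bit intensity units; ``poisson_gain`` > 0
    enables shot noise with that many photo-electrons per intensity unit.
    """

    chambers: list[tuple[ChamberGeometry, ChamberKinetics]]
    frame_shape: tuple[int, int] = (480, 640)
    frame_rate: float = 30.0
    duration: float = 20.0
    background_level: float = 10.0
    noise_sd: float = 2.0
    poisson_gain: float = 0.0
    channel_gains: tuple[float, ...] = (1.0, 0.3, 0.1)
    rim_width: float = 12.0
    rim_gain: float = 0.35
    seed: int = 0
    dtype: str = "uint8"

    def __post_init__(self) -> None:
        if not self.chambers:
            raise ValidationError("at least one chamber required")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValidationError("duration and frame_rate must be positive")
        for _, kin in self.chambers:
            if kin.t_arrival >= self.duration:
                raise ValidationError("chamber arrival time beyond video duration")
        masks = [geo.mask(self.frame_shape) for geo, _ in self.chambers]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if np.any(masks[i] & masks[j]):
                    raise ValidationError(f"chambers {i} and {j} overlap")
        if self.dtype not in ("uint8", "uint16"):
            raise ValidationError("dtype must be uint8 or uint16")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) / self.frame_rate

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["chambers"] = [
            {"geometry": asdict(g), "kinetics": asdict(k)} for g, k in self.chambers
        ]
        Path(path).write_text(json.dumps(payload, indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomConfig":
        payload = json.loads(Path(path).read_text())
        chambers = [
            (
                ChamberGeometry(
                    kind=c["geometry"]["kind"], params=tuple(c["geometry"]["params"])
                ),
                ChamberKinetics(**c["kinetics"]),
            )
            for c in payload.pop("chambers")
        ]
        payload["frame_shape"] = tuple(payload["frame_shape"])
        payload["channel_gains"] = tuple(payload["channel_gains"])
        return cls(chambers=chambers, **payload)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a rendered phantom video.

    ``chamber_masks`` are the full chamber footprints (core + rim);
    ``clean_curves[i]`` is the noiseless dominant-channel intensity trace
    of a core pixel of chamber ``i``, quantized exactly as the render is.
    """

    chamber_masks: list[BinaryMask]
    clean_curves: np.ndarray  # (n_chambers, T)
    config: PhantomConfig


def kinetic_curve(kin: ChamberKinetics, times: np.ndarray) -> np.ndarray:
    """Bolus curve A·(1−e^{−k_in·τ})·e^{−k_out·τ}, zero before arrival.

    ``times`` must be non-decreasing and start at >= 0.  The curve is
    continuous at onset, has a single interior maximum at
    :attr:`ChamberKinetics.peak_time`, and tends to zero.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (times[0] < 0 or np.any(np.diff(times) < 0)):
        raise DomainError("times must be non-decreasing and start at >= 0")
    tau = times - kin.t_arrival
    out = np.zeros_like(times)
    on = tau >= 0
    out[on] = kin.amplitude * (1.0 - np.exp(-kin.k_in * tau[on])) * np.exp(-kin.k_out * tau[on])
    return out


def generate_phantom(config: PhantomConfig) -> tuple[VideoStack, PhantomTruth]:
    """Render a phantom video and its ground truth.

    Chamber pixels carry background + channel_gains · (weight · kinetic
    curve), with weight 1 in the core and ``rim_gain`` in the wall rim;
    background pixels carry ``background_level``.  Seeded noise is applied
    per pixel, frame and channel; intensities are clipped to the dtype
    range and rounded.  Bit-identical for identical configs.
    """
    h, w = config.frame_shape
    t_total = config.n_frames
    dtype = np.dtype(config.dtype)
    dmax = float(np.iinfo(dtype).max)
    gains = np.asarray(config.channel_gains, dtype=np.float32)
    n_ch = gains.size
    dom = int(np.argmax(gains))

    # per-chamber weight maps (core 1, rim rim_gain) and truth masks
    weights = []
    masks = []
    for geo, _ in config.chambers:
        full = geo.mask(config.frame_shape)
        core = geo.mask(config.frame_shape, shrink=config.rim_width)
        wmap = np.zeros((h, w), dtype=np.float32)
        wmap[full] = config.rim_gain
        wmap[core] = 1.0
        weights.append(wmap)
        masks.append(BinaryMask(full.astype(np.uint8), label=f"chamber{len(masks) + 1}"))

    times = config.times
    curves = np.stack(
        [kinetic_curve(kin, times) for _, kin in config.chambers]
    ).astype(np.float32)  # (n_chambers, T), fraction of dynamic range

    rng = np.random.default_rng(config.seed)
    frames = np.empty((t_total, h, w, n_ch), dtype=dtype)
    wstack = np.stack(weights)  # (n_chambers, H, W)
    bg = np.float32(config.background_level)
    for start in range(0, t_total, _CHUNK):
        stop = min(start + _CHUNK, t_total)
        # (chunk, H, W) fraction-of-range fluorescence signal
        sig = np.einsum("ct,chw->thw", curves[:, start:stop], wstack)
        block = sig[..., None] * gains[None, None, None, :]
        block *= np.float32(dmax)
        block += bg
        if config.poisson_gain > 0:
            block = (
                rng.poisson(np.maximum(block, 0, dtype=np.float64) * config.poisson_gain)
                / config.poisson_gain
            ).astype(np.float32)
        if config.noise_sd > 0:
            noise = rng.standard_normal(block.shape, dtype=np.float32)
            noise *= np.float32(config.noise_sd)
            block += noise
        np.rint(block, out=block)
        np.clip(block, 0, dmax, out=block)
        frames[start:stop] = block.astype(dtype)

    # mirror the render's float32 arithmetic order so a noise-free render
    # of a core pixel equals the clean curve bit-exactly
    clean32 = curves * gains[dom]
    clean32 *= np.float32(dmax)
    clean32 += bg
    clean = np.clip(np.rint(clean32), 0, dmax).astype(np.float64)
    truth = PhantomTruth(chamber_masks=masks, clean_curves=clean, config=config)
    return VideoStack(frames, config.frame_rate), truth


def default_bench_phantom(seed: int = 0) -> PhantomConfig:
    """Canonical two-chamber scene: fast-flow top and slow-flow bottom chamber.

    Two 120×480-pixel rectangular chambers in a 480×640 frame, 20 s at
    30 fps.  The top chamber (wide inlet analogue) fills and clears fast
    (k_in 1.5/s, k_out 0.15/s, bolus arrival 1.5 s); the bottom chamber
    (narrow inlet analogue) is slow (k_in 0.5/s, k_out 0.05/s, arrival
    2.5 s).  These rate constants are package defaults chosen to give
    clearly distinct wash-in/wash-out profiles; they are not bench
    measurements.
    """
    top = (
        ChamberGeometry(kind="rectangle", params=(80, 80, 200, 560)),
        ChamberKinetics(t_arrival=1.5, k_in=1.5, k_out=0.15, amplitude=0.75),
    )
    bottom = (
        ChamberGeometry(kind="rectangle", params=(280, 80, 400, 560)),
        ChamberKinetics(t_arrival=2.5, k_in=0.5, k_out=0.05, amplitude=0.75),
    )
    return PhantomConfig(chambers=[top, bottom], seed=seed)
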