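"""Optical bench characterization formulas.

Pure-math calculators for the figures of merit used to characterize a
fibre-bundle NIR fluorescence imaging probe:

* angular field of illumination (AFOI) from spot diameter and working
  distance, and its inverse (minimum working distance for a target size);
* Michelson contrast / contrast transfer function (CTF) of bar-target
  line pairs, a linear CTF-vs-frequency fit, and the Rayleigh-criterion
  conversion of a line-pair frequency to a minimum resolvable object size;
* fluorescence signal-to-noise ratio against a fluorophore-free control;
* optical power attenuation in decibels.

Angles cross the API in degrees (bench reports use degrees); trigonometry
is done in radians internally.  All functions return full precision —
rounding for display is left to callers and the CLI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from icgmargin.exceptions import DomainError, UndefinedContrastError

#: Rayleigh criterion: the Michelson contrast at which two bar-target lines
#: are considered just resolvable.
RAYLEIGH_CONTRAST = 0.264


@dataclass(frozen=True)
class IlluminationGeometry:
    """Illumination cone: spot diameter (mm) at a working distance (mm).

    ``afoi`` is the full cone angle in degrees, 2·atan(SD / (2·WD)).
    """

    spot_diameter: float
    working_distance: float
    afoi: float

    def __post_init__(self) -> None:
        if self.spot_diameter <= 0 or self.working_distance <= 0:
            raise DomainError("spot_diameter and working_distance must be positive")
        if not 0 < self.afoi < 180:
            raise DomainError("afoi must lie in (0, 180) degrees")


@dataclass(frozen=True)
class ContrastMeasurement:
    """One bar-target reading: extreme grayscale values at a spatial frequency."""

    i_max: float
    i_min: float
    spatial_frequency: float
    ctf: float

    def __post_init__(self) -> None:
        if self.i_min < 0 or self.i_max < self.i_min:
            raise DomainError("require i_max >= i_min >= 0")
        if self.spatial_frequency <= 0:
            raise DomainError("spatial_frequency must be positive")


@dataclass(frozen=True)
class SensitivityMeasurement:
    """Fluorescence ROI statistics against a fluorophore-free control ROI."""

    signal_mean: float
    control_mean: float
    control_sd: float
    snr: float

    def __post_init__(self) -> None:
        if self.control_sd <= 0:
            raise DomainError("control_sd must be positive")


@dataclass(frozen=True)
class PowerMeasurement:
    """Optical power before/after an attenuating path, with the dB loss."""

    power_in: float
    power_out: float
    attenuation_db: float

    def __post_init__(self) -> None:
        if self.power_in <= 0 or self.power_out <= 0:
            raise DomainError("powers must be positive")


def compute_afoi(spot_diameter: float, working_distance: float) -> float:
    """Full angular field of illumination, in degrees.

    AFOI = 2·atan(SD / (2·WD)) for a spot of diameter ``spot_diameter`` mm
    measured ``working_distance`` mm from the probe tip.
    """
    if spot_diameter <= 0:
        raise DomainError(f"spot_diameter must be > 0, got {spot_diameter}")
    if working_distance <= 0:
        raise DomainError(f"working_distance must be > 0, got {working_distance}")
    return math.degrees(2.0 * math.atan(spot_diameter / (2.0 * working_distance)))


def min_working_distance(target_diameter: float, afoi: float) -> float:
    """Minimum probe-tip distance (mm) that illuminates a whole target.

    Inverts :func:`compute_afoi`: WD = D / (2·tan(AFOI/2)) for a target of
    diameter ``target_diameter`` mm under a cone of ``afoi`` degrees.
    """
    if target_diameter <= 0:
        raise DomainError(f"target_diameter must be > 0, got {target_diameter}")
    if not 0 < afoi < 180:
        raise DomainError(f"afoi must lie in (0, 180) degrees, got {afoi}")
    return target_diameter / (2.0 * math.tan(math.radians(afoi) / 2.0))


def michelson_ctf(i_max: float, i_min: float) -> float:
    """Michelson contrast (I_max − I_min) / (I_max + I_min), in [0, 1]."""
    if i_min < 0 or i_max < i_min:
        raise DomainError(f"require i_max >= i_min >= 0, got ({i_max}, {i_min})")
    if i_max + i_min == 0:
        raise UndefinedContrastError("contrast undefined when i_max + i_min == 0")
    return (i_max - i_min) / (i_max + i_min)


def min_resolvable_object(spatial_frequency: float) -> float:
    """Minimum object size (µm) at a line-pair frequency (lp/mm).

    Half the line-pair period: 1000 / (2·f) µm.
    """
    if spatial_frequency <= 0:
        raise DomainError(f"spatial_frequency must be > 0, got {spatial_frequency}")
    return 1000.0 / (2.0 * spatial_frequency)


def fluorescence_snr(signal_mean: float, control_mean: float, control_sd: float) -> float:
    """SNR = (S − C) / σ_C for a fluorescence ROI vs a control ROI."""
    if control_sd <= 0:
        raise DomainError(f"control_sd must be > 0, got {control_sd}")
    return (signal_mean - control_mean) / control_sd


def attenuation_db(power_in: float, power_out: float) -> float:
    """Power attenuation 10·log10(P_in / P_out) in decibels.

    Zero when the powers are equal; additive over cascaded stages.
    """
    if power_in <= 0 or power_out <= 0:
        raise DomainError(f"powers must be > 0, got ({power_in}, {power_out})")
    return 10.0 * math.log10(power_in / power_out)


def ctf_linear_fit(
    spatial_frequencies: "np.ndarray | list[float]",
    ctf_values: "np.ndarray | list[float]",
) -> tuple[float, float, float]:
    """Least-squares line CTF ≈ slope·f + intercept; returns (slope, intercept, r²).

    Bar-target CTF falls roughly linearly with spatial frequency over the
    range where the bundle resolves the pattern; the fitted line is what
    the Rayleigh criterion is applied to.
    """
    f = np.asarray(spatial_frequencies, dtype=float)
    c = np.asarray(ctf_values, dtype=float)
    if f.ndim != 1 or f.shape != c.shape or f.size < 2:
        raise DomainError("need two equal-length 1-D arrays with >= 2 points")
    slope, intercept = np.polyfit(f, c, 1)
    resid = c - (slope * f + intercept)
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def resolution_limit_from_fit(
    spatial_frequencies: "np.ndarray | list[float]",
    ctf_values: "np.ndarray | list[float]",
    contrast_threshold: float = RAYLEIGH_CONTRAST,
) -> tuple[float, float, float]:
    """Rayleigh-limit frequency and object size from a linear CTF fit.

    Fits CTF vs frequency, solves for the frequency where the fitted CTF
    equals ``contrast_threshold`` (default 0.264), and converts it with
    :func:`min_resolvable_object`.  Returns (limit frequency lp/mm,
    minimum object size µm, fit r²).
    """
    slope, intercept, r2 = ctf_linear_fit(spatial_frequencies, ctf_values)
    if slope >= 0:
        raise DomainError("CTF fit is non-decreasing in frequency; no resolution limit")
    f_limit = (contrast_threshold - intercept) / slope
    if f_limit <= 0:
        raise DomainError("fitted contrast never reaches the threshold at f > 0")
    return float(f_limit), min_resolvable_object(f_limit), r2
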