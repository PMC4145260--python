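"""Quantitative image metrics: SNR, CNR efficiency, retention, percent change.

SNR uses the phased-array noise correction SNR = 0.695 * S / sigma, where
sigma is the standard deviation of an artifact-free background region and the
multiplier is the four-channel-coil value; the factor is configurable for
other coil counts.  CNR efficiency normalizes the SNR difference of two
regions by the square root of the scan time per slice (minutes) and by the
slice thickness (mm), enabling fair comparison across protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

#: Phased-array noise correction multiplier for a four-channel coil.
FOUR_CHANNEL_CORRECTION = 0.695


@dataclass(frozen=True)
class ROIStats:
    mean_signal: float
    noise_sd: float
    n_pixels: int = 1

    def __post_init__(self):
        if self.noise_sd <= 0.0:
            raise ValueError("noise_sd must be > 0")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


@dataclass(frozen=True)
class MetricResult:
    snr: float
    cnr_eff: float
    context: dict


class CnrDenominator(str, Enum):
    """Which normalization the CNR-efficiency denominator uses."""

    SQRT_TIME_TIMES_THICKNESS = "sqrt_time_times_thickness"  # sqrt(T_sl) * SL_th
    SQRT_OF_PRODUCT = "sqrt_of_product"  # sqrt(T_sl * SL_th)
    PRODUCT = "product"  # T_sl * SL_th


def snr(roi: ROIStats, correction: float = FOUR_CHANNEL_CORRECTION) -> float:
    """SNR = correction * mean / noise SD (0.695 for a four-channel coil)."""
    return correction * roi.mean_signal / roi.noise_sd


def cnr_eff(
    snr_a: float,
    snr_lumen: float,
    scan_time_per_slice: float,
    slice_thickness: float,
    denominator: CnrDenominator | str = CnrDenominator.SQRT_TIME_TIMES_THICKNESS,
) -> float:
    """CNR efficiency: (SNR_a - SNR_lumen) / (sqrt(T_sl) * SL_th) by default.

    ``scan_time_per_slice`` is in minutes, ``slice_thickness`` in mm.  The
    default denominator follows the convention that efficiency scales with the
    square root of scan time; the alternatives are available for comparison.
    """
    if scan_time_per_slice <= 0.0 or slice_thickness <= 0.0:
        raise ValueError("scan time and slice thickness must be > 0")
    denominator = CnrDenominator(denominator)
    if denominator is CnrDenominator.SQRT_TIME_TIMES_THICKNESS:
        denom = math.sqrt(scan_time_per_slice) * slice_thickness
    elif denominator is CnrDenominator.SQRT_OF_PRODUCT:
        denom = math.sqrt(scan_time_per_slice * slice_thickness)
    else:
        denom = scan_time_per_slice * slice_thickness
    return (snr_a - snr_lumen) / denom


def theoretical_retention(t_imsde: float, t2: float) -> float:
    """Idealized tissue signal retention through the preparation: e^(-T/T2)."""
    if t_imsde < 0.0:
        raise ValueError("t_imsde must be >= 0")
    if t2 <= 0.0:
        raise ValueError("t2 must be > 0")
    return math.exp(-t_imsde / t2)


def percent_change(value: float, reference: float, decrease: bool = True) -> float:
    """Percent decrease (default) of ``value`` relative to ``reference``.

    With ``decrease=False`` returns the signed percent change
    100 * (value - reference) / reference.
    """
    if reference == 0.0:
        raise ValueError("reference must be non-zero")
    if decrease:
        return 100.0 * (reference - value) / reference
    return 100.0 * (value - reference) / reference
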