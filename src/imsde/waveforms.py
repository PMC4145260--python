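"""Gradient lobe synthesis, moment calculus and m1-targeted design.

Two lobe shapes are supported: a trapezoid (linear ramps plus flat top) and a
half-sine.  Refocusing pulses invert the sign of subsequently accrued phase;
moments are therefore computed on the *effective* waveform s(t)*G(t), where the
sign profile s(t) flips at each refocusing pulse.

The designer solves a four-lobe iMSDE arrangement to a requested first moment
by one-dimensional root finding over the lobe duration with the amplitude
pinned at its maximum (falling back to an amplitude solve when the duration
bound is hit), mirroring how clinical protocols hold the gradient strength
fixed and stretch the lobes for higher flow sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from imsde.errors import GeometryError, HardwareLimitError, InfeasibleDesignError


class LobeShape(str, Enum):
    TRAPEZOID = "trapezoid"
    SINUSOID = "sinusoid"


class Axis(str, Enum):
    X = "x"
    Y = "y"
    Z = "z"


@dataclass(frozen=True)
class GradientLobe:
    """One parametric gradient lobe.

    ``amplitude`` is signed (mT/m).  For a trapezoid, ``ramp_time`` and
    ``flat_time`` are the ramp and flat-top durations (ms); for a half-sine,
    ``ramp_time`` is 0 and ``flat_time`` holds the total half-sine duration.
    """

    shape: LobeShape
    amplitude: float
    ramp_time: float
    flat_time: float
    start_time: float
    axis: Axis = Axis.Z

    @property
    def duration(self) -> float:
        if self.shape is LobeShape.TRAPEZOID:
            return 2.0 * self.ramp_time + self.flat_time
        return self.flat_time

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def center(self) -> float:
        return self.start_time + 0.5 * self.duration

    @property
    def area(self) -> float:
        """Signed zeroth moment of the lobe alone (mT*ms/m)."""
        if self.shape is LobeShape.TRAPEZOID:
            return self.amplitude * (self.flat_time + self.ramp_time)
        return 2.0 * self.amplitude * self.flat_time / math.pi

    @property
    def peak_slew(self) -> float:
        """Peak |dG/dt| in mT/m/ms (inf for an unramped rectangle)."""
        if self.amplitude == 0.0:
            return 0.0
        if self.shape is LobeShape.TRAPEZOID:
            if self.ramp_time == 0.0:
                return math.inf
            return abs(self.amplitude) / self.ramp_time
        return abs(self.amplitude) * math.pi / self.flat_time

    def evaluate(self, t) -> np.ndarray:
        """Sampled amplitude at times ``t`` (ms); exactly 0 outside the lobe."""
        t = np.asarray(t, dtype=float)
        u = t - self.start_time
        d = self.duration
        if d <= 0.0 or self.amplitude == 0.0:
            return np.zeros_like(u)
        if self.shape is LobeShape.SINUSOID:
            out = self.amplitude * np.sin(np.pi * np.clip(u / d, 0.0, 1.0))
        else:
            r, f = self.ramp_time, self.flat_time
            if r > 0.0:
                env = np.minimum(u / r, (d - u) / r)
            else:
                env = np.ones_like(u)
            out = self.amplitude * np.clip(env, 0.0, 1.0)
        return np.where((u >= 0.0) & (u <= d), out, 0.0)


@dataclass(frozen=True)
class SignProfile:
    """Phase-sign inversion history caused by refocusing pulses.

    The effective sign at time t equals ``initial_sign * (-1)**n`` where n is
    the number of flips at or before t.
    """

    flip_times: tuple = ()
    initial_sign: int = 1

    def __post_init__(self):
        ft = tuple(float(t) for t in self.flip_times)
        if any(b <= a for a, b in zip(ft, ft[1:])):
            raise ValueError("flip_times must be strictly increasing")
        object.__setattr__(self, "flip_times", ft)

    def sign_at(self, t: float) -> int:
        n = sum(1 for f in self.flip_times if f <= t)
        return self.initial_sign * (-1) ** n

    def breakpoints_within(self, t0: float, t1: float) -> list:
        return [f for f in self.flip_times if t0 < f < t1]


@dataclass(frozen=True)
class MomentReport:
    """Zeroth (mT*ms/m) and first (mT*ms^2/m) moments about ``reference_time``."""

    m0: float
    m1: float
    reference_time: float = 0.0


def make_lobe(
    shape: LobeShape | str,
    amplitude: float,
    ramp_time: float,
    flat_time: float,
    start_time: float = 0.0,
    axis: Axis | str = Axis.Z,
    max_amplitude: float | None = None,
) -> GradientLobe:
    """Construct and validate a gradient lobe.

    Raises :class:`HardwareLimitError` if ``|amplitude|`` exceeds
    ``max_amplitude`` and ``ValueError`` for negative durations.
    """
    shape = LobeShape(shape)
    axis = Axis(axis)
    if ramp_time < 0.0 or flat_time < 0.0:
        raise ValueError("lobe durations must be >= 0")
    if shape is LobeShape.SINUSOID and ramp_time != 0.0:
        raise ValueError("a half-sine lobe has no ramps; pass ramp_time=0")
    if max_amplitude is not None and abs(amplitude) > max_amplitude + 1e-12:
        raise HardwareLimitError(
            f"|amplitude| {abs(amplitude):g} mT/m exceeds limit {max_amplitude:g} mT/m"
        )
    lobe = GradientLobe(shape, float(amplitude), float(ramp_time), float(flat_time),
                        float(start_time), axis)
    if amplitude != 0.0 and lobe.duration <= 0.0:
        raise ValueError("a lobe with non-zero amplitude needs a positive duration")
    return lobe


def _check_no_overlap(lobes: Sequence[GradientLobe]) -> None:
    by_axis: dict = {}
    for lobe in lobes:
        by_axis.setdefault(lobe.axis, []).append(lobe)
    for axis, group in by_axis.items():
        group = sorted(group, key=lambda l: l.start_time)
        for a, b in zip(group, group[1:]):
            if b.start_time < a.end_time - 1e-12:
                raise GeometryError(f"lobes overlap on axis {axis.value}")


def _lobe_moments_analytic(lobe: GradientLobe, reference_time: float) -> tuple:
    # both supported shapes are symmetric about their center
    a = lobe.area
    return a, a * (lobe.center - reference_time)


def _lobe_moments_quad(lobe: GradientLobe, reference_time: float,
                       t0: float | None = None, t1: float | None = None) -> tuple:
    lo = lobe.start_time if t0 is None else max(t0, lobe.start_time)
    hi = lobe.end_time if t1 is None else min(t1, lobe.end_time)
    if hi <= lo:
        return 0.0, 0.0
    pts = [lobe.start_time + lobe.ramp_time, lobe.end_time - lobe.ramp_time]
    pts = [p for p in pts if lo < p < hi]
    m0, _ = quad(lobe.evaluate, lo, hi, points=pts, limit=200)
    m1, _ = quad(lambda t: lobe.evaluate(t) * (t - reference_time), lo, hi,
                 points=pts, limit=200)
    return m0, m1


def moments(
    lobes: Iterable[GradientLobe],
    signs: SignProfile | None = None,
    reference_time: float = 0.0,
    method: str = "analytic",
) -> MomentReport:
    """Effective moments m0 = int s(t)G(t) dt and m1 = int s(t)G(t)(t-ref) dt.

    ``method='analytic'`` uses the closed forms for the (symmetric) supported
    shapes; ``method='quad'`` integrates numerically with adaptive quadrature.
    Both agree to <= 1e-6 relative for rectangles, trapezoids and half-sines.
    """
    lobes = list(lobes)
    signs = signs or SignProfile()
    _check_no_overlap(lobes)
    m0 = 0.0
    m1 = 0.0
    for lobe in lobes:
        inner = signs.breakpoints_within(lobe.start_time, lobe.end_time)
        if method == "analytic" and not inner:
            l0, l1 = _lobe_moments_analytic(lobe, reference_time)
            s = signs.sign_at(lobe.center)
            m0 += s * l0
            m1 += s * l1
        else:
            edges = [lobe.start_time, *inner, lobe.end_time]
            for a, b in zip(edges, edges[1:]):
                l0, l1 = _lobe_moments_quad(lobe, reference_time, a, b)
                s = signs.sign_at(0.5 * (a + b))
                m0 += s * l0
                m1 += s * l1
    return MomentReport(m0=m0, m1=m1, reference_time=reference_time)


@dataclass(frozen=True)
class FourLobeLayout:
    """Placement of four identical-magnitude lobes around two refocusing pulses.

    Time origin (t = 0) is the center of the tip-down 90° pulse; each RF
    rotation acts at the end of its pulse duration, so the tip-down rotation
    occurs at ``tip_down_duration / 2`` and the preparation time runs from
    there to the end of the tip-up pulse.  ``polarities`` are the physical
    lobe signs; with the sign inversions of the two refocusing pulses the
    default (+, -, +, -) yields a balanced (m0 = 0) waveform with a large
    velocity sensitivity.
    """

    tip_down_duration: float = 0.4
    refocus_duration: float = 0.8
    tip_up_duration: float = 0.4
    gap: float = 0.1
    polarities: tuple = (1, -1, 1, -1)
    axis: Axis = Axis.Z

    def place(self, shape: LobeShape, amplitude: float, ramp_time: float,
              lobe_duration: float) -> "PlacedLayout":
        """Lay the four lobes out sequentially and return the full geometry."""
        if len(self.polarities) != 4:
            raise GeometryError("the four-lobe layout needs exactly 4 polarities")
        g = self.gap
        a, b, c = self.tip_down_duration, self.refocus_duration, self.tip_up_duration
        D = lobe_duration
        rot_90 = a / 2.0                      # tip-down rotation (pulse end)
        l1 = rot_90 + g
        refo1_start = l1 + D + g
        flip1 = refo1_start + b               # first refocusing rotation
        l2 = flip1 + g
        l3 = l2 + D + g
        refo2_start = l3 + D + g
        flip2 = refo2_start + b
        l4 = flip2 + g
        tip_start = l4 + D + g
        rot_tip = tip_start + c               # tip-up rotation (pulse end)
        if shape is LobeShape.SINUSOID:
            ramp, flat = 0.0, D
        else:
            ramp, flat = ramp_time, D - 2.0 * ramp_time
            if flat < -1e-12:
                raise GeometryError("trapezoid duration shorter than its two ramps")
            flat = max(flat, 0.0)
        lobes = tuple(
            GradientLobe(shape, p * amplitude, ramp, flat, start, self.axis)
            for p, start in zip(self.polarities, (l1, l2, l3, l4))
        )
        signs = SignProfile(flip_times=(flip1, flip2))
        return PlacedLayout(
            lobes=lobes,
            signs=signs,
            rotation_times=(rot_90, flip1, flip2, rot_tip),
            rf_start_times=(-a / 2.0, refo1_start, refo2_start, tip_start),
            t_imsde=rot_tip - rot_90,
        )


@dataclass(frozen=True)
class PlacedLayout:
    lobes: tuple
    signs: SignProfile
    rotation_times: tuple
    rf_start_times: tuple
    t_imsde: float


@dataclass(frozen=True)
class DesignResult:
    """Outcome of :func:`design_prep_gradients`."""

    lobes: tuple
    report: MomentReport
    signs: SignProfile
    t_imsde: float
    amplitude: float
    lobe_duration: float
    shape: LobeShape
    layout: FourLobeLayout


def _layout_m1(layout: FourLobeLayout, shape: LobeShape, amplitude: float,
               ramp_time: float, lobe_duration: float) -> float:
    placed = layout.place(shape, amplitude, ramp_time, lobe_duration)
    return abs(moments(placed.lobes, placed.signs, reference_time=0.0).m1)


def design_prep_gradients(
    target_m1: float,
    shape: LobeShape | str = LobeShape.TRAPEZOID,
    max_amplitude: float = 20.0,
    ramp_time: float = 0.5,
    layout: FourLobeLayout | None = None,
    lobe_duration: float | None = None,
    slew_max: float | None = None,
    tol: float = 1e-4,
    duration_bounds: tuple = (0.05, 30.0),
) -> DesignResult:
    """Design the four-lobe set achieving ``|m1| = target_m1``.

    The primary unknown is the lobe duration with the amplitude pinned at
    ``max_amplitude`` (trapezoid ramps fixed at ``ramp_time``).  If the target
    sits below the reach of the shortest admissible lobe, the duration is
    pinned at its lower bound and the amplitude is solved instead.  Passing
    ``lobe_duration`` solves the amplitude at a fixed duration (used for
    duration-matched shape comparisons); with ``slew_max`` set, a half-sine
    whose solved amplitude would exceed the slew limit is lengthened to the
    slew-limited minimum duration instead.

    Raises :class:`InfeasibleDesignError` naming the binding constraint when
    the target is unreachable.
    """
    shape = LobeShape(shape)
    layout = layout or FourLobeLayout()
    if target_m1 < 0.0:
        raise ValueError("target_m1 must be >= 0")
    if max_amplitude <= 0.0:
        raise ValueError("max_amplitude must be > 0")

    d_lo, d_hi = duration_bounds
    if shape is LobeShape.TRAPEZOID:
        d_lo = max(d_lo, 2.0 * ramp_time)

    def finish(amplitude: float, duration: float) -> DesignResult:
        placed = layout.place(shape, amplitude, ramp_time, duration)
        report = moments(placed.lobes, placed.signs, reference_time=0.0)
        return DesignResult(
            lobes=placed.lobes, report=report, signs=placed.signs,
            t_imsde=placed.t_imsde, amplitude=amplitude, lobe_duration=duration,
            shape=shape, layout=layout,
        )

    if target_m1 == 0.0:
        return finish(0.0, d_lo if lobe_duration is None else lobe_duration)

    def m1_of(amplitude: float, duration: float) -> float:
        return _layout_m1(layout, shape, amplitude, ramp_time, duration)

    def solve_amplitude(duration: float) -> float:
        unit = m1_of(1.0, duration)  # m1 is linear in amplitude at fixed geometry
        amp = target_m1 / unit
        if amp > max_amplitude * (1.0 + 1e-9):
            raise InfeasibleDesignError(
                f"amplitude limit: target m1 {target_m1:g} needs {amp:.2f} mT/m "
                f"at lobe duration {duration:g} ms (limit {max_amplitude:g} mT/m)"
            )
        return amp

    if lobe_duration is not None:
        unit = m1_of(1.0, lobe_duration)
        needed = target_m1 / unit
        if (slew_max is not None and shape is LobeShape.SINUSOID
                and needed * math.pi / lobe_duration > slew_max):
            # lengthen to the slew-limited minimum: D = G*pi/slew_max
            def resid(amp_):
                return m1_of(amp_, amp_ * math.pi / slew_max) - target_m1
            amp = brentq(resid, 1e-3, max_amplitude, xtol=1e-12, rtol=1e-12)
            return finish(amp, amp * math.pi / slew_max)
        return finish(solve_amplitude(lobe_duration), lobe_duration)

    f_lo = m1_of(max_amplitude, d_lo) - target_m1
    if f_lo >= 0.0:
        # shortest lobe already overshoots: pin duration, scale amplitude down
        return finish(solve_amplitude(d_lo), d_lo)
    f_hi = m1_of(max_amplitude, d_hi) - target_m1
    if f_hi < 0.0:
        raise InfeasibleDesignError(
            f"lobe duration bound: target m1 {target_m1:g} unreachable with "
            f"duration <= {d_hi:g} ms at amplitude {max_amplitude:g} mT/m"
        )
    dur = brentq(lambda d: m1_of(max_amplitude, d) - target_m1,
                 d_lo, d_hi, xtol=1e-10, rtol=1e-12)
    result = finish(max_amplitude, dur)
    achieved = abs(result.report.m1)
    if abs(achieved - target_m1) > tol * target_m1:
        raise InfeasibleDesignError(
            f"solver tolerance: achieved m1 {achieved:g} vs target {target_m1:g}"
        )
    return result


def design_multi_axis(
    targets: dict,
    shape: LobeShape | str = LobeShape.TRAPEZOID,
    **kwargs,
) -> tuple:
    """Independent per-axis designs with a combined |m1| report.

    ``targets`` maps axis -> target m1.  Flow sensitization along each axis is
    independent; the combined sensitivity is the Euclidean norm of the per-axis
    first moments.
    """
    results = {}
    for axis, target in targets.items():
        axis = Axis(axis)
        layout = kwargs.pop("layout", None) or FourLobeLayout(axis=axis)
        results[axis] = design_prep_gradients(
            target, shape=shape, layout=replace(layout, axis=axis), **kwargs
        )
    combined = math.sqrt(sum(r.report.m1 ** 2 for r in results.values()))
    return results, combined
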