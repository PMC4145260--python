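"""Magnetization propagation through a preparation timeline.

The propagator applies, in time order: instantaneous RF rotations (scaled by
the spin's B1+ factor), exponential T1/T2 relaxation over every inter-event
interval, and the gradient-induced precession phase accumulated by a spin at
constant position/velocity within each interval.  Refocusing-pulse sign
inversion is not imposed by hand - it emerges from the 180° rotations acting
on the transverse components.  A final spoiler destroys transverse
magnetization.

For an ideal static spin this reduces exactly to the black-blood literature's
decay model Mz/M0 = exp(-T_prep / T2): the only surviving pathway is the
transverse magnetization stored between the 90° and -90° pulses, and any T1
recovery during the preparation is returned to the transverse plane by the
tip-up pulse and spoiled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from imsde.constants import (
    off_resonance_phase_rad,
    position_phase_rad,
    velocity_phase_rad,
)
from imsde.errors import GeometryError
from imsde.rf_pulses import rotation_operator
from imsde.waveforms import GradientLobe, SignProfile, moments

if TYPE_CHECKING:  # pragma: no cover
    from imsde.prep_sequences import PrepModule


@dataclass
class SpinState:
    """Magnetization vector plus its tissue / motion / RF context.

    ``M`` is dimensionless with equilibrium M0 = 1 along +z.  ``position`` and
    ``velocity`` are along the gradient axis.
    """

    M: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    T1: float = math.inf  # ms
    T2: float = math.inf  # ms
    position: float = 0.0  # m
    velocity: float = 0.0  # m/s
    b1_scale: float = 1.0
    off_resonance: float = 0.0  # Hz

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float).copy()
        if self.T1 <= 0.0 or self.T2 <= 0.0:
            raise ValueError("T1 and T2 must be > 0")
        if self.T2 > self.T1:
            raise ValueError("T2 must not exceed T1")


def relax(M: np.ndarray, dt: float, T1: float, T2: float, M0: float = 1.0) -> np.ndarray:
    """Free relaxation over ``dt`` ms: Mxy *= e^(-dt/T2); Mz -> M0 + (Mz-M0)e^(-dt/T1)."""
    if dt < 0.0:
        raise ValueError("dt must be >= 0")
    M = np.asarray(M, dtype=float)
    e2 = math.exp(-dt / T2) if math.isfinite(T2) else 1.0
    e1 = math.exp(-dt / T1) if math.isfinite(T1) else 1.0
    return np.array([M[0] * e2, M[1] * e2, M0 + (M[2] - M0) * e1])


def _rot_z(phi: float) -> np.ndarray:
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _window_integrals(lobes: Sequence[GradientLobe], t0: float, t1: float) -> tuple:
    """(I0, I1) = (int G dt, int G t dt) over [t0, t1], analytic when possible."""
    I0 = 0.0
    I1 = 0.0
    for lobe in lobes:
        if lobe.end_time <= t0 or lobe.start_time >= t1:
            continue
        if lobe.start_time >= t0 - 1e-12 and lobe.end_time <= t1 + 1e-12:
            I0 += lobe.area
            I1 += lobe.area * lobe.center
        else:  # partial overlap: fall back to quadrature
            from imsde.waveforms import _lobe_moments_quad

            l0, l1 = _lobe_moments_quad(lobe, 0.0, t0, t1)
            I0 += l0
            I1 += l1
    return I0, I1


def gradient_phase(
    lobes: Iterable[GradientLobe],
    signs: SignProfile | None = None,
    position: float = 0.0,
    velocity: float = 0.0,
) -> float:
    """Net phase (rad) of a spin at constant position/velocity: gamma*(m0 x + m1 v)."""
    report = moments(lobes, signs, reference_time=0.0)
    return position_phase_rad(report.m0, position) + velocity_phase_rad(report.m1, velocity)


def propagate_prep(
    spin: SpinState,
    prep: "PrepModule",
    m_equilibrium: float = 1.0,
    relaxation: bool = True,
    stop_before_tip_up: bool = False,
) -> SpinState:
    """Propagate a spin through a preparation; returns a new SpinState.

    With ``stop_before_tip_up`` the state is returned just before the tip-up
    rotation (used to inspect the accumulated transverse phase).
    """
    events = sorted(prep.rf_events, key=lambda e: e.rotation_time)
    times = [e.rotation_time for e in events]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise GeometryError("RF rotations must be strictly ordered in time")
    M = np.asarray(spin.M, dtype=float).copy()
    t_prev: float | None = None
    for event in events:
        t = event.rotation_time
        if t_prev is not None:
            dt = t - t_prev
            if relaxation:
                M = relax(M, dt, spin.T1, spin.T2, M0=m_equilibrium)
            I0, I1 = _window_integrals(prep.lobes, t_prev, t)
            phi = (
                position_phase_rad(I0, spin.position)
                + velocity_phase_rad(I1, spin.velocity)
                + off_resonance_phase_rad(spin.off_resonance, dt)
            )
            if phi != 0.0:
                M = _rot_z(phi) @ M
        if stop_before_tip_up and event is events[-1]:
            return replace_state(spin, M)
        M = rotation_operator(event.pulse, spin.b1_scale) @ M
        t_prev = t
    # spoiler: perfect transverse nulling
    M[0] = 0.0
    M[1] = 0.0
    return replace_state(spin, M)


def replace_state(spin: SpinState, M: np.ndarray) -> SpinState:
    return SpinState(
        M=M, T1=spin.T1, T2=spin.T2, position=spin.position,
        velocity=spin.velocity, b1_scale=spin.b1_scale,
        off_resonance=spin.off_resonance,
    )


def prep_phase(prep: "PrepModule", position: float = 0.0, velocity: float = 0.0) -> float:
    """Transverse phase accrued through the preparation, via full propagation.

    Propagates an ideal relaxation-free spin to just before the tip-up pulse
    and reads the phase of its transverse magnetization relative to the static
    reference (a static spin ends along the same axis it started on).
    """
    spin = SpinState(position=position, velocity=velocity)
    out = propagate_prep(spin, prep, relaxation=False, stop_before_tip_up=True)
    ref = propagate_prep(SpinState(), prep, relaxation=False, stop_before_tip_up=True)
    m = complex(out.M[0], out.M[1])
    m_ref = complex(ref.M[0], ref.M[1])
    return float(np.angle(m / m_ref))


def voxel_average(signals: Sequence[complex], weights: Sequence[float] | None = None) -> float:
    """Magnitude of the weighted complex sum of an ensemble's signals.

    ``signals`` are post-readout-excitation transverse magnetizations (for a
    spoiled preparation these are the final Mz values, real and signed).
    Weights default to uniform and must sum to 1.
    """
    signals = np.asarray(signals, dtype=complex)
    if signals.size == 0:
        raise ValueError("empty ensemble")
    if weights is None:
        weights = np.full(signals.size, 1.0 / signals.size)
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return float(abs(np.sum(weights * signals)))


def laminar_ensemble(mean_velocity: float, n_radial: int = 201) -> tuple:
    """Velocities and weights for laminar (parabolic) flow in a circular lumen.

    v(r) = 2 v_mean (1 - r^2/R^2) with uniform spin density over the disk;
    weights are annulus areas at midpoint radii.  (The induced velocity
    distribution is uniform on [0, 2 v_mean].)
    """
    if n_radial < 1:
        raise ValueError("n_radial must be >= 1")
    edges = np.linspace(0.0, 1.0, n_radial + 1)
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    weights = edges[1:] ** 2 - edges[:-1] ** 2  # annulus areas, sum to 1
    velocities = 2.0 * mean_velocity * (1.0 - r_mid ** 2)
    return velocities, weights
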