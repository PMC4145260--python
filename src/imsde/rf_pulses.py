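"""Hard and composite RF pulses and the rotation operators they induce.

Pulses are modeled as instantaneous rotations (the hard-pulse approximation);
their durations are kept only for timeline/T2 bookkeeping.  Durations scale
linearly with flip angle at fixed RF amplitude, calibrated so a hard 90° pulse
lasts 0.4 ms.  The rotation convention is right-handed about the in-plane axis
at azimuth = phase: a 90° pulse with phase 0 (x) takes +z to -y.

Four preparation permutations are supported: NOCP (all hard pulses), CP90
(composite -90° tip-up: -360° then +270°, 2.8 ms total), CP180 (composite
refocusing 90°x-180°y-90°x) and CP180_90 (both).  B1+ miscalibration is a
scalar scale on every flip angle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from enum import Enum

import numpy as np
from scipy.spatial.transform import Rotation

#: Hard-pulse duration calibration: a 90° pulse lasts 0.4 ms.
HARD_90_DURATION_MS = 0.4


@dataclass(frozen=True)
class RFPulse:
    flip_angle: float  # degrees, signed
    phase: float  # degrees
    duration: float  # ms
    label: str = ""

    def __post_init__(self):
        if self.duration <= 0.0:
            raise ValueError("pulse duration must be > 0")


def hard_pulse(flip_angle: float, phase: float = 0.0, label: str = "") -> RFPulse:
    """A hard pulse with duration proportional to |flip| (90° -> 0.4 ms)."""
    duration = abs(flip_angle) / 90.0 * HARD_90_DURATION_MS
    return RFPulse(float(flip_angle), float(phase), duration, label)


@dataclass(frozen=True)
class CompositePulse:
    sub_pulses: tuple
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sub_pulses", tuple(self.sub_pulses))
        if not self.sub_pulses:
            raise ValueError("a composite pulse needs at least one sub-pulse")

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.sub_pulses)

    def to_json(self) -> str:
        return json.dumps(
            {"label": self.label, "sub_pulses": [asdict(p) for p in self.sub_pulses]}
        )

    @classmethod
    def from_json(cls, text: str) -> "CompositePulse":
        obj = json.loads(text)
        return cls(tuple(RFPulse(**p) for p in obj["sub_pulses"]), obj["label"])


class PulsePermutation(str, Enum):
    NOCP = "NOCP"
    CP90 = "CP90"
    CP180 = "CP180"
    CP180_90 = "CP180_90"

    @property
    def composite_refocus(self) -> bool:
        return self in (PulsePermutation.CP180, PulsePermutation.CP180_90)

    @property
    def composite_tip_up(self) -> bool:
        return self in (PulsePermutation.CP90, PulsePermutation.CP180_90)


class PulseRole(str, Enum):
    TIP_DOWN_90 = "tip_down_90"
    REFOCUS_180 = "refocus_180"
    TIP_UP_MINUS90 = "tip_up_minus90"


def expand(permutation: PulsePermutation | str, role: PulseRole | str) -> CompositePulse:
    """Expand a permutation/role pair into its (possibly composite) pulse.

    The composite -90° tip-up is [-360°, +270°] on the same phase axis as the
    simple -90° (2.8 ms total); the composite refocusing pulse is the standard
    90°x-180°y-90°x, whose net rotation equals a hard 180°y exactly at nominal
    B1.  Every other role is a hard pulse.
    """
    permutation = PulsePermutation(permutation)
    role = PulseRole(role)
    if role is PulseRole.TIP_DOWN_90:
        return CompositePulse((hard_pulse(90.0, 0.0, "90x"),), "tip-down 90")
    if role is PulseRole.REFOCUS_180:
        if permutation.composite_refocus:
            return CompositePulse(
                (
                    hard_pulse(90.0, 0.0, "90x"),
                    hard_pulse(180.0, 90.0, "180y"),
                    hard_pulse(90.0, 0.0, "90x"),
                ),
                "composite 180",
            )
        return CompositePulse((hard_pulse(180.0, 90.0, "180y"),), "hard 180")
    # tip-up -90
    if permutation.composite_tip_up:
        return CompositePulse(
            (hard_pulse(-360.0, 0.0, "-360x"), hard_pulse(270.0, 0.0, "270x")),
            "composite -90",
        )
    return CompositePulse((hard_pulse(-90.0, 0.0, "-90x"),), "hard -90")


def rotation_operator(pulse: RFPulse | CompositePulse, b1_scale: float = 1.0) -> np.ndarray:
    """3x3 rotation operator for a pulse at a given B1+ scale.

    Each sub-pulse rotates by ``b1_scale * flip_angle`` about the unit axis
    (cos(phase), sin(phase), 0); operators compose in time order.  The result
    is orthogonal with determinant +1.
    """
    if b1_scale <= 0.0:
        raise ValueError("b1_scale must be > 0")
    subs = pulse.sub_pulses if isinstance(pulse, CompositePulse) else (pulse,)
    op = np.eye(3)
    for p in subs:
        phase = np.deg2rad(p.phase)
        axis = np.array([np.cos(phase), np.sin(phase), 0.0])
        rot = Rotation.from_rotvec(np.deg2rad(b1_scale * p.flip_angle) * axis)
        op = rot.as_matrix() @ op
    return op


def refocusing_efficiency(pulse: RFPulse | CompositePulse, b1_scale: float) -> float:
    """Spin-echo refocusing efficiency |beta| of a pulse at a given B1+ scale.

    Writing the pulse's action on transverse magnetization m = Mx + i*My as
    m' = alpha*m + beta*conj(m), the conjugating coefficient beta is the
    pathway a spin echo refocuses; |beta| = 1 for an ideal 180°.  An
    identical-looking criterion based on the Frobenius deviation of the full
    net operator from the ideal 180°y does not discriminate between the hard
    and composite refocusing pulses (both deviate equally off-nominal); the
    echo pathway does, and is what governs the prepared-sequence signal.
    """
    R = rotation_operator(pulse, b1_scale)
    beta = 0.5 * complex(R[0, 0] - R[1, 1], R[1, 0] + R[0, 1])
    return float(abs(beta))
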