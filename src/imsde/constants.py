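"""Physical constants and the project-wide unit conventions.

Units are fixed across the package: gradient amplitude in mT/m, time in ms,
gradient moments in mT*ms/m (m0) and mT*ms^2/m (m1), position in m, velocity
in m/s.  Every phase computation routes through the helpers below so the unit
conversion factors appear in exactly one place.
"""

import math

#: Proton gyromagnetic ratio over 2*pi, in kHz/mT (equivalently cycles/(ms*mT)).
GAMMA_KHZ_PER_MT: float = 42.577

_TWO_PI = 2.0 * math.pi

#: m/s expressed in m/ms.
_MS_PER_S = 1.0e-3


def position_phase_rad(m0: float, position_m: float) -> float:
    """Phase (rad) accrued by a static spin at ``position_m`` for a net m0."""
    return _TWO_PI * GAMMA_KHZ_PER_MT * m0 * position_m


def velocity_phase_rad(m1: float, velocity_m_per_s: float) -> float:
    """Phase (rad) accrued by a constant-velocity spin for a net m1."""
    return _TWO_PI * GAMMA_KHZ_PER_MT * m1 * velocity_m_per_s * _MS_PER_S


def off_resonance_phase_rad(frequency_hz: float, dt_ms: float) -> float:
    """Free-precession phase (rad) over ``dt_ms`` at ``frequency_hz``."""
    return _TWO_PI * frequency_hz * dt_ms * 1.0e-3
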