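import numpy as np
import pytest

from imsde.waveforms import GradientLobe, LobeShape, SignProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20140809)


def random_lobe_set(rng, n_max=4, allow_flips=True):
    """A random non-overlapping lobe set with an optional sign profile."""
    n = int(rng.integers(1, n_max + 1))
    t = float(rng.uniform(0.0, 2.0))
    lobes = []
    for _ in range(n):
        shape = LobeShape.SINUSOID if rng.random() < 0.5 else LobeShape.TRAPEZOID
        amp = float(rng.uniform(-30.0, 30.0))
        if shape is LobeShape.SINUSOID:
            ramp, flat = 0.0, float(rng.uniform(0.3, 5.0))
        else:
            ramp, flat = float(rng.uniform(0.0, 1.0)), float(rng.uniform(0.0, 5.0))
            if 2 * ramp + flat == 0.0:
                flat = 0.5
        lobes.append(GradientLobe(shape, amp, ramp, flat, t))
        t = lobes[-1].end_time + float(rng.uniform(0.05, 2.0))
    flips = ()
    if allow_flips and n > 1 and rng.random() < 0.7:
        k = int(rng.integers(1, n))
        flips = tuple(
            sorted(0.5 * (lobes[i].end_time + lobes[i + 1].start_time)
                   for i in rng.choice(n - 1, size=k, replace=False))
        )
    return tuple(lobes), SignProfile(flip_times=flips)


def sampled_moments(lobes, signs, reference_time=0.0, dt=2e-4):
    """Brute-force fixed-step moment integration (independent oracle)."""
    t0 = min(l.start_time for l in lobes)
    t1 = max(l.end_time for l in lobes)
    t = np.arange(t0, t1 + dt, dt)
    g = np.zeros_like(t)
    for lobe in lobes:
        g += lobe.evaluate(t)
    s = np.ones_like(t) * signs.initial_sign
    for f in signs.flip_times:
        s[t >= f] *= -1.0
    m0 = float(np.trapezoid(s * g, t))
    m1 = float(np.trapezoid(s * g * (t - reference_time), t))
    return m0, m1
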