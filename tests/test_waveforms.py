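import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_lobe_set, sampled_moments
from imsde.errors import GeometryError, HardwareLimitError, InfeasibleDesignError
from imsde.waveforms import (
    FourLobeLayout,
    LobeShape,
    SignProfile,
    design_prep_gradients,
    make_lobe,
    moments,
)


class TestMakeLobe:
    def test_trapezoid_geometry(self):
        lobe = make_lobe("trapezoid", 20.0, 0.5, 2.0)
        assert lobe.duration == pytest.approx(3.0)
        assert lobe.evaluate(1.5) == pytest.approx(20.0)
        # evaluation is exactly zero outside the lobe
        assert lobe.evaluate([-0.1, 3.1]).tolist() == [0.0, 0.0]

    def test_zero_amplitude_lobe_is_null(self):
        lobe = make_lobe("sinusoid", 0.0, 0.0, 1.0)
        assert np.all(lobe.evaluate(np.linspace(-1, 2, 50)) == 0.0)
        rep = moments([lobe])
        assert rep.m0 == 0.0 and rep.m1 == 0.0

    def test_half_sine_area_closed_form(self):
        lobe = make_lobe("sinusoid", 26.0, 0.0, 1.1)
        assert lobe.area == pytest.approx(2 * 26 * 1.1 / math.pi)
        assert lobe.area == pytest.approx(18.2073254897, abs=1e-9)

    def test_amplitude_limit_enforced(self):
        with pytest.raises(HardwareLimitError):
            make_lobe("trapezoid", 25.0, 0.5, 1.0, max_amplitude=20.0)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            make_lobe("trapezoid", 10.0, -0.1, 1.0)


class TestMoments:
    def test_rectangle_m1_is_area_times_center(self):
        lobe = make_lobe("trapezoid", 10.0, 0.0, 2.0, start_time=4.0)
        rep = moments([lobe])
        assert rep.m0 == pytest.approx(20.0)
        assert rep.m1 == pytest.approx(100.0)

    def test_bipolar_pair_first_moment(self):
        # two rectangles, one flip between them: |m0|=0, |m1| = G*d*separation
        a = make_lobe("trapezoid", 20.0, 0.0, 2.0, start_time=0.0)
        b = make_lobe("trapezoid", 20.0, 0.0, 2.0, start_time=12.175)
        signs = SignProfile(flip_times=(6.0,))
        rep = moments([a, b], signs)
        assert rep.m0 == pytest.approx(0.0, abs=1e-12)
        assert abs(rep.m1) == pytest.approx(20.0 * 2.0 * 12.175)
        # matches the brute-force sampled oracle
        m0s, m1s = sampled_moments([a, b], signs)
        assert m1s == pytest.approx(rep.m1, rel=1e-4)

    def test_odd_effective_waveform_has_zero_m0(self):
        a = make_lobe("sinusoid", 15.0, 0.0, 2.0, start_time=1.0)
        b = make_lobe("sinusoid", 15.0, 0.0, 2.0, start_time=5.0)
        rep = moments([a, b], SignProfile(flip_times=(4.0,)))
        assert rep.m0 == pytest.approx(0.0, abs=1e-12)

    def test_overlapping_lobes_rejected(self):
        a = make_lobe("trapezoid", 10.0, 0.0, 2.0, start_time=0.0)
        b = make_lobe("trapezoid", 10.0, 0.0, 2.0, start_time=1.0)
        with pytest.raises(GeometryError):
            moments([a, b])

    def test_quadrature_agrees_with_analytic(self, rng):
        for _ in range(20):
            lobes, signs = random_lobe_set(rng)
            ana = moments(lobes, signs)
            quad = moments(lobes, signs, method="quad")
            scale = max(abs(ana.m0), abs(ana.m1), 1.0)
            assert abs(ana.m0 - quad.m0) <= 1e-6 * scale
            assert abs(ana.m1 - quad.m1) <= 1e-6 * scale

    def test_flip_inside_lobe_handled_by_splitting(self):
        lobe = make_lobe("trapezoid", 10.0, 0.0, 4.0, start_time=0.0)
        rep = moments([lobe], SignProfile(flip_times=(2.0,)))
        assert rep.m0 == pytest.approx(0.0, abs=1e-9)  # halves cancel

    @given(flip=st.floats(5.0, 9.0))
    @settings(max_examples=25, deadline=None)
    def test_sign_flip_negation_invariance(self, flip):
        """Inserting a flip at t and negating later lobes leaves moments unchanged."""
        a = make_lobe("trapezoid", 18.0, 0.3, 1.5, start_time=0.0)
        b = make_lobe("sinusoid", 12.0, 0.0, 2.0, start_time=10.0)
        before = moments([a, b])
        b_neg = make_lobe("sinusoid", -12.0, 0.0, 2.0, start_time=10.0)
        after = moments([a, b_neg], SignProfile(flip_times=(flip,)))
        assert after.m0 == pytest.approx(before.m0, abs=1e-9)
        assert after.m1 == pytest.approx(before.m1, abs=1e-9)


class TestDesign:
    def test_zero_target_returns_null_lobes(self):
        res = design_prep_gradients(0.0)
        assert all(l.amplitude == 0.0 for l in res.lobes)
        assert res.report.m1 == 0.0

    def test_round_trip_recovers_target(self):
        res = design_prep_gradients(487.0, "trapezoid", max_amplitude=20.0)
        assert abs(res.report.m1) == pytest.approx(487.0, rel=1e-4)
        # re-measuring the designed lobes reproduces the report
        rep = moments(res.lobes, res.signs)
        assert rep.m1 == pytest.approx(res.report.m1, rel=1e-9)

    def test_duration_monotone_in_target(self):
        targets = [181.0, 487.0, 925.0, 1518.0, 2278.0, 3108.0]
        results = [design_prep_gradients(t, "trapezoid", 20.0) for t in targets]
        durations = [r.t_imsde for r in results]
        assert durations == sorted(durations)
        assert results[-1].lobe_duration > results[1].lobe_duration

    def test_small_target_falls_back_to_amplitude_solve(self):
        res = design_prep_gradients(20.0, "trapezoid", max_amplitude=20.0)
        assert abs(res.report.m1) == pytest.approx(20.0, rel=1e-4)
        assert res.amplitude < 20.0

    def test_sinusoid_needs_higher_amplitude_or_longer_duration(self):
        trap = design_prep_gradients(925.0, "trapezoid", max_amplitude=20.0)
        sin_same_amp = design_prep_gradients(925.0, "sinusoid", max_amplitude=20.0)
        assert sin_same_amp.lobe_duration > trap.lobe_duration
        sin_matched = design_prep_gradients(
            925.0, "sinusoid", max_amplitude=35.0, lobe_duration=trap.lobe_duration)
        assert sin_matched.amplitude > trap.amplitude

    def test_infeasible_target_names_binding_constraint(self):
        with pytest.raises(InfeasibleDesignError, match="duration bound"):
            design_prep_gradients(1e6, "trapezoid", max_amplitude=20.0,
                                  duration_bounds=(1.0, 8.0))
        with pytest.raises(InfeasibleDesignError, match="amplitude limit"):
            design_prep_gradients(3000.0, "trapezoid", max_amplitude=20.0,
                                  lobe_duration=2.0)

    def test_slew_limited_sinusoid_respects_slew(self):
        res = design_prep_gradients(181.0, "sinusoid", max_amplitude=30.0,
                                    lobe_duration=1.2, slew_max=40.0)
        assert res.lobes[0].peak_slew <= 40.0 + 1e-9
        assert abs(res.report.m1) == pytest.approx(181.0, rel=1e-4)

    def test_layout_reports_consistent_t_imsde(self):
        layout = FourLobeLayout()
        placed = layout.place(LobeShape.TRAPEZOID, 20.0, 0.5, 2.0)
        assert placed.t_imsde == pytest.approx(
            placed.rotation_times[-1] - placed.rotation_times[0])
        # all lobes lie strictly between the tip-down and tip-up rotations
        for lobe in placed.lobes:
            assert lobe.start_time >= placed.rotation_times[0]
            assert lobe.end_time <= placed.rotation_times[-1]
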