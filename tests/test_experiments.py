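import math

import numpy as np
import pytest

from imsde.experiments import (
    EddyModel,
    design_shape_pair,
    eddy_moment_residuals,
    eddy_response,
    fixture_snr_table,
    generate_fixture_image,
    provenance_block,
    run_b1_map,
    run_blood_suppression,
    run_phantom_sweep,
)
from imsde.prep_sequences import build_imsde
from imsde.waveforms import make_lobe

M1_SHORT = (487.0, 1518.0, 3108.0)


class TestEddyResponse:
    def test_zero_amplitude_gives_zero_residual(self):
        lobes = (make_lobe("trapezoid", 20.0, 0.5, 2.0, 1.0),)
        _, residual = eddy_response(lobes, EddyModel(amplitude=0.0))
        assert np.all(residual == 0.0)

    def test_rectangle_step_transients(self):
        """An unramped rectangle produces opposite-sign exponential transients
        of peak amplitude a*G at its edges."""
        G, a_eddy, tau = 20.0, 0.01, 0.5
        lobes = (make_lobe("trapezoid", G, 0.0, 3.0, 2.0),)
        t, residual = eddy_response(lobes, EddyModel(a_eddy, tau), dt=0.001)
        i_up = np.argmin(residual)
        i_down = np.argmax(residual)
        assert residual[i_up] == pytest.approx(-a_eddy * G, rel=0.02)
        assert residual[i_down] == pytest.approx(a_eddy * G, rel=0.02)
        assert t[i_up] < t[i_down]
        # transient decays with the model's time constant
        j = i_down + int(tau / 0.001)
        assert residual[j] == pytest.approx(residual[i_down] / math.e, rel=0.05)

    def test_sinusoid_phase_error_smaller_than_trapezoid(self):
        """Duration-matched half-sine lobes leave a smaller sign-weighted
        residual than trapezoids at matched m1, across eddy time constants."""
        preps = design_shape_pair(1518.0)
        for tau in (0.2, 0.5, 1.0, 3.0):
            model = EddyModel(0.005, tau)
            m0_trap, _ = eddy_moment_residuals(preps[list(preps)[0]], model)
            m0_sin, _ = eddy_moment_residuals(preps[list(preps)[1]], model)
            assert abs(m0_sin) <= abs(m0_trap) + 1e-12


class TestPhantomSweep:
    def test_zero_eddy_reduces_to_theory(self):
        result = run_phantom_sweep(
            t2_values=(50.0,), m1_values=M1_SHORT, eddy=EddyModel(amplitude=0.0))
        ok = result.data[result.data.status == "ok"]
        assert len(ok) == 2 * len(M1_SHORT)
        assert np.allclose(ok.retention_ideal, ok.retention_theory, atol=1e-12)
        assert np.allclose(ok.retention_eddy, ok.retention_theory, atol=1e-12)

    def test_short_t2_retains_less(self):
        result = run_phantom_sweep(m1_values=M1_SHORT)
        data = result.data
        for (m1, shape), group in data.groupby(["m1", "shape"]):
            r50 = group[group.t2 == 50.0].retention_ideal.iloc[0]
            r89 = group[group.t2 == 89.0].retention_ideal.iloc[0]
            assert r50 < r89

    def test_sinusoid_retention_at_least_trapezoid_under_eddy(self):
        result = run_phantom_sweep(t2_values=(50.0,), m1_values=M1_SHORT)
        data = result.data
        gaps = []
        for m1, group in data.groupby("m1"):
            sin = group[group["shape"] == "sinusoid"].retention_eddy.iloc[0]
            trap = group[group["shape"] == "trapezoid"].retention_eddy.iloc[0]
            assert sin >= trap - 1e-12
            gaps.append(sin - trap)
        assert gaps == sorted(gaps)  # gap widens with m1

    def test_provenance_is_reproducible(self):
        a = run_phantom_sweep(t2_values=(50.0,), m1_values=(487.0,))
        b = run_phantom_sweep(t2_values=(50.0,), m1_values=(487.0,))
        assert a.provenance["config_sha256"] == b.provenance["config_sha256"]
        assert a.data.equals(b.data)


class TestBloodSuppression:
    def test_zero_m1_is_tissue_equivalent_retention(self):
        result = run_blood_suppression(m1_values=(0.0,), n_radial=51)
        row = result.data.iloc[0]
        assert row.residual_lumen == pytest.approx(
            math.exp(-row.t_imsde / 250.0), abs=1e-9)

    def test_residual_below_threshold_reported(self):
        result = run_blood_suppression(m1_values=M1_SHORT)
        assert result.provenance["threshold_m1"] == 487.0
        assert (result.data.residual_lumen < 0.05).all()

    def test_plug_flow_rephasing_caveat(self):
        """Plug flow at the velocity where phi = 2*pi rephases coherently."""
        from imsde.bloch import SpinState, propagate_prep
        from imsde.constants import GAMMA_KHZ_PER_MT
        prep = build_imsde(487.0, "CP180", "sinusoid", max_amplitude=30.0)
        v_2pi = 1.0 / (GAMMA_KHZ_PER_MT * abs(prep.m1_effective) * 1e-3)
        out = propagate_prep(SpinState(T2=250.0, velocity=v_2pi), prep)
        assert out.M[2] == pytest.approx(math.exp(-prep.t_imsde / 250.0), abs=1e-9)


class TestB1Map:
    def test_composite_refocus_improves_mean_retention(self):
        result = run_b1_map(n_b1=13)
        summary = {r["permutation"]: r for r in result.provenance["summary"]}
        assert summary["CP180"]["mean"] > summary["NOCP"]["mean"]
        assert summary["CP180"]["min"] > summary["NOCP"]["min"]

    def test_nominal_b1_ordering_set_by_duration(self):
        """With a degenerate flat B1 range the permutations rank purely by
        their preparation durations."""
        result = run_b1_map(b1_range=(1.0, 1.0), n_b1=1, t2=50.0)
        data = result.data.set_index("permutation")
        for perm in ("NOCP", "CP90", "CP180", "CP180_90"):
            row = data.loc[perm]
            assert row.retention == pytest.approx(
                math.exp(-row.t_imsde / 50.0), abs=1e-9)
        assert (data.loc["NOCP"].retention / data.loc["CP90"].retention
                == pytest.approx(math.exp(2.4 / 50.0), abs=1e-9))


class TestFixtureImage:
    def test_noiseless_means_are_exact(self):
        image, masks = generate_fixture_image(noise_sd=0.0, seed=1)
        assert np.all(image[masks["muscle"]] == 100.0)
        assert np.all(image[masks["lumen"]] == 10.0)
        assert np.all(image[masks["background"]] == 0.0)

    def test_deterministic_for_seed(self):
        a, _ = generate_fixture_image(seed=7)
        b, _ = generate_fixture_image(seed=7)
        c, _ = generate_fixture_image(seed=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_snr_pipeline_recovers_ground_truth(self):
        image, masks = generate_fixture_image(noise_sd=10.0, seed=3)
        table = fixture_snr_table(image, masks).set_index("compartment")
        n_bg = int(masks["background"].sum())
        assert n_bg > 800  # enough pixels for a stable noise estimate
        # Eq-style SNR = 0.695 * mean / sd with a few-percent sampling tolerance
        assert table.loc["muscle", "snr"] == pytest.approx(6.95, rel=0.05)

    def test_masks_disjoint(self):
        _, masks = generate_fixture_image(seed=0)
        total = sum(m.astype(int) for m in masks.values())
        assert total.max() == 1


def test_provenance_block_hash_stable():
    a = provenance_block({"x": 1, "y": [2, 3]}, seed=5)
    b = provenance_block({"y": [2, 3], "x": 1}, seed=5)
    assert a["config_sha256"] == b["config_sha256"]
    assert a["seed"] == 5 and "gamma_khz_per_mt" in a
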