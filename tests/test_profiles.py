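"""Profile I/O, normalization, resampling, FWHM/penumbra and OIT analysis."""

import numpy as np
import pytest
from scipy.special import ndtr

import beamtune as bt
from beamtune.errors import (
    DegenerateProfileError,
    GeometryError,
    MetricUndefinedError,
    ProfileValidationError,
    SchemaError,
)
from conftest import Z80, erf_profile, step_profile


class TestProfileInvariants:
    def test_positions_must_increase(self):
        with pytest.raises(ProfileValidationError, match="increasing"):
            bt.Profile("crossline", [0.0, 1.0, 1.0], [1, 2, 3], 10.0, 3.0)

    def test_minimum_length(self):
        with pytest.raises(ProfileValidationError, match="3 samples"):
            bt.Profile("crossline", [0.0, 1.0], [1, 2], 10.0, 3.0)

    def test_unknown_axis_rejected(self):
        with pytest.raises(ProfileValidationError, match="axis"):
            bt.Profile("diagonal", [0, 1, 2], [1, 2, 3], 10.0, 3.0)


class TestProfileIO:
    def test_minimal_three_row_file(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text(
            "#axis: crossline\n#depth_cm: 10\n#ssd_cm: 90\n#field_size_cm: 3\n"
            "#oit_mm: 1.2\n#collimation: mlc\nposition_mm,dose\n"
            "-1.0,50\n0.0,100\n1.0,50\n"
        )
        (p,) = bt.read_profiles(f)
        assert len(p) == 3
        assert p.oit == 1.2 and p.axis == "crossline"

    def test_duplicate_position_names_the_row(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text(
            "#axis: crossline\n#depth_cm: 10\n#ssd_cm: 90\n#field_size_cm: 3\n"
            "#oit_mm: 0\n#collimation: mlc\nposition_mm,dose\n"
            "0.0,100\n0.0,99\n1.0,50\n"
        )
        with pytest.raises(ProfileValidationError, match=":9:"):
            bt.read_profiles(f)

    def test_missing_metadata_is_schema_error(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("#axis: crossline\nposition_mm,dose\n0,1\n1,2\n2,3\n")
        with pytest.raises(SchemaError, match="depth_cm"):
            bt.read_profiles(f)

    def test_simulator_round_trip(self, tmp_path, default_params):
        cfg = bt.SimConfig(noise_sd=0.3, seed=7)
        orig = bt.simulate_profile(default_params, 3.0, 10.0, "crossline", 1.2, cfg)
        bt.write_profile(tmp_path / "p.csv", orig)
        (back,) = bt.read_profiles(tmp_path / "p.csv")
        assert back.geometry == orig.geometry
        np.testing.assert_allclose(back.positions, orig.positions, atol=1e-6)
        np.testing.assert_allclose(back.dose, orig.dose, atol=1e-5)


class TestNormalization:
    def test_uniform_profile_scales_to_100(self):
        p = bt.Profile("crossline", [-1, 0, 1], [50.0, 50.0, 50.0], 10.0, 3.0)
        q = bt.normalize_to_cax(p)
        np.testing.assert_array_equal(q.dose, [100.0, 100.0, 100.0])

    def test_idempotent(self):
        p = bt.normalize_to_cax(erf_profile())
        q = bt.normalize_to_cax(p)
        np.testing.assert_allclose(q.dose, p.dose, rtol=1e-15)

    def test_arbitrary_units_rescaled(self):
        p = erf_profile()
        scaled = bt.Profile(p.axis, p.positions, p.dose * 0.0087, p.depth, p.field_size)
        q = bt.normalize_to_cax(scaled)
        i = int(np.argmin(np.abs(q.positions)))
        assert q.dose[i] == pytest.approx(100.0, abs=1e-9)

    def test_nonpositive_cax_rejected(self):
        p = bt.Profile("crossline", [-1, 0, 1], [1.0, 0.0, 1.0], 10.0, 3.0)
        with pytest.raises(DegenerateProfileError):
            bt.normalize_to_cax(p)


class TestResampling:
    def test_linear_midpoint(self):
        p = bt.Profile("crossline", [0.0, 1.0, 2.0], [0.0, 100.0, 0.0], 10.0, 3.0)
        q = bt.resample_linear(p, 0.5)
        np.testing.assert_allclose(q.positions, [0, 0.5, 1, 1.5, 2])
        assert q.dose[1] == pytest.approx(50.0)

    def test_identity_on_already_gridded(self):
        p = erf_profile(step=0.5)
        q = bt.resample_linear(p, 0.5)
        np.testing.assert_allclose(q.dose, p.dose, rtol=1e-12)

    def test_erf_resampled_close_to_analytic(self):
        # linear-interp error bound is h^2*max|f''|/8 ~ 0.047% for sigma=4
        p = erf_profile(sigma=4.0, step=0.5)
        q = bt.resample_linear(p, 0.1)
        analytic = 100.0 * (
            ndtr((q.positions + 15) / 4.0) - ndtr((q.positions - 15) / 4.0)
        )
        assert np.abs(q.dose - analytic).max() < 0.05

    def test_step_larger_than_span_rejected(self):
        p = bt.Profile("crossline", [0.0, 1.0, 2.0], [0, 1, 0], 10.0, 3.0)
        with pytest.raises(ValueError, match="span"):
            bt.resample_linear(p, 5.0)


class TestFieldMetrics:
    def test_step_field_width(self):
        assert bt.fwhm(step_profile(half_width=15.0)) == pytest.approx(30.0, abs=1e-9)

    def test_symmetric_blur_preserves_fwhm(self):
        # a symmetric Gaussian blur moves dose but not the 50% crossing
        assert bt.fwhm(erf_profile(sigma=2.0)) == pytest.approx(30.0, abs=1e-3)

    def test_no_crossing_is_metric_undefined(self):
        p = bt.Profile("crossline", [-1, 0, 1], [80.0, 100.0, 80.0], 10.0, 3.0)
        with pytest.raises(MetricUndefinedError):
            bt.fwhm(p)

    @pytest.mark.parametrize("sigma,expected", [(1.0, 2 * Z80), (2.0, 4 * Z80)])
    def test_erf_penumbra_scales_with_sigma(self, sigma, expected):
        p = erf_profile(sigma=sigma)
        assert bt.penumbra_width(p, "right") == pytest.approx(expected, rel=2e-3)
        assert bt.penumbra_width(p, "left") == pytest.approx(expected, rel=2e-3)

    def test_step_penumbra_shrinks_with_sampling(self):
        # a sampled step spreads both crossings over one sample interval,
        # so the degenerate penumbra vanishes with the sampling step
        for step in (0.1, 0.01):
            assert bt.penumbra_width(step_profile(step=step), "right") <= step

    def test_penumbra_region_location(self):
        region = bt.penumbra_region(erf_profile(sigma=1.0), "right")
        assert region.lo == pytest.approx(15.0 - Z80, abs=5e-3)
        assert region.hi == pytest.approx(15.0 + Z80, abs=5e-3)

    def test_mirroring_swaps_sides(self):
        # build an asymmetric profile: sharp left edge, soft right edge
        x = np.arange(-45.0, 45.0001, 0.1)
        d = 100.0 * (ndtr((x + 15) / 1.0) - ndtr((x - 15) / 3.0))
        p = bt.Profile("crossline", x, d, 10.0, 3.0)
        m = bt.Profile("crossline", -x[::-1], d[::-1], 10.0, 3.0)
        assert bt.fwhm(m) == pytest.approx(bt.fwhm(p), abs=1e-9)
        assert bt.penumbra_width(m, "left") == pytest.approx(
            bt.penumbra_width(p, "right"), abs=1e-9
        )
        assert bt.penumbra_width(m, "right") == pytest.approx(
            bt.penumbra_width(p, "left"), abs=1e-9
        )


def _cosine_sweep(oits, pitch=5.0, fwhm_amp=0.3, pen_amp=0.05):
    """Analytic sweep entries: cosine-modulated FWHM and penumbra."""
    oits = np.asarray(oits, float)
    phase = np.cos(2 * np.pi * oits / pitch)
    return bt.OITSweep(
        oit=oits,
        fwhm=30.9 + fwhm_amp * phase,
        penumbra_mean=4.8 * (1 + pen_amp * phase),
        leaf_pitch=pitch,
    )


class TestOITSweep:
    def test_unmodulated_simulated_sweep_is_flat(self, default_params):
        cfg = bt.SimConfig(fwhm_modulation_amp=0.0, penumbra_modulation_amp=0.0)
        profs = bt.simulate_oit_sweep(default_params, cfg, oit_step=2.0)
        sweep = bt.oit_sweep_metrics(profs)
        np.testing.assert_allclose(sweep.fwhm_norm, 1.0, atol=1e-6)

    def test_normalized_metrics_average_to_one(self, default_params):
        cfg = bt.SimConfig(grid_step=0.1)
        profs = bt.simulate_oit_sweep(default_params, cfg, oit_step=1.0)
        sweep = bt.oit_sweep_metrics(profs)
        assert sweep.fwhm_norm.mean() == pytest.approx(1.0, abs=1e-12)
        assert sweep.penumbra_norm.mean() == pytest.approx(1.0, abs=1e-12)

    def test_extrema_at_leaf_centres_and_junctions(self, default_params):
        # FWHM largest between leaves (OIT = 0, +/-5, +/-10), smallest under
        # the leaf centres (+/-2.5, +/-7.5)
        cfg = bt.SimConfig(grid_step=0.1)
        profs = bt.simulate_oit_sweep(default_params, cfg, oit_step=0.5)
        sweep = bt.oit_sweep_metrics(profs)
        maxima = set(sweep.oit[sweep.fwhm_norm >= sweep.fwhm_norm.max() - 1e-9])
        minima = set(sweep.oit[sweep.fwhm_norm <= sweep.fwhm_norm.min() + 1e-9])
        assert maxima == {0.0, 5.0, -5.0, 10.0, -10.0}
        assert minima == {2.5, -2.5, 7.5, -7.5}

    def test_heterogeneous_geometry_rejected(self, default_params):
        cfg = bt.SimConfig()
        profs = bt.simulate_oit_sweep(default_params, cfg, oit_step=5.0)
        other = bt.simulate_profile(default_params, 2.0, 10.0, "crossline", 1.0, cfg)
        with pytest.raises(GeometryError, match="heterogeneous"):
            bt.oit_sweep_metrics(profs + [other])

    def test_inline_profile_rejected(self, default_params):
        cfg = bt.SimConfig()
        profs = bt.simulate_oit_sweep(default_params, cfg, oit_step=5.0)
        inline = bt.simulate_profile(default_params, 3.0, 10.0, "inline", 0.0, cfg)
        with pytest.raises(GeometryError, match="crossline"):
            bt.oit_sweep_metrics(profs + [inline])


class TestRepresentativeOIT:
    def test_quarter_pitch_selected_on_fine_cosine_sweep(self):
        sweep = _cosine_sweep(np.arange(-10, 10.001, 0.25))
        assert bt.representative_oit(sweep) == pytest.approx(1.25)

    def test_flat_sweep_tie_breaks_to_zero(self):
        sweep = _cosine_sweep(np.arange(-10, 10.001, 0.5), fwhm_amp=0.0, pen_amp=0.0)
        assert bt.representative_oit(sweep) == 0.0

    def test_coarse_candidates_pick_nearest_to_quarter_pitch(self):
        # exhaustive check over the three candidates: |cos| is smallest at 1.2
        sweep = _cosine_sweep([0.0, 1.2, 2.5])
        assert bt.representative_oit(sweep) == pytest.approx(1.2)

    def test_positive_sign_preferred_among_mirrored_ties(self):
        sweep = _cosine_sweep(np.arange(-10, 10.001, 1.25))
        assert bt.representative_oit(sweep) == pytest.approx(1.25)

    def test_quarter_pitch_within_one_step_property(self):
        # property: on any decently sampled cosine sweep the selection lands
        # within one sweep step of pitch/4
        for step in (0.2, 0.25, 0.4, 0.5, 1.0):
            sweep = _cosine_sweep(np.arange(-10, 10.001, step))
            assert abs(abs(bt.representative_oit(sweep)) - 1.25) <= step + 1e-9
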