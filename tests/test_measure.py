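"""Measurement pipeline: segmentation, morphometrics, uncertainties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cocomorph import (CoccolithSpec, OpticalConstants, SegmentationParams,
                       UncertaintyBudget)
from cocomorph.measure import (measure_particle, measure_sample,
                               propagate_uncertainty, segment_particles)
from cocomorph.synth import (_moment_skewness, make_thickness_map,
                             render_image, scale_to_mean_thickness)


def _render_coccoliths(cal, constants, lengths, mean_t=0.07, noise_sd=0.0,
                       seed=0):
    maps, truths = [], []
    for L in lengths:
        spec = scale_to_mean_thickness(
            CoccolithSpec(length=L), mean_t, constants)
        tmap, truth = make_thickness_map(spec, constants)
        maps.append(tmap)
        truths.append(truth)
    image, offsets = render_image(maps, cal, constants, noise_sd=noise_sd,
                                  rng=seed)
    return image, truths


class TestSkewness:
    def test_brute_force_moment_fixture(self):
        # {1,1,1,5}: m2 = 3, m3 = 6 → g1 = 6/3^1.5
        assert _moment_skewness([1, 1, 1, 5]) == pytest.approx(
            6 / 3 ** 1.5, abs=1e-9)
        assert _moment_skewness([1, 1, 1, 5]) == pytest.approx(1.1547,
                                                               abs=1e-4)

    def test_symmetric_distribution_has_zero_skewness(self):
        assert _moment_skewness([1, 1, 3, 3]) == 0.0

    def test_sign_flips_under_mirroring(self):
        vals = np.array([1.0, 1.0, 1.0, 5.0])
        assert _moment_skewness(-vals) == pytest.approx(
            -_moment_skewness(vals))

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=0.01, max_value=100.0),
           st.floats(min_value=-50.0, max_value=50.0))
    def test_invariant_under_positive_affine_maps(self, scale, shift):
        vals = np.array([0.2, 0.5, 0.9, 1.4, 3.0])
        g_ref = _moment_skewness(vals)
        assert _moment_skewness(scale * vals + shift) == pytest.approx(
            g_ref, rel=1e-8, abs=1e-8)


class TestSegmentation:
    def test_three_disjoint_coccoliths_three_masks(self, cal, constants):
        image, _ = _render_coccoliths(cal, constants, [2.5, 2.8, 3.1],
                                      noise_sd=40.0)
        masks = segment_particles(image)
        assert len(masks) == 3
        # masks are disjoint
        total = sum(m.astype(int) for m in masks)
        assert total.max() == 1

    def test_blank_image_yields_empty_list(self, cal, constants):
        image, _ = render_image([], cal, constants, noise_sd=40.0, rng=0)
        assert segment_particles(image) == []

    def test_border_straddling_particle_excluded_by_policy(self, cal,
                                                           constants):
        image, _ = _render_coccoliths(cal, constants, [2.7], noise_sd=0.0)
        cropped = image[60:, :]  # cuts into the particle
        on = segment_particles(cropped,
                               SegmentationParams(exclude_border=True))
        off = segment_particles(cropped,
                                SegmentationParams(exclude_border=False))
        assert on == []
        assert len(off) == 1

    def test_min_area_filter_drops_specks(self, cal, constants):
        image, _ = _render_coccoliths(cal, constants, [2.7], noise_sd=0.0)
        params = SegmentationParams(min_area=50.0)  # larger than any E. hux
        assert segment_particles(image, params) == []

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError):
            segment_particles(np.zeros((4, 4, 3), dtype=np.uint8))


class TestMeasureParticle:
    def test_uniform_disk_analytic_oracle(self, cal, constants):
        """A flat disk of known diameter and thickness: moment-ellipse axes
        recover the diameter and mass is exactly d·area·t."""
        px = constants.pixel_size
        t = 0.08
        radius_px = 1.0 / px  # diameter 2.0 μm
        n = int(radius_px * 2 + 20)
        yy, xx = np.mgrid[:n, :n]
        mask = (yy - n / 2) ** 2 + (xx - n / 2) ** 2 <= radius_px ** 2
        thickness = np.where(mask, t, 0.0)
        from cocomorph.optics import thickness_to_retardation
        image = np.asarray(cal.grey(
            thickness_to_retardation(thickness, constants)))
        m = measure_particle(mask, image, cal, constants)
        assert m.length == pytest.approx(2.0, abs=2 * px)
        assert m.width == pytest.approx(2.0, abs=2 * px)
        assert m.mass == pytest.approx(
            constants.density * m.area * t, rel=1e-9)
        assert m.mean_thickness == pytest.approx(t, rel=1e-9)
        assert m.skewness == pytest.approx(0.0, abs=1e-9)

    def test_integration_identity_holds_exactly(self, cal, constants):
        image, _ = _render_coccoliths(cal, constants, [2.7, 3.2],
                                      noise_sd=40.0)
        for mask in segment_particles(image):
            m = measure_particle(mask, image, cal, constants)
            assert m.mass == pytest.approx(
                constants.density * m.area * m.mean_thickness, rel=1e-12)
            assert m.pixel_count * constants.pixel_area == pytest.approx(
                m.area, rel=1e-12)
            assert m.aspect_ratio >= 1.0

    def test_tiny_mask_rejected(self, cal, constants):
        image = np.full((10, 10), int(cal.dark_offset), dtype=np.uint16)
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(ValueError, match="4 pixels"):
            measure_particle(mask, image, cal, constants)

    def test_grey_skewness_differs_from_thickness_skewness(self, cal,
                                                           constants):
        image, _ = _render_coccoliths(cal, constants, [2.7], noise_sd=0.0)
        mask = segment_particles(image)[0]
        on_t = measure_particle(mask, image, cal, constants,
                                skewness_on="thickness")
        on_g = measure_particle(mask, image, cal, constants,
                                skewness_on="grey")
        assert on_t.skewness != pytest.approx(on_g.skewness, abs=1e-3)


class TestZeroNoiseRecovery:
    def test_round_trip_recovers_ground_truth(self, cal, constants):
        lengths = [2.5, 2.7, 2.9, 3.2, 5.0]
        image, truths = _render_coccoliths(cal, constants, lengths,
                                           noise_sd=0.0)
        table = measure_sample([image], cal, constants, strain="t",
                               salinity=34.0)
        assert table.n == len(lengths)
        df = table.data.sort_values("length_um").reset_index(drop=True)
        truths = sorted(truths, key=lambda t: t.length)
        px = constants.pixel_size
        for i, truth in enumerate(truths):
            assert df.loc[i, "length_um"] == pytest.approx(
                truth.length, abs=2 * px)
            assert df.loc[i, "mean_thickness_um"] == pytest.approx(
                truth.mean_thickness, rel=0.02)
            assert df.loc[i, "mass_pg"] == pytest.approx(truth.mass,
                                                         rel=0.02)

    def test_measure_sample_deterministic(self, cal, constants):
        image, _ = _render_coccoliths(cal, constants, [2.6, 3.0],
                                      noise_sd=40.0)
        t1 = measure_sample([image], cal, constants)
        t2 = measure_sample([image], cal, constants)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_blank_image_gives_empty_table(self, cal, constants):
        image, _ = render_image([], cal, constants, noise_sd=40.0, rng=0)
        table = measure_sample([image], cal, constants)
        assert table.n == 0

    def test_no_images_rejected(self, cal, constants):
        with pytest.raises(ValueError):
            measure_sample([], cal, constants)


class TestUncertaintyPropagation:
    def _ehux_measurement(self, cal, constants):
        image, _ = _render_coccoliths(cal, constants, [2.7], mean_t=0.07,
                                      noise_sd=0.0)
        mask = segment_particles(image)[0]
        return measure_particle(mask, image, cal, constants)

    def test_zero_budget_gives_zero_uncertainties(self, cal, constants):
        m = self._ehux_measurement(cal, constants)
        budget = UncertaintyBudget(grey_noise_sd=0, calibration_rel_sd=0,
                                   pixel_size_rel_sd=0,
                                   edge_localization_px=0)
        assert propagate_uncertainty(m, budget, cal, constants) == (0, 0, 0)

    def test_equal_components_add_in_quadrature(self, cal, constants):
        m = self._ehux_measurement(cal, constants)
        a = 0.04
        budget = UncertaintyBudget(grey_noise_sd=0, calibration_rel_sd=a,
                                   pixel_size_rel_sd=a / 2,
                                   edge_localization_px=0)
        _, _, u_m = propagate_uncertainty(m, budget, cal, constants)
        assert u_m / m.mass == pytest.approx(1.96 * a * np.sqrt(2),
                                             rel=1e-9)

    def test_default_budget_lands_in_stated_bands(self, cal, constants):
        """E. huxleyi-scale particle: ±0.2 μm length, ±0.007 μm thickness,
        13–20 % relative mass at 95 % confidence."""
        m = self._ehux_measurement(cal, constants)
        assert m.pixel_count > 5000  # ~10⁴-pixel particle
        u_l, u_t, u_m = propagate_uncertainty(
            m, UncertaintyBudget(), cal, constants)
        assert round(u_l, 1) == 0.2
        assert round(u_t, 3) == 0.007
        assert 0.13 <= u_m / m.mass <= 0.20

    def test_negative_budget_component_rejected(self):
        with pytest.raises(ValueError):
            UncertaintyBudget(grey_noise_sd=-1)


def test_sample_summary_uses_t_confidence_interval(cal, constants):
    image, _ = _render_coccoliths(cal, constants, [2.5, 2.7, 2.9, 3.1],
                                  noise_sd=0.0)
    table = measure_sample([image], cal, constants)
    summ = table.summary()
    vals = table.data["length_um"].to_numpy()
    from scipy.stats import t as t_dist
    expected = t_dist.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) \
        / np.sqrt(len(vals))
    assert summ["length_um"]["ci95"] == pytest.approx(expected, rel=1e-9)
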