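"""Wall measurement: border detection, HU-integral thickness, APF,
centerline extraction, selection and aggregation."""

import numpy as np
import pytest
from scipy import ndimage

from airwayct import (
    RunConfig,
    rasterize_phantom,
    single_tube_scene,
    tube_acquisition,
)
from airwayct.airway_quant import (
    Centerline,
    CrossSection,
    LocationMeasurement,
    RadialProfile,
    aggregate_lobes,
    assess_outer_border,
    centerlines_from_truth,
    detect_inner_border,
    extract_centerlines,
    generation_of_location,
    measure_cross_sections,
    measure_wall_ibwt,
    perimeter_to_diameter,
    sample_cross_sections,
    select_fixed_diameter_locations,
    summarize_cross_section,
)
from airwayct.volume import LabelVolume, LUMEN_CODE, TRACHEA_CODE


STEP = 0.01  # fine synthetic-profile step so the 1D oracles are sharp


def make_profile(hu, step=STEP):
    hu = np.asarray(hu, dtype=float)
    return RadialProfile(np.arange(len(hu)) * step, hu, step)


def box_wall_profile(
    inner=1.75, width=0.6, air=-1000.0, wall=0.0, outside=-1000.0,
    sigma=0.0, length=5.0, step=STEP,
):
    """1D oracle: a box wall on asymmetric baselines, optionally convolved
    with a Gaussian of standard deviation ``sigma`` (blur-in-1D reference)."""
    r = np.arange(0.0, length, step)
    hu = np.where(r < inner, air, np.where(r < inner + width, wall, outside))
    if sigma > 0:
        pad = int(np.ceil(5 * sigma / step))
        padded = np.concatenate([np.full(pad, air), hu, np.full(pad, outside)])
        blurred = ndimage.gaussian_filter1d(padded, sigma / step)
        hu = blurred[pad : pad + len(r)]
    return RadialProfile(r, hu, step)


class TestPerimeterToDiameter:
    def test_pi10_equivalent(self):
        assert perimeter_to_diameter(10.0) == pytest.approx(3.18, abs=0.005)

    def test_identity_and_zero(self):
        assert perimeter_to_diameter(np.pi) == pytest.approx(1.0)
        assert perimeter_to_diameter(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            perimeter_to_diameter(-1.0)


class TestDetectInnerBorder:
    def test_ideal_step_found_at_edge(self):
        ray = box_wall_profile(inner=1.75, width=3.0)
        r = detect_inner_border(ray, -1000.0, 0.0)
        assert r == pytest.approx(1.75, abs=STEP)

    def test_blurred_symmetric_edge_stays_at_edge(self):
        # isolated edge: half-max of a blurred symmetric edge is the edge
        ray = box_wall_profile(inner=1.75, width=3.0, sigma=0.3)
        r = detect_inner_border(ray, -1000.0, 0.0)
        assert r == pytest.approx(1.75, abs=STEP)

    def test_all_air_ray_unassessed(self):
        ray = make_profile(np.full(400, -1000.0))
        assert detect_inner_border(ray, -1000.0, 0.0) is None

    def test_sub_step_interpolation(self):
        ray = box_wall_profile(inner=1.753, width=1.0, step=0.1)
        r = detect_inner_border(ray, -1000.0, 0.0)
        assert r == pytest.approx(1.753, abs=0.05)


class TestMeasureWallIBWT:
    def test_unblurred_box_is_exact(self):
        ray = box_wall_profile(inner=1.75, width=0.6)
        t = measure_wall_ibwt(ray, 1.75, -1000.0, 0.0, -1000.0, window_mm=2.0)
        assert t == pytest.approx(0.6, abs=2 * STEP)

    def test_integral_preserved_under_blur_air_both_sides(self):
        ray = box_wall_profile(inner=1.75, width=0.6, sigma=0.4)
        t = measure_wall_ibwt(ray, 1.75, -1000.0, 0.0, -1000.0, window_mm=2.0)
        assert t == pytest.approx(0.6, abs=0.02)

    def test_asymmetric_baselines_with_blur(self):
        ray = box_wall_profile(inner=1.75, width=0.6, outside=-880.0, sigma=0.4)
        t = measure_wall_ibwt(ray, 1.75, -1000.0, 0.0, -880.0, window_mm=2.0)
        assert t == pytest.approx(0.6, abs=0.05)

    @pytest.mark.parametrize("width", [0.4, 0.6, 0.9])
    def test_blur_robust_across_widths(self, width):
        sharp = box_wall_profile(inner=1.75, width=width, outside=-880.0)
        blurred = box_wall_profile(inner=1.75, width=width, outside=-880.0, sigma=0.35)
        t0 = measure_wall_ibwt(sharp, 1.75, -1000.0, 0.0, -880.0)
        t1 = measure_wall_ibwt(blurred, 1.75, -1000.0, 0.0, -880.0)
        assert abs(t0 - t1) < 0.05

    def test_invalid_wall_reference_rejected(self):
        ray = box_wall_profile()
        with pytest.raises(ValueError):
            measure_wall_ibwt(ray, 1.75, -1000.0, -1000.0, -880.0)


class TestAssessOuterBorder:
    def test_clean_outer_edge_detected(self):
        ray = box_wall_profile(inner=1.75, width=0.6, outside=-880.0, sigma=0.3)
        i_peak = int(np.argmax(ray.hu))
        assert assess_outer_border(ray, ray.radii[i_peak], -880.0, 0.0)

    def test_adjacent_same_density_blocks(self):
        # wall continues as soft tissue: profile never descends
        ray = box_wall_profile(inner=1.75, width=10.0)
        i_peak = int(np.argmax(ray.hu))
        assert not assess_outer_border(ray, ray.radii[i_peak], -880.0, 0.0)

    def test_empty_window_is_false(self):
        ray = box_wall_profile(inner=1.75, width=0.6, outside=-880.0)
        i_peak = int(np.argmax(ray.hu))
        assert not assess_outer_border(
            ray, ray.radii[i_peak], -880.0, 0.0, d_max_mm=0.0
        )


class TestSummarizeCrossSection:
    def _section(self, n_rays=8):
        radii = np.arange(0, 5.0, 0.1)
        rays = [RadialProfile(radii, np.zeros_like(radii), 0.1) for _ in range(n_rays)]
        return CrossSection(0, 0, np.zeros(3), "LUL", 5, rays)

    def test_circular_lumen(self):
        cs = self._section()
        cs.inner_radius_mm = np.full(8, 1.75)
        cs.thickness_mm = np.full(8, 0.6)
        cs.assessed = np.ones(8, dtype=bool)
        out = summarize_cross_section(cs)
        assert out.internal_diameter_mm == pytest.approx(3.5)
        assert out.apf_local == 1.0

    def test_partial_assessment_means(self):
        cs = self._section()
        cs.inner_radius_mm = np.full(8, 1.75)
        cs.thickness_mm = np.array([0.5, 0.7] + [np.nan] * 6)
        cs.assessed = np.array([True, True] + [False] * 6)
        out = summarize_cross_section(cs)
        assert out.awt_mm == pytest.approx(0.6)
        assert out.apf_local == pytest.approx(0.25)

    def test_elliptical_lumen_uses_mean_radius_convention(self):
        # eccentric lumen: the mean of the polar ray radii is the documented
        # convention and differs from the equal-area diameter
        n = 32
        theta = 2 * np.pi * np.arange(n) / n
        a, b = 1.2, 2.2
        radii = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        cs = self._section(n)
        cs.inner_radius_mm = radii
        cs.thickness_mm = np.full(n, 0.5)
        cs.assessed = np.ones(n, dtype=bool)
        out = summarize_cross_section(cs)
        expected_mean = 2 * radii.mean()
        equal_area = 2 * np.sqrt(a * b)
        assert out.internal_diameter_mm == pytest.approx(expected_mean, abs=1e-9)
        assert abs(out.internal_diameter_mm - equal_area) > 0.05

    def test_too_few_inner_borders_drops_section(self):
        cs = self._section()
        cs.inner_radius_mm = np.array([1.75, 1.75, 1.75] + [np.nan] * 5)
        cs.thickness_mm = np.full(8, np.nan)
        cs.assessed = np.zeros(8, dtype=bool)
        assert summarize_cross_section(cs) is None


class TestSelectLocations:
    def _sections(self, diameters, apf=1.0):
        out = []
        for d in diameters:
            cs = CrossSection(0, 0, np.zeros(3), "LUL", 5, [])
            cs.internal_diameter_mm = d
            cs.apf_local = apf
            cs.awt_mm = 0.6
            cs.inner_radius_mm = np.full(8, d / 2)
            out.append(cs)
        return out

    def test_interval_selection(self):
        secs = self._sections([3.0, 3.3, 3.5, 3.8])
        kept = select_fixed_diameter_locations(secs, 3.5, 0.25)
        assert sorted(l.internal_diameter_mm for l in kept) == [3.3, 3.5]

    def test_low_apf_excluded(self):
        secs = self._sections([3.5], apf=0.20)
        assert select_fixed_diameter_locations(secs, 3.5, 0.25, min_apf=0.25) == []

    def test_zero_tolerance_keeps_exact_only(self):
        secs = self._sections([3.3, 3.5, 3.8])
        kept = select_fixed_diameter_locations(secs, 3.5, 0.0)
        assert [l.internal_diameter_mm for l in kept] == [3.5]


class TestAggregateLobes:
    def _loc(self, lobe, awt, apf):
        return LocationMeasurement(lobe, 5, 3.5, awt, apf)

    def test_uniform_weights_reduce_to_plain_mean(self):
        locs = [self._loc(l, a, 1.0) for l, a in
                [("LUL", 0.5), ("LLL", 0.6), ("RUL", 0.7)]]
        _, awt, _ = aggregate_lobes(locs)
        assert awt == pytest.approx(0.6)

    def test_weighted_two_lobe_example(self):
        locs = [self._loc("LUL", 0.5, 1.0)] * 100 + [self._loc("LLL", 0.7, 1.0)] * 50
        _, awt, apf_total = aggregate_lobes(locs)
        assert awt == pytest.approx((0.5 * 100 + 0.7 * 50) / 150)
        assert apf_total == pytest.approx(150.0)

    def test_single_lobe_identity(self):
        locs = [self._loc("RML", 0.55, 0.8)]
        summaries, awt, _ = aggregate_lobes(locs)
        assert awt == pytest.approx(0.55)
        assert set(summaries) == {"RML"}

    def test_whole_lung_within_lobe_range(self, rng):
        locs = [
            self._loc(l, rng.uniform(0.4, 0.9), rng.uniform(0.3, 1.0))
            for l in ("LUL", "LLL", "RUL", "RML", "RLL") for _ in range(5)
        ]
        summaries, awt, _ = aggregate_lobes(locs)
        lobe_awts = [s.awt_mm for s in summaries.values()]
        assert min(lobe_awts) - 1e-12 <= awt <= max(lobe_awts) + 1e-12

    def test_zero_apf_flagged(self):
        with pytest.raises(ValueError, match="APF"):
            aggregate_lobes([self._loc("LUL", 0.5, 0.0)])


class TestGenerationOfLocation:
    def test_depths(self, tree_bundle):
        tree = tree_bundle["branches"]
        root = [b for b in tree if b.parent_id is None][0]
        loc = LocationMeasurement("LUL", 0, 12.0, 1.0, 1.0, branch_id=root.branch_id)
        assert generation_of_location(loc, tree) == 0
        # child of root's child
        level1 = [b for b in tree if b.parent_id == root.branch_id][0]
        level2 = [b for b in tree if b.parent_id == level1.branch_id][0]
        loc2 = LocationMeasurement("LUL", 0, 7.0, 1.0, 1.0, branch_id=level2.branch_id)
        assert generation_of_location(loc2, tree) == 2

    def test_orphan_rejected(self):
        loc = LocationMeasurement("LUL", 0, 3.5, 0.6, 1.0, branch_id=777)
        with pytest.raises(ValueError):
            generation_of_location(loc, [])


class TestSampleCrossSections:
    def test_endpoint_inclusive_count(self, tube_bundle):
        cl = Centerline(
            0,
            np.column_stack([np.zeros(21), np.zeros(21), np.linspace(10, 0, 21)]),
            np.tile([0.0, 0.0, -1.0], (21, 1)),
        )
        secs = sample_cross_sections(tube_bundle["ct"], cl, step_mm=1.0)
        assert len(secs) == 11

    def test_axial_tube_rays_stay_in_plane(self, tube_bundle):
        secs = sample_cross_sections(tube_bundle["ct"], tube_bundle["centerline"])
        cs = secs[len(secs) // 2]
        # all rays of an axial tube sample constant z: HU at r=0 equals the
        # lumen center for every ray
        first = [ray.hu[0] for ray in cs.rays]
        assert np.ptp(first) == 0.0

    def test_interpolation_identity_at_voxel_centers(self, tube_bundle):
        ct = tube_bundle["ct"]
        i, j, k = 10, 12, 14
        p = np.array(ct.origin_mm) + np.array(ct.spacing_mm) * [i, j, k]
        cl = Centerline(0, p[None, :], np.array([[0.0, 0.0, 1.0]]))
        secs = sample_cross_sections(
            ct, cl, step_mm=1.0, ray_len_mm=ct.spacing_mm[0] * 3,
            ray_step_mm=ct.spacing_mm[0],
        )
        ray0 = secs[0].rays[0]  # +x direction from a voxel center
        expected = ct.voxels[i : i + 4, j, k][: len(ray0.hu)]
        np.testing.assert_allclose(ray0.hu, expected, atol=1e-9)

    def test_rays_exiting_volume_are_nan(self, tube_bundle):
        ct = tube_bundle["ct"]
        edge = np.array(ct.origin_mm) + [1.0, 1.0, 5.0]
        cl = Centerline(0, edge[None, :], np.array([[0.0, 0.0, 1.0]]))
        secs = sample_cross_sections(ct, cl, ray_len_mm=10.0)
        has_nan = any(np.isnan(ray.hu).any() for ray in secs[0].rays)
        assert has_nan


class TestTubeRecovery:
    def test_wall_thickness_recovered(self, tube_bundle):
        awts = [s.awt_mm for s in tube_bundle["sections"]]
        assert abs(np.nanmean(awts) - 0.6) < 0.05

    def test_diameter_within_band(self, tube_bundle):
        d = np.mean([s.internal_diameter_mm for s in tube_bundle["sections"]])
        assert abs(d - 3.5) <= 0.25

    def test_full_apf_for_isolated_tube(self, tube_bundle):
        apf = np.mean([s.apf_local for s in tube_bundle["sections"]])
        assert apf > 0.95

    def test_measurement_is_deterministic(self, tube_bundle, config):
        secs = measure_cross_sections(
            tube_bundle["ct"], tube_bundle["centerline"], config
        )
        a = np.array([s.awt_mm for s in secs])
        b = np.array([s.awt_mm for s in tube_bundle["sections"]])
        np.testing.assert_array_equal(a, b)


class TestAdjacentVessel:
    @pytest.fixture(scope="class")
    @staticmethod
    def pair(config):
        out = {}
        for vessel in (False, True):
            branches, truth = single_tube_scene(
                3.5, 0.6, length_mm=30.0, adjacent_vessel=vessel,
                vessel_fraction=0.25,
            )
            ct, _ = rasterize_phantom(
                branches, truth, tube_acquisition(noise_sd_hu=25.0, seed=5)
            )
            cl = centerlines_from_truth(branches)[0]
            out[vessel] = measure_cross_sections(ct, cl, config)
        return out

    def test_apf_reduced_by_occluded_fraction(self, pair, config):
        apf = np.mean([s.apf_local for s in pair[True]])
        assert abs((1.0 - apf) - 0.25) <= 1.0 / config.n_rays + 0.02

    def test_inner_radii_unchanged_by_occlusion(self, pair):
        d_clear = np.mean([s.internal_diameter_mm for s in pair[False]])
        d_vessel = np.mean([s.internal_diameter_mm for s in pair[True]])
        assert abs(d_clear - d_vessel) < 0.1


class TestExtractCenterlines:
    def _labels(self, mask, spacing=(0.7, 0.7, 0.7)):
        return LabelVolume(mask.astype(np.int16) * LUMEN_CODE, spacing)

    def test_empty_mask_gives_empty_list(self):
        assert extract_centerlines(self._labels(np.zeros((10, 10, 10)))) == []

    def test_straight_cylinder_axis_recovered(self):
        shape = (31, 31, 60)
        spacing = (0.7, 0.7, 0.7)
        x = (np.arange(shape[0]) - 15.0)[:, None, None] * spacing[0]
        y = (np.arange(shape[1]) - 15.0)[None, :, None] * spacing[1]
        mask = np.broadcast_to(
            np.sqrt(x**2 + y**2) <= 3.0, shape
        ).copy()
        cls = extract_centerlines(self._labels(mask, spacing))
        assert len(cls) == 1
        pts = cls[0].points
        off_axis = np.sqrt(
            (pts[:, 0] - 15 * 0.7) ** 2 + (pts[:, 1] - 15 * 0.7) ** 2
        )
        rms = np.sqrt(np.mean(off_axis**2))
        assert rms < 0.5 * 0.7

    def test_y_mask_topology(self):
        shape = (60, 40, 60)
        mask = np.zeros(shape, dtype=bool)
        # stem along z then two diagonal limbs
        mask[28:33, 18:23, 40:59] = True
        for k in range(25):
            mask[28 - k // 2 : 33 - k // 2, 18:23, 40 - k - 3 : 40 - k] = True
            mask[28 + k // 2 : 33 + k // 2, 18:23, 40 - k - 3 : 40 - k] = True
        cls = extract_centerlines(self._labels(mask))
        assert len(cls) == 3
        gens = sorted(c.generation for c in cls)
        assert gens == [0, 1, 1]

    def test_disconnected_mask_raises(self):
        mask = np.zeros((30, 30, 30), dtype=bool)
        mask[5:9, 5:9, 5:25] = True
        mask[20:24, 20:24, 5:25] = True
        with pytest.raises(ValueError, match="disconnected"):
            extract_centerlines(self._labels(mask))

    def test_tree_generations_match_truth(self, tree_bundle):
        from collections import Counter

        truth_gens = Counter(b.generation for b in tree_bundle["branches"])
        got_gens = Counter(c.generation for c in tree_bundle["centerlines"])
        # the airway tree's depth and breadth are recovered
        assert max(got_gens) >= max(truth_gens) - 1
        for g in range(5):
            assert abs(got_gens.get(g, 0) - truth_gens[g]) <= 1

    def test_tree_lobes_assigned(self, tree_bundle):
        lobes = {c.lobe for c in tree_bundle["centerlines"] if c.generation >= 3}
        assert lobes == {"LUL", "LLL", "RUL", "RML", "RLL"}


class TestFixedDiameterOnTree:
    def test_locations_concentrate_at_caliber_generation(self, tree_bundle, config):
        from collections import Counter

        locs = select_fixed_diameter_locations(
            tree_bundle["sections"], config.target_diameter_mm,
            config.tol_mm, config.min_apf,
        )
        assert len(locs) > 20
        gens = Counter(l.generation for l in locs)
        mode = max(gens, key=gens.get)
        assert mode == 5  # the generation whose true lumen is 3.5 mm
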