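"""Diameter sampling, pore accounting, surface-area estimation."""

import numpy as np
import pytest

from fibermesh import io as fio
from fibermesh import morphometry as morph
from fibermesh import segmentation as seg
from fibermesh.errors import ValidationError


class TestLocalDiameters:
    def test_ribbon_width_recovered_within_one_pixel(self, cal):
        m = np.zeros((40, 160), bool)
        m[17:26, 20:121] = True  # 9 px wide
        sk = seg.skeletonize_mask(m)
        ds = morph.local_diameters(m, sk, cal)
        inc = ds.included_um
        assert inc.size > 0
        assert np.all(np.abs(inc - 0.45) <= 0.05 + 1e-9)  # +- 1 px

    def test_disk_center_reports_its_diameter(self, cal):
        from skimage.morphology import disk

        r = 15
        m = np.zeros((64, 64), bool)
        m[10 : 10 + 2 * r + 1, 10 : 10 + 2 * r + 1] = disk(r).astype(bool)
        sk = seg.skeletonize_mask(m, prune_px=0)
        ds = morph.local_diameters(m, sk, cal)
        assert ds.diameter_um.max() == pytest.approx(2 * r * 0.05, abs=2 * 0.05)

    def test_empty_skeleton_gives_empty_samples(self, cal):
        sk = seg.skeletonize_mask(np.zeros((8, 8), bool))
        ds = morph.local_diameters(np.zeros((8, 8), bool), sk, cal)
        assert len(ds) == 0

    def test_skeleton_outside_mask_rejected(self, cal):
        m = np.zeros((8, 8), bool)
        m[4, 1:6] = True
        sk = seg.skeletonize_mask(m)
        with pytest.raises(ValidationError):
            morph.local_diameters(np.zeros((8, 8), bool), sk, cal)

    def test_mesh_mean_diameter_within_ten_percent_of_truth(self, medium_mesh, cal):
        _, image, truth = medium_mesh
        mask = seg.clean_mask(seg.binarize(image), 16, 0)
        sk = seg.skeletonize_mask(mask)
        ds = morph.local_diameters(mask, sk, cal)
        truth_mean = np.mean([f.diameter_um for f in truth.fibers])
        truth_median = np.median([f.diameter_um for f in truth.fibers])
        st = morph.fiber_stats(ds)
        assert st.mean_um == pytest.approx(truth_mean, rel=0.10)
        assert st.median_um == pytest.approx(truth_median, rel=0.10)
        assert st.positively_skewed  # generating sigma_log = 0.586 >= 0.3


class TestFiberStats:
    def test_hand_computed_example(self):
        st = morph.fiber_stats(np.array([0.2, 0.4, 0.4, 1.0]), min_n=1)
        assert st.mean_um == pytest.approx(0.5)
        assert st.median_um == pytest.approx(0.4)
        assert st.positively_skewed
        assert st.sd_um == pytest.approx(0.3, rel=1e-9)  # population SD

    def test_constant_samples_not_skewed(self):
        st = morph.fiber_stats(np.full(100, 0.5))
        assert st.mean_um == st.median_um == 0.5
        assert st.sd_um == 0.0
        assert not st.positively_skewed
        assert not st.min_n_warning

    def test_reported_mesh_statistics_are_positively_skewed(self):
        # a distribution summarized as mean 0.57, median 0.48 has mean > median
        rng = np.random.default_rng(0)
        d = 0.48 * np.exp(rng.normal(0, 0.586, 5000))
        st = morph.fiber_stats(d)
        assert st.mean_um > st.median_um
        assert st.positively_skewed

    def test_histogram_counts_sum_to_n(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0.05, 1.3, 257)
        st = morph.fiber_stats(d)
        assert st.counts.sum() == st.n == 257
        assert np.all(np.diff(st.bin_edges_um) > 0)

    def test_min_n_warning_below_threshold(self):
        st = morph.fiber_stats(np.array([0.3, 0.4]), min_n=100)
        assert st.min_n_warning

    def test_no_included_samples_is_an_error(self):
        ds = morph.DiameterSamples(
            rows=np.array([1]), cols=np.array([1]),
            diameter_um=np.array([0.5]), excluded=np.array([True]),
        )
        with pytest.raises(ValidationError):
            morph.fiber_stats(ds)


class TestPoreDistribution:
    def test_equivalent_diameter_of_unit_pi_area(self):
        # hole of 100 px at sqrt(pi)/10 um/px has area exactly pi um^2
        m = np.ones((30, 30), bool)
        m[10:20, 10:20] = False
        c = fio.Calibration(um_per_px=np.sqrt(np.pi) / 10)
        pt = morph.pore_distribution(m, c)
        assert len(pt.areas_um2) == 1
        assert pt.areas_um2[0] == pytest.approx(np.pi)
        assert pt.equivalent_diameters_um[0] == pytest.approx(2.0)

    def test_void_area_fractions_by_class(self):
        m = np.ones((40, 60), bool)
        m[10:20, 5:15] = False  # 100 px = 1 um^2 at 0.1 um/px
        m[10:20, 25:55] = False  # 300 px = 3 um^2
        c = fio.Calibration(um_per_px=0.1)
        pt = morph.pore_distribution(m, c, bins_um=(0.0, 1.5))
        assert sorted(pt.areas_um2.tolist()) == pytest.approx([1.0, 3.0])
        # d_eq are 1.13 and 1.95 um -> classes [0,1.5) and [1.5, inf)
        assert pt.class_area_fractions.tolist() == pytest.approx([0.25, 0.75])

    def test_border_touching_pores_excluded_but_counted(self, small_mesh):
        spec, _, truth = small_mesh
        c = fio.Calibration(spec.um_per_px)
        pt = morph.pore_distribution(truth.fiber_mask, c)
        assert pt.border_excluded_count >= 1
        total_px = truth.fiber_mask.size
        assert (
            pt.included_area_px + pt.border_excluded_area_px + pt.fiber_area_px
            == total_px
        )

    def test_all_foreground_gives_empty_table(self, cal):
        pt = morph.pore_distribution(np.ones((16, 16), bool), cal)
        assert len(pt.areas_um2) == 0
        assert pt.border_excluded_count == 0

    def test_class_fractions_sum_to_one_when_pores_exist(self, small_mesh):
        spec, _, truth = small_mesh
        pt = morph.pore_distribution(truth.fiber_mask, fio.Calibration(spec.um_per_px))
        if pt.areas_um2.size:
            assert pt.class_area_fractions.sum() == pytest.approx(1.0)


class TestSurfaceArea:
    def test_a_star_is_pi_d(self):
        assert morph.surface_area_per_unit_length(1.0) == pytest.approx(np.pi)
        assert morph.surface_area_per_unit_length(2.0) == pytest.approx(2 * np.pi)
        # linearity at the mesh scale measured for DMSO-cast fibers
        assert morph.surface_area_per_unit_length(0.51) == pytest.approx(1.6022, abs=5e-4)

    def test_non_positive_diameter_rejected(self):
        with pytest.raises(ValidationError):
            morph.surface_area_per_unit_length(0.0)

    def test_constant_diameter_modes_agree(self, cal):
        # L = 100 um at 0.05 um/px -> 2000 px axial line; d = 0.5 um
        m = np.zeros((40, 2101), bool)
        m[20, 50:2051] = True
        sk = seg.skeletonize_mask(m, prune_px=0)
        ds = morph.DiameterSamples(
            rows=np.argwhere(m)[:, 0],
            cols=np.argwhere(m)[:, 1],
            diameter_um=np.full(int(m.sum()), 0.5),
            excluded=np.zeros(int(m.sum()), bool),
        )
        a = morph.total_surface_area(sk, ds, cal, mode="mean_diameter")
        b = morph.total_surface_area(sk, ds, cal, mode="per_pixel")
        assert a.total_length_um == pytest.approx(100.0)
        assert a.total_area_um2 == pytest.approx(50 * np.pi, rel=1e-6)
        assert b.total_area_um2 == pytest.approx(50 * np.pi, rel=1e-6)

    def test_empty_skeleton_gives_zero_estimate(self, cal):
        sk = seg.skeletonize_mask(np.zeros((8, 8), bool))
        ds = morph.local_diameters(np.zeros((8, 8), bool), sk, cal)
        est = morph.total_surface_area(sk, ds, cal)
        assert est.total_area_um2 == 0.0
        assert est.normalized == 0.0

    def test_per_pixel_matches_both_independent_oracles(self, medium_mesh, cal):
        # oracle 1: generator's analytic sum of pi*d*L
        # oracle 2: cylinder-projection identity pi * (mask area)
        spec, image, truth = medium_mesh
        mask = seg.clean_mask(seg.binarize(image), 16, 0)
        sk = seg.skeletonize_mask(mask)
        ds = morph.local_diameters(mask, sk, cal)
        est = morph.total_surface_area(sk, ds, cal, mode="per_pixel")
        assert est.total_area_um2 == pytest.approx(
            truth.analytic_surface_area_um2, rel=0.15
        )
        mask_area_um2 = truth.fiber_mask.sum() * spec.um_per_px**2
        assert est.total_area_um2 == pytest.approx(np.pi * mask_area_um2, rel=0.15)

    def test_compare_identity_and_forced_ratio(self):
        a = morph.SurfaceAreaEstimate(1.0, 1.0, 1.0, 0.58)
        b = morph.SurfaceAreaEstimate(1.0, 1.0, 1.0, 0.50)
        assert morph.compare_surface_areas(a, a) == pytest.approx(1.0)
        assert morph.compare_surface_areas(a, b) == pytest.approx(1.16)
        with pytest.raises(ValidationError):
            morph.compare_surface_areas(a, morph.SurfaceAreaEstimate(1, 1, 1, 0.0))

    def test_ratio_tracks_coverage_ratio(self, small_mesh, medium_mesh):
        # cylinder-projection identity: normalized per-pixel surface is
        # ~ pi * coverage, so the ratio of two meshes tracks their coverage
        def measure(mesh):
            spec, image, truth = mesh
            c = fio.Calibration(spec.um_per_px)
            mask = seg.clean_mask(seg.binarize(image), 16, 0)
            sk = seg.skeletonize_mask(mask)
            ds = morph.local_diameters(mask, sk, c)
            return morph.total_surface_area(sk, ds, c, "per_pixel"), truth

        est_a, truth_a = measure(small_mesh)
        est_b, truth_b = measure(medium_mesh)
        ratio = morph.compare_surface_areas(est_a, est_b)
        coverage_ratio = truth_a.fiber_area_fraction / truth_b.fiber_area_fraction
        assert ratio == pytest.approx(coverage_ratio, rel=0.10)


class TestScaleEquivariance:
    def test_lengths_scale_linearly_and_areas_quadratically(self, small_mesh):
        _, image, _ = small_mesh
        mask = seg.clean_mask(seg.binarize(image), 16, 0)
        sk = seg.skeletonize_mask(mask)
        results = {}
        for c_factor in (1.0, 2.0):
            c = fio.Calibration(0.05 * c_factor)
            ds = morph.local_diameters(mask, sk, c)
            st = morph.fiber_stats(ds)
            est = morph.total_surface_area(sk, ds, c, "per_pixel")
            pt = morph.pore_distribution(mask, c)
            results[c_factor] = (st, est, pt)
        st1, est1, pt1 = results[1.0]
        st2, est2, pt2 = results[2.0]
        assert st2.mean_um == pytest.approx(2 * st1.mean_um)
        assert st2.median_um == pytest.approx(2 * st1.median_um)
        assert est2.total_length_um == pytest.approx(2 * est1.total_length_um)
        assert est2.total_area_um2 == pytest.approx(4 * est1.total_area_um2)
        assert est2.normalized == pytest.approx(est1.normalized)
        assert pt2.areas_um2 == pytest.approx(4 * pt1.areas_um2)


def test_subsample_per_fiber_one_value_per_label(small_mesh, cal):
    _, image, truth = small_mesh
    mask = seg.clean_mask(seg.binarize(image), 16, 0)
    sk = seg.skeletonize_mask(mask)
    ds = morph.local_diameters(mask, sk, cal)
    per_fiber = morph.subsample_per_fiber(ds, truth.label_image)
    assert 0 < len(per_fiber) <= len(truth.fibers)
    truth_mean = np.mean([f.diameter_um for f in truth.fibers])
    assert per_fiber.mean() == pytest.approx(truth_mean, rel=0.15)
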