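"""Log-polar descriptors, the mean endpoint model and histogram matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cctrace as ct
from cctrace.shape_context import LocalFrame, _END_LABEL, compute_shape_context

import oracles

CFG = ct.LogPolarConfig()


def _frame(angle_deg=0.0, height=10.0):
    rad = np.radians(angle_deg)
    return LocalFrame(end="anterior",
                      reference_dir=np.array([np.cos(rad), -np.sin(rad)]),
                      norm_height_mm=height)


class TestConfig:
    def test_angular_bin_width(self):
        assert CFG.angular_bin_deg == 360.0 / 15 == 24.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ct.ShapeContextError):
            ct.LogPolarConfig(n_angular=1)
        with pytest.raises(ct.ShapeContextError):
            ct.LogPolarConfig(r_min_norm=0.5, r_max_norm=0.1)


class TestComputeShapeContext:
    def test_two_point_contour_single_bin(self):
        h = 10.0
        p = np.array([0.0, 0.0])
        q = np.array([CFG.r_min_norm * h, 0.0])  # angle 0, radius r_min
        hist = compute_shape_context(p, np.vstack([p, q]), _frame(0.0, h), CFG)
        assert hist.bins[0, 0] == 1.0
        assert hist.bins.sum() == 1.0

    def test_toy_contour_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 30, (10, 2))
        frame = _frame(37.0, height=12.0)
        hist = compute_shape_context(pts[0], pts, frame, CFG)
        brute = oracles.shape_context_brute(
            pts[0], pts, frame.reference_dir, 12.0, CFG.n_angular,
            CFG.n_radial, CFG.r_min_norm, CFG.r_max_norm)
        assert np.allclose(hist.bins, brute)

    def test_co_rotation_by_one_angular_bin_is_exact(self):
        # points at mid-bin angles and radii; rotate everything by 24 degrees
        angles = np.radians(np.arange(0, 360, 24) + 7.0)
        radii = np.linspace(2.03, 17.91, len(angles))  # clear of bin edges
        pts = np.column_stack([radii * np.cos(angles),
                               -radii * np.sin(angles)])
        pts = np.vstack([[0.0, 0.0], pts])
        h0 = compute_shape_context(pts[0], pts, _frame(0.0), CFG)
        rad = np.radians(24.0)
        rot = np.array([[np.cos(rad), -np.sin(rad)],
                        [np.sin(rad), np.cos(rad)]])
        pts_up = pts * [1, -1]
        pts_rot = (pts_up @ rot.T) * [1, -1]
        h1 = compute_shape_context(pts_rot[0], pts_rot, _frame(24.0), CFG)
        assert np.array_equal(h0.bins, h1.bins)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_histogram_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-50, 50, (rng.integers(2, 80), 2))
        hist = compute_shape_context(pts[0], pts, _frame(rng.uniform(0, 360)),
                                     CFG)
        assert abs(hist.bins.sum() - 1.0) < 1e-9
        assert np.all(hist.bins >= 0)

    def test_insufficient_contour_error(self):
        with pytest.raises(ct.ShapeContextError, match="insufficient contour"):
            compute_shape_context([0, 0], [[0, 0]], _frame(), CFG)

    def test_scale_invariance_under_mask_upsampling(self, cc_sample):
        mask = cc_sample.mask
        an1 = ct.analyze_mask(mask, CFG)
        big = ct.BinaryMask(np.kron(mask.grid, np.ones((2, 2), np.uint8)),
                            pixel_size_mm=mask.pixel_size_mm / 2)
        an2 = ct.analyze_mask(big, CFG)
        h1 = compute_shape_context(an1.samples[0], an1.samples,
                                   an1.frames["anterior"], CFG,
                                   mask.pixel_size_mm)
        j = np.argmin(np.linalg.norm(an2.samples - 2 * an1.samples[0], axis=1))
        h2 = compute_shape_context(an2.samples[j], an2.samples,
                                   an2.frames["anterior"], CFG,
                                   big.pixel_size_mm)
        assert np.abs(h1.bins - h2.bins).max() < 0.05


class TestLocalFrame:
    def test_reference_dirs_mirror_on_symmetric_arch(self):
        yy, xx = np.mgrid[:60, :121]
        x, y_up = xx - 60.0, 55.0 - yy
        r = np.hypot(x, y_up)
        g = ((r >= 35) & (r <= 50) & (y_up >= 0)).astype(np.uint8)
        mask = ct.BinaryMask(g)
        frame = ct.oriented_frame(mask)
        part = ct.partition_cc(mask, frame)
        fa = ct.local_frame(part, frame, "anterior").reference_dir
        fp = ct.local_frame(part, frame, "posterior").reference_dir
        # mirror images about the vertical symmetry axis; both are sign-fixed
        # anterior-to-posterior, so x-components match and y-components flip
        assert abs(fa[0] - fp[0]) < np.sin(np.radians(2.0))
        assert abs(fa[1] + fp[1]) < np.sin(np.radians(2.0))

    def test_rotation_equivariance_of_reference_dirs(self):
        # rotating the shape rotates the local reference frames with it
        def dirs(rotation):
            s = ct.generate_cc(ct.SyntheticSpec(
                seed=11, boundary_noise_sigma_px=0.0, rotation_deg=rotation))
            an = ct.analyze_mask(s.mask, CFG)
            return {end: an.frames[end].reference_dir
                    for end in ("anterior", "posterior")}

        d0, d1 = dirs(0.0), dirs(12.0)
        for end in ("anterior", "posterior"):
            cos = np.clip(d0[end] @ d1[end], -1, 1)
            sin = d0[end][0] * -d1[end][1] - -d0[end][1] * d1[end][0]
            turned = np.degrees(np.arctan2(sin, cos))
            assert abs(turned - 12.0) < 5.0

    def test_degenerate_subregion_falls_back(self, caplog):
        import logging
        part_dirs = np.full((5, 2), np.nan)
        from cctrace.geometry import Partition
        part = Partition(labels=np.zeros((4, 4), np.int8),
                         divider_origin=np.zeros(2),
                         ray_angles_deg=np.arange(4.0),
                         fan_angles_deg=(0.0, 180.0),
                         subregion_centroids=np.zeros((5, 2)),
                         subregion_major_dirs=part_dirs)
        from cctrace.geometry import OrientedFrame
        frame = OrientedFrame(centroid=np.zeros(2),
                              major_dir=np.array([1.0, 0.0]),
                              minor_dir=np.array([0.0, 1.0]),
                              rect_corners=np.zeros((4, 2)),
                              rect_length_mm=10, rect_height_mm=5,
                              orientation_deg=0.0)
        with caplog.at_level(logging.WARNING, logger="cctrace.shape_context"):
            lf = ct.local_frame(part, frame, "posterior")
        assert np.allclose(lf.reference_dir, [1.0, 0.0])
        assert any("falling back" in r.message for r in caplog.records)


class TestBuildModel:
    def test_single_sample_model_equals_its_histogram(self, gen):
        s = gen(5)
        model = ct.build_model(
            [(s.mask, s.true_anterior, s.true_posterior)])
        assert model.n_training == 1
        model2 = ct.build_model(
            [(s.mask, s.true_anterior, s.true_posterior)] * 2)
        assert np.allclose(model.anterior_hist.bins, model2.anterior_hist.bins)
        assert np.allclose(model.posterior_hist.bins,
                           model2.posterior_hist.bins)

    def test_mean_matches_naive_accumulation(self, gen, trained_model):
        samples = [gen(s) for s in range(1000, 1015)]
        acc = np.zeros_like(trained_model.anterior_hist.bins)
        for s in samples:
            single = ct.build_model(
                [(s.mask, s.true_anterior, s.true_posterior)])
            acc = acc + single.anterior_hist.bins
        assert np.allclose(trained_model.anterior_hist.bins, acc / 15)

    def test_model_histograms_normalised(self, trained_model):
        assert trained_model.anterior_hist.bins.sum() == pytest.approx(1.0)
        assert trained_model.posterior_hist.bins.sum() == pytest.approx(1.0)

    def test_off_boundary_label_rejected(self, gen):
        s = gen(5)
        centroid = ct.oriented_frame(s.mask).centroid
        with pytest.raises(ct.ShapeContextError,
                           match="endpoint not on boundary"):
            ct.build_model([(s.mask, centroid, s.true_posterior)])


class TestLocalize:
    def test_self_match_returns_labelled_point(self, gen):
        # label the contour start pixel: it is both a boundary pixel and a
        # resampled point, so its own histogram matches the K=1 model exactly
        s = gen(5)
        an = ct.analyze_mask(s.mask, CFG)
        label = an.samples[0]
        model = ct.build_model([(s.mask, label, s.true_posterior)])
        found = ct.localize_endpoint(s.mask, model, ct.ANTERIOR,
                                     candidate_mode="all")
        assert np.array_equal(found, label)

    def test_matches_exhaustive_search(self, gen, trained_model):
        s = gen(8)
        an = ct.analyze_mask(s.mask, trained_model.config)
        for end in (ct.ANTERIOR, ct.POSTERIOR):
            found = ct.localize_endpoint(s.mask, trained_model, end,
                                         analysis=an)
            cand = np.nonzero(an.sample_labels == _END_LABEL[end])[0]
            best, best_cost = None, np.inf
            for j in cand:
                brute = oracles.shape_context_brute(
                    an.samples[j], an.samples,
                    an.frames[end].reference_dir,
                    an.frames[end].norm_height_mm,
                    CFG.n_angular, CFG.n_radial,
                    CFG.r_min_norm, CFG.r_max_norm)
                cost = np.abs(trained_model.hist(end).bins - brute).sum()
                if cost < best_cost:
                    best, best_cost = j, cost
            assert np.array_equal(found, an.samples[best])

    def test_no_candidates_error(self, gen, trained_model):
        s = gen(5)
        an = ct.analyze_mask(s.mask, trained_model.config)
        an.sample_labels[:] = 3
        with pytest.raises(ct.ShapeContextError, match="no candidates"):
            ct.localize_endpoint(s.mask, trained_model, ct.ANTERIOR,
                                 analysis=an)

    @pytest.mark.parametrize("rotation", [-10.0, 0.0, 10.0])
    def test_rotation_tolerance_noise_free(self, gen, rotation):
        # rotations within one angular bin leave the detection within 2 px
        train = [ct.generate_cc(ct.SyntheticSpec(
            seed=s, boundary_noise_sigma_px=0.0)) for s in range(1000, 1015)]
        model = ct.build_model([(s.mask, s.true_anterior, s.true_posterior)
                                for s in train])
        s = ct.generate_cc(ct.SyntheticSpec(
            seed=3, boundary_noise_sigma_px=0.0, rotation_deg=rotation))
        an = ct.analyze_mask(s.mask, model.config)
        for end, truth in ((ct.ANTERIOR, s.true_anterior),
                           (ct.POSTERIOR, s.true_posterior)):
            found = ct.localize_endpoint(s.mask, model, end, analysis=an)
            assert np.linalg.norm(found - truth) <= 2.0
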