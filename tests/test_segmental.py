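"""Morphology pipelines: preprocessing, thresholds, watershed, skeletons."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from orgdyn.segmental import (
    MitoConfig,
    PreprocessConfig,
    analyze_regions,
    isodata_threshold,
    mito_segment,
    mito_skeleton_stats,
    moments_threshold,
    preprocess_vesicle_frame,
    segment_vesicle_frame,
    size_filter,
    split_touching,
    top_fraction_mask,
)
from oracles import (
    isodata_fixed_points,
    moments_threshold_bruteforce,
    random_histogram_image,
)

PX = 0.04  # µm per pixel used throughout


def _disc(shape, cy, cx, r, value=1.0, img=None):
    img = np.zeros(shape) if img is None else img
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = value
    return img


class TestPreprocess:
    def test_constant_image_becomes_zero(self):
        out = preprocess_vesicle_frame(np.full((128, 128), 7.0))
        assert np.allclose(out, 0.0)

    def test_hot_pixel_removed_by_despeckle(self):
        img = np.zeros((128, 128))
        img[64, 64] = 100.0
        out = preprocess_vesicle_frame(img)
        assert out[64, 64] == 0.0

    def test_contrast_of_blob_on_ramp_not_degraded(self):
        yy, xx = np.mgrid[:128, :128]
        ramp = 0.3 * xx / 128.0
        img = _disc((128, 128), 64, 64, 8, 1.0) + ramp
        def contrast(a):
            fg = a[60:69, 60:69].mean()
            bg = np.median(a)
            return (fg - bg) / (a.max() - a.min() + 1e-12)
        out = preprocess_vesicle_frame(img)
        assert contrast(out) >= contrast(img) - 1e-9

    def test_rejects_tiny_frames(self):
        with pytest.raises(ValueError, match="rolling-ball"):
            preprocess_vesicle_frame(np.zeros((20, 20)))


class TestThresholds:
    def test_moments_separates_two_deltas(self):
        img = np.array([10.0] * 500 + [200.0] * 500)
        t = moments_threshold(img)
        assert 10.0 < t < 200.0
        assert np.array_equal(img > t, img >= 200.0)

    @pytest.mark.parametrize("trial", range(25))
    def test_moments_matches_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        img = random_histogram_image(rng, trial)
        t = moments_threshold(img)
        t_oracle = moments_threshold_bruteforce(img)
        assert np.array_equal(img > t, img > t_oracle)

    def test_moments_affine_invariant_partition(self, rng):
        img = random_histogram_image(rng, 0)
        t1 = moments_threshold(img)
        t2 = moments_threshold(3.0 * img + 17.0)
        assert np.array_equal(img > t1, (3.0 * img + 17.0) > t2)

    def test_moments_constant_image_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            moments_threshold(np.full(100, 3.0))

    def test_isodata_two_deltas_near_midpoint_of_means(self):
        img = np.array([10.0] * 500 + [200.0] * 500)
        t = isodata_threshold(img)
        assert abs(t - 105.0) <= (img.max() - img.min()) / 256

    @pytest.mark.parametrize("trial", range(25))
    def test_isodata_is_an_intermeans_fixed_point(self, trial):
        rng = np.random.default_rng(300 + trial)
        img = random_histogram_image(rng, trial)
        t = isodata_threshold(img)
        fps = isodata_fixed_points(img)
        assert fps, "oracle found no fixed point"
        binw = (img.max() - img.min()) / 256
        assert min(abs(t - f) for f in fps) <= binw

    def test_isodata_fixed_point_property_directly(self, rng):
        img = random_histogram_image(rng, 2)
        t = isodata_threshold(img)
        mb, ma = img[img <= t].mean(), img[img > t].mean()
        binw = (img.max() - img.min()) / 256
        assert abs(t - 0.5 * (mb + ma)) <= 1.5 * binw


class TestTopFractionMask:
    def test_keeps_top_quarter_of_range(self):
        img = np.zeros((10, 10))
        img[0, 0] = 200.0
        img[5, 5] = 151.0
        img[6, 6] = 149.0
        m = top_fraction_mask(img, 0.25)
        assert m[0, 0] and m[5, 5] and not m[6, 6]

    def test_uniform_and_full_fraction(self):
        assert top_fraction_mask(np.full((4, 4), 3.0), 0.25).all()
        img = np.arange(16.0).reshape(4, 4)
        assert top_fraction_mask(img, 1.0).all()

    def test_zero_frame_gives_empty_mask(self):
        assert not top_fraction_mask(np.zeros((4, 4))).any()


class TestSizeFilter:
    def test_paper_cutoff_in_um2(self):
        # 0.05 µm² (31 px) removed, 0.07 µm² (44 px) kept at 0.04 µm/px
        m = np.zeros((64, 64), bool)
        m[2:4, 2:18] = True  # 32 px = 0.0512 µm²
        m[30:34, 30:41] = True  # 44 px = 0.0704 µm²
        out = size_filter(m, 0.06, PX)
        assert not out[2, 2] and out[30, 30]

    def test_empty_and_identity(self):
        m = np.zeros((8, 8), bool)
        assert not size_filter(m, 0.06, PX).any()
        m[2:6, 2:6] = True
        assert np.array_equal(size_filter(m, 0.0, PX), m)

    def test_monotone_in_min_area(self, quiet_frame):
        p, truth, stack = quiet_frame
        img = stack.channel("organelle")[0]
        mask = img > 0.5 * img.max()
        counts = [
            ndi.label(size_filter(mask, a, PX))[1] for a in (0.0, 0.06, 0.2, 0.5)
        ]
        assert counts == sorted(counts, reverse=True)


class TestSplitTouching:
    def test_two_overlapping_discs_split_along_saddle(self):
        # dome-profile discs (bright centres) so the pair shows two
        # intensity peaks with a saddle at the waist
        shape = (80, 80)
        yy, xx = np.mgrid[: shape[0], : shape[1]]

        def dome(cy, cx, r):
            d2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / r**2
            return np.clip(1.0 - d2, 0.0, None)

        img = np.maximum(dome(40, 30, 12), dome(40, 46, 12))
        img = ndi.gaussian_filter(img, 1.0)
        mask = img > 0.15 * img.max()
        lab = split_touching(mask, img, 0.05 * (img.max() - img.min()))
        assert lab.max() == 2
        # ≥95 % of pixels agree with nearest-centre assignment
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        truth = np.where(
            (yy - 40) ** 2 + (xx - 30) ** 2 <= (yy - 40) ** 2 + (xx - 46) ** 2,
            1,
            2,
        )
        m = mask
        a = lab[m]
        b = truth[m]
        agree = max(
            np.mean(a == b), np.mean(a == (3 - b))
        )  # label order is arbitrary
        assert agree >= 0.95

    def test_single_disc_single_label_identical_to_mask(self):
        img = ndi.gaussian_filter(_disc((64, 64), 32, 32, 10), 2.0)
        mask = img > 0.4 * img.max()
        lab = split_touching(mask, img, 0.05)
        assert lab.max() == 1
        assert np.array_equal(lab > 0, mask)

    def test_huge_prominence_preserves_components(self):
        img = np.maximum(
            _disc((80, 80), 40, 25, 10), _disc((80, 80), 40, 55, 10)
        )
        mask = img > 0.5
        lab = split_touching(mask, img, 10.0)  # above global max
        assert lab.max() == 2  # two components kept whole

    def test_labels_partition_the_mask(self, quiet_frame):
        p, truth, stack = quiet_frame
        img = stack.channel("organelle")[0]
        lab = segment_vesicle_frame(img, p.pixel_size_um)
        mask = lab > 0
        # disjoint by construction; union covers every labelled pixel
        assert (np.bincount(lab.ravel())[1:] > 0).all()
        assert mask.sum() == sum(np.bincount(lab.ravel())[1:])


class TestAnalyzeRegions:
    def test_disc_circularity_close_to_one(self):
        lab = _disc((128, 128), 64, 64, 50).astype(int)
        rec = analyze_regions(lab, PX)[0]
        assert 0.95 <= 4 * np.pi * rec.area_um2 / rec.perimeter_um**2 <= 1.05

    def test_area_arithmetic(self):
        lab = np.zeros((20, 20), int)
        lab[5:15, 5:15] = 1  # 100 px
        rec = analyze_regions(lab, PX)[0]
        assert rec.area_um2 == pytest.approx(0.16)

    def test_thin_rectangle_circularity_formula(self):
        # continuous 1x9 rectangle: 4π·9/40² ≈ 0.283; digital Crofton
        # perimeter deviates a little, so compare loosely
        lab = np.zeros((30, 30), int)
        lab[10:11, 5:14] = 1
        rec = analyze_regions(lab, PX)[0]
        assert rec.circularity == pytest.approx(0.283, abs=0.12)

    def test_empty_label_image(self):
        assert analyze_regions(np.zeros((8, 8), int), PX) == []

    def test_translation_and_rotation_invariance(self):
        img = _disc((100, 100), 40, 40, 15)
        lab1 = img.astype(int)
        lab2 = np.zeros_like(lab1)
        lab2[20:, 30:] = lab1[:-20, :-30]  # translate
        lab3 = np.rot90(lab1)
        r1 = analyze_regions(lab1, PX)[0]
        for lab in (lab2, lab3):
            r = analyze_regions(lab, PX)[0]
            assert r.area_um2 == pytest.approx(r1.area_um2, rel=0.02)
            assert r.circularity == pytest.approx(r1.circularity, rel=0.02)


class TestMito:
    def test_flat_image_yields_no_labels(self):
        assert mito_segment(np.zeros((128, 128)), PX).max() == 0

    def test_two_disjoint_tubules_two_labels(self):
        img = np.zeros((128, 128))
        img[30:36, 20:100] = 1.0
        img[80:86, 20:100] = 1.0
        img = ndi.gaussian_filter(img, 1.5)
        assert mito_segment(img, PX).max() == 2

    def test_straight_bar_one_branch_full_length(self):
        bar = np.zeros((50, 120), int)
        bar[20:25, 10:110] = 1
        rec = mito_skeleton_stats(bar, PX)[0]
        assert rec.branch_count == 1
        # thinning retracts ~half the bar width from each end
        assert 0.95 * 4.0 <= rec.skeleton_length_um <= 4.01

    def test_symmetric_y_three_branches(self):
        img = np.zeros((201, 201), bool)
        for ang in (90, 210, 330):
            th = np.deg2rad(ang)
            for s in range(51):
                y, x = int(100 + s * np.sin(th)), int(100 + s * np.cos(th))
                img[y - 2 : y + 3, x - 2 : x + 3] = True
        rec = mito_skeleton_stats(img.astype(int), PX)[0]
        assert rec.branch_count == 3
        assert rec.branches_per_um == pytest.approx(
            3 / rec.skeleton_length_um
        )

    def test_per_label_stats_are_local(self):
        bar = np.zeros((60, 120), int)
        bar[10:15, 10:110] = 1
        single = mito_skeleton_stats(bar, PX)
        bar2 = bar.copy()
        bar2[40:45, 10:110] = 2
        both = mito_skeleton_stats(bar2, PX)
        assert both[0].skeleton_length_um == single[0].skeleton_length_um
        assert both[0].branch_count == single[0].branch_count

    def test_single_pixel_skeleton_convention(self):
        lab = np.zeros((16, 16), int)
        lab[8, 8] = 1
        rec = mito_skeleton_stats(lab, PX)[0]
        assert rec.branch_count == 0
        assert rec.skeleton_length_um == pytest.approx(PX)

    def test_network_recovery_on_synthetic_tubules(self):
        from orgdyn.synthgen import SynthParams, render_stack, simulate_trajectories

        p = SynthParams(
            seed=1,
            n_organelles=6,
            organelle_shape="network",
            mean_radius_um=0.12,
            fission_rate_per_org_per_min=0.0,
            n_frames=2,
            field_size_px=(384, 384),
            diffusion_coeff_um2_s=0.0002,
        )
        truth = simulate_trajectories(p)
        stack = render_stack(truth, p)
        lab = mito_segment(stack.channel("organelle")[0], p.pixel_size_um)
        assert lab.max() == 6
        # labelled foreground covers >= 95 % of the true mask
        true_mask = truth.label_stack()[0] > 0
        assert ((lab > 0) & true_mask).sum() / true_mask.sum() >= 0.95
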