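import numpy as np
import pytest
from dataclasses import replace

import oracles as O

from turpeval import (
    Label,
    PhantomSpec,
    SkillProfile,
    build_phantom,
    circularity,
    evaluate_case,
    min_peripheral_thickness,
    preservation_ratio,
    simulate_resection,
    smoothness,
)
from turpeval.metrics import (
    SliceMetrics,
    mask_area_mm2,
    mask_convex_area_mm2,
    mask_perimeter_mm,
    slice_metrics,
)
from turpeval.phantom import AMATEUR, EXPERT


def annulus(outer_px, inner_px, offset_px=0, n=None):
    n = n or 2 * outer_px + 21
    c = n // 2
    yy, xx = np.mgrid[:n, :n]
    lab = np.zeros((n, n), np.uint8)
    lab[(yy - c) ** 2 + (xx - c) ** 2 <= outer_px ** 2] = Label.PERIPHERAL
    lab[(yy - c) ** 2 + (xx - c - offset_px) ** 2 <= inner_px ** 2] = Label.CENTRAL
    return lab


def disc_mask(r, pad=6):
    n = 2 * (r + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    return ((yy - r - pad) ** 2 + (xx - r - pad) ** 2) <= r * r


class TestMinPeripheralThickness:
    def test_concentric_annulus(self):
        assert min_peripheral_thickness(annulus(100, 50), 0.1) == pytest.approx(5.0, abs=0.1)

    def test_breach_gives_zero(self):
        lab = annulus(50, 25)
        lab[lab.shape[0] // 2, :] = Label.CENTRAL  # cut a channel to the border
        assert min_peripheral_thickness(lab, 0.1) == 0.0

    def test_eccentric_annulus_matches_brute_force(self):
        # inner disc (r = 5 mm) offset 2 mm inside an outer 10 mm disc
        lab = annulus(100, 50, offset_px=20)
        got = min_peripheral_thickness(lab, 0.1)
        assert got == pytest.approx(O.min_thickness_oracle(lab, 0.1), abs=1e-9)
        assert got == pytest.approx(3.0, abs=0.1)  # 10 - 5 - 2 mm

    def test_no_peripheral_is_nan(self):
        lab = np.full((32, 32), Label.CENTRAL, np.uint8)
        assert np.isnan(min_peripheral_thickness(lab, 0.1))


class TestSmoothness:
    def test_disc_cavity_stack_is_one(self):
        # fine grid so rasterization error of the hull stays below 0.01
        spec = PhantomSpec(n_slices=5)
        pre = build_phantom(spec)
        post, _ = simulate_resection(pre, SkillProfile())
        post_m = [slice_metrics(post[k], k, spec.pixel_spacing_mm)
                  for k in range(post.n_slices)]
        assert smoothness(post_m) == pytest.approx(1.0, abs=0.01)

    def test_plus_shape_frozen_value(self):
        plus = np.zeros((15, 15), bool)
        plus[3:12, 6:9] = True
        plus[6:9, 3:12] = True
        area = mask_area_mm2(plus, 1.0)
        hull = mask_convex_area_mm2(plus, 1.0)
        assert (area, hull) == (45.0, 57.0)
        assert area / hull == pytest.approx(45 / 57)
        assert hull == pytest.approx(O.convex_area_oracle(plus))

    def test_rougher_cavity_is_less_smooth(self, small_phantom):
        base = dict(asymmetry_offset_mm=0.0, seed=4)
        mild, _ = simulate_resection(small_phantom, SkillProfile(roughness_amplitude=0.1, **base))
        rough, _ = simulate_resection(small_phantom, SkillProfile(roughness_amplitude=0.3, **base))
        px = small_phantom.pixel_spacing_mm
        sm_mild = smoothness([slice_metrics(mild[k], k, px) for k in range(mild.n_slices)])
        sm_rough = smoothness([slice_metrics(rough[k], k, px) for k in range(rough.n_slices)])
        assert sm_rough < sm_mild

    def test_solidity_bounded(self, small_phantom):
        post, _ = simulate_resection(small_phantom, replace(AMATEUR, seed=9))
        for k in range(post.n_slices):
            m = slice_metrics(post[k], k, small_phantom.pixel_spacing_mm)
            if m.valid:
                assert 0.0 < m.a_uret_mm2 <= m.a_conv_mm2
                assert m.a_uret_mm2 / m.a_conv_mm2 <= 1.0


class TestCircularity:
    def test_analytic_disc_exact(self):
        r = 3.7
        assert circularity(np.pi * r ** 2, 2 * np.pi * r) == pytest.approx(1.0)

    def test_square_cavity(self):
        sq = np.zeros((140, 140), bool)
        sq[10:130, 10:130] = True
        c = circularity(mask_area_mm2(sq, 0.1), mask_perimeter_mm(sq, 0.1))
        assert c == pytest.approx(np.pi / 4, abs=0.02)

    def test_digital_disc_r50(self):
        m = disc_mask(50)
        c = circularity(mask_area_mm2(m, 0.1), mask_perimeter_mm(m, 0.1))
        assert 0.98 <= c <= 1.02

    def test_translation_and_rot90_invariance(self):
        m = np.zeros((90, 90), bool)
        m[20:50, 30:55] = True
        m[35:60, 40:70] = True
        def circ(mask):
            return circularity(mask_area_mm2(mask, 1.0), mask_perimeter_mm(mask, 1.0))
        base = circ(m)
        assert circ(np.roll(m, (7, -5), axis=(0, 1))) == pytest.approx(base, rel=1e-9)
        assert circ(np.rot90(m)) == pytest.approx(base, rel=1e-9)

    def test_scale_convergence(self):
        cs = [circularity(mask_area_mm2(disc_mask(r), 1.0),
                          mask_perimeter_mm(disc_mask(r), 1.0)) for r in (10, 30, 80)]
        assert abs(cs[-1] - 1.0) < abs(cs[0] - 1.0) + 0.01
        assert cs[-1] == pytest.approx(1.0, abs=0.01)

    def test_degenerate_region_invalid(self):
        lab = annulus(30, 1)
        lab[lab == Label.CENTRAL] = Label.CAVITY
        m = slice_metrics(lab, 0, 0.1)
        assert not m.valid and m.reason == "degenerate cavity"


class TestRatios:
    @staticmethod
    def _metrics(t=1.0, a=10.0, conv=10.0, p=11.2, c=1.0, valid=True, i=0):
        return SliceMetrics(index=i, t_min_peri_mm=t, a_uret_mm2=a, a_conv_mm2=conv,
                            p_uret_mm=p, circularity=c, valid=valid)

    def test_preservation_identity(self):
        pre = [self._metrics(t=4.0, i=i) for i in range(5)]
        assert preservation_ratio(pre, pre) == 1.0

    def test_preservation_half_breached(self):
        pre = [self._metrics(t=4.0, i=i) for i in range(10)]
        post = [self._metrics(t=(0.0 if i < 5 else 4.0), i=i) for i in range(10)]
        assert preservation_ratio(pre, post) == pytest.approx(0.5)

    def test_preservation_matches_breach_record_expectation(self):
        # circular cross-sections so the recorded radial breach depth predicts
        # the post-surgery minimum thickness: t_aft ~ min(t_bef, depth*(1-f)/f)
        spec = PhantomSpec(width_mm=36, depth_mm=36, pixel_spacing_mm=0.2, n_slices=16)
        pre = build_phantom(spec)
        f = 0.5
        skill = SkillProfile(breach_probability=1.0, breach_depth_fraction=f, seed=21)
        post, record = simulate_resection(pre, skill)
        case = evaluate_case(pre, post)
        depth = {ev.slice_index: ev.max_depth_mm for ev in record}
        expected = []
        for i, m in enumerate(case.pre):
            if not m.valid:
                continue
            t_bef = m.t_min_peri_mm
            t_aft = min(t_bef, depth[i] * (1 - f) / f) if i in depth else t_bef
            expected.append(t_aft / t_bef)
        assert case.r_pres == pytest.approx(np.mean(expected), abs=0.05)

    def test_circularity_ratio_scale_invariant(self):
        pre = [self._metrics(c=0.91)]
        post = [self._metrics(c=0.91)]
        from turpeval import circularity_ratio
        assert circularity_ratio(pre, post) == pytest.approx(1.0)
        # rasterized: similar discs at two scales
        c_small = circularity(mask_area_mm2(disc_mask(25), 1.0), mask_perimeter_mm(disc_mask(25), 1.0))
        c_big = circularity(mask_area_mm2(disc_mask(75), 1.0), mask_perimeter_mm(disc_mask(75), 1.0))
        assert c_big / c_small == pytest.approx(1.0, abs=0.02)

    def test_disc_pre_square_post(self):
        from turpeval import circularity_ratio
        m = disc_mask(60)
        sq = np.zeros((140, 140), bool)
        sq[10:130, 10:130] = True
        pre = [self._metrics(c=circularity(mask_area_mm2(m, 0.1), mask_perimeter_mm(m, 0.1)))]
        post = [self._metrics(c=circularity(mask_area_mm2(sq, 0.1), mask_perimeter_mm(sq, 0.1)))]
        assert circularity_ratio(pre, post) == pytest.approx(np.pi / 4, abs=0.02)

    def test_expert_beats_amateur_over_seeds(self, small_phantom):
        r_expert, r_amateur = [], []
        for seed in range(10):
            for profile, out in ((EXPERT, r_expert), (AMATEUR, r_amateur)):
                post, _ = simulate_resection(small_phantom, replace(profile, seed=seed))
                out.append(evaluate_case(small_phantom, post).r_circ)
        assert np.mean(r_expert) > np.mean(r_amateur)


class TestEvaluateCase:
    def test_identity_case(self, small_phantom):
        case = evaluate_case(small_phantom, small_phantom)
        assert case.r_pres == 1.0
        assert case.r_circ == pytest.approx(1.0)
        assert case.r_smoo > 0.9  # urethra disc is a few pixels wide here
        assert case.n == small_phantom.n_slices

    def test_n_counts_valid_pairs(self, small_phantom):
        post, _ = simulate_resection(small_phantom, SkillProfile(seed=1))
        case = evaluate_case(small_phantom, post)
        n_valid = sum(1 for a, b in zip(case.pre, case.post) if a.valid and b.valid)
        assert case.n == n_valid

    def test_ground_truth_vs_noise_free_segmentation(self, small_phantom, noise_free):
        from turpeval import SegmentationParams, render_ultrasound, segment_stack
        post, _ = simulate_resection(small_phantom, SkillProfile(roughness_amplitude=0.15, seed=2))
        gt = evaluate_case(small_phantom, post)
        params = SegmentationParams()
        seg_pre = segment_stack(render_ultrasound(small_phantom, noise_free), params)
        seg_post = segment_stack(render_ultrasound(post, noise_free), params)
        seg = evaluate_case(seg_pre.labels, seg_post.labels)
        assert seg.r_pres == pytest.approx(gt.r_pres, abs=1e-3)
        assert seg.r_smoo == pytest.approx(gt.r_smoo, abs=1e-3)
        assert seg.r_circ == pytest.approx(gt.r_circ, abs=1e-3)

    def test_mismatched_lengths_truncate(self, small_phantom):
        from turpeval.volume import LabelVolume
        short = LabelVolume(small_phantom.data[:10], small_phantom.pixel_spacing_mm,
                            small_phantom.slice_spacing_mm)
        case = evaluate_case(small_phantom, short)
        assert len(case.pre) == 10

    def test_all_invalid_errors(self):
        from turpeval.volume import LabelVolume
        blank = LabelVolume(np.zeros((3, 16, 16), np.uint8), 0.2, 0.5)
        with pytest.raises(ValueError, match="no valid"):
            evaluate_case(blank, blank)


class TestOracleEquivalence:
    """Spot equivalence on random masks (the full 100-mask sweep runs in the
    acceptance suite)."""

    @pytest.mark.parametrize("seed", range(5))
    def test_random_mask_agreement(self, seed):
        from skimage.data import binary_blobs
        from scipy import ndimage
        m = binary_blobs(length=64, blob_size_fraction=0.25, volume_fraction=0.35, rng=seed)
        lab, n = ndimage.label(m)
        assert n > 0
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        m = ndimage.binary_fill_holes(lab == np.argmax(sizes) + 1)
        assert mask_convex_area_mm2(m, 1.0) == pytest.approx(O.convex_area_oracle(m), abs=2.0)
        assert mask_perimeter_mm(m, 1.0) == pytest.approx(O.traced_contour_length(m), rel=1e-6)
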