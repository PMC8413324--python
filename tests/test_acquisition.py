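"""Biopsy planning, section detection and rigid stack alignment."""

import numpy as np
import pytest
from scipy import ndimage

from cortex3d.acquisition import (RigidTransform2D, SectionDetectParams,
                                  align_stack, detect_sections,
                                  plan_biopsies)


def textured_image(shape=(512, 512), seed=0, blur=6):
    rng = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(rng.random(shape), blur)
    return (base - base.min()) / np.ptp(base) * 255.0


def rigid_move(img, angle_deg, dx, dy):
    rot = ndimage.rotate(img, -angle_deg, reshape=False, order=1,
                         mode="nearest")
    return ndimage.shift(rot, (dy, dx), order=1, mode="nearest")


class TestPlanBiopsies:
    full_poly = [(0, 0), (0, 99), (99, 99), (99, 0)]

    def test_uniform_mask_quartile_rows(self):
        img = np.full((100, 100), 255.0)
        plan = plan_biopsies(img, self.full_poly, biopsy_diameter_px=8,
                             seed=0)
        # uniform cumulative sum: quartiles at rows 24/49/74 (0-based)
        assert plan.quartile_rows == (24, 49, 74)
        assert plan.chosen_quarters in ((1, 3), (2, 4))

    def test_thin_stripe_erosion_annihilates(self):
        img = np.zeros((100, 100))
        img[:, 40:60] = 255.0   # 20-px-wide stripe
        with pytest.raises(ValueError, match="too small"):
            plan_biopsies(img, self.full_poly, biopsy_diameter_px=40,
                          seed=0)

    def test_erosion_matches_brute_force_disk_test(self):
        rng = np.random.default_rng(4)
        img = (ndimage.gaussian_filter(rng.random((60, 60)), 5) > 0.5) \
            * 255.0
        if not img.any() or img.all():
            pytest.skip("degenerate random blob")
        poly = [(0, 0), (0, 59), (59, 59), (59, 0)]
        radius = 3
        plan = plan_biopsies(img, poly, biopsy_diameter_px=2 * radius,
                             seed=0)
        sample = plan.sample_mask
        yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
        disk = (yy ** 2 + xx ** 2) <= radius ** 2
        brute = np.zeros_like(sample)
        for r in range(radius, sample.shape[0] - radius):
            for c in range(radius, sample.shape[1] - radius):
                patch = sample[r - radius:r + radius + 1,
                               c - radius:c + radius + 1]
                brute[r, c] = bool(np.all(patch[disk]))
        assert np.array_equal(plan.eroded_mask.astype(bool),
                              brute.astype(bool))

    def test_deterministic_and_clear_of_boundary(self):
        img = np.full((120, 120), 255.0)
        poly = [(0, 0), (0, 119), (119, 119), (119, 0)]
        p1 = plan_biopsies(img, poly, biopsy_diameter_px=14, seed=7)
        p2 = plan_biopsies(img, poly, biopsy_diameter_px=14, seed=7)
        assert p1.chosen_points == p2.chosen_points
        for r, c in p1.chosen_points:
            assert p1.eroded_mask[r, c]


class TestDetectSections:
    @staticmethod
    def montage(seed=1):
        rng = np.random.default_rng(seed)
        img = np.full((360, 520), 230.0)
        corners = [(30 + r * 170, 30 + c * 165) for r in range(2)
                   for c in range(3)]
        for r0, c0 in corners:
            img[r0:r0 + 120, c0:c0 + 120] = \
                120 + 60 * rng.random((120, 120))
        return img, corners

    def test_constant_image_zero_sections_with_warning(self):
        det = detect_sections(np.full((100, 100), 50.0))
        assert det.n_sections == 0
        assert det.warnings

    def test_six_rectangles_in_reading_order(self):
        img, corners = self.montage()
        det = detect_sections(img, SectionDetectParams(min_area=2000))
        assert det.n_sections == 6
        # bottom-right to top-left: rows bottom-up, right-to-left within
        expected = sorted(corners, key=lambda t: (-t[0], -t[1]))
        for (r0, c0, r1, c1), (tr, tc) in zip(det.boxes, expected):
            assert abs(r0 - tr) < 15 and abs(c0 - tc) < 15

    def test_systematic_sampling_every_second(self):
        img, _ = self.montage()
        det_all = detect_sections(img, SectionDetectParams(min_area=2000))
        det_k2 = detect_sections(img, SectionDetectParams(min_area=2000,
                                                          every_k=2))
        assert det_k2.n_sections == 3
        assert det_k2.boxes == det_all.boxes[::2]   # sections 1, 3, 5

    def test_padding_invariance(self):
        img, _ = self.montage()
        det = detect_sections(img, SectionDetectParams(min_area=2000))
        pad = 40
        det_p = detect_sections(np.pad(img, pad, constant_values=230.0),
                                SectionDetectParams(min_area=2000))
        assert det_p.n_sections == det.n_sections
        shifted = [(r0 - pad, c0 - pad, r1 - pad, c1 - pad)
                   for (r0, c0, r1, c1) in det_p.boxes]
        for a, b in zip(shifted, det.boxes):
            assert np.allclose(a, b, atol=3)


class TestAlignStack:
    def test_identical_images_identity_transforms(self):
        img = textured_image(seed=2)
        tfs, aligned = align_stack([img, img.copy()])
        assert abs(tfs[1].angle_deg) < 0.1
        assert abs(tfs[1].dx) < 0.5 and abs(tfs[1].dy) < 0.5

    def test_recovers_known_rotation_and_shift(self):
        img = textured_image(seed=0)
        mov = rigid_move(img, 3.0, 10.0, -5.0)
        tfs, aligned = align_stack([img, mov])
        t = tfs[1]
        assert t.angle_deg == pytest.approx(3.0, abs=0.2)
        # translation about the image centre (the applied convention)
        c = (np.array(img.shape[::-1]) - 1) / 2.0
        rot = t.matrix[:2, :2]
        t_center = np.array([t.dx, t.dy]) - (np.eye(2) - rot) @ c
        assert np.allclose(t_center, (10.0, -5.0), atol=1.0)

    def test_alignment_improves_stack_correlation(self):
        rng = np.random.default_rng(5)
        img = textured_image(seed=5)
        imgs = [img]
        cur = img
        for _ in range(5):
            cur = rigid_move(cur, rng.uniform(-2, 2), rng.uniform(-6, 6),
                             rng.uniform(-6, 6))
            imgs.append(cur)

        def ncc(a, b):
            a = (a - a.mean()) / a.std()
            b = (b - b.mean()) / b.std()
            return float((a * b).mean())

        tfs, aligned = align_stack(imgs)
        pre = np.mean([ncc(imgs[i], imgs[i + 1]) for i in range(5)])
        post = np.mean([ncc(aligned[i], aligned[i + 1]) for i in range(5)])
        assert post > pre

    def test_idempotent_on_aligned_stack(self):
        img = textured_image(seed=0)
        mov = rigid_move(img, 2.0, 6.0, -4.0)
        _, aligned = align_stack([img, mov])
        tfs2, _ = align_stack(aligned)
        assert abs(tfs2[1].angle_deg) < 0.1
        assert abs(tfs2[1].dx) < 0.5 and abs(tfs2[1].dy) < 0.5

    def test_transform_composition_inverse(self):
        t = RigidTransform2D(17.0, 4.0, -2.5)
        ident = t.compose(t.inverse())
        assert abs(ident.angle_deg) < 1e-9
        assert abs(ident.dx) < 1e-9 and abs(ident.dy) < 1e-9

    def test_single_image_rejected(self):
        with pytest.raises(ValueError):
            align_stack([textured_image()])
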