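"""Picking, extraction, 2D classification, class identification, counting."""

import numpy as np
import pytest
from scipy import stats

from shotgunem.density import Orientation, project, rotate_image, shift_image
from shotgunem.em2d import (
    ParticleStack,
    classify_2d,
    count_state_ratio,
    dog_pick,
    extract_particles,
    match_class_averages,
)
from shotgunem.synthdata import render_micrograph, render_particle_stack


def disk_annulus(n=32):
    yy, xx = np.indices((n, n))
    r = np.hypot(yy - n / 2, xx - n / 2)
    return (r < 8).astype(float), ((r > 5) & (r < 10)).astype(float)


def two_shape_stack(n_per=100, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    disk, ann = disk_annulus()
    imgs, labels = [], []
    for base, lab in ((disk, 0), (ann, 1)):
        for _ in range(n_per):
            dx, dy = rng.integers(-2, 3, 2)
            img = shift_image(rotate_image(base, rng.uniform(0, 360)), dx, dy)
            if noise > 0:
                img = img + rng.normal(0, noise, img.shape)
            imgs.append(img)
            labels.append(lab)
    return ParticleStack(np.stack(imgs), 1.0), np.array(labels)


def purity(assignments, labels, K):
    correct = 0
    for k in range(K):
        mask = assignments == k
        if mask.any():
            correct += np.bincount(labels[mask]).max()
    return correct / len(labels)


class TestDogPick:
    def test_blank_micrograph_zero_picks(self):
        assert len(dog_pick(np.zeros((256, 256)), 6, 12, 1.0, 20)) == 0

    def test_recall_precision_on_planted_micrograph(self, capped_barrel, heptamer):
        # SNR 2 within particle boxes
        clean = render_micrograph([capped_barrel, heptamer], [0.5, 0.5], 50,
                                  (768, 768), 0.0, 40, seed=4)
        sig = np.mean(
            [clean.image[y - 16 : y + 16, x - 16 : x + 16].var()
             for x, y, _, _ in clean.truth]
        )
        noise = np.sqrt(sig / 2.0)
        mg = render_micrograph([capped_barrel, heptamer], [0.5, 0.5], 50,
                               (768, 768), noise, 40, seed=4)
        picks = dog_pick(mg, r_min=8, r_max=16, threshold=1.0, min_distance=24)
        truth = np.array([(x, y) for x, y, _, _ in mg.truth], dtype=float)
        tp, used = 0, set()
        for px, py in picks:
            d = np.hypot(truth[:, 0] - px, truth[:, 1] - py)
            j = int(np.argmin(d))
            if d[j] <= 16 and j not in used:  # 0.5 x box matching radius
                tp += 1
                used.add(j)
        assert tp / len(picks) >= 0.9  # precision
        assert tp / len(truth) >= 0.9  # recall

    def test_min_distance_enforced(self, capped_barrel, heptamer):
        mg = render_micrograph([capped_barrel, heptamer], [0.5, 0.5], 30,
                               (700, 700), 1.0, 40, seed=2)
        picks = dog_pick(mg, 8, 16, 0.5, 24)
        if len(picks) > 1:
            d = np.hypot(picks[:, None, 0] - picks[None, :, 0],
                         picks[:, None, 1] - picks[None, :, 1]).astype(float)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 24

    def test_bad_radii_rejected(self):
        with pytest.raises(ValueError):
            dog_pick(np.zeros((64, 64)), 12, 8)


class TestExtract:
    def test_centered_box(self):
        img = np.zeros((128, 128))
        img[64, 64] = 7.0
        stack = extract_particles(img, [(64, 64)], 32)
        assert stack.images[0][16, 16] == 7.0

    def test_edge_center_skipped(self):
        img = np.zeros((128, 128))
        stack = extract_particles(img, [(1, 1), (64, 64)], 64)
        assert len(stack) == 1 and list(stack.ids) == [1]

    def test_box_larger_than_micrograph_rejected(self):
        with pytest.raises(ValueError):
            extract_particles(np.zeros((32, 32)), [(16, 16)], 64)


class TestClassify2D:
    def test_single_class_average_is_mean_of_aligned(self):
        stack, _ = two_shape_stack(n_per=10, seed=1)
        classes, assign, align = classify_2d(stack, 1, 30.0, 2, 4, seed=0)
        assert len(classes) == 1 and classes[0].count == len(stack)
        assert np.all(assign == 0)

    def test_noiseless_two_shape_purity_is_one(self):
        stack, labels = two_shape_stack(n_per=100, seed=0)
        _, assign, _ = classify_2d(stack, 2, 15.0, 3, 10, seed=1)
        assert purity(assign, labels, 2) == 1.0

    def test_deterministic(self):
        stack, _ = two_shape_stack(n_per=20, noise=0.5, seed=2)
        _, a1, al1 = classify_2d(stack, 2, 30.0, 2, 5, seed=9)
        _, a2, al2 = classify_2d(stack, 2, 30.0, 2, 5, seed=9)
        assert np.array_equal(a1, a2) and np.array_equal(al1, al2)

    def test_objective_non_decreasing(self):
        # mean best-correlation should not degrade across iterations
        stack, _ = two_shape_stack(n_per=30, noise=1.0, seed=3)
        nccs = []
        for it in (1, 3, 6):
            _, _, align = classify_2d(stack, 2, 30.0, 2, it, seed=4)
            nccs.append(align[:, 3].mean())
        assert nccs[1] >= nccs[0] - 1e-6 and nccs[2] >= nccs[1] - 1e-6

    def test_k_larger_than_stack_rejected(self):
        stack, _ = two_shape_stack(n_per=2, seed=0)
        with pytest.raises(ValueError):
            classify_2d(stack, 10, 30.0, 2, 2, seed=0)


class TestMatchClassAverages:
    def test_identity_match_is_exact(self):
        disk, ann = disk_annulus()
        m = match_class_averages([disk], [("disk", disk), ("ann", ann)], 15.0, 3)
        assert m[0].reference_id == "disk"
        assert m[0].ncc == pytest.approx(1.0, abs=1e-6)

    def test_rotation_recovered_within_step(self, capped_barrel):
        # asymmetric projection so the in-plane angle is identifiable
        ref = project(capped_barrel.volume, Orientation(0, 90, 0)).image
        rotated = rotate_image(ref, 25.0)
        m = match_class_averages([rotated], [("side", ref)], 5.0, 3)
        # matching applies the angle to the class; expect ~ -25 deg mod 360
        err = min(abs(m[0].in_plane_rotation - 335.0),
                  360 - abs(m[0].in_plane_rotation - 335.0))
        assert err <= 5.0

    def test_ncc_invariant_under_affine_rescale(self):
        disk, ann = disk_annulus()
        m1 = match_class_averages([ann], [("ann", ann)], 30.0, 2)
        m2 = match_class_averages([3.0 * ann + 1.0], [("ann", ann)], 30.0, 2)
        # invariance holds to the float32 working precision of the aligner
        assert m1[0].ncc == pytest.approx(m2[0].ncc, abs=1e-6)

    def test_empty_library_rejected(self):
        disk, _ = disk_annulus()
        with pytest.raises(ValueError):
            match_class_averages([disk], [], 30.0, 2)

    def test_heptamer_vs_barrel_discrimination(self, heptamer, barrel):
        """Ring class average identified against a two-shape reprojection library."""
        hep_top = project(heptamer.volume, Orientation(0, 0, 0)).image
        lib = [
            ("hep_top", project(heptamer.volume, Orientation(0, 0, 0)).image),
            ("hep_side", project(heptamer.volume, Orientation(0, 90, 0)).image),
            ("barrel_top", project(barrel.volume, Orientation(0, 0, 0)).image),
            ("barrel_side", project(barrel.volume, Orientation(0, 90, 0)).image),
        ]
        rng = np.random.default_rng(0)
        noisy = hep_top + rng.normal(0, 0.1 * hep_top.std(), hep_top.shape)
        m = match_class_averages([noisy], lib, 10.0, 3)
        assert m[0].reference_id.startswith("hep")
        barrel_best = max(
            match_class_averages([noisy], [x for x in lib if "barrel" in x[0]],
                                 10.0, 3),
            key=lambda mm: mm.ncc,
        )
        assert m[0].ncc - barrel_best.ncc >= 0.1


class TestCountStateRatio:
    def test_three_to_two(self):
        assign = np.array([0] * 60 + [1] * 40)
        sc = count_state_ratio(assign, {0: "core", 1: "capped"}, "core", "capped")
        assert sc.ratio == 1.5 and (sc.count_a, sc.count_b) == (60, 40)

    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            count_state_ratio(np.zeros(10, int), {0: "core"}, "core", "capped")

    def test_ci_matches_clopper_pearson(self):
        assign = np.array([0] * 60 + [1] * 40)
        sc = count_state_ratio(assign, {0: "a", 1: "b"}, "a", "b")
        lo = stats.beta.ppf(0.025, 60, 41)
        hi = stats.beta.ppf(0.975, 61, 40)
        assert sc.ci_low == pytest.approx(lo, abs=1e-9)
        assert sc.ci_high == pytest.approx(hi, abs=1e-9)

    def test_unlabelled_classes_ignored(self):
        assign = np.array([0, 0, 1, 1, 2, 2])
        sc = count_state_ratio(assign, {0: "a", 1: "b"}, "a", "b")
        assert (sc.count_a, sc.count_b) == (2, 2)
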