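"""Fitting: candidate initialisation, loss, gradients, frame and sequence."""

import numpy as np
import pytest
from scipy import ndimage

from crystalsizer import (
    CrystalAngles,
    FitConfig,
    HexTemplate,
    SceneParams,
    SequenceParams,
    fit_frame,
    fit_sequence,
    generate_growth_sequence,
    init_candidates,
    loss,
    loss_grad,
    polygon_vertices,
    render_hard_mask,
    render_soft_mask,
    template_errors,
)
from crystalsizer.hexfit import _pack, _unpack

from conftest import random_active_template


def iou(a, b):
    a, b = a.astype(bool), b.astype(bool)
    return (a & b).sum() / (a | b).sum()


class TestInitCandidates:
    def test_theta_grid_spacing(self, angles):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[20:40, 20:40] = 1
        cands = init_candidates(mask, angles, 8)
        thetas = [c.theta1 for c in cands]
        np.testing.assert_allclose(np.diff(thetas), 22.5)

    def test_projection_init_recovers_truth_distances(self, angles):
        truth = HexTemplate(
            center=np.array([64.0, 64.0]), theta1=0.0,
            dists=np.array([[15.0, 17.0], [30.0, 33.0], [31.0, 29.0]]),
        )
        mask = render_hard_mask(truth, (128, 128))
        cand = init_candidates(mask, angles, 1)[0]  # grid puts theta1 at 0
        de, te = template_errors(cand, truth)
        assert te < 1e-9
        assert de.max() <= 1.0

    def test_deterministic(self, angles):
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask[10:20, 8:25] = 1
        a = init_candidates(mask, angles, 5, seed=1)
        b = init_candidates(mask, angles, 5, seed=1)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.dists, y.dists)

    def test_empty_mask_rejected(self, angles):
        with pytest.raises(ValueError):
            init_candidates(np.zeros((16, 16)), angles, 1)


class TestLoss:
    def test_exact_render_gives_near_zero_mse(self, needle_template):
        cfg = FitConfig(sharpness=100.0, weights=(1.0, 0.0, 0.0, 0.0))
        target = render_hard_mask(needle_template, (128, 128))
        total, terms = loss(needle_template, target, None, cfg)
        assert total <= 1e-4

    def test_symmetry_term_squared_gap(self):
        """A (5, 3) distance pair contributes (5-3)^2 = 4."""
        t = HexTemplate(
            center=np.array([16.0, 16.0]), theta1=0.0,
            dists=np.array([[5.0, 3.0], [4.0, 4.0], [4.0, 4.0]]),
        )
        cfg = FitConfig(weights=(0.0, 0.0, 1.0, 0.0))
        target = render_hard_mask(t, (32, 32))
        total, terms = loss(t, target, None, cfg)
        assert total == pytest.approx(4.0)
        assert terms["sym"] == pytest.approx(4.0)

    def test_disjoint_masks_mse_is_area_sum_over_n(self):
        cfg = FitConfig(sharpness=100.0, weights=(1.0, 0.0, 0.0, 0.0))
        a = HexTemplate(center=np.array([8.3, 8.6]), theta1=0.0,
                        dists=np.full((3, 2), 3.0), rel_angles=(60.0, -60.0))
        b = HexTemplate(center=np.array([24.3, 23.6]), theta1=0.0,
                        dists=np.full((3, 2), 3.0), rel_angles=(60.0, -60.0))
        target = render_hard_mask(b, (32, 32))
        a1 = render_hard_mask(a, (32, 32)).sum()
        a2 = target.sum()
        total, _ = loss(a, target, None, cfg)
        assert total == pytest.approx((a1 + a2) / 32**2, rel=0.05)

    def test_temporal_term_zero_without_prev(self, needle_template):
        cfg = FitConfig()
        target = render_hard_mask(needle_template, (128, 128))
        _, terms = loss(needle_template, target, None, cfg)
        assert terms["temporal"] == 0.0
        prev = needle_template.copy()
        prev.dists = prev.dists + 2.0
        _, terms = loss(needle_template, target, prev, cfg)
        assert terms["temporal"] == pytest.approx(6 * 4.0)

    def test_shape_mismatch_rejected(self, needle_template):
        with pytest.raises(ValueError):
            loss(needle_template, np.zeros((4, 4, 4)), None, FitConfig())


class TestGradients:
    def test_analytic_gradient_matches_central_differences(self):
        """Hand-derived gradients of the composite loss agree with finite
        differences on random small instances."""
        rng = np.random.default_rng(21)
        cfg = FitConfig(sharpness=1.2, weights=(1.0, 1e-4, 1e-4, 1e-3))
        for _ in range(5):
            truth = random_active_template(rng, shape=(64, 64), lo=8.0, hi=22.0)
            target = render_hard_mask(truth, (64, 64)).astype(float)
            t = truth.copy()
            t.center = t.center + rng.uniform(-3, 3, 2)
            t.theta1 += rng.uniform(-8, 8)
            t.dists = np.clip(t.dists + rng.uniform(-3, 3, (3, 2)), 1.0, None)
            prev = truth.copy()
            g = loss_grad(t, target, prev, cfg)
            p0 = _pack(t)
            for i in range(9):
                h = 1e-5 * max(1.0, abs(p0[i]))
                pp, pm = p0.copy(), p0.copy()
                pp[i] += h
                pm[i] -= h
                lp, _ = loss(_unpack(pp, t.rel_angles), target, prev, cfg)
                lm, _ = loss(_unpack(pm, t.rel_angles), target, prev, cfg)
                fd = (lp - lm) / (2 * h)
                assert abs(g[i] - fd) / max(abs(fd), 1e-10) < 1e-4, i


class TestFitFrame:
    def test_noiseless_recovery(self, angles, fast_cfg):
        rng = np.random.default_rng(2)
        truth = random_active_template(rng)
        mask = render_hard_mask(truth, (128, 128))
        fit = fit_frame(mask, init_candidates(mask, angles, fast_cfg.n_candidates), fast_cfg)
        de, te = template_errors(fit.template, truth)
        assert de.max() <= 1.0
        assert te <= 1.0
        assert iou(render_hard_mask(fit.template, (128, 128)), mask) >= 0.98

    def test_salt_and_pepper_mask_recovery(self, angles, fast_cfg):
        rng = np.random.default_rng(4)
        truth = random_active_template(rng)
        mask = render_hard_mask(truth, (128, 128)).astype(bool)
        noisy = mask ^ (rng.random(mask.shape) < 0.05)
        cleaned = ndimage.binary_fill_holes(
            ndimage.binary_opening(noisy)
        ).astype(np.uint8)
        fit = fit_frame(cleaned, init_candidates(cleaned, angles, fast_cfg.n_candidates), fast_cfg)
        assert iou(render_hard_mask(fit.template, (128, 128)), mask) >= 0.95

    def test_sumdist_weight_shrinks_area(self, angles, needle_template):
        mask = render_hard_mask(needle_template, (128, 128))
        inits = init_candidates(mask, angles, 4)
        lean = fit_frame(mask, inits, FitConfig(n_candidates=4, weights=(1, 0, 1e-6, 0)))
        heavy = fit_frame(mask, inits, FitConfig(n_candidates=4, weights=(1, 3e-4, 1e-6, 0)))
        assert (
            render_hard_mask(heavy.template, (128, 128)).sum()
            <= render_hard_mask(lean.template, (128, 128)).sum()
        )

    def test_loss_history_non_increasing(self, angles, needle_template, fast_cfg):
        mask = render_hard_mask(needle_template, (128, 128))
        fit = fit_frame(mask, init_candidates(mask, angles, 4), fast_cfg)
        h = np.array(fit.loss_history)
        assert len(h) >= 2
        assert np.all(np.diff(h) <= 1e-15)

    def test_grown_out_face_still_converges(self, angles, needle_template, fast_cfg):
        t = needle_template.copy()
        t.dists[1, 0] = 90.0  # face grown out of the outline
        mask = render_hard_mask(t, (160, 160))
        fit = fit_frame(mask, init_candidates(mask, angles, fast_cfg.n_candidates), fast_cfg)
        assert fit.converged
        assert len(polygon_vertices(fit.template, min_edge=1.0)) == 5
        assert iou(render_hard_mask(fit.template, (160, 160)), mask) >= 0.98

    def test_no_candidates_rejected(self, needle_template):
        with pytest.raises(ValueError):
            fit_frame(np.ones((8, 8)), [], FitConfig())


@pytest.fixture(scope="module")
def small_sequence():
    truth0 = HexTemplate(
        center=np.array([64.0, 66.0]), theta1=100.0,
        dists=np.array([[12.0, 13.0], [26.0, 28.0], [27.0, 25.0]]),
    )
    rates = np.array([[0.1, 0.15], [0.9, 1.0], [0.95, 0.85]])
    p = SequenceParams(
        scene=SceneParams(template=truth0, shape=(160, 160), seed=8),
        rates=rates, n_frames=8,
    )
    return p, generate_growth_sequence(p)


class TestFitSequence:
    def test_tracked_sequence_recovers_distances(self, small_sequence, fast_cfg):
        p, (images, truths, times) = small_sequence
        res = fit_sequence(images, times, (0, tuple(truths[0].center)), fast_cfg)
        assert res.failed_at is None
        for fit, truth in zip(res.fits, truths):
            de, _ = template_errors(fit.template, truth)
            assert de.max() <= 1.5

    def test_selection_frame_invariance(self, small_sequence, fast_cfg):
        p, (images, truths, times) = small_sequence
        r0 = fit_sequence(images, times, (0, tuple(truths[0].center)), fast_cfg)
        r5 = fit_sequence(images, times, (5, tuple(truths[5].center)), fast_cfg)
        for a, b in zip(r0.fits, r5.fits):
            pa = a.template.dists.sum(axis=1)
            pb = b.template.dists.sum(axis=1)
            assert np.abs(pa - pb).max() <= 1.0

    def test_single_frame_equals_fit_frame(self, angles, needle_template, fast_cfg):
        mask = render_hard_mask(needle_template, (128, 128))
        res = fit_sequence([mask], [0.0], (0, tuple(needle_template.center)), fast_cfg)
        direct = fit_frame(
            mask, init_candidates(mask, angles, fast_cfg.n_candidates, fast_cfg.seed), fast_cfg
        )
        de, te = template_errors(res.fits[0].template, direct.template)
        assert de.max() < 0.1 and te < 0.1

    def test_partial_results_on_failure(self, small_sequence, fast_cfg):
        p, (images, truths, times) = small_sequence
        broken = list(images)
        broken[5] = np.full_like(broken[5], 0.5)  # uniform frame: no crystal
        res = fit_sequence(broken, times, (2, tuple(truths[2].center)), fast_cfg)
        assert res.failed_at == 5
        assert res.error
        assert all(res.fits[i] is not None for i in range(5))
        assert all(f is None for f in res.fits[5:])

    def test_empty_sequence_rejected(self, fast_cfg):
        with pytest.raises(ValueError):
            fit_sequence([], [], (0, (0, 0)), fast_cfg)
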