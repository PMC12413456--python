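"""Event simulator: rendering, event conversion, noise and distributions."""

import numpy as np
import pytest
from scipy import stats

from covrf.events import (
    EventMovie,
    MotionSpec,
    ShapeSpec,
    _sample_movie_params,
    frames_to_events,
    generate_movie,
    make_dataset,
    render_shape,
    sparsity,
)


class TestRendering:
    def test_circle_centroid_matches_label(self):
        spec = ShapeSpec("circle", 80.0, (150.0, 150.0))
        grid = render_shape(spec, resolution=2400)
        ys, xs = np.nonzero(grid)
        f = 2400 / 300
        cx_expected = (150.0 + 0.5) * f - 0.5
        assert abs(xs.mean() - cx_expected) < 0.5
        assert abs(ys.mean() - cx_expected) < 0.5

    def test_square_fourfold_symmetry(self):
        a = render_shape(ShapeSpec("square", 60.0, (150.0, 150.0), 0.0))
        b = render_shape(
            ShapeSpec("square", 60.0, (150.0, 150.0), np.pi / 2)
        )
        # identical up to the 1-px rasterization of the sampled outline
        assert (a ^ b).sum() / a.sum() < 0.02

    def test_contour_mass_scales_with_diameter(self):
        counts = []
        for d in (10, 20, 40, 80):
            g = render_shape(ShapeSpec("circle", float(d), (150.0, 150.0)))
            counts.append(g.sum())
        counts = np.asarray(counts, dtype=float)
        ratios = counts / counts[0] / np.array([1.0, 2.0, 4.0, 8.0])
        assert np.all(np.abs(ratios - 1.0) < 0.1)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            ShapeSpec("circle", -1.0, (0.0, 0.0))
        with pytest.raises(ValueError):
            ShapeSpec("hexagon", 10.0, (0.0, 0.0))


class TestFramesToEvents:
    def test_no_change_no_events(self):
        f = np.random.default_rng(0).random((16, 16)).astype(np.float32)
        acc = np.zeros_like(f)
        ev, acc2 = frames_to_events(f, f, acc, 0.5)
        assert ev.sum() == 0
        assert np.allclose(acc2, 0.0)

    def test_single_step_crossing(self):
        prev = np.zeros((8, 8), np.float32)
        cur = prev.copy()
        cur[3, 4] = 1.0
        ev, acc = frames_to_events(cur, prev, np.zeros_like(prev), 0.5)
        assert ev[0].sum() == 1 and ev[0, 3, 4] == 1
        assert ev[1].sum() == 0
        assert np.isclose(acc[3, 4], 0.5)

    def test_oscillation_matches_running_sum_oracle(self):
        """Events appear exactly when the integrated difference crosses the
        threshold (brute-force accumulator oracle on one pixel)."""
        rng = np.random.default_rng(5)
        deltas = rng.uniform(-0.3, 0.3, 10)
        thr = 0.5
        intensities = np.concatenate([[0.0], np.cumsum(deltas)])
        acc = np.zeros((1, 1), np.float32)
        events = []
        for t in range(1, len(intensities)):
            ev, acc = frames_to_events(
                np.array([[intensities[t]]], np.float32),
                np.array([[intensities[t - 1]]], np.float32),
                acc, thr,
            )
            events.append(int(ev[0, 0, 0]) - int(ev[1, 0, 0]))
        # oracle: running accumulator with threshold resets
        a, expected = 0.0, []
        for d in deltas:
            a += d
            if a >= thr:
                expected.append(1)
                a -= thr
            elif a <= -thr:
                expected.append(-1)
                a += thr
            else:
                expected.append(0)
        assert events == expected

    def test_event_conservation(self):
        """Net (positive - negative) event mass per pixel equals the net
        intensity change divided by the threshold, within one event."""
        movie = generate_movie(
            [ShapeSpec("square", 40.0, (140.0, 160.0))],
            MotionSpec((0.9, -0.4), 0.0),
            noise_rate=0.0, seed=3,
        )
        thr = movie.meta["threshold"]
        net_events = movie.frames[:, 0].astype(int).sum(axis=0) - \
            movie.frames[:, 1].astype(int).sum(axis=0)
        # reconstruct net intensity change from first/last rendered frames
        from covrf.events import _paste_shape, _shape_at

        first = np.zeros((300, 300), np.float32)
        last = np.zeros((300, 300), np.float32)
        spec = ShapeSpec("square", 40.0, (140.0, 160.0))
        mot = MotionSpec((0.9, -0.4), 0.0)
        _paste_shape(first, _shape_at(spec, mot, 0.0, 300)[0], 300, 8)
        _paste_shape(last, _shape_at(spec, mot, 50.0, 300)[0], 300, 8)
        expected = (last - first) / thr
        assert np.max(np.abs(net_events - expected)) <= 1.0 + 1e-6


class TestGenerateMovie:
    def test_static_noise_free_is_empty(self):
        m = generate_movie(
            [ShapeSpec(g, 30.0 + 10 * i, (80.0 + 60 * i, 150.0))
             for i, g in enumerate(("triangle", "square", "circle"))],
            MotionSpec((0.0, 0.0), 0.0),
            noise_rate=0.0, seed=0,
        )
        assert m.frames.sum() == 0
        assert sparsity(m) == 0.0

    def test_deterministic_per_seed(self):
        a = make_dataset("spatial", 2, seed=11, resolution=64)
        b = make_dataset("spatial", 2, seed=11, resolution=64)
        for x, y in zip(a, b):
            assert (x.frames == y.frames).all()
            assert (x.labels == y.labels).all()

    def test_movie_contract(self):
        movies = make_dataset("temporal", 3, seed=2, resolution=64)
        for m in movies:
            assert m.frames.shape == (50, 2, 64, 64)
            assert m.labels.shape == (50, 3, 2)
            assert m.frames.dtype == np.uint8
            assert set(np.unique(m.frames)) <= {0, 1}
            assert (m.labels >= 0).all() and (m.labels < 64).all()
        splits = [m.meta["split"] for m in movies]
        assert "validation" in splits and "train" in splits

    def test_label_centroid_tracks_trajectory(self):
        """Noise-free event centroids follow the ground-truth trajectory."""
        m = generate_movie(
            [ShapeSpec("circle", 50.0, (120.0, 150.0))],
            MotionSpec((0.8, 0.5), 0.0),
            noise_rate=0.0, seed=0,
        )
        errs = []
        for t in range(5, m.n_frames):
            ys, xs = np.nonzero(m.frames[t].any(axis=0))
            if len(xs) < 5:
                continue
            errs.append(np.hypot(xs.mean() - m.labels[t, 0, 0],
                                 ys.mean() - m.labels[t, 0, 1]))
        assert np.mean(errs) < 2.0

    def test_noise_only_matches_binomial(self):
        """Per-movie Bernoulli noise: active-pixel count within 3 SD."""
        m = generate_movie([], [], noise_rate=5.0, seed=9)
        n_pix = 300 * 300
        p = 5.0 / 1000
        hits = m.frames.any(axis=(0, 1)).sum()
        sd = np.sqrt(n_pix * p * (1 - p))
        assert abs(hits - n_pix * p) < 3 * sd
        # sparsity spreads those events over 50 frames
        assert sparsity(m) == pytest.approx(hits / (50 * n_pix) * 1000)

    def test_single_event_sparsity_counting(self):
        frames = np.zeros((50, 2, 300, 300), np.uint8)
        frames[10, 0, 5, 5] = 1
        m = EventMovie(frames=frames, labels=np.zeros((50, 3, 2)))
        assert sparsity(m) == pytest.approx(1000 / (50 * 300 * 300))


class TestDatasetDistributions:
    def test_spatial_sizes_log_uniform(self):
        """KS test of log starting sizes against Uniform(log 10, log 80)."""
        rng = np.random.default_rng(0)
        sizes = []
        for _ in range(1000):
            shapes, _, _ = _sample_movie_params(rng, "spatial", 300, None)
            sizes.extend(s.size for s in shapes)
        logs = np.log(sizes)
        u = (logs - np.log(10.0)) / (np.log(80.0) - np.log(10.0))
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_sparsity_monotone_in_velocity(self):
        means = []
        for v in (0.16, 0.32, 0.64, 1.28):
            ms = make_dataset("temporal", 6, seed=21, scale_velocity=v,
                              resolution=150)
            means.append(np.mean([sparsity(m) for m in ms]))
        assert all(b > a for a, b in zip(means, means[1:]))
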