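"""Numerical covariance checks: matched arms succeed, mismatched arms fail."""

import numpy as np
import pytest
from scipy import ndimage

from covrf.covariance import (
    SpatioTemporalKernelSpec,
    TransformSpec,
    joint_covariance_demo,
    match_parameters,
    verify_galilean,
    verify_spatial_affine,
    verify_temporal_li,
    verify_temporal_lif,
)
from covrf.temporal import LIFParams


def _pulse(fine_dt=1e-3, n=4000, center=1.0, width=0.2):
    t = np.arange(1, n + 1) * fine_dt
    return np.exp(-0.5 * ((t - center) / width) ** 2)


class TestMatchParameters:
    def test_identity(self):
        spec = SpatioTemporalKernelSpec(np.eye(2), 2.0, np.array([0.5, 0.0]))
        out = match_parameters(spec, TransformSpec())
        assert np.allclose(out.Sigma, spec.Sigma)
        assert out.tau == spec.tau
        assert np.allclose(out.v, spec.v)

    def test_temporal_scaling_rule(self):
        spec = SpatioTemporalKernelSpec(np.eye(2), 1.0)
        out = match_parameters(spec, TransformSpec(S_t=2.0))
        assert out.tau == 4.0
        assert np.allclose(out.v, 0.0)

    def test_velocity_rule(self):
        spec = SpatioTemporalKernelSpec(np.eye(2), 1.0, np.array([1.0, 1.0]))
        xf = TransformSpec(A=2 * np.eye(2), u=np.array([1.0, 0.0]), S_t=2.0)
        out = match_parameters(spec, xf)
        assert np.allclose(out.v, [1.5, 1.0])

    def test_group_consistency(self, rng):
        """Matching two transforms in sequence equals matching their
        composition: x'' = A2 (A1 (x + u1 t) + u2 t') with t'' = S2 S1 t."""
        for _ in range(10):
            spec = SpatioTemporalKernelSpec(
                np.diag(rng.uniform(0.5, 2.0, 2)) + 0.1 * np.ones((2, 2)),
                float(rng.uniform(0.5, 4.0)),
                rng.normal(size=2),
            )
            a1, a2 = (rng.normal(size=(2, 2)) + 2 * np.eye(2) for _ in "ab")
            u1, u2 = rng.normal(size=2), rng.normal(size=2)
            s1, s2 = rng.uniform(0.5, 2.0, 2)
            step = match_parameters(
                match_parameters(spec, TransformSpec(A=a1, u=u1, S_t=s1)),
                TransformSpec(A=a2, u=u2, S_t=s2),
            )
            # with the x' = A x + u t reading of the matching rules, two
            # steps compose to A = A2 A1 and u = A2 u1 + S1 u2
            composed = TransformSpec(
                A=a2 @ a1, u=a2 @ u1 + s1 * u2, S_t=s1 * s2,
            )
            direct = match_parameters(spec, composed)
            assert np.allclose(step.Sigma, direct.Sigma)
            assert np.isclose(step.tau, direct.tau)
            assert np.allclose(step.v, direct.v)


class TestTemporalLI:
    def test_identity(self):
        rep = verify_temporal_li(_pulse(), S_t=1.0, mu=0.3)
        assert rep.relative_deviation < 1e-12

    @pytest.mark.parametrize("s_t", [2.0, 4.0])
    def test_matched_small_deviation(self, s_t):
        rep = verify_temporal_li(_pulse(), S_t=s_t, mu=0.3)
        assert rep.relative_deviation < 1e-2

    def test_mismatched_much_worse(self):
        matched = verify_temporal_li(_pulse(), S_t=2.0, mu=0.3)
        control = verify_temporal_li(_pulse(), S_t=2.0, mu=0.3, mu_prime=0.3)
        assert control.relative_deviation >= 10 * matched.relative_deviation

    def test_refinement_monotone(self):
        devs = [
            verify_temporal_li(
                _pulse(fine_dt=dt, n=int(4 / dt)), S_t=2.0, mu=0.3, fine_dt=dt
            ).relative_deviation
            for dt in (4e-3, 2e-3, 1e-3)
        ]
        assert devs[0] > devs[1] > devs[2]

    def test_matched_beats_mismatched_across_seeds(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            sig = np.exp(
                -0.5 * ((np.arange(1, 4001) * 1e-3 - r.uniform(0.8, 1.5))
                        / r.uniform(0.1, 0.3)) ** 2
            )
            mu = r.uniform(0.2, 0.5)
            matched = verify_temporal_li(sig, 2.0, mu)
            control = verify_temporal_li(sig, 2.0, mu, mu_prime=mu)
            assert control.relative_deviation >= 10 * matched.relative_deviation


class TestTemporalLIF:
    params = LIFParams(mu=0.3, theta_thr=0.5, theta_reset=0.0, mu_r=0.05)

    def _signal(self, seed=0):
        t = np.arange(1, 4001) * 1e-3
        r = np.random.default_rng(seed)
        return (1.3 + 0.4 * r.random()) * np.exp(
            -0.5 * ((t - 2.0) / 0.6) ** 2
        )

    def test_identity(self):
        rep = verify_temporal_lif(self._signal(), 1.0, self.params)
        assert rep.extra["counts_equal"]
        assert rep.max_abs_deviation == 0.0

    def test_matched_spike_times_scale(self):
        rep = verify_temporal_lif(self._signal(), 2.0, self.params)
        assert rep.extra["counts_equal"]
        assert rep.extra["n_spikes"] > 5
        assert rep.max_abs_deviation <= 2e-3

    def test_mismatched_reset_constant_diverges(self):
        """With mu_r left unscaled the spike trains drift apart (here the
        faster reset recovery produces extra spikes)."""
        rep = verify_temporal_lif(
            self._signal(), 2.0, self.params, mu_r_prime=self.params.mu_r
        )
        assert (not rep.extra["counts_equal"]) or rep.max_abs_deviation > 2e-2

    def test_matched_beats_mismatched_across_seeds(self):
        for seed in range(5):
            matched = verify_temporal_lif(self._signal(seed), 2.0, self.params)
            control = verify_temporal_lif(
                self._signal(seed), 2.0, self.params,
                mu_r_prime=self.params.mu_r,
            )
            assert matched.extra["counts_equal"]
            bad = (
                np.inf if not control.extra["counts_equal"]
                else control.max_abs_deviation
            )
            assert bad >= 10 * max(matched.max_abs_deviation, 1e-4)


class TestSpatialAffine:
    @staticmethod
    def _image(n=129):
        c = np.arange(n) - (n - 1) / 2
        x, y = np.meshgrid(c, c)
        return np.exp(-(x**2 + y**2) / (2 * 6.0**2)) + 0.4 * np.exp(
            -((x - 10) ** 2 + (y + 8) ** 2) / (2 * 9.0**2)
        )

    def test_identity(self):
        sig = np.array([[4.0, 1.0], [1.0, 3.0]])
        rep = verify_spatial_affine(self._image(), np.eye(2), sig)
        assert rep.relative_deviation < 1e-12

    def test_pure_scaling(self):
        sig = np.array([[4.0, 1.0], [1.0, 3.0]])
        rep = verify_spatial_affine(self._image(), 2 * np.eye(2), sig)
        assert rep.relative_deviation < 5e-3

    def test_rotation(self):
        th = np.pi / 4
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        sig = np.array([[4.0, 1.0], [1.0, 3.0]])
        rep = verify_spatial_affine(self._image(), rot, sig)
        assert rep.relative_deviation < 1e-2

    def test_matched_beats_mismatched_across_seeds(self):
        """Using the untransported covariance on the warped image is at
        least 10x worse than the matched transport."""
        c = np.arange(129) - 64
        x, y = np.meshgrid(c, c)
        img = np.exp(-(x**2 + y**2) / (2 * 10.0**2)) + 0.4 * np.exp(
            -((x - 12) ** 2 + (y + 8) ** 2) / (2 * 14.0**2)
        )
        for seed in range(5):
            r = np.random.default_rng(seed)
            th = r.uniform(0.3, 1.2)
            rot = np.array([[np.cos(th), -np.sin(th)],
                            [np.sin(th), np.cos(th)]])
            a = rot @ np.diag([r.uniform(2.0, 2.4), r.uniform(0.7, 0.9)])
            sig = np.diag(r.uniform(8.0, 14.0, 2)) + 1.0
            matched = verify_spatial_affine(img, a, sig)
            # control: smooth the warped image with the *untransported* Sigma
            from covrf.covariance import affine_warp, gaussian_smooth

            warped = affine_warp(img, a)
            lhs = gaussian_smooth(warped, sig)
            rhs = affine_warp(gaussian_smooth(img, sig), a)
            m = matched.extra["margin"]
            core = (slice(m, img.shape[0] - m), slice(m, img.shape[1] - m))
            bad = np.abs(lhs[core] - rhs[core]).max() / np.abs(rhs[core]).max()
            assert bad >= 10 * matched.relative_deviation


class TestGalilean:
    @staticmethod
    def _movie(n=96, frames=30, v=(1.0, 0.0)):
        c = np.arange(n) - (n - 1) / 2
        x, y = np.meshgrid(c, c)
        return np.stack([
            np.exp(-((x + 20 - v[0] * t) ** 2 + (y - v[1] * t) ** 2)
                   / (2 * 4.0**2))
            for t in range(frames)
        ])

    def test_identity(self):
        spec = SpatioTemporalKernelSpec(4.0 * np.eye(2), 4.0,
                                        np.array([1.0, 0.0]))
        rep = verify_galilean(self._movie(), np.zeros(2), spec)
        assert rep.relative_deviation < 1e-10

    def test_matched_peak_constant(self):
        spec = SpatioTemporalKernelSpec(4.0 * np.eye(2), 4.0,
                                        np.array([1.0, 0.0]))
        rep = verify_galilean(self._movie(), np.array([0.5, 0.0]), spec)
        peaks = rep.extra["peak_trace"]
        assert (peaks.max() - peaks.min()) / peaks.max() < 0.02
        assert rep.relative_deviation < 0.05

    def test_mismatched_velocity_decays(self):
        spec = SpatioTemporalKernelSpec(4.0 * np.eye(2), 4.0,
                                        np.array([1.0, 0.0]))
        rep = verify_galilean(
            self._movie(), np.array([0.5, 0.0]), spec,
            v_prime=np.array([0.0, 0.0]),
        )
        peaks = rep.extra["peak_trace"]
        # the unadapted response smears the moving blob: peaks drop
        matched = verify_galilean(self._movie(), np.array([0.5, 0.0]), spec)
        assert peaks[-1] < 0.9 * matched.extra["peak_trace"][-1]
        assert rep.relative_deviation >= 10 * matched.relative_deviation


class TestJointDemo:
    def test_traces_similar_despite_size_spread(self):
        out = joint_covariance_demo()
        n = len(out["velocities"])
        assert out["final_sizes"].max() / out["final_sizes"].min() >= 4.0
        for i in range(n):
            assert out["pairwise_l2"][i, i] == 0.0
            for j in range(n):
                assert out["pairwise_r"][i, j] > 0.9

    def test_zero_velocity_static_after_transient(self):
        out = joint_covariance_demo(velocities=(0.0,), timesteps=100)
        trace = out["traces"][0]
        tail = trace[60:]  # the mu=8 integrator transient has died down here
        assert (tail.max() - tail.min()) / abs(tail).max() < 0.02
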