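import numpy as np
import pytest

import vsd_spacetime as vs
from vsd_spacetime.state_space import (divergence_time, spatial_pca,
                                       temporal_condition_difference,
                                       trajectory_coords)


def rank3_field(rng, n_channels=40, n_times=300):
    modes = rng.standard_normal((n_channels, 3))
    courses = rng.standard_normal((3, n_times))
    return modes @ courses


class TestSpatialPCA:
    def test_exact_rank3_concentrates_variance(self, rng):
        pca = spatial_pca({"c": rank3_field(rng)}, onset_index=None)
        assert pca.variance_fractions[:3].sum() == pytest.approx(1.0,
                                                                 abs=1e-10)

    def test_reconstruction_residual_is_tiny(self, rng):
        field = rank3_field(rng) + 0.1 * rng.standard_normal((40, 300))
        pca = spatial_pca({"c": field}, onset_index=None)
        centered = (field - field.mean(axis=1, keepdims=True)).T
        resid = np.linalg.norm(pca.reconstruction() - centered)
        assert resid / np.linalg.norm(centered) < 1e-10

    def test_observation_stacking_rule(self, rng):
        # rows = times x replicates x conditions, channels as columns
        fields = {(c, r): rng.standard_normal((10, 50))
                  for c in "ab" for r in range(3)}
        pca = spatial_pca(fields, onset_index=20)
        assert pca.coords.shape[0] == 50 * 3 * 2
        assert pca.components.shape[0] == 10

    def test_variance_fractions_invariant_to_channel_permutation(self, rng):
        field = rank3_field(rng) + 0.05 * rng.standard_normal((40, 300))
        perm = rng.permutation(40)
        a = spatial_pca({"c": field}, onset_index=None)
        b = spatial_pca({"c": field[perm]}, onset_index=None)
        np.testing.assert_allclose(a.variance_fractions, b.variance_fractions,
                                   atol=1e-10)

    def test_coordinates_scale_linearly_with_input(self, rng):
        field = rank3_field(rng)
        a = spatial_pca({"c": field}, onset_index=100)
        b = spatial_pca({"c": 4.0 * field}, onset_index=100)
        np.testing.assert_allclose(4.0 * np.abs(a.coords[:, :3]),
                                   np.abs(b.coords[:, :3]), atol=1e-8)

    def test_duplicated_condition_yields_identical_trajectories(self, rng):
        field = rank3_field(rng)
        pca = spatial_pca({"a": field, "b": field}, onset_index=50)
        np.testing.assert_allclose(trajectory_coords(pca, "a"),
                                   trajectory_coords(pca, "b"), atol=1e-10)

    def test_unknown_condition_is_an_error(self, rng):
        pca = spatial_pca({"a": rank3_field(rng)}, onset_index=None)
        with pytest.raises(KeyError):
            trajectory_coords(pca, "zz")

    def test_prestim_null_coordinates_stay_near_origin(self, hex61):
        noise = vs.generate_baseline(hex61, 1, 1300.0, 1600.0,
                                     vs.BaselineParams(ou_sigma=1.0), seed=6)[0]
        pca = spatial_pca({"c": noise}, onset_index=800)
        traj = trajectory_coords(pca, "c")
        norms = np.linalg.norm(traj, axis=1)
        pre = norms[:800]
        assert norms.max() < pre.mean() + 3 * pre.std() + pre.max()


class TestDivergenceTime:
    def test_infinite_threshold_never_diverges(self, rng):
        a = rng.standard_normal((500, 3))
        b = rng.standard_normal((500, 3))
        assert divergence_time(a, b, 200, 1600.0, k_sd=1e9) is None

    def test_short_prestim_rejected(self, rng):
        a = rng.standard_normal((200, 3))
        with pytest.raises(ValueError, match="too short"):
            divergence_time(a, a, 50, 1600.0)

    def test_step_separation_is_localized(self, rng):
        a = 0.1 * rng.standard_normal((600, 3))
        b = 0.1 * rng.standard_normal((600, 3))
        b[400:] += 5.0
        t = divergence_time(a, b, 300, 1600.0, k_sd=3.0, sustain_ms=10.0)
        assert t == pytest.approx((400 - 300) / 1.6, abs=1.0)

    def test_threshold_is_monotone_in_k_sd(self, rng):
        a = 0.1 * rng.standard_normal((600, 3))
        b = 0.1 * rng.standard_normal((600, 3))
        b[350:] += np.linspace(0, 3, 250)[:, None]
        t_low = divergence_time(a, b, 300, 1600.0, k_sd=2.0)
        t_high = divergence_time(a, b, 300, 1600.0, k_sd=6.0)
        assert t_low is not None and t_high is not None
        assert t_low <= t_high


class TestTemporalConditionDifference:
    @staticmethod
    def series(rng, n_reps=4, n_times=400, shift=0.0):
        t = np.linspace(0, 1, n_times)
        base = np.sin(2 * np.pi * t)
        out = {}
        for r in range(n_reps):
            out[("a", r)] = base + 0.1 * rng.standard_normal(n_times)
            out[("b", r)] = (base + shift * np.exp(-((t - 0.7) ** 2) / 0.002)
                             + 0.1 * rng.standard_normal(n_times))
        return out

    def test_pure_pc1_series_loads_only_on_pc1(self):
        # every series is a multiple of one unit vector, so PC1 = +-v and the
        # orthonormal higher components carry exactly zero beta weight
        t = np.linspace(0, 1, 400)
        v = np.sin(2 * np.pi * t)
        v = v / np.linalg.norm(v)
        series = {}
        coeffs = {}
        for r in range(4):
            coeffs[("a", r)] = 1.0 + 0.1 * r
            coeffs[("b", r)] = 2.0 + 0.1 * r
            series[("a", r)] = coeffs[("a", r)] * v
            series[("b", r)] = coeffs[("b", r)] * v
        res = temporal_condition_difference(series)
        for key, beta in res.betas.items():
            assert abs(beta[0]) == pytest.approx(coeffs[key], abs=1e-8)
            np.testing.assert_allclose(beta[1:], 0.0, atol=1e-8)

    def test_fewer_than_three_replicates_rejected(self, rng):
        zs = self.series(rng, n_reps=2)
        with pytest.raises(ValueError, match="3 replicates"):
            temporal_condition_difference(zs)

    def test_localized_difference_is_detected_in_place(self, rng):
        zs = self.series(rng, n_reps=8, shift=1.5)
        res = temporal_condition_difference(zs)
        t = np.linspace(0, 1, 400)
        window = np.abs(t - 0.7) < 0.08
        assert res.significant[window].mean() > 0.5

    def test_three_components_explain_smooth_low_rank_set(self, rng):
        # mean CFOV series of a smooth low-rank synthetic ensemble
        t = np.linspace(0, 1, 500)
        basis = np.stack([np.sin(np.pi * (k + 1) * t) for k in range(3)])
        x = np.vstack([
            (rng.standard_normal(3) @ basis) + 0.05 * rng.standard_normal(500)
            for _ in range(16)
        ])
        xc = x - x.mean(axis=0, keepdims=True)
        s = np.linalg.svd(xc, compute_uv=False)
        assert (s[:3] ** 2).sum() / (s**2).sum() >= 0.85
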