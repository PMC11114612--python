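"""Gaussian pRF model: forward prediction, two-stage fit, filtering, binning."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crowdprf.prf import (
    ECC_BIN_EDGES,
    FitResult,
    PRFParams,
    bin_by_eccentricity,
    coarse_fit,
    derive_polar_ecc,
    filter_fits,
    fine_fit,
    fits_to_frame,
    gaussian_weights,
    neural_timecourse,
    predict_timecourse,
    regress_scale,
    GridPredictions,
)
from crowdprf.stimulus import FieldRaster


class TestGaussianWeights:
    def test_peak_one_at_centre_and_value_at_one_sigma(self, small_raster):
        # place the centre on a pixel of the 41-pixel grid (0.45 deg spacing)
        p = PRFParams(0.9, -1.8, 2.0)
        w = gaussian_weights(p, small_raster)
        assert w.max() == pytest.approx(1.0)
        xx, yy = small_raster.grid()
        at_sigma = np.isclose(np.hypot(xx - p.x0, yy - p.y0), p.sigma)
        assert np.allclose(w[at_sigma], np.exp(-0.5), atol=1e-12)

    def test_rotation_invariance_about_centre(self):
        p = PRFParams(1.0, 2.0, 1.3)
        r, d = 2.2, 1.3
        angles = np.deg2rad(np.arange(8) * 45.0)
        vals = [
            np.exp(-((r * np.cos(a)) ** 2 + (r * np.sin(a)) ** 2) / (2 * d**2))
            for a in angles
        ]
        assert np.ptp(vals) < 1e-12

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            PRFParams(0.0, 0.0, 0.0)


class TestPrediction:
    def test_zero_movie_gives_zero_prediction(self, bar_movie, hrf):
        import copy

        movie = copy.copy(bar_movie)
        movie.frames = np.zeros_like(bar_movie.frames)
        movie.meta = {}
        p = PRFParams(0.0, 0.0, 1.0)
        assert np.all(predict_timecourse(p, movie, hrf) == 0)

    def test_full_field_movie_gives_flat_prediction(self, bar_movie, hrf):
        import copy

        movie = copy.copy(bar_movie)
        movie.frames = np.ones_like(bar_movie.frames)
        movie.meta = {}
        p = PRFParams(0.0, 0.0, 2.0)
        w_sum = gaussian_weights(p, movie.raster).sum()
        neural = neural_timecourse(p, movie)
        assert np.allclose(neural, w_sum)
        pred = predict_timecourse(p, movie, hrf)
        assert np.ptp(pred[-10:]) < 1e-6 * abs(pred[-1])

    def test_neural_peak_frame_covers_prf_centre(self, bar_movie, hrf):
        p = PRFParams(3.15, 0.0, 0.9)
        neural = neural_timecourse(p, bar_movie)
        # independent oracle: overlap of every frame with the weight map
        w = gaussian_weights(p, bar_movie.raster)
        overlaps = [(f * w).sum() for f in bar_movie.frames]
        best = np.argmax(neural)
        assert best == np.argmax(overlaps)
        assert bar_movie.frames[best].reshape(
            bar_movie.raster.n_pixels, -1
        )[np.unravel_index(np.argmax(w), w.shape)]

    def test_raster_mismatch_rejected(self, bar_movie, hrf):
        from crowdprf.prf import predict_many

        other = FieldRaster(9.0, 21)
        p = PRFParams(0.0, 0.0, 1.0)
        w = gaussian_weights(p, other)
        assert w.shape != bar_movie.frames.shape[1:]


class TestRegressScale:
    def test_identity_fit(self, rng):
        pred = rng.normal(size=50)
        beta, base, r2 = regress_scale(pred, pred)
        assert (beta, base, r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_affine_fit(self, rng):
        pred = rng.normal(size=50)
        beta, base, r2 = regress_scale(pred, 2.0 * pred + 5.0)
        assert (beta, base, r2) == pytest.approx((2.0, 5.0, 1.0))

    def test_orthogonal_noise_gives_near_zero_r2(self, rng):
        pred = np.sin(np.linspace(0, 20, 144))
        noise = rng.normal(size=144)
        noise -= (noise @ pred) / (pred @ pred) * pred  # orthogonalize
        _, _, r2 = regress_scale(pred, noise)
        assert abs(r2) < 0.05

    def test_constant_prediction_degenerates(self):
        beta, base, r2 = regress_scale(np.ones(10), np.arange(10.0))
        assert (beta, base, r2) == (0.0, 4.5, 0.0)


class TestCoarseFit:
    def test_matches_exhaustive_oracle_on_20_random_voxels(
        self, bar_movie, hrf, rng
    ):
        grid = {
            "x0": np.linspace(-6, 6, 5),
            "y0": np.linspace(-6, 6, 5),
            "sigma": np.array([0.5, 1.5, 3.0]),
        }
        gp = GridPredictions(bar_movie, hrf, grid)
        for _ in range(20):
            obs = rng.normal(size=bar_movie.n_trs)
            res = coarse_fit(obs, bar_movie, hrf, precomputed=gp)
            # independent oracle: re-evaluate every grid point directly
            best_r2, best_pt = -np.inf, None
            for pt in gp.points:
                pred = predict_timecourse(PRFParams(*pt), bar_movie, hrf)
                r = sps.pearsonr(pred, obs).statistic
                key = (r**2, -pt[2], -np.hypot(pt[0], pt[1]))
                if best_pt is None or key > best_key:
                    best_r2, best_pt, best_key = r**2, pt, key
            assert (res.params.x0, res.params.y0, res.params.sigma) == tuple(best_pt)

    def test_noiseless_voxel_at_grid_point_recovered(self, bar_movie, hrf):
        grid = {
            "x0": np.linspace(-6, 6, 5),
            "y0": np.linspace(-6, 6, 5),
            "sigma": np.array([0.5, 1.5, 3.0]),
        }
        truth = PRFParams(3.0, -3.0, 1.5)
        obs = predict_timecourse(truth, bar_movie, hrf)
        res = coarse_fit(obs, bar_movie, hrf, grid=grid)
        assert (res.params.x0, res.params.y0, res.params.sigma) == (3.0, -3.0, 1.5)
        assert res.r2 == pytest.approx(1.0)

    def test_tie_broken_by_smaller_sigma(self, bar_movie, hrf):
        # duplicated sigma values create exact ties at the best (x0, y0)
        grid = {
            "x0": np.array([0.0, 3.0]),
            "y0": np.array([0.0]),
            "sigma": np.array([2.0, 1.0, 1.0 + 0.0]),
        }
        truth = PRFParams(3.0, 0.0, 1.0)
        obs = predict_timecourse(truth, bar_movie, hrf)
        res = coarse_fit(obs, bar_movie, hrf, grid=grid)
        assert res.params.sigma == 1.0

    def test_constant_voxel_flagged_unfittable(self, bar_movie, hrf):
        res = coarse_fit(np.ones(bar_movie.n_trs), bar_movie, hrf,
                         grid={"x0": [0.0], "y0": [0.0], "sigma": [1.0]})
        assert res.unfittable


class TestFineFit:
    def test_noiseless_off_grid_voxel_recovered(
        self, bar_movie, hrf, coarse_grid_predictions
    ):
        truth = PRFParams(2.3, 4.1, 1.7)
        obs = 1.5 * predict_timecourse(truth, bar_movie, hrf) + 10.0
        seed = coarse_fit(obs, bar_movie, hrf, precomputed=coarse_grid_predictions)
        res = fine_fit(obs, bar_movie, hrf, seed.params)
        assert res.params.x0 == pytest.approx(truth.x0, abs=0.05)
        assert res.params.y0 == pytest.approx(truth.y0, abs=0.05)
        assert res.params.sigma == pytest.approx(truth.sigma, abs=0.05)
        assert res.beta == pytest.approx(1.5, rel=1e-3)
        assert res.baseline == pytest.approx(10.0, rel=1e-3)

    def test_ssr_never_exceeds_seed(self, bar_movie, hrf, rng):
        from crowdprf.prf import _ssr

        obs = rng.normal(size=bar_movie.n_trs)
        seed = PRFParams(1.0, 1.0, 1.0)
        res = fine_fit(obs, bar_movie, hrf, seed)
        assert _ssr(res.params, obs, bar_movie, hrf)[0] <= (
            _ssr(seed, obs, bar_movie, hrf)[0] + 1e-9
        )

    def test_median_sigma_error_under_noise(
        self, bar_movie, hrf, coarse_grid_predictions, rng
    ):
        errors = []
        for _ in range(20):
            truth = PRFParams(
                rng.uniform(-5, 5), rng.uniform(-5, 5), rng.uniform(0.8, 2.5)
            )
            signal = predict_timecourse(truth, bar_movie, hrf)
            obs = signal + rng.normal(0, 0.5 * signal.std(), signal.size)
            seed = coarse_fit(obs, bar_movie, hrf,
                              precomputed=coarse_grid_predictions)
            res = fine_fit(obs, bar_movie, hrf, seed.params)
            errors.append(abs(res.params.sigma - truth.sigma))
        assert np.median(errors) < 0.15


class TestFilterAndDerived:
    def _toy(self):
        rows = []
        for r2, beta in zip(
            [0.01, 0.05, 0.6, 0.6, 0.2, 0.9], [1.0, 1.0, -0.2, 1.0, 1.0, 0.0]
        ):
            rows.append({"r2": r2, "beta": beta, "sigma": 1.0, "ecc": 2.0})
        return pd.DataFrame(rows)

    def test_boundary_r2_retained_negative_beta_removed(self):
        kept = filter_fits(self._toy())
        assert len(kept) == 3
        assert (kept["r2"] >= 0.05).all() and (kept["beta"] > 0).all()

    def test_filtering_idempotent_and_order_independent(self):
        df = self._toy()
        once = filter_fits(df)
        pd.testing.assert_frame_equal(filter_fits(once), once)
        shuffled = df.sample(frac=1.0, random_state=0)
        assert set(filter_fits(shuffled).index) == set(once.index)

    def test_derive_polar_ecc_345_triangle(self):
        ecc, polar = derive_polar_ecc(PRFParams(3.0, 4.0, 1.0))
        assert ecc == pytest.approx(5.0)
        assert polar == pytest.approx(53.13, abs=0.01)

    def test_origin_has_undefined_polar(self):
        ecc, polar = derive_polar_ecc(PRFParams(0.0, 0.0, 1.0))
        assert ecc == 0.0 and polar is None

    def test_trained_locus_at_65_degrees(self):
        ecc, polar = derive_polar_ecc(PRFParams(2.747, 5.891, 1.0))
        assert ecc == pytest.approx(6.5, abs=1e-3)
        assert polar == pytest.approx(65.0, abs=0.01)


class TestBinning:
    def test_bin_assignment_and_exclusions(self):
        df = pd.DataFrame(
            {"ecc": [6.6, 0.3, 9.5], "sigma": [1.0, 1.0, 1.0],
             "r2": [1, 1, 1], "beta": [1, 1, 1]}
        )
        bm = bin_by_eccentricity(df)
        assert len(bm.edges) == 18 and bm.count.size == 17
        bin_65 = np.flatnonzero((bm.edges[:-1] == 6.5))[0]
        assert bm.count[bin_65] == 1
        assert bm.count.sum() == 1  # 0.3 and 9.5 excluded

    def test_hand_computed_bin_mean(self):
        df = pd.DataFrame({"ecc": [1.1, 1.3], "sigma": [0.8, 1.2]})
        bm = bin_by_eccentricity(df)
        b = np.flatnonzero(bm.edges[:-1] == 1.0)[0]
        assert bm.mean_sigma[b] == pytest.approx(1.0)
        assert bm.se_sigma[b] == pytest.approx(
            np.std([0.8, 1.2], ddof=1) / np.sqrt(2)
        )

    def test_last_bin_closed(self):
        df = pd.DataFrame({"ecc": [9.0], "sigma": [2.0]})
        bm = bin_by_eccentricity(df)
        assert bm.count[-1] == 1

    def test_monotone_size_ecc_relation_recovered(self, rng):
        ecc = rng.uniform(0.5, 9.0, 400)
        sigma = 0.8 + 0.1 * ecc + rng.normal(0, 0.05, ecc.size)
        bm = bin_by_eccentricity(pd.DataFrame({"ecc": ecc, "sigma": sigma}))
        ok = bm.count >= 5
        rho = sps.spearmanr(bm.centers[ok], bm.mean_sigma[ok]).statistic
        assert rho > 0.9
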