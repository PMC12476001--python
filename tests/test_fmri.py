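"""fMRI first-level machinery: HRF regressors, design matrices, the
AR(1)-Toeplitz likelihood against a dense multivariate-normal oracle,
zero-phase detrending, and the two Bayesian fit variants."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trialwise as tw
from trialwise.fmri import (FmriDataset, FmriPackedModel, NoiseModel,
                            ar1_pointwise_loglik, design_column_names,
                            fmri_beta_draws, fmri_pointwise_loglik,
                            synthetic_fmri_experiment)


class TestHrfRegressor:
    def test_no_onsets_all_zero(self):
        col = tw.hrf_regressor([], 2.0, 100, 2.0)
        np.testing.assert_array_equal(col, np.zeros(100))

    def test_isolated_event_peaks_at_one(self):
        # sampling aligned with the convolution grid hits the fixed
        # height exactly; a 0.5 s TR lands within ~1% of the peak
        col = tw.hrf_regressor([10.0], 2.0, 2000, 0.05)
        assert col.max() == pytest.approx(1.0, abs=1e-6)
        coarse = tw.hrf_regressor([10.0], 2.0, 100, 0.5)
        assert coarse.max() == pytest.approx(1.0, abs=0.02)

    def test_short_event_also_peaks_at_one(self):
        col = tw.hrf_regressor([10.0], 0.1, 2000, 0.05)
        assert col.max() == pytest.approx(1.0, abs=1e-6)

    def test_linearity_for_separated_events(self):
        a = tw.hrf_regressor([10.0], 2.0, 200, 1.0)
        b = tw.hrf_regressor([120.0], 2.0, 200, 1.0)
        both = tw.hrf_regressor([10.0, 120.0], 2.0, 200, 1.0)
        np.testing.assert_allclose(both, a + b, atol=1e-8)

    def test_onset_outside_scan_rejected(self):
        with pytest.raises(ValueError, match="scan"):
            tw.hrf_regressor([500.0], 2.0, 100, 2.0)


class TestDesignMatrix:
    def _build(self, n_volumes=120, tr=2.0):
        events = {("CSP", "ACQ"): [20.0, 60.0], ("GS1", "HAB"): [5.0]}
        motion = np.zeros((n_volumes, 6))
        return tw.build_design_matrix(events, [21.9], motion, n_volumes, tr)

    def test_nineteen_columns_in_documented_order(self):
        X = self._build()
        assert X.shape[1] == 19
        assert list(X.columns) == design_column_names()
        assert X.columns[12] == "US"

    def test_empty_condition_column_is_zero(self):
        X = self._build()
        assert (X["GS3_EXT"] == 0).all()
        assert X["CSP_ACQ"].max() > 0.9

    def test_column_order_roundtrips_through_csv(self, tmp_path):
        X = self._build()
        path = tmp_path / "design.csv"
        X.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert list(back.columns) == list(X.columns)
        np.testing.assert_allclose(back.to_numpy(), X.to_numpy(), atol=1e-12)

    def test_wrong_motion_shape_rejected(self):
        with pytest.raises(ValueError, match="motion"):
            tw.build_design_matrix({}, [], np.zeros((120, 5)), 120, 2.0)


class TestToeplitzCovariance:
    def test_lambda_zero_is_scaled_identity(self):
        cov = tw.toeplitz_covariance(NoiseModel(lam=0.0, sigma=2.0), 4)
        np.testing.assert_array_equal(cov, 4.0 * np.eye(4))

    def test_first_row_geometric(self):
        cov = tw.toeplitz_covariance(NoiseModel(lam=0.5, sigma=1.0), 3)
        np.testing.assert_allclose(cov[0], [1.0, 0.5, 0.25])

    @pytest.mark.parametrize("lam", np.linspace(0.0, 0.99, 12))
    def test_positive_definite_across_lambda(self, lam):
        cov = tw.toeplitz_covariance(NoiseModel(lam=float(lam), sigma=1.0), 30)
        np.linalg.cholesky(cov)  # raises if not PD

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(lam=1.0, sigma=1.0)


class TestGlsLoglik:
    def _problem(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 19))
        beta = rng.normal(size=19)
        y = X @ beta + rng.normal(size=n)
        return y, X, beta

    def test_lambda_zero_equals_iid_sum(self):
        y, X, beta = self._problem()
        noise = NoiseModel(lam=0.0, sigma=1.3)
        mine = tw.gls_loglik(y, X, beta, noise)
        iid = stats.norm.logpdf(y - X @ beta, scale=1.3).sum()
        assert mine == pytest.approx(iid, abs=1e-10)

    def test_matches_dense_mvn_oracle(self):
        y, X, beta = self._problem(n=50)
        noise = NoiseModel(lam=0.4, sigma=0.9)
        cov = tw.toeplitz_covariance(noise, 50)
        oracle = stats.multivariate_normal(mean=X @ beta, cov=cov).logpdf(y)
        assert tw.gls_loglik(y, X, beta, noise) == pytest.approx(oracle, abs=1e-8)

    def test_censoring_equals_row_deletion(self):
        y, X, beta = self._problem(n=40)
        noise = NoiseModel(lam=0.3, sigma=1.1)
        censored = np.zeros(40, dtype=bool)
        censored[[5, 6, 20]] = True
        keep = ~censored
        # marginalizing an MVN = dropping rows/cols of the covariance
        lags = np.abs(np.subtract.outer(np.flatnonzero(keep), np.flatnonzero(keep)))
        cov = noise.sigma ** 2 * noise.lam ** lags
        oracle = stats.multivariate_normal(mean=(X @ beta)[keep], cov=cov).logpdf(y[keep])
        assert tw.gls_loglik(y, X, beta, noise, censored=censored) == \
            pytest.approx(oracle, abs=1e-8)

    def test_innovations_factorization_sums_to_joint(self):
        y, X, beta = self._problem(n=30)
        noise = NoiseModel(lam=0.6, sigma=0.8)
        keep = np.ones(30, dtype=bool)
        keep[[3, 10, 11]] = False
        resid = (y - X @ beta)[keep]
        pointwise = ar1_pointwise_loglik(resid, np.flatnonzero(keep),
                                         noise.lam, noise.sigma)
        joint = tw.gls_loglik(y, X, beta, noise, censored=~keep)
        assert pointwise.sum() == pytest.approx(joint, abs=1e-8)


class TestHighpassDetrend:
    def test_constant_input_removed(self):
        out = tw.highpass_detrend(np.full(500, 7.0))
        assert np.abs(out).max() < 1e-6 * 7.0

    def test_passband_sinusoid_preserved(self):
        t = np.arange(2000) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)  # well above the 0.0065 Hz cutoff
        out = tw.highpass_detrend(x)
        inner = slice(200, -200)
        ratio = out[inner].std() / x[inner].std()
        assert abs(ratio - 1.0) < 0.01

    def test_zero_phase(self):
        t = np.arange(2000) * 2.0
        x = np.sin(2 * np.pi * 0.03 * t)
        out = tw.highpass_detrend(x)
        xc = np.correlate(out[100:-100], x[100:-100], mode="full")
        lag = xc.argmax() - (len(out[100:-100]) - 1)
        assert lag == 0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            tw.highpass_detrend(np.zeros(100), cutoff=0.3, tr=2.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            tw.highpass_detrend(np.zeros(20), order=5)


@pytest.fixture(scope="module")
def small_fmri_fit():
    datasets, true_betas = synthetic_fmri_experiment(4, 120, seed=42)
    config = tw.SamplerConfig(n_chains=2, n_warmup=250, n_draws=250, seed=43)
    indep = tw.fit_first_level(datasets, "independent", config,
                               check_convergence=False)
    multi = tw.fit_first_level(datasets, "multilevel", config,
                               check_convergence=False)
    return datasets, true_betas, indep, multi


class TestFirstLevelFits:
    def test_multilevel_needs_two_participants(self):
        datasets, _ = synthetic_fmri_experiment(1, 60, seed=1)
        with pytest.raises(ValueError, match="participants"):
            FmriPackedModel(datasets, "multilevel")

    def test_beta_recovery_independent(self, small_fmri_fit):
        datasets, true_betas, indep, _ = small_fmri_fit
        betas = fmri_beta_draws(indep, datasets)
        est = betas.mean(axis=0)
        sd = betas.std(axis=0)
        within = np.abs(est - true_betas) < 3.5 * sd + 0.05
        assert within.mean() > 0.9

    def test_multilevel_shrinks_toward_group_mean(self, small_fmri_fit):
        datasets, _, indep, multi = small_fmri_fit
        b_i = fmri_beta_draws(indep, datasets).mean(axis=0)
        b_m = fmri_beta_draws(multi, datasets).mean(axis=0)
        center = b_i.mean(axis=0, keepdims=True)
        closer = np.abs(b_m - center) <= np.abs(b_i - center) + 0.02
        assert closer.mean() > 0.75

    def test_pointwise_loglik_covers_retained_volumes(self, small_fmri_fit):
        datasets, _, indep, _ = small_fmri_fit
        mat = fmri_pointwise_loglik(indep, datasets)
        n_retained = sum(len(ds.retained) for ds in datasets)
        assert mat.n_obs == n_retained

    def test_fit_deterministic(self):
        datasets, _ = synthetic_fmri_experiment(2, 60, seed=7)
        config = tw.SamplerConfig(n_chains=2, n_warmup=50, n_draws=50, seed=8)
        a = tw.fit_first_level(datasets, "independent", config,
                               check_convergence=False)
        b = tw.fit_first_level(datasets, "independent", config,
                               check_convergence=False)
        np.testing.assert_array_equal(a.samples, b.samples)


def test_fmri_dataset_validation():
    with pytest.raises(ValueError, match="columns"):
        FmriDataset(bold=np.zeros(10), design=np.zeros((10, 5)),
                    censored=np.zeros(10, dtype=bool))
    with pytest.raises(ValueError, match="length"):
        FmriDataset(bold=np.zeros(10), design=np.zeros((10, 19)),
                    censored=np.zeros(9, dtype=bool))
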