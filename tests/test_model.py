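import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import multivariate_normal, norm

from geosurv.geometry import DistanceMatrix, centroid_distances
from geosurv.model import (BaselineHazard, ModelError, NormalPrior, PriorSpec,
                           SpatialCorrelation, SpatialPHModel, SurvivalDataset,
                           baseline_hazard, correlation, covariance_matrix,
                           chol_with_jitter, cumulative_baseline,
                           dataset_from_dataframe, frailty_log_density,
                           log_likelihood, log_prior, loglik_pointwise,
                           make_spline_knots)
from geosurv.simulate import make_grid_map


def make_dataset(rng, n=30, n_districts=4, p=2):
    X = rng.standard_normal((n, p))
    return SurvivalDataset(
        t=rng.exponential(100.0, n) + 1.0,
        delta=rng.integers(0, 2, n),
        X=X, columns=tuple(f"x{j}" for j in range(p)),
        district_index=rng.integers(0, n_districts, n),
        district_ids=tuple(f"D{i}" for i in range(n_districts)))


class TestBaselineHazard:
    def test_weibull_shape_one_is_exponential(self):
        bl = BaselineHazard("weibull", [1.0, 0.2])
        assert baseline_hazard(3.0, bl) == pytest.approx(0.2)
        assert cumulative_baseline(3.0, bl) == pytest.approx(0.6)

    def test_weibull_closed_form(self):
        bl = BaselineHazard("weibull", [2.0, 0.5])
        assert baseline_hazard(2.0, bl) == pytest.approx(2.0)   # 2*0.5*2
        assert cumulative_baseline(2.0, bl) == pytest.approx(2.0)  # 0.5*4

    def test_exponential(self):
        bl = BaselineHazard("exponential", [0.3])
        t = np.array([0.0, 1.0, 5.0])
        np.testing.assert_allclose(baseline_hazard(t, bl), 0.3)
        np.testing.assert_allclose(cumulative_baseline(t, bl), 0.3 * t)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bspline_H0_matches_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        knots = make_spline_knots(10.0, n_interior=3)
        coef = rng.normal(-1.0, 0.5, len(knots) - 4)
        bl = BaselineHazard("bspline", coef, knots=knots)
        for t in rng.uniform(0.5, 9.5, 5):
            oracle, err = quad(lambda u: baseline_hazard(u, bl), 0.0, t,
                               limit=200)
            assert cumulative_baseline(t, bl) == pytest.approx(oracle, rel=1e-6)

    def test_weibull_H0_matches_quadrature(self):
        bl = BaselineHazard("weibull", [1.7, 0.01])
        for t in (0.5, 2.0, 40.0):
            oracle, _ = quad(lambda u: baseline_hazard(u, bl), 0.0, t)
            assert cumulative_baseline(t, bl) == pytest.approx(oracle, rel=1e-8)

    def test_H0_monotone_and_zero_at_origin(self):
        rng = np.random.default_rng(5)
        knots = make_spline_knots(100.0)
        bl = BaselineHazard("bspline", rng.normal(size=len(knots) - 4), knots=knots)
        t = np.linspace(0.0, 120.0, 80)
        H = cumulative_baseline(t, bl)
        assert H[0] == 0.0
        assert np.all(np.diff(H) >= -1e-12)

    def test_negative_time_errors(self):
        bl = BaselineHazard("exponential", [1.0])
        with pytest.raises(ModelError):
            baseline_hazard(-1.0, bl)
        with pytest.raises(ModelError):
            cumulative_baseline(np.array([1.0, -2.0]), bl)

    def test_invalid_params(self):
        with pytest.raises(ModelError):
            BaselineHazard("weibull", [1.0])
        with pytest.raises(ModelError):
            BaselineHazard("exponential", [-1.0])
        with pytest.raises(ModelError):
            BaselineHazard("cauchy", [1.0])


class TestSpatialCorrelation:
    def test_rho_zero_distance(self):
        for phi in (1.0, 16_384.0, 1e6):
            assert correlation(0.0, phi) == pytest.approx(1.0)

    def test_rho_at_range_is_e_inverse(self):
        # reported range parameter: correlation e^-1 at d = phi
        assert correlation(16_384.0, 16_384.0) == pytest.approx(np.exp(-1.0))
        assert correlation(16_384.0, 16_384.0) == pytest.approx(0.3679, abs=5e-5)

    def test_covariance_elementwise_and_pd(self, rng, centroid_map_factory):
        dmap = centroid_map_factory(rng.uniform(0, 1e5, size=(10, 2)))
        D = centroid_distances(dmap)
        corr = SpatialCorrelation(sigma2=0.7, phi=2e4)
        Sigma = covariance_matrix(D, corr)
        for i in range(10):
            for j in range(10):
                assert Sigma[i, j] == pytest.approx(
                    0.7 * np.exp(-D.d[i, j] / 2e4), rel=1e-12)
        L, jitter = chol_with_jitter(Sigma)
        assert jitter == 0.0
        np.testing.assert_allclose(L @ L.T, Sigma, atol=1e-10)

    def test_invalid_params(self):
        with pytest.raises(ModelError):
            SpatialCorrelation(sigma2=0.0, phi=1.0)
        with pytest.raises(ModelError):
            correlation(1.0, -2.0)


class TestLogLikelihood:
    def test_single_patient_closed_form(self):
        data = SurvivalDataset(t=[1.0], delta=[1], X=np.zeros((1, 0)),
                               columns=(), district_index=[0],
                               district_ids=("D0",))
        model = SpatialPHModel(beta=np.zeros(0),
                               baseline=BaselineHazard("exponential", [1.0]),
                               corr=SpatialCorrelation(1.0, 1.0), Y=[0.0])
        assert log_likelihood(data, model) == pytest.approx(-1.0)

    def test_censored_exponential_closed_form(self, rng):
        # Independent textbook oracle: n_event*log(lam) - lam*sum(t)
        data = make_dataset(rng, n=60, p=0)
        lam = 0.013
        model = SpatialPHModel(beta=np.zeros(0),
                               baseline=BaselineHazard("exponential", [lam]),
                               corr=SpatialCorrelation(1.0, 1.0),
                               Y=np.zeros(4))
        oracle = data.delta.sum() * np.log(lam) - lam * data.t.sum()
        assert log_likelihood(data, model) == pytest.approx(oracle, abs=1e-10)

    def test_rate_frailty_confounding_invariance(self, rng):
        # halving lambda while adding log 2 to every Y leaves logL unchanged
        data = make_dataset(rng, n=40, p=2)
        beta = rng.normal(0, 0.3, 2)
        Y = rng.normal(0, 0.5, 4)
        m1 = SpatialPHModel(beta=beta, baseline=BaselineHazard("exponential", [0.02]),
                            corr=SpatialCorrelation(1.0, 1.0), Y=Y)
        m2 = SpatialPHModel(beta=beta, baseline=BaselineHazard("exponential", [0.01]),
                            corr=SpatialCorrelation(1.0, 1.0), Y=Y + np.log(2.0))
        assert log_likelihood(data, m1) == pytest.approx(log_likelihood(data, m2),
                                                         rel=1e-12)

    def test_proportional_hazards_property(self, rng):
        # multiplying exp(x beta) by k multiplies h(t) by k for all t
        bl = BaselineHazard("weibull", [1.5, 0.01])
        x = np.array([0.7])
        beta1, beta2 = np.array([0.4]), np.array([0.4 + np.log(3.0) / 0.7])
        for t in (1.0, 5.0, 50.0):
            h1 = baseline_hazard(t, bl) * np.exp(x @ beta1)
            h2 = baseline_hazard(t, bl) * np.exp(x @ beta2)
            assert h2 / h1 == pytest.approx(3.0, rel=1e-12)

    def test_reduces_to_nonspatial(self, rng):
        # sigma2 -> 0 pins Y at its mean; compare with an independently
        # coded non-spatial parametric PH log-likelihood
        data = make_dataset(rng, n=50, p=3)
        beta = rng.normal(0, 0.2, 3)
        sigma2 = 1e-12
        bl = BaselineHazard("weibull", [1.3, 0.004])
        model = SpatialPHModel(beta=beta, baseline=bl,
                               corr=SpatialCorrelation(sigma2, 1.0),
                               Y=np.full(4, -sigma2 / 2.0))

        def nonspatial(t, d, X, b, shape, scale):
            lin = X @ b
            return np.sum(d * (np.log(shape * scale) + (shape - 1) * np.log(t)
                               + lin) - scale * t ** shape * np.exp(lin))

        oracle = nonspatial(data.t, data.delta, data.X, beta, 1.3, 0.004)
        assert log_likelihood(data, model) == pytest.approx(oracle, rel=1e-9)

    def test_survival_function_monotone(self):
        bl = BaselineHazard("weibull", [0.8, 0.05])
        t = np.linspace(0.0, 200.0, 100)
        for lin in (-0.5, 0.0, 1.2):
            S = np.exp(-cumulative_baseline(t, bl) * np.exp(lin))
            assert S[0] == 1.0
            assert np.all(np.diff(S) <= 1e-12)

    def test_dimension_mismatch_errors(self, rng):
        data = make_dataset(rng, n=10, p=2)
        model = SpatialPHModel(beta=np.zeros(3),
                               baseline=BaselineHazard("exponential", [1.0]),
                               corr=SpatialCorrelation(1.0, 1.0), Y=np.zeros(4))
        with pytest.raises(ModelError, match="beta"):
            log_likelihood(data, model)

    def test_nonfinite_reports_index(self, rng):
        data = make_dataset(rng, n=5, p=1)
        terms = loglik_pointwise(data, np.array([500.0]),
                                 BaselineHazard("exponential", [1.0]),
                                 np.zeros(4))
        model = SpatialPHModel(beta=np.array([500.0]),
                               baseline=BaselineHazard("exponential", [1.0]),
                               corr=SpatialCorrelation(1.0, 1.0), Y=np.zeros(4))
        if not np.all(np.isfinite(terms)):
            with pytest.raises(ModelError, match="patient"):
                log_likelihood(data, model)


class TestFrailtyPrior:
    def test_iid_case_equals_product_of_univariates(self):
        sigma2 = 0.49
        Sigma = sigma2 * np.eye(6)
        Y = np.full(6, -sigma2 / 2.0)  # at the prior mean
        got = frailty_log_density(Y, Sigma)
        oracle = norm(loc=-sigma2 / 2.0, scale=np.sqrt(sigma2)).logpdf(Y).sum()
        assert got == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_dense_mvn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dmap = make_grid_map(8, "west", cell_km=10.0)
        D = centroid_distances(dmap)
        sigma2, phi = 0.6, 25_000.0
        Sigma = sigma2 * np.exp(-D.d / phi)
        Y = rng.normal(0, 0.5, 8)
        mean = np.full(8, -sigma2 / 2.0)
        oracle = multivariate_normal(mean=mean, cov=Sigma).logpdf(Y)
        assert frailty_log_density(Y, Sigma) == pytest.approx(oracle, abs=1e-8)


class TestPriors:
    def test_missing_prior_errors(self, rng):
        data = make_dataset(rng, n=10, p=1)
        dmap = make_grid_map(4, "west", cell_km=10.0)
        model = SpatialPHModel(beta=np.zeros(1),
                               baseline=BaselineHazard("exponential", [1.0]),
                               corr=SpatialCorrelation(0.1, 1e4),
                               Y=np.zeros(4), distances=centroid_distances(dmap))
        priors = PriorSpec(beta=NormalPrior(0, 10), log_omega=None,
                           log_sigma2=NormalPrior(0, 2), log_phi=NormalPrior(0, 2))
        with pytest.raises(ModelError, match="log_omega"):
            log_prior(model, priors)

    def test_log_prior_finite(self, rng):
        dmap = make_grid_map(4, "west", cell_km=10.0)
        model = SpatialPHModel(beta=np.array([0.1]),
                               baseline=BaselineHazard("exponential", [0.01]),
                               corr=SpatialCorrelation(0.1, 1e4),
                               Y=np.zeros(4), distances=centroid_distances(dmap))
        lp = log_prior(model, PriorSpec.default())
        assert np.isfinite(lp)

    def test_invalid_sd(self):
        with pytest.raises(ModelError):
            NormalPrior(0.0, -1.0)


class TestDatasetFromDataframe:
    def make_df(self):
        return pd.DataFrame({
            "time": [10.0, 20.0, 5.0, 7.0],
            "event": [1, 0, 1, 1],
            "district_id": ["D0", "D1", "D0", "Dx"],
            "sex": ["f", "m", "missing", "m"],
            "age": [50.0, 60.0, 70.0, 55.0],
        })

    def test_dummy_coding_reference_first(self):
        ds = dataset_from_dataframe(self.make_df(), ["D0", "D1"],
                                    factors={"sex": ["f", "m", "missing"]},
                                    numeric=["age"], standardise_numeric=False)
        assert ds.columns == ("sex[m]", "sex[missing]", "age")
        assert ds.n == 3  # unknown district dropped with a log
        np.testing.assert_allclose(ds.X[:, 0], [0.0, 1.0, 0.0])
        np.testing.assert_allclose(ds.X[:, 1], [0.0, 0.0, 1.0])
        # dummy columns of one factor sum to <= 1 per row
        assert np.all(ds.X[:, :2].sum(axis=1) <= 1.0)

    def test_undeclared_level_errors(self):
        df = self.make_df()
        with pytest.raises(ModelError, match="sex"):
            dataset_from_dataframe(df, ["D0", "D1", "Dx"],
                                   factors={"sex": ["f", "m"]})

    def test_standardisation(self):
        ds = dataset_from_dataframe(self.make_df(), ["D0", "D1"],
                                    factors={}, numeric=["age"])
        assert ds.X[:, 0].mean() == pytest.approx(0.0, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ModelError, match="positive"):
            SurvivalDataset(t=[0.0], delta=[1], X=np.zeros((1, 0)), columns=(),
                            district_index=[0], district_ids=("D0",))
        with pytest.raises(ModelError, match="0/1"):
            SurvivalDataset(t=[1.0], delta=[2], X=np.zeros((1, 0)), columns=(),
                            district_index=[0], district_ids=("D0",))
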