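"""TLS-GP normative model, noise estimation, splitting, scoring."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from placentaging import (
    CohortSpec,
    OLSGPBaseline,
    TLSGPNormativeModel,
    estimate_sigma_delta_bins,
    estimate_sigma_eps,
    simulate_cohort,
    split_cohort,
)
from placentaging.tlsgp import InfeasibleBinningError


class ZeroNoise:
    sigma_eps = 0.0
    sigma_delta = 0.0


@pytest.fixture(scope="module")
def fitted(cohort90):
    X = cohort90[["ga_weeks", "mean_t2s"]].to_numpy()
    return TLSGPNormativeModel(random_state=0).fit(X), X


class TestSigmaEstimates:
    def test_sigma_eps_term_window(self):
        assert estimate_sigma_eps(37.0, 42.0) == pytest.approx(5.0 / (2 * 1.96))
        assert round(estimate_sigma_eps(37.0, 42.0), 1) == 1.3
        assert estimate_sigma_eps(37.0, 37.0 + 2 * 1.96) == pytest.approx(1.0)
        assert estimate_sigma_eps(30.0, 42.0) == pytest.approx(12.0 / (2 * 1.96))
        with pytest.raises(ValueError):
            estimate_sigma_eps(42.0, 37.0)

    def _clustered(self, sds, centres, k=4):
        # k points per cluster with exact sample SD sds[i]
        base = np.array([-3.0, -1.0, 1.0, 3.0])
        base = base / base.std(ddof=1)
        ga, t2 = [], []
        for c, sd in zip(centres, sds):
            ga.extend(c + np.array([-0.5, -0.5, 0.5, 0.5]))
            t2.extend(100 + sd * base)
        return np.array(ga), np.array(t2)

    def test_identical_bin_sds(self):
        ga, t2 = self._clustered([10.0] * 4, [20, 25, 30, 35])
        assert estimate_sigma_delta_bins(ga, t2, sigma_eps=1.3) == pytest.approx(10.0)

    def test_mean_of_bin_sds(self):
        ga, t2 = self._clustered([8.0, 10.0, 12.0, 14.0], [20, 25, 30, 35])
        assert estimate_sigma_delta_bins(ga, t2, sigma_eps=1.3) == pytest.approx(11.0)

    def test_infeasible_binning_reports(self):
        ga = np.array([20.0, 20.1, 20.2, 20.3, 30.0])
        with pytest.raises(InfeasibleBinningError, match="1 of 4"):
            estimate_sigma_delta_bins(ga, np.ones(5), sigma_eps=1.3)

    def test_recovers_generator_noise(self):
        # small cohort like a reduced-field-strength replication study
        df = simulate_cohort(
            CohortSpec(n_low_risk=36, n_high_risk=0, sigma_delta_true=16.4, seed=9)
        )
        est = estimate_sigma_delta_bins(
            df.ga_weeks.to_numpy(), df.mean_t2s.to_numpy(), sigma_eps=1.3
        )
        # bins of >=4 points: sampling SE of an SD is sigma/sqrt(2(n-1)) per
        # bin, ~3 ms after averaging 4 bins, plus a small trend contribution
        assert abs(est - 16.4) < 5.0


class TestSplit:
    def test_sizes_and_exclusivity(self):
        df = simulate_cohort(CohortSpec(n_low_risk=90, n_high_risk=20, seed=1))
        train, test = split_cohort(df, seed=0)
        assert len(train) == 63 and len(test) == 47
        assert (train.group == "low_risk").all()
        assert set(train.subject_id).isdisjoint(test.subject_id)
        assert set(train.subject_id) | set(test.subject_id) == set(df.subject_id)

    def test_reseed_permutes_membership_preserves_sizes(self):
        df = simulate_cohort(CohortSpec(n_low_risk=90, n_high_risk=0, seed=1))
        t0, _ = split_cohort(df, seed=0)
        t1, _ = split_cohort(df, seed=1)
        assert len(t0) == len(t1) == 63
        assert set(t0.subject_id) != set(t1.subject_id)

    def test_bad_inputs(self):
        df = simulate_cohort(CohortSpec(n_low_risk=12, n_high_risk=0, seed=1))
        with pytest.raises(ValueError):
            split_cohort(df, ratio=(7, 0))
        with pytest.raises(ValueError):
            split_cohort(df.head(5))


class TestProjection:
    def test_round_trip_identity(self, fitted):
        model, X = fitted
        back = model.inverse_transform(model.transform(X))
        assert np.abs(back - X).max() < 1e-10

    def test_rotation_orthonormal_and_sign_convention(self, fitted):
        model, X = fitted
        U = model.rotation_
        assert np.abs(U.T @ U - np.eye(2)).max() < 1e-10
        assert U[0, 0] > 0 and U[1, 1] > 0
        # refit gives the identical rotation (deterministic SVD signs)
        refit = TLSGPNormativeModel(random_state=1).fit(X)
        assert np.array_equal(refit.rotation_, U)

    def test_collinear_data(self):
        ga = np.linspace(20, 40, 30)
        X = np.column_stack([ga, 180 - 3.5 * ga])
        m = TLSGPNormativeModel(random_state=0).fit(X)
        assert np.abs(m.train_proj_[:, 1]).max() < 1e-12
        c = m.predict_curve([25.0, 30.0, 35.0])
        line = 180 - 3.5 * c["age"].to_numpy()
        assert np.abs(c["mean"].to_numpy() - line).max() < 1e-8
        # bands collapse onto the line
        assert np.abs(c["upper_3"] - c["lower_3"]).max() < 1e-6

    def test_swap_symmetry(self, cohort90):
        Xa = cohort90[["ga_weeks", "mean_t2s"]].to_numpy()
        A = TLSGPNormativeModel(sigma_eps=1.3, sigma_delta=8.7, random_state=0).fit(Xa)
        B = TLSGPNormativeModel(sigma_eps=8.7, sigma_delta=1.3, random_state=0).fit(
            Xa[:, ::-1]
        )
        za, zb = A.z_score(Xa), B.z_score(Xa[:, ::-1])
        assert np.abs(np.abs(za) - np.abs(zb)).max() < 1e-6

    def test_degenerate_data_rejected(self):
        X = np.column_stack([np.full(10, 30.0), np.linspace(40, 120, 10)])
        with pytest.raises(ValueError):
            TLSGPNormativeModel().fit(X)


class TestScoring:
    def test_on_curve_point_scores_zero(self, fitted):
        model, _ = fitted
        c = model.predict_curve([30.0])
        z = model.z_score([[30.0, float(c["mean"][0])]])
        assert abs(z[0]) < 1e-4

    def test_z_monotone_in_t2s(self, fitted):
        model, _ = fitted
        t2s = np.linspace(20, 150, 60)
        z = model.z_score(np.column_stack([np.full(60, 30.0), t2s]))
        assert np.all(np.diff(z) > 0)  # lower T2* => lower Z

    def test_band_ordering_and_halfwidth(self, fitted):
        model, _ = fitted
        c = model.predict_curve(np.linspace(24, 36, 13))
        assert (c["lower_3"] < c["lower_1.96"]).all()
        assert (c["lower_1.96"] < c["mean"]).all()
        assert (c["mean"] < c["upper_1.96"]).all()
        assert (c["upper_1.96"] < c["upper_3"]).all()

    def test_projected_band_matches_direct_gp_query(self, fitted):
        model, _ = fitted
        t = np.array([[0.0]])
        m, s = model.gp_.predict(t, return_std=True)
        lo = model.inverse_transform(np.column_stack([t, m - 1.96 * s]))
        hi = model.inverse_transform(np.column_stack([t, m + 1.96 * s]))
        # band half-width in projected space is exactly 1.96 * predictive SD
        proj_width = model.transform(hi)[0, 1] - model.transform(lo)[0, 1]
        assert proj_width == pytest.approx(2 * 1.96 * s[0], rel=1e-9)

    def test_extrapolation_warns(self, fitted):
        model, _ = fitted
        with pytest.warns(UserWarning, match="training age range"):
            model.predict_curve([10.0])

    def test_nonfinite_inputs_rejected(self, fitted):
        model, _ = fitted
        with pytest.raises(ValueError):
            model.z_score([[np.nan, 80.0]])

    def test_test_set_z_calibration(self):
        df = simulate_cohort(CohortSpec(n_low_risk=90, n_high_risk=0, seed=4))
        train, test = split_cohort(df, seed=4)
        m = TLSGPNormativeModel(random_state=4).fit(
            train[["ga_weeks", "mean_t2s"]].to_numpy()
        )
        z = m.z_score(test[["ga_weeks", "mean_t2s"]].to_numpy())
        assert abs(z.mean()) < 0.3
        assert 0.7 < z.std() < 1.3


class TestProbability:
    def test_zero_noise_degenerate_limits(self, fitted):
        model, _ = fitted
        low = np.array([[30.0, 20.0]])  # far below the curve
        assert model.z_score(low)[0] < -3
        assert model.prob_accelerated_aging(low, n_samples=50, noise=ZeroNoise()) == 1.0
        c = model.predict_curve([30.0])
        on = np.array([[30.0, float(c["mean"][0])]])
        assert model.prob_accelerated_aging(on, n_samples=50, noise=ZeroNoise()) == 0.0

    def test_seeded_and_binomial_spread(self, fitted):
        model, _ = fitted
        probe = np.array([[32.0, 38.0]])  # sits near the Z=-3 boundary
        a = model.prob_accelerated_aging(probe, n_samples=2000, random_state=0)
        b = model.prob_accelerated_aging(probe, n_samples=2000, random_state=0)
        assert a == b
        ps = np.array(
            [
                model.prob_accelerated_aging(probe, n_samples=2000, random_state=s)[0]
                for s in range(8)
            ]
        )
        p = ps.mean()
        assert 0.05 < p < 0.95  # probe really is in the uncertain zone
        se = np.sqrt(p * (1 - p) / 2000)
        assert ps.std(ddof=1) < 3 * se

    def test_monotone_in_t2s_on_grid(self, fitted):
        model, _ = fitted
        t2s = np.array([30.0, 45.0, 60.0, 80.0, 100.0])
        X = np.column_stack([np.full(t2s.size, 30.0), t2s])
        p = model.prob_accelerated_aging(X, n_samples=4000, random_state=1)
        assert np.all(np.diff(p) <= 1e-12)  # non-increasing in T2*


class TestOLSContrast:
    def test_ols_coincides_on_collinear_data(self):
        ga = np.linspace(20, 40, 30)
        X = np.column_stack([ga, 180 - 3.5 * ga])
        ols = OLSGPBaseline(random_state=0).fit(X)
        assert np.abs(ols.predict(X[:, 1]) - ga).max() < 1e-3
        assert np.abs(ols.z_score(X)).max() < 0.01

    def test_tls_removes_age_bias_ols_keeps_it(self, cohort90):
        X = cohort90[["ga_weeks", "mean_t2s"]].to_numpy()
        tls = TLSGPNormativeModel(random_state=0).fit(X)
        ols = OLSGPBaseline(random_state=0).fit(X)
        r_tls = pearsonr(tls.z_score(X), X[:, 0]).statistic
        r_ols = pearsonr(ols.z_score(X), X[:, 0]).statistic
        assert abs(r_tls) < 0.15
        assert abs(r_ols) > 0.3
        s_tls = np.polyfit(X[:, 0], tls.z_score(X), 1)[0]
        s_ols = np.polyfit(X[:, 0], ols.z_score(X), 1)[0]
        assert abs(s_tls) < abs(s_ols) / 3
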