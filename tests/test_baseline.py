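"""Covariogram estimation, WLS covariance fitting and ordinary kriging."""

import math

import numpy as np
import pytest

from trophlink.baseline import (
    JITTER,
    BaselineObservation,
    CovarianceModel,
    baseline_for_stations,
    distance_matrix,
    empirical_covariogram,
    fit_covariance,
    haversine_km,
    krige,
)
from trophlink.synthetic import SyntheticConfig, make_baseline_field


class TestHaversine:
    def test_identity_symmetry_and_meridian_arc(self):
        assert haversine_km(50.0, 1.0, 50.0, 1.0) == 0.0
        assert haversine_km(50, 0, 51, 2) == pytest.approx(haversine_km(51, 2, 50, 0))
        # one degree of latitude on a 6371 km sphere
        assert haversine_km(50, 0, 51, 0) == pytest.approx(6371 * math.pi / 180, rel=1e-9)

    def test_latitude_validation(self):
        with pytest.raises(ValueError):
            haversine_km(95, 0, 50, 0)
        with pytest.raises(ValueError):
            distance_matrix(np.array([91.0]), np.array([0.0]))

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(1)
        lat, lon = rng.uniform(45, 55, 6), rng.uniform(-2, 3, 6)
        D = distance_matrix(lat, lon)
        for i in range(6):
            for j in range(6):
                assert D[i, j] == pytest.approx(
                    haversine_km(lat[i], lon[i], lat[j], lon[j]), abs=1e-9)


class TestEmpiricalCovariogram:
    def test_two_point_hand_computation(self):
        """z = (7, 8): deviations ±0.5, pair product −0.25."""
        obs = [BaselineObservation("a", 50.0, 1.0, 7.0),
               BaselineObservation("b", 50.05, 1.0, 8.0)]
        emp = empirical_covariogram(obs, bin_width=10.0, max_lag=50.0)
        assert emp.cov_hat[0] == pytest.approx(-0.25)
        assert emp.n_pairs[0] == 1

    def test_constant_field_has_zero_covariance(self):
        rng = np.random.default_rng(2)
        obs = [BaselineObservation(str(k), 50 + rng.uniform(0, 1),
                                   rng.uniform(0, 1), 7.69) for k in range(20)]
        emp = empirical_covariogram(obs, bin_width=10.0)
        assert np.allclose(emp.cov_hat, 0.0)

    def test_short_lag_covariance_near_sill(self):
        """Large simulated field: cov(≈0) ≈ sill within replicate spread."""
        vals = []
        for seed in range(10):
            field = make_baseline_field(SyntheticConfig(seed=seed, n_stations=400))
            emp = empirical_covariogram(field, bin_width=10.0)
            vals.append(emp.cov_hat[0])
        sill = 0.90**2
        spread = np.std(vals, ddof=1)
        assert abs(np.mean(vals) - sill) < 3 * spread / math.sqrt(len(vals)) + 0.05 * sill

    def test_errors(self):
        obs = [BaselineObservation("a", 50.0, 1.0, 7.0),
               BaselineObservation("b", 51.0, 1.0, 8.0)]
        with pytest.raises(ValueError, match="max_lag"):
            empirical_covariogram(obs, bin_width=5.0, max_lag=1.0)
        with pytest.raises(ValueError):
            empirical_covariogram(obs[:1])


class TestFitCovariance:
    def _emp_from_model(self, sill, rng_km, family="gaussian", n=12):
        from trophlink.baseline import EmpiricalCovariogram, _correlation
        h = np.linspace(5, 115, n)
        return EmpiricalCovariogram(
            bin_mid=h, cov_hat=sill * _correlation(family, h, rng_km),
            n_pairs=np.arange(1, n + 1) * 10)

    def test_noise_free_inversion_is_exact(self):
        emp = self._emp_from_model(0.8, 40.0)
        m = fit_covariance(emp, "gaussian")
        assert m.sill == pytest.approx(0.8, abs=1e-4)
        assert m.range_km == pytest.approx(40.0, abs=1e-4)
        assert m.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_weight_scaling_invariance(self):
        emp = self._emp_from_model(0.5, 60.0)
        noisy = emp.cov_hat + np.array([0.02, -0.03, 0.01, 0.0, -0.01, 0.02,
                                        -0.02, 0.01, 0.0, 0.01, -0.01, 0.0])
        emp.cov_hat = noisy
        m1 = fit_covariance(emp, "gaussian")
        emp.n_pairs = emp.n_pairs * 17
        m2 = fit_covariance(emp, "gaussian")
        assert m1.sill == pytest.approx(m2.sill, rel=1e-6)
        assert m1.range_km == pytest.approx(m2.range_km, rel=1e-6)

    def test_matches_dense_grid_search_oracle(self):
        """WLS optimum agrees with a dense (sill, range) grid within resolution."""
        from trophlink.baseline import _correlation
        emp = self._emp_from_model(0.7, 50.0)
        emp.cov_hat = emp.cov_hat + np.sin(np.arange(12)) * 0.03  # deterministic noise
        m = fit_covariance(emp, "gaussian")

        def wls(sill, rng_km):
            resid = emp.cov_hat - sill * _correlation("gaussian", emp.bin_mid, rng_km)
            return float(np.sum(emp.n_pairs * resid**2))

        sills = np.linspace(0.3, 1.2, 181)
        ranges = np.linspace(10, 120, 221)
        grid_best = min(((wls(s, r), s, r) for s in sills for r in ranges))
        assert wls(m.sill, m.range_km) <= grid_best[0] + 1e-12
        assert abs(m.sill - grid_best[1]) <= (sills[1] - sills[0])
        assert abs(m.range_km - grid_best[2]) <= (ranges[1] - ranges[0])

    def test_parameter_recovery_from_simulated_fields(self):
        """Mean fitted (sill, range) over 20 seeds within 25% of truth."""
        sills, ranges = [], []
        for seed in range(20):
            field = make_baseline_field(SyntheticConfig(seed=seed, n_stations=500))
            emp = empirical_covariogram(field, bin_width=10.0)
            m = fit_covariance(emp, "gaussian")
            sills.append(m.sill)
            ranges.append(m.range_km)
        assert abs(np.mean(sills) - 0.81) / 0.81 < 0.25
        assert abs(np.mean(ranges) - 40.0) / 40.0 < 0.25

    def test_semivariogram_mode_recovers_same_parameters(self):
        from trophlink.baseline import EmpiricalCovariogram, _correlation
        h = np.linspace(5, 115, 12)
        emp = EmpiricalCovariogram(
            bin_mid=h, cov_hat=0.8 * (1 - _correlation("gaussian", h, 40.0)),
            n_pairs=np.full(12, 10), mode="semivariogram")
        m = fit_covariance(emp, "gaussian")
        assert m.sill == pytest.approx(0.8, abs=1e-4)
        assert m.range_km == pytest.approx(40.0, abs=1e-4)


def kriging_oracle(obs, model, target):
    """Independent ordinary-kriging solve by explicit matrix inversion."""
    n = len(obs)
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            h = haversine_km(obs[i].lat, obs[i].lon, obs[j].lat, obs[j].lon)
            A[i, j] = model.sill * math.exp(-((h / model.range_km) ** 2))
            if i == j:
                A[i, j] = model.sill + model.nugget + JITTER
        A[i, n] = A[n, i] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        h = haversine_km(obs[i].lat, obs[i].lon, target[0], target[1])
        b[i] = (model.sill + model.nugget if h == 0
                else model.sill * math.exp(-((h / model.range_km) ** 2)))
    b[n] = 1.0
    sol = np.linalg.inv(A) @ b
    lam = sol[:n]
    return float(lam @ np.array([o.d15N for o in obs])), lam


class TestKrige:
    def test_weights_sum_to_one_and_match_oracle(self, five_obs):
        model = CovarianceModel("gaussian", sill=0.8, range_km=40.0)
        rng = np.random.default_rng(3)
        for _ in range(25):
            target = (50.0 + rng.uniform(-0.3, 0.3), 1.0 + rng.uniform(-0.4, 0.4))
            res = krige(five_obs, model, [target])[0]
            assert abs(res.weights.sum() - 1.0) < 1e-8
            pred, lam = kriging_oracle(five_obs, model, target)
            assert res.d15N_pred == pytest.approx(pred, abs=1e-8)

    def test_exact_interpolation_at_observation_sites(self, five_obs):
        model = CovarianceModel("gaussian", sill=0.8, range_km=40.0)
        targets = [(o.lat, o.lon) for o in five_obs]
        for o, res in zip(five_obs, krige(five_obs, model, targets)):
            assert res.d15N_pred == pytest.approx(o.d15N, abs=1e-6)
            assert res.krig_var == pytest.approx(0.0, abs=1e-6)

    def test_midpoint_of_two_equal_observations(self):
        obs = [BaselineObservation("a", 50.0, 0.0, 7.0),
               BaselineObservation("b", 50.0, 1.0, 8.0)]
        model = CovarianceModel("gaussian", sill=1.0, range_km=50.0)
        res = krige(obs, model, [(50.0, 0.5)])[0]
        assert np.allclose(res.weights, [0.5, 0.5], atol=1e-9)
        assert res.d15N_pred == pytest.approx(7.5)

    def test_single_observation_degenerate_case(self):
        obs = [BaselineObservation("a", 50.0, 0.0, 7.3)]
        model = CovarianceModel("gaussian", sill=1.0, range_km=50.0)
        res = krige(obs, model, [(51.0, 1.0)])[0]
        assert res.d15N_pred == 7.3
        assert res.weights.sum() == 1.0

    def test_duplicate_locations_are_averaged(self):
        obs = [BaselineObservation("a", 50.0, 0.0, 7.0),
               BaselineObservation("b", 50.0, 0.0, 9.0),
               BaselineObservation("c", 50.0, 1.0, 8.0)]
        model = CovarianceModel("gaussian", sill=1.0, range_km=50.0)
        res = krige(obs, model, [(50.0, 0.0)])[0]
        assert res.d15N_pred == pytest.approx(8.0)  # average of the duplicates

    def test_nonneg_weights_imply_bounded_predictions(self, five_obs):
        model = CovarianceModel("exponential", sill=0.8, range_km=40.0)
        zmin = min(o.d15N for o in five_obs)
        zmax = max(o.d15N for o in five_obs)
        rng = np.random.default_rng(4)
        for _ in range(20):
            target = (50.0 + rng.uniform(-0.3, 0.3), 1.0 + rng.uniform(-0.4, 0.4))
            res = krige(five_obs, model, [target])[0]
            if np.all(res.weights >= -1e-10):
                assert zmin - 1e-9 <= res.d15N_pred <= zmax + 1e-9


class TestBaselineForStations:
    def test_colocated_stations_use_observed_values(self, study):
        import pandas as pd
        obs = [BaselineObservation(str(r.id), float(r.lat), float(r.lon),
                                   float(r.d15N))
               for r in study.baseline_obs.itertuples(index=False)]
        table, model = baseline_for_stations(obs, study.stations)
        merged = table.merge(study.baseline_obs, left_on="station_id",
                             right_on="id", how="inner")
        assert (merged["source"] == "observed").all()
        assert np.allclose(merged["d15N_baseline"], merged["d15N"])

    def test_heldout_interpolation_beats_field_sd(self, study):
        obs = [BaselineObservation(str(r.id), float(r.lat), float(r.lon),
                                   float(r.d15N))
               for r in study.baseline_obs.itertuples(index=False)]
        table, _ = baseline_for_stations(obs, study.stations)
        held = study.stations[~study.stations.station_id.isin(study.baseline_obs.id)]
        k = table.set_index("station_id").loc[held.station_id]
        mae = np.mean(np.abs(k["d15N_baseline"].to_numpy()
                             - held["d15N_baseline_true"].to_numpy()))
        assert mae < 0.90  # field SD

    def test_constant_observations_give_constant_baseline(self):
        import pandas as pd
        rng = np.random.default_rng(5)
        obs = [BaselineObservation(str(k), 50 + rng.uniform(0, 1),
                                   rng.uniform(0, 1), 7.69) for k in range(15)]
        stations = pd.DataFrame({
            "station_id": ["t1", "t2"], "lat": [50.2, 50.7], "lon": [0.3, 0.6]})
        table, _ = baseline_for_stations(obs, stations)
        assert np.allclose(table["d15N_baseline"], 7.69, atol=1e-6)
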