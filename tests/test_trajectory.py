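"""Nearest-neighbor expected-response model and failure boundary."""

import numpy as np
import pytest
from scipy import stats as sps

from otrack.trajectory import (
    ExpectedTrajectoryModel,
    ReferencePool,
    TrajectoryConfig,
    boundary,
    dynamic_boundary_sequence,
    fit_expected_model,
    fit_patient_slope,
    select_neighbors,
)


def _pool_from_law(n_patients, rng, beta=(1.8, -0.4, 0.005, 0.004),
                   sigma_p=0.2, sigma_e=0.1, t_range=(10, 30)):
    b0, b1, b2, b3 = beta
    trajectories = {}
    for pid in range(n_patients):
        T = int(rng.integers(*t_range))
        u = rng.normal(0, sigma_p)
        s = np.arange(1, T + 1)
        y = b0 + u + b1 * np.log(s) + b2 * T + b3 * np.log(s) * T \
            + rng.normal(0, sigma_e, T)
        trajectories[pid] = dict(zip(s.tolist(), y.tolist()))
    return ReferencePool.from_trajectories(trajectories)


class TestPatientSlope:
    def test_constant_trajectory_slope_zero(self):
        assert fit_patient_slope([1, 2, 3, 4], [1.5] * 4) == pytest.approx(0.0)

    def test_exact_log_law_recovered(self):
        s = np.arange(1, 8)
        y = 2.0 - 0.5 * np.log(s)
        assert fit_patient_slope(s, y) == pytest.approx(-0.5)

    def test_matches_closed_form_ols(self):
        s = np.array([1, 2, 3, 4])
        y = np.array([1.8, 1.2, 0.9, 0.7])
        x = np.log(s)
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sum((x - x.mean()) ** 2))
        assert fit_patient_slope(s, y) == pytest.approx(expected)

    def test_fewer_than_three_sessions_excluded(self):
        assert fit_patient_slope([1, 2], [2.0, 1.0]) is None

    def test_improving_flag_means_negative_slope(self, rng):
        pool = _pool_from_law(20, rng)
        for p in pool.patients:
            assert p.improving == (p.slope < 0)


class TestSelectNeighbors:
    def test_identical_trajectory_ranks_first(self, rng):
        pool = _pool_from_law(10, rng)
        target = pool.improving()[0]
        history = dict(zip(target.sessions[:6], target.hscl[:6]))
        ids = select_neighbors(history, pool, k=3)
        assert ids[0] == target.patient_id

    def test_k_equal_pool_returns_all_eligible(self, rng):
        pool = _pool_from_law(8, rng)
        eligible = [p for p in pool.improving() if p.total_sessions >= 6]
        history = {s: 1.5 for s in range(1, 7)}
        ids = select_neighbors(history, pool, k=len(pool))
        assert sorted(ids) == sorted(p.patient_id for p in eligible)

    def test_ranking_matches_brute_force(self, rng):
        """Five-patient toy pool: ranking equals exhaustive enumeration."""
        pool = _pool_from_law(5, rng, sigma_p=0.4, t_range=(8, 15))
        history = {s: 1.6 - 0.2 * np.log(s) for s in range(1, 7)}
        dists = []
        for p in pool.improving():
            if p.total_sessions < 6:
                continue
            idx = {s: i for i, s in enumerate(p.sessions)}
            d = np.sqrt(np.mean([(history[s] - p.hscl[idx[s]]) ** 2
                                 for s in history]))
            dists.append((d, p.patient_id))
        expected = [pid for _, pid in sorted(dists)]
        assert select_neighbors(history, pool, k=len(expected)) == expected

    def test_short_archival_courses_excluded(self, rng):
        pool = _pool_from_law(10, rng, t_range=(4, 9))
        history = {s: 1.5 for s in range(1, 9)}
        ids = select_neighbors(history, pool, k=50, improving_only=False)
        assert all(pool[i].total_sessions >= 8 for i in ids)

    def test_zero_eligible_is_error(self, rng):
        pool = _pool_from_law(5, rng, t_range=(5, 8))
        with pytest.raises(ValueError):
            select_neighbors({s: 1.0 for s in range(1, 31)}, pool, k=5)

    def test_distance_vector_non_increasing_in_pool_size(self, rng):
        """A superset pool can only improve (or keep) selected distances."""
        big = _pool_from_law(30, rng)
        small = ReferencePool(big.patients[:12])
        history = {s: 1.5 - 0.1 * np.log(s) for s in range(1, 7)}

        def dist_vec(pool):
            ids = select_neighbors(history, pool, k=5)
            out = []
            for pid in ids:
                p = pool[pid]
                idx = {s: i for i, s in enumerate(p.sessions)}
                out.append(np.sqrt(np.mean(
                    [(history[s] - p.hscl[idx[s]]) ** 2 for s in history])))
            return np.array(out)

        assert np.all(dist_vec(big) <= dist_vec(small) + 1e-12)


class TestFitExpectedModel:
    def test_noise_free_coefficients_recovered(self, rng):
        beta = (1.7, -0.45, 0.006, 0.003)
        pool = _pool_from_law(12, rng, beta=beta, sigma_p=0.0, sigma_e=0.0,
                              t_range=(10, 28))
        ids = [p.patient_id for p in pool.patients]
        with pytest.warns(UserWarning):
            model = fit_expected_model(pool, ids)
        assert model.params == pytest.approx(beta, abs=1e-8)

    def test_zero_patient_variance_matches_ols(self, rng):
        pool = _pool_from_law(15, rng, sigma_p=0.0, sigma_e=0.15)
        ids = [p.patient_id for p in pool.patients]
        model = fit_expected_model(pool, ids)
        import statsmodels.api as sm
        rows = [(np.log(s), p.total_sessions, y)
                for p in pool.patients for s, y in zip(p.sessions, p.hscl)]
        arr = np.array(rows)
        X = sm.add_constant(np.column_stack(
            [arr[:, 0], arr[:, 1], arr[:, 0] * arr[:, 1]]))
        ols = sm.OLS(arr[:, 2], X).fit()
        assert model.params == pytest.approx(np.asarray(ols.params), abs=5e-2)

    def test_shared_total_sessions_drops_T_terms(self, rng):
        pool = _pool_from_law(8, rng, t_range=(15, 16))  # all T = 15
        ids = [p.patient_id for p in pool.patients]
        with pytest.warns(UserWarning):
            model = fit_expected_model(pool, ids)
        assert not model.has_T_terms and model.params.size == 2

    def test_parameter_recovery_coverage(self, rng):
        """Known generating coefficients fall in their 95% CIs >= 90/100."""
        beta = np.array([1.8, -0.4, 0.005, 0.004])
        hits = np.zeros(4)
        n_rep = 100
        for _ in range(n_rep):
            pool = _pool_from_law(50, rng, beta=tuple(beta), sigma_p=0.25,
                                  sigma_e=0.12)
            ids = [p.patient_id for p in pool.patients]
            model = fit_expected_model(pool, ids)
            if not model.has_T_terms:
                continue
            se = np.sqrt(np.diag(model.cov_params))
            hits += (np.abs(model.params - beta) <= 1.96 * se)
        assert np.all(hits >= 0.90 * n_rep * 0.97)


class TestBoundary:
    def _model(self, params=(1.0, 0.0), cov=None, var_p=0.0, var_e=0.0):
        p = np.asarray(params, dtype=float)
        cov = np.zeros((p.size, p.size)) if cov is None else cov
        return ExpectedTrajectoryModel(
            params=p, cov_params=cov, var_patient=var_p, var_resid=var_e,
            neighbor_ids=(0,), has_T_terms=(p.size == 4))

    def test_zero_se_upper_equals_expected(self):
        model = self._model()
        e, u = boundary(model, T_query=20, session=6)
        assert u == pytest.approx(e)

    def test_expected_one_se_fifth_gives_1329(self):
        model = self._model(var_e=0.04)  # flat curve at 1.0, SE = 0.2
        e, u = boundary(model, T_query=20, session=10)
        assert e == pytest.approx(1.0)
        assert u == pytest.approx(1.0 + sps.norm.ppf(0.95) * 0.2)
        assert round(u, 3) == 1.329

    def test_upper_monotone_in_se(self):
        uppers = [boundary(self._model(var_e=v), 20, 8)[1]
                  for v in (0.0, 0.01, 0.04, 0.09)]
        assert np.all(np.diff(uppers) > 0)

    @pytest.mark.parametrize("session", [5, 31])
    def test_outside_window_undefined(self, session):
        with pytest.raises(ValueError):
            boundary(self._model(), 20, session)


class TestDynamicBoundary:
    def test_deterministic_sequence(self, rng):
        pool = _pool_from_law(30, rng)
        history = {s: 1.6 - 0.25 * np.log(s) for s in range(1, 13)}
        cfg = TrajectoryConfig(k=10)
        fb1 = dynamic_boundary_sequence(0, history, pool, cfg,
                                        total_sessions=12)
        fb2 = dynamic_boundary_sequence(0, history, pool, cfg,
                                        total_sessions=12)
        assert fb1 == fb2
        assert fb1.sessions == tuple(range(6, 13))

    def test_upper_exceeds_expected_by_z_times_se(self, rng):
        pool = _pool_from_law(30, rng)
        history = {s: 1.6 - 0.25 * np.log(s) for s in range(1, 10)}
        fb = dynamic_boundary_sequence(0, history, pool, TrajectoryConfig(k=10),
                                       total_sessions=9)
        assert all(u >= e for e, u in zip(fb.expected, fb.upper))

    def test_single_neighbor_pool_tracks_that_curve(self, rng):
        pool = _pool_from_law(1, rng, sigma_p=0.0, sigma_e=0.0,
                              t_range=(20, 21))
        p = pool.patients[0]
        history = dict(zip(p.sessions, p.hscl))
        fb = dynamic_boundary_sequence(0, history, pool, TrajectoryConfig(k=1),
                                       total_sessions=p.total_sessions)
        idx = {s: i for i, s in enumerate(p.sessions)}
        for s, e in zip(fb.sessions, fb.expected):
            assert e == pytest.approx(p.hscl[idx[s]], abs=1e-6)

    def test_on_mean_patient_stays_under_boundary(self, rng):
        """A patient tracking the pool's mean curve never crosses."""
        beta = (1.7, -0.4, 0.005, 0.004)
        pool = _pool_from_law(40, rng, beta=beta, sigma_p=0.15, sigma_e=0.1)
        b0, b1, b2, b3 = beta
        T = 20
        history = {s: b0 + b1 * np.log(s) + b2 * T + b3 * np.log(s) * T
                   for s in range(1, T + 1)}
        fb = dynamic_boundary_sequence(0, history, pool, TrajectoryConfig(k=15),
                                       total_sessions=T)
        for s, u in zip(fb.sessions, fb.upper):
            assert history[s] <= u
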