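"""Group statistics: chi-square, t-tests, effect sizes and the nested GLMM."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.api as sm

from otrack.glmm import _gh_nodes, _loglik_and_grad, _prepare, \
    fit_nested_logistic_arrays
from otrack.stats import (ModelSpec, cohens_d, fit_nested_logistic,
                          grand_mean_center, item_comparison_report,
                          model_building, pearson_chi2, two_sample_t)
from otrack.synthetic import simulate_glmm_dataset


class TestGrandMeanCenter:
    def test_basic(self):
        assert grand_mean_center([1, 2, 3]) == pytest.approx([-1, 0, 1])

    def test_constant_vector_all_zero(self):
        assert grand_mean_center([4.2] * 5) == pytest.approx([0] * 5)

    def test_idempotent(self, rng):
        x = rng.normal(3, 2, 50)
        once = grand_mean_center(x)
        assert grand_mean_center(once) == pytest.approx(once)


class TestPearsonChi2:
    def test_equal_proportions_zero(self):
        assert pearson_chi2([[30, 70], [60, 140]]).chi2 == pytest.approx(0.0)

    def test_matches_direct_formula(self, rng):
        for _ in range(50):
            t = rng.integers(1, 200, (2, 2)).astype(float)
            res = pearson_chi2(t)
            row, col, n = t.sum(1), t.sum(0), t.sum()
            expected = np.outer(row, col) / n
            assert res.chi2 == pytest.approx(
                ((t - expected) ** 2 / expected).sum())
            assert res.df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [5, 10]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[1.5, 2], [3, 4]])


class TestTwoSampleT:
    def test_identical_groups(self):
        t, df, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_toy_groups_closed_form(self):
        # means 1 and 2, each variance 2, pooled var 2, n=2 each
        t, df, p = two_sample_t([0, 2], [1, 3])
        assert t == pytest.approx(-1 / np.sqrt(2))
        assert df == 2

    def test_swap_flips_sign_keeps_p(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        t1, _, p1 = two_sample_t(a, b)
        t2, _, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_variance(self):
        t, _, p = two_sample_t([2, 2], [2, 2])
        assert t == 0.0 and p == 1.0
        with pytest.raises(ValueError):
            two_sample_t([2, 2], [3, 3])


class TestCohensD:
    def test_treatment_length_effect_size(self):
        assert cohens_d(24.09, 14.25, 273, 32.07, 14.17, 140) == \
            pytest.approx(0.56, abs=5e-3)

    def test_equal_means_zero(self):
        assert cohens_d(5, 2, 10, 5, 3, 12) == pytest.approx(0.0)

    def test_equal_sds_closed_form(self):
        assert cohens_d(1.0, 2.0, 30, 2.0, 2.0, 30) == pytest.approx(0.5)

    def test_magnitude_convention(self):
        assert cohens_d(2.0, 1.0, 20, 1.0, 1.0, 20) == \
            cohens_d(1.0, 1.0, 20, 2.0, 1.0, 20)


class TestNestedLogistic:
    def test_gradient_matches_numerical(self):
        df = simulate_glmm_dataset(n_patients=25, n_therapists=5,
                                   sessions_per_patient=4,
                                   beta={"intercept": -1.0, "risk": 0.8},
                                   sigma_patient=1.0, sigma_therapist=0.4,
                                   seed=3)
        X = np.column_stack([np.ones(len(df)), df.risk])
        prep = _prepare(df.not_on_track.to_numpy(float), X,
                        df.patient_id.to_numpy(), df.therapist_id.to_numpy())
        y_s, X_s, pat_idx, row_starts, ther_starts, _, _ = prep
        z_p, lw_p = _gh_nodes(11)
        z_t, lw_t = _gh_nodes(11)
        theta = np.array([-0.7, 0.6, 0.8, 0.3])
        _, g = _loglik_and_grad(theta, y_s, X_s, pat_idx, row_starts,
                                ther_starts, z_t, lw_t, z_p, lw_p)
        num = np.empty_like(theta)
        for i in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += 1e-6
            tm[i] -= 1e-6
            fp, _ = _loglik_and_grad(tp, y_s, X_s, pat_idx, row_starts,
                                     ther_starts, z_t, lw_t, z_p, lw_p)
            fm, _ = _loglik_and_grad(tm, y_s, X_s, pat_idx, row_starts,
                                     ther_starts, z_t, lw_t, z_p, lw_p)
            num[i] = (fp - fm) / 2e-6
        assert g == pytest.approx(num, rel=1e-5, abs=1e-6)

    def test_zero_variance_matches_single_level_glm(self):
        df = simulate_glmm_dataset(n_patients=300, n_therapists=10,
                                   sessions_per_patient=8,
                                   beta={"intercept": -1.0, "session": 0.15,
                                         "risk": 0.8},
                                   sigma_patient=0.0, sigma_therapist=0.0,
                                   seed=2)
        X = np.column_stack([np.ones(len(df)), df.session, df.risk])
        y = df.not_on_track.to_numpy(float)
        res = fit_nested_logistic_arrays(y, X, df.patient_id.to_numpy(),
                                         df.therapist_id.to_numpy())
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert res.params == pytest.approx(np.asarray(glm.params), abs=1e-2)
        assert res.var_patient < 0.05 and res.var_therapist < 0.05

    def test_matches_lme4_glmer_oracle(self, tmp_path):
        """Independent cross-check against lme4::glmer with nAGQ=25."""
        df = simulate_glmm_dataset(n_patients=120, n_therapists=15,
                                   sessions_per_patient=8,
                                   beta={"intercept": -1.5, "session": 0.1,
                                         "risk": 1.0},
                                   sigma_patient=1.2, seed=7)
        csv = tmp_path / "fix.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(not_on_track ~ session + risk + (1|patient_id),
                       data=d, family=binomial, nAGQ=25)
            co <- summary(m)$coefficients
            cat(sprintf("%.8f\\n", c(co[,1], co[,2], logLik(m), AIC(m),
                sqrt(unlist(VarCorr(m))))))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        vals = np.array([float(v) for v in out.stdout.split()])
        r_params, r_bse = vals[:3], vals[3:6]
        r_llf, r_aic, r_sd = vals[6], vals[7], vals[8]

        X = np.column_stack([np.ones(len(df)), df.session, df.risk])
        res = fit_nested_logistic_arrays(
            df.not_on_track.to_numpy(float), X, df.patient_id.to_numpy(),
            None, n_quad=25)
        assert res.params == pytest.approx(r_params, abs=1e-3)
        assert res.llf == pytest.approx(r_llf, abs=1e-3)
        assert res.aic == pytest.approx(r_aic, abs=1e-2)
        assert np.sqrt(res.var_patient) == pytest.approx(r_sd, abs=1e-3)
        assert res.bse == pytest.approx(r_bse, rel=0.02)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_nested_logistic_arrays(
                np.zeros(20), np.ones((20, 1)), np.repeat(np.arange(5), 4))

    def test_icc_in_unit_interval(self):
        df = simulate_glmm_dataset(n_patients=150, n_therapists=15,
                                   sessions_per_patient=6,
                                   beta={"intercept": -1.0},
                                   sigma_patient=1.5, sigma_therapist=0.5,
                                   seed=5)
        res = fit_nested_logistic(df, ModelSpec())
        assert 0.0 <= res.icc_patient <= 1.0
        assert res.var_patient > 0.3


class TestModelBuilding:
    def test_time_trend_prefers_model2_and_trace_deterministic(self):
        df = simulate_glmm_dataset(n_patients=200, n_therapists=20,
                                   sessions_per_patient=10,
                                   beta={"intercept": -3.0, "session": 0.15,
                                         "risk": 1.0, "life_events": -0.7},
                                   sigma_patient=1.2, seed=4)
        for col in ("motivation", "alliance", "social_support",
                    "emotion_regulation"):
            if col not in df:
                rng = np.random.default_rng(hash(col) % 2 ** 31)
                trait = rng.normal(size=df.patient_id.nunique())
                df[col] = trait[df.patient_id.to_numpy()]
        spec = ModelSpec(n_quad=9)
        mb1 = model_building(df, spec=spec)
        mb2 = model_building(df, spec=spec)
        assert mb1.base_model_name == "model2"
        assert mb1.model2.aic < mb1.model1.aic
        assert "risk" in mb1.retained_domains
        assert mb1.trace == mb2.trace
        assert mb1.retained_domains == mb2.retained_domains


class TestItemComparison:
    def _items(self, values_by_group):
        rows = []
        pid = 0
        for is_not, values in values_by_group:
            for v in [values] if np.isscalar(values[0]) else values:
                for item, val in enumerate(v, start=1):
                    rows.append({"patient_id": pid, "instrument": "ASC",
                                 "item": item, "value": float(val)})
                pid += 1
        return pd.DataFrame(rows)

    def test_percent_crossing_matches_hand_count(self):
        """Ten-patient fixture: crossing percentages by direct enumeration."""
        ot = [[1, 5], [2, 5], [3, 5], [4, 5], [5, 5]]   # item1: 2/5 <= 2
        nt = [[1, 5], [1, 5], [2, 5], [3, 5], [5, 5]]   # item1: 3/5 <= 2
        items = self._items([(False, ot), (True, nt)])
        labels = {i: i >= 5 for i in range(10)}
        cutoffs = {("ASC", 1): (2, "at_or_below"), ("ASC", 2): (2, "at_or_below")}
        rep = item_comparison_report(items, labels, cutoffs).set_index("item")
        assert rep.loc[1, "pct_crossed_ot"] == pytest.approx(40.0)
        assert rep.loc[1, "pct_crossed_not"] == pytest.approx(60.0)
        assert rep.loc[2, "pct_crossed_ot"] == pytest.approx(0.0)

    def test_identical_groups_nothing_significant(self, rng):
        vals = rng.integers(1, 6, (20, 3))
        items = self._items([(False, vals[:10].tolist()),
                             (True, vals[:10].tolist())])
        labels = {i: i >= 10 for i in range(20)}
        rep = item_comparison_report(items, labels, {})
        assert (rep["p"].dropna() > 0.05).all()
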