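"""Logistic per-pair estimation, the OR-from-fit formula, delta-method SEs."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from pairodds import (
    DegenerateDataError,
    SurveyTable,
    directed_odds_ratio,
    estimate_all_pairs,
    estimates_to_frame,
    fit_pair_logistic,
    or_from_fit,
)
from pairodds.contingency import DirectedPair, PairContingency
from pairodds.estimation import _log_or_gradient, _raw_or_matrices

from conftest import realize_table

AB = DirectedPair(predictor="B", target="A")


class TestSurveyTable:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="0/1"):
            SurveyTable(pd.DataFrame({"a": [0, 2], "b": [1, 0]}))

    def test_rejects_duplicate_surveys(self):
        frame = pd.DataFrame({"a": [0, 1]}, index=["s1", "s1"])
        with pytest.raises(ValueError, match="unique"):
            SurveyTable(frame)

    def test_rejects_unmapped_site(self):
        with pytest.raises(ValueError, match="site"):
            SurveyTable(pd.DataFrame({"a": [0, 1]}), sites=[1, np.nan])

    def test_pair_table_and_prevalence(self):
        st = realize_table(15, 35, 5, 45)
        t = st.pair_table("A", "B")
        assert (t.c, t.d, t.e, t.f) == (15, 35, 5, 45)
        assert st.prevalence()["A"] == pytest.approx(0.5)
        assert st.prevalence()["B"] == pytest.approx(0.2)


class TestLogisticFit:
    def test_saturated_fit_reproduces_cell_proportions(self):
        st = realize_table(15, 35, 5, 45)
        fit = fit_pair_logistic(st, AB)
        assert fit.z0 == pytest.approx(logit(35 / 80), rel=1e-12)
        assert fit.z1 == pytest.approx(logit(15 / 20), rel=1e-12)
        assert fit.b == pytest.approx(0.2)
        assert fit.converged and not fit.boundary

    def test_matches_statsmodels_glm(self):
        """Closed-form MLE against iteratively reweighted least squares."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        X = (rng.random((300, 2)) < [0.45, 0.3]).astype(int)
        st = SurveyTable(pd.DataFrame(X, columns=["A", "B"]))
        fit = fit_pair_logistic(st, AB)
        glm = sm.GLM(
            X[:, 0], sm.add_constant(X[:, 1].astype(float)),
            family=sm.families.Binomial(),
        ).fit()
        assert fit.z0 == pytest.approx(glm.params[0], abs=1e-6)
        assert fit.z1 - fit.z0 == pytest.approx(glm.params[1], abs=1e-6)
        assert np.allclose(fit.coef_cov, glm.cov_params(), atol=1e-6)

    def test_separation_flagged_as_boundary(self):
        frame = pd.DataFrame({"A": [0, 1, 0, 1], "B": [0, 1, 0, 1]})
        fit = fit_pair_logistic(SurveyTable(frame), AB)
        assert fit.boundary and not fit.converged
        assert math.isinf(fit.z1)

    def test_constant_predictor_rejected(self):
        frame = pd.DataFrame({"A": [0, 1, 0, 1], "B": [1, 1, 1, 1]})
        with pytest.raises(DegenerateDataError):
            fit_pair_logistic(SurveyTable(frame), AB)

    def test_slope_recovery_within_three_se(self):
        """At n=800 the estimated slope lands within 3 SEs of the generating
        slope in effectively all replicates."""
        beta0, beta1, b = -1.0, 1.2, 0.4
        hits = 0
        reps = 500
        for r in range(reps):
            rng = np.random.default_rng(10_000 + r)
            x = (rng.random(800) < b).astype(np.int8)
            y = (rng.random(800) < expit(beta0 + beta1 * x)).astype(np.int8)
            st = SurveyTable(pd.DataFrame({"A": y, "B": x}))
            fit = fit_pair_logistic(st, AB)
            hits += abs((fit.z1 - fit.z0) - beta1) <= 3.0 * math.sqrt(fit.coef_cov[1, 1])
        assert hits / reps >= 0.99


class TestOrFromFit:
    def test_equals_closed_form_on_worked_example(self):
        st = realize_table(15, 35, 5, 45)
        est = or_from_fit(fit_pair_logistic(st, AB), AB)
        assert est.or_value == pytest.approx(3.0, rel=1e-12)

    def test_zero_slope_gives_or_exactly_one(self):
        st = realize_table(12, 28, 18, 42)  # independent margins
        fit = fit_pair_logistic(st, AB)
        est = or_from_fit(fit, AB)
        assert est.or_value == 1.0
        assert est.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("cells", [(0, 10, 10, 80), (10, 20, 0, 70)])
    def test_boundary_or_has_no_uncertainty(self, cells):
        st = realize_table(*cells)
        est = or_from_fit(fit_pair_logistic(st, AB), AB)
        assert est.or_value in (0.0, math.inf)
        assert math.isnan(est.log_or_se)
        assert math.isnan(est.p_value)
        assert est.status == "boundary"

    def test_fuzzed_equality_with_contingency_form(self):
        """The model-derived OR reconstructs the closed-form directed OR."""
        rng = np.random.default_rng(99)
        for _ in range(300):
            c, d, e, f = rng.integers(1, 60, size=4)
            st = realize_table(c, d, e, f)
            est = or_from_fit(fit_pair_logistic(st, AB), AB)
            closed = directed_odds_ratio(st.pair_table("A", "B"), "A")
            assert est.or_value == pytest.approx(closed, rel=1e-9)

    def test_ci_brackets_estimate(self):
        st = realize_table(15, 35, 5, 45)
        est = or_from_fit(fit_pair_logistic(st, AB), AB)
        assert est.ci_low <= est.or_value <= est.ci_high

    def test_gradient_matches_finite_differences(self):
        for z0, z1, b in [(-0.5, 0.8, 0.3), (1.2, -0.4, 0.7), (0.0, 2.0, 0.5)]:
            g0, g1, _ = _log_or_gradient(z0, z1, b)

            def log_or(b0, b1):
                pbar = (1 - b) * expit(b0) + b * expit(b0 + b1)
                return (b0 + b1) - logit(pbar)

            h = 1e-6
            fd0 = (log_or(z0 + h, z1 - z0) - log_or(z0 - h, z1 - z0)) / (2 * h)
            fd1 = (log_or(z0, z1 - z0 + h) - log_or(z0, z1 - z0 - h)) / (2 * h)
            assert g0 == pytest.approx(fd0, rel=1e-4)
            assert g1 == pytest.approx(fd1, rel=1e-4)

    def test_delta_se_matches_bootstrap(self):
        """Delta-method SE of log OR vs a 10,000-draw nonparametric
        bootstrap over surveys on the worked-example proportions (n=400,
        where no bootstrap draw lands on an empty cell)."""
        rng = np.random.default_rng(2024)
        st = realize_table(60, 140, 20, 180)
        est = or_from_fit(fit_pair_logistic(st, AB), AB)
        X = st.presence.to_numpy()
        n = len(X)
        draws = []
        for _ in range(10_000):
            m = _raw_or_matrices(X[rng.integers(0, n, n)])
            if np.isfinite(m["log_or"][0, 1]):
                draws.append(m["log_or"][0, 1])
        boot_se = float(np.std(draws, ddof=1))
        assert est.log_or_se == pytest.approx(boot_se, rel=0.10)


class TestEstimateAllPairs:
    def test_counts_and_ordering(self):
        rng = np.random.default_rng(1)
        X = (rng.random((120, 5)) < 0.4).astype(int)
        st = SurveyTable(pd.DataFrame(X, columns=list("edcba")))
        ests = estimate_all_pairs(st, "raw")
        assert len(ests) == 5 * 4
        keys = [(e.target, e.predictor) for e in ests]
        assert keys == sorted(keys)

    def test_two_species_two_estimates(self):
        st = realize_table(15, 35, 5, 45)
        assert len(estimate_all_pairs(st, "raw")) == 2

    def test_raw_and_logistic_agree(self):
        rng = np.random.default_rng(8)
        X = (rng.random((250, 6)) < [0.2, 0.35, 0.5, 0.65, 0.3, 0.45]).astype(int)
        st = SurveyTable(pd.DataFrame(X, columns=list("abcdef")))
        raw = estimate_all_pairs(st, "raw")
        log = estimate_all_pairs(st, "logistic")
        for a, b in zip(raw, log):
            assert (a.target, a.predictor) == (b.target, b.predictor)
            assert a.or_value == pytest.approx(b.or_value, rel=1e-9)
            if not math.isnan(a.log_or_se):
                assert a.log_or_se == pytest.approx(b.log_or_se, rel=1e-9)

    def test_degenerate_species_flagged_not_fatal(self):
        frame = pd.DataFrame(
            {"a": [1, 0, 1, 0], "b": [1, 1, 1, 1], "c": [0, 1, 1, 0]}
        )
        ests = estimate_all_pairs(SurveyTable(frame), "raw")
        assert len(ests) == 6
        frame_out = estimates_to_frame(ests)
        involving_b = frame_out[(frame_out.target == "b") | (frame_out.predictor == "b")]
        assert (involving_b.status == "degenerate").all()

    def test_wald_interval_coverage_at_null(self):
        """95% Wald interval covers OR=1 in 93-97% of replicates
        (independent surveys, n=800, prevalences 0.3/0.3)."""
        covered = 0
        reps = 1000
        for r in range(reps):
            rng = np.random.default_rng(20_000 + r)
            X = (rng.random((800, 2)) < 0.3).astype(np.int8)
            m = _raw_or_matrices(X)
            lo = m["log_or"][0, 1]
            se = m["se"][0, 1]
            covered += abs(lo) <= 1.959963984540054 * se
        assert 0.93 <= covered / reps <= 0.97
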