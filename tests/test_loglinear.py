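"""Log-linear capture-recapture fitting: model enumeration, deviance and
information criteria, missing-cell estimation, identifiability flags,
intervals, selection, and completeness.

Cross-checks use two independent routes: iterative proportional fitting for
the independence model, and statsmodels' Poisson GLM for arbitrary designs.
"""

import dataclasses
import math

import numpy as np
import pytest
import statsmodels.api as sm

from crcbias import (
    CaptureRecapture,
    CaptureTable,
    LoglinearModelSpec,
    aic,
    bic,
    chi2_pvalue,
    enumerate_models,
)
from crcbias.capture import CELL_PATTERNS

INDEP = LoglinearModelSpec(frozenset())


def ipf_independence(cells, tol=1e-12, max_iter=20000):
    """Independence-model fitted cells by iterative proportional fitting:
    alternately rescales both levels of each source dichotomy to match the
    observed totals.  Entirely independent of the IRLS path."""
    y = np.asarray(cells, dtype=float)
    pats = np.asarray(CELL_PATTERNS)
    mu = np.ones(7)
    for _ in range(max_iter):
        mu_old = mu.copy()
        for ax in range(3):
            for level in (0, 1):
                mask = pats[:, ax] == level
                mu[mask] *= y[mask].sum() / mu[mask].sum()
        if np.max(np.abs(mu - mu_old)) < tol:
            break
    return mu


class TestEnumerateModels:
    def test_eight_distinct_specs(self):
        specs = enumerate_models()
        assert len(specs) == 8
        assert len({s.label for s in specs}) == 8

    def test_canonical_endpoints(self):
        specs = enumerate_models()
        assert specs[0].label == "A B C"
        assert specs[-1].label == "A B C AB AC BC"
        assert specs[-1].interactions == frozenset({"AB", "AC", "BC"})

    def test_df(self):
        assert [s.df for s in enumerate_models()] == [3, 2, 2, 2, 1, 1, 1, 0]


class TestCriteria:
    @pytest.mark.parametrize(
        "g2, df, expected", [(3.10, 3, -2.90), (0.0, 0, 0.0), (1.84, 2, -2.16)]
    )
    def test_aic(self, g2, df, expected):
        assert aic(g2, df) == pytest.approx(expected)

    def test_bic_zero_df_returns_g2(self):
        assert bic(2.7, 0, 34) == 2.7

    def test_bic_printed_formula(self):
        assert bic(3.10, 3, 34) == pytest.approx(3.10 - 3 * math.log(34 / (2 * math.pi)))
        assert bic(3.10, 3, 34) == pytest.approx(-1.97, abs=0.005)

    @pytest.mark.parametrize("g2, df", [(0.0, 3), (0.0, 0)])
    def test_chi2_pvalue_zero_deviance(self, g2, df):
        assert chi2_pvalue(g2, df) == 1.0

    def test_chi2_pvalue_review_deviance(self, review_table):
        """The review's independence deviance maps to its printed p-value."""
        fit = CaptureRecapture(review_table).fit(INDEP, ci_level=None)
        assert chi2_pvalue(fit.g2, 3) == pytest.approx(0.3767, abs=5e-5)

    def test_chi2_pvalue_rejects_negative(self):
        with pytest.raises(ValueError):
            chi2_pvalue(-1.0, 2)


class TestFitModel:
    def test_exact_independence_table(self, independence_table):
        fit = CaptureRecapture(independence_table).fit(INDEP)
        assert fit.g2 == pytest.approx(0.0, abs=1e-8)
        assert fit.x_hat == pytest.approx(10.0, abs=1e-6)
        assert fit.n_est == pytest.approx(80.0, abs=1e-6)

    def test_review_independence_fit(self, review_table):
        fit = CaptureRecapture(review_table).fit(INDEP, ci_level=None)
        assert fit.g2 == pytest.approx(3.10, abs=0.005)
        assert fit.p == pytest.approx(0.3767, abs=5e-5)
        assert round(fit.x_hat) == 5 and round(fit.n_est) == 39

    def test_review_divergent_fit_flagged(self, review_table):
        fit = CaptureRecapture(review_table).fit(
            LoglinearModelSpec(frozenset({"AB", "BC"})), ci_level=None
        )
        assert not fit.identifiable
        assert math.isinf(fit.x_hat) and math.isinf(fit.n_est)

    def test_saturated_zero_deviance_any_positive_table(self):
        rng = np.random.default_rng(3)
        saturated = LoglinearModelSpec(frozenset({"AB", "AC", "BC"}))
        for _ in range(10):
            table = CaptureTable(*rng.integers(1, 30, size=7))
            fit = CaptureRecapture(table).fit(saturated, ci_level=None)
            assert fit.g2 == pytest.approx(0.0, abs=1e-6)

    def test_likelihood_equations_margins_match(self, review_table):
        """Fitted totals equal observed totals for every term in the model."""
        pats = np.asarray(CELL_PATTERNS)
        y = np.asarray(review_table.cells, dtype=float)
        model = CaptureRecapture(review_table)
        for spec in enumerate_models():
            fit = model.fit(spec, ci_level=None)
            mu = fit.fitted
            assert mu.sum() == pytest.approx(y.sum(), abs=1e-6)
            for ax in range(3):
                mask = pats[:, ax] == 1
                assert mu[mask].sum() == pytest.approx(y[mask].sum(), abs=1e-6)
            axes = {"AB": (0, 1), "AC": (0, 2), "BC": (1, 2)}
            for term in spec.interactions:
                i, j = axes[term]
                mask = (pats[:, i] == 1) & (pats[:, j] == 1)
                assert mu[mask].sum() == pytest.approx(y[mask].sum(), abs=1e-6)

    def test_independence_matches_ipf_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            table = CaptureTable(*rng.integers(1, 25, size=7))
            fit = CaptureRecapture(table).fit(INDEP, ci_level=None)
            mu_ipf = ipf_independence(table.cells)
            np.testing.assert_allclose(fit.fitted, mu_ipf, atol=1e-6)
            x_ipf = mu_ipf[0] * mu_ipf[1] / mu_ipf[3]  # exp(intercept)
            assert fit.x_hat == pytest.approx(x_ipf, abs=1e-6)

    def test_matches_statsmodels_glm(self, review_table):
        y = np.asarray(review_table.cells, dtype=float)
        model = CaptureRecapture(review_table)
        for spec in (INDEP, LoglinearModelSpec(frozenset({"AC"}))):
            fit = model.fit(spec, ci_level=None)
            glm = sm.GLM(y, spec.design(), family=sm.families.Poisson()).fit()
            np.testing.assert_allclose(fit.params, glm.params, atol=1e-6)
            assert fit.g2 == pytest.approx(glm.deviance, abs=1e-8)

    def test_x_hat_invariant_to_source_relabeling(self, review_table):
        base = CaptureRecapture(review_table).fit(INDEP, ci_level=None).x_hat
        for order in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            permuted = review_table.permute(order)
            x = CaptureRecapture(permuted).fit(INDEP, ci_level=None).x_hat
            assert x == pytest.approx(base, rel=1e-8)


class TestFitAll:
    def test_review_table_one_rows(self, review_table):
        fits = CaptureRecapture(review_table).fit_all(ci_level=None)
        rows = [f.summary_row() for f in fits]
        assert [(r["N_est"], r["X"]) for r in rows[:4]] == [
            (39, 5),
            (40, 6),
            (38, 4),
            (41, 7),
        ]
        assert sum(not f.identifiable for f in fits) == 2
        assert [r["G2"] for r in rows] == [3.10, 3.09, 1.84, 1.98, 1.73, 0.48, 0.91, 0.00]

    def test_aic_identity_all_rows(self, review_table):
        for f in CaptureRecapture(review_table).fit_all(ci_level=None):
            assert f.aic == f.g2 - 2 * f.df


class TestConfidenceInterval:
    def test_interval_contains_point_estimate(self, review_table):
        model = CaptureRecapture(review_table)
        fit = model.fit(INDEP)
        lo, hi = fit.ci_x
        assert 0 <= lo <= fit.x_hat <= hi

    def test_interval_collapses_at_tiny_level(self, independence_table):
        model = CaptureRecapture(independence_table)
        lo, hi = model.confidence_interval_x(INDEP, level=1e-6)
        assert hi - lo < 0.1
        assert lo <= 10.0 <= hi

    def test_lognormal_interval_brackets_estimate(self, review_table):
        model = CaptureRecapture(review_table)
        fit = model.fit(INDEP, ci_method="lognormal")
        lo, hi = fit.ci_x
        assert 0 < lo < fit.x_hat < hi

    def test_undefined_for_divergent_fit(self, review_table):
        model = CaptureRecapture(review_table)
        with pytest.raises(ValueError, match="CI undefined"):
            model.confidence_interval_x(LoglinearModelSpec(frozenset({"AB", "BC"})))


class TestSelection:
    def test_review_selects_no_interaction_model(self, review_table):
        fits = CaptureRecapture(review_table).fit_all(ci_level=None)
        assert fits.select("aic").model.label == "A B C"
        assert fits.select("bic").model.label == "A B C"

    def test_tie_breaks_toward_fewer_interactions(self, review_table):
        fits = CaptureRecapture(review_table).fit_all(ci_level=None)
        indep, one_term = fits[0], fits[2]
        tied = dataclasses.replace(one_term, aic=indep.aic)
        from crcbias.loglinear import CrcFitCollection

        assert CrcFitCollection((tied, indep)).select("aic") is indep

    def test_single_fit_selected(self, review_table):
        from crcbias.loglinear import CrcFitCollection

        fit = CaptureRecapture(review_table).fit(INDEP, ci_level=None)
        assert CrcFitCollection((fit,)).select("aic") is fit

    def test_no_identifiable_fits_raises(self, review_table):
        fits = CaptureRecapture(review_table).fit_all(ci_level=None)
        bad = tuple(f for f in fits if not f.identifiable)
        from crcbias.loglinear import CrcFitCollection

        with pytest.raises(ValueError, match="identifiable"):
            CrcFitCollection(bad).select("aic")


class TestCompleteness:
    def test_review_completeness_percents(self, review_table):
        fits = CaptureRecapture(review_table).fit_all()
        comp = fits.completeness(fits.select("aic"))
        pcts = [round(r.pct, 1) for r in comp.rows]
        assert pcts == [53.8, 66.7, 15.4, 87.2]
        assert comp.overall.observed == 34

    def test_near_zero_missing_gives_full_completeness(self):
        table = CaptureTable(1, 1, 1, 10, 10, 10, 30)
        fits = CaptureRecapture(table).fit_all(ci_level=None)
        fit = fits[0]
        assert fit.x_hat < 0.5  # rounds to an N of exactly n_obs
        comp = fits.completeness(fit)
        assert comp.overall.pct == pytest.approx(100.0)

    def test_ci_bounds_bracket_point(self, review_table):
        fits = CaptureRecapture(review_table).fit_all()
        comp = fits.completeness(fits.select("aic"))
        for r in comp.rows:
            lo, hi = r.ci_pct
            assert lo <= r.observed / (34 + fits[0].x_hat) * 100 <= hi

    def test_rejects_divergent_fit(self, review_table):
        fits = CaptureRecapture(review_table).fit_all(ci_level=None)
        with pytest.raises(ValueError):
            fits.completeness(fits[5])
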