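"""Logistic case-control fits, Wald arithmetic, and the consistency triage."""

import itertools

import numpy as np
import pytest
from scipy import optimize, stats

from episcan.medcheck import (
    SeparationError,
    casecontrol_combined,
    casecontrol_term,
    classify_consistency,
    fit_logistic,
    wald_p,
)
from episcan.synthcohort import MedModel, SimSpec, simulate_cohort


def _logistic_data(n, beta, seed):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, len(beta) - 1))])
    p = 1 / (1 + np.exp(-(X @ beta)))
    return (rng.random(n) < p).astype(float), X


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(100), np.zeros(900)]
        fit = fit_logistic(y, np.ones((1000, 1)))
        assert fit.coef[0] == pytest.approx(np.log(0.1 / 0.9), abs=1e-8)
        assert fit.n_cases == 100 and fit.n_controls == 900

    def test_score_equations_satisfied_at_convergence(self):
        y, X = _logistic_data(2000, np.array([-1.0, 0.5, -0.3]), seed=0)
        fit = fit_logistic(y, X)
        assert fit.converged
        mu = 1 / (1 + np.exp(-(X @ fit.coef)))
        assert np.abs(X.T @ (y - mu)).max() < 1e-8

    def test_matches_direct_likelihood_maximiser(self):
        """Independent route: Nelder-Mead on the negative log-likelihood."""
        y, X = _logistic_data(500, np.array([-0.5, 0.8]), seed=1)
        fit = fit_logistic(y, X)

        def nll(b):
            eta = X @ b
            return float(np.sum(np.log1p(np.exp(eta))) - y @ eta)

        direct = optimize.minimize(nll, np.zeros(2), method="Nelder-Mead",
                                   options={"xatol": 1e-8, "fatol": 1e-12})
        np.testing.assert_allclose(fit.coef, direct.x, atol=1e-4)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        y, X = _logistic_data(1500, np.array([-1.0, 0.4, 0.2, -0.6]), seed=2)
        fit = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)

    def test_null_slopes_stay_small(self):
        for seed in range(5):
            y, X = _logistic_data(2000, np.array([-1.0, 0.0, 0.0]), seed=10 + seed)
            fit = fit_logistic(y, X)
            assert np.abs(fit.z()[1:]).max() < 4

    def test_perfect_separation_raises(self):
        x = np.r_[np.linspace(-2, -0.1, 50), np.linspace(0.1, 2, 50)]
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(y, np.column_stack([np.ones(100), x]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(np.ones(10), np.ones((10, 1)))

    def test_parameter_recovery_within_three_se(self):
        """Known interaction coefficient 0.3 at n = 5000: the estimate lies
        within +/-3 SE of truth in >= 95 of 100 replicates."""
        inside = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g1 = rng.binomial(2, 0.3, 5000).astype(float)
            g2 = rng.binomial(2, 0.4, 5000).astype(float)
            eta = -2.0 + 0.1 * g1 - 0.1 * g2 + 0.3 * g1 * g2
            y = (rng.random(5000) < 1 / (1 + np.exp(-eta))).astype(float)
            X = np.column_stack([np.ones(5000), g1, g2, g1 * g2])
            fit = fit_logistic(y, X)
            inside += abs(fit.coef[3] - 0.3) < 3 * fit.se[3]
        assert inside >= 95


class TestCaseControl:
    def _cohort(self, seed, n=3000, med_int_coef=0.0):
        spec = SimSpec(
            n_individuals=n, n_snps=4, seed=seed,
            med_model=MedModel(
                intercept=1.0, hdl_slope=-2.0,
                interaction_pair=(0, 3) if med_int_coef else None,
                interaction_coef=med_int_coef,
            ),
        )
        return simulate_cohort(spec, f"C{seed}")

    def test_single_cohort_combined_reduces_to_plain_fit(self):
        c = self._cohort(1)
        pair = (c.genotypes.snp_names[0], c.genotypes.snp_names[3])
        solo = casecontrol_term(c, pair)
        combined = casecontrol_combined([c], pair)
        np.testing.assert_allclose(solo.coef, combined.coef, atol=1e-12)

    def test_duplicated_cohort_shrinks_se_by_sqrt2(self):
        c = self._cohort(2)
        pair = (c.genotypes.snp_names[0], c.genotypes.snp_names[3])
        solo = casecontrol_term(c, pair)
        doubled = casecontrol_combined([c, c], pair)
        b1, se1, _ = solo["interaction"]
        b2, se2, _ = doubled["interaction"]
        assert b2 == pytest.approx(b1, abs=1e-8)
        assert se2 == pytest.approx(se1 / np.sqrt(2), rel=1e-6)

    def test_pooled_fit_differs_from_ivw_meta_of_per_cohort_fits(self):
        """The combined individual-level fit and the inverse-variance meta of
        per-cohort fits are distinct estimators; both are computed and they
        disagree at finite n while staying in the same neighbourhood."""
        cohorts = [self._cohort(s, n=2000, med_int_coef=0.3) for s in (3, 4, 5)]
        pair = (cohorts[0].genotypes.snp_names[0], cohorts[0].genotypes.snp_names[3])
        combined = casecontrol_combined(cohorts, pair)
        fits = [casecontrol_term(c, pair) for c in cohorts]
        w = np.array([1 / f["interaction"][1] ** 2 for f in fits])
        b = np.array([f["interaction"][0] for f in fits])
        ivw_beta = (w * b).sum() / w.sum()
        b_comb = combined["interaction"][0]
        assert b_comb != ivw_beta
        assert b_comb == pytest.approx(ivw_beta, rel=0.2)

    def test_direct_medication_interaction_sign_recovered(self):
        """Planted positive direct effect on treatment odds: the fitted
        interaction coefficient is positive in >= 90 of 100 replicates."""
        wins = 0
        for seed in range(100):
            c = self._cohort(100 + seed, n=5000, med_int_coef=0.3)
            pair = (c.genotypes.snp_names[0], c.genotypes.snp_names[3])
            fit = casecontrol_term(c, pair)
            wins += fit["interaction"][0] > 0
        assert wins >= 90


class TestWaldP:
    @pytest.mark.parametrize(
        "beta,se,printed",
        [(-0.53, 0.1841, 0.00398), (0.293, 0.1175, 0.01267)],
    )
    def test_worked_examples_from_printed_tables(self, beta, se, printed):
        assert wald_p(beta, se) == pytest.approx(printed, rel=5e-3)

    def test_zero_beta_gives_one(self):
        assert wald_p(0.0, 1.0) == 1.0

    def test_monotone_decreasing_in_z(self):
        ps = [wald_p(b, 0.1) for b in (0.1, 0.2, 0.5, 1.0)]
        assert ps == sorted(ps, reverse=True)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_p(0.2, 0.0)


class TestClassifyConsistency:
    TRUTH = {
        # (discovery, replication, medication) -> verdict
        ("+", "+", "+"): "counterintuitive",
        ("+", "+", "-"): "consistent",
        ("+", "-", "+"): "sign-discordant",
        ("+", "-", "-"): "sign-discordant",
        ("-", "+", "+"): "sign-discordant",
        ("-", "+", "-"): "sign-discordant",
        ("-", "-", "+"): "consistent",
        ("-", "-", "-"): "counterintuitive",
    }

    @pytest.mark.parametrize("signs", list(itertools.product("+-", repeat=3)))
    def test_full_truth_table(self, signs):
        assert classify_consistency(*signs).verdict == self.TRUTH[signs]

    def test_invalid_sign_rejected(self):
        with pytest.raises(ValueError, match="sign"):
            classify_consistency("+", "?", "-")
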