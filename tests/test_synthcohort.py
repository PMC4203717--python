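"""Generator guarantees: determinism, HWE calibration, LD targets, effect bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from episcan.genodata import hwe_exact_test
from episcan.metafilter import fit_single_pair
from episcan.phenoprep import adjusted_cohort
from episcan.powercalc import PowerQuery, power_of_effect
from episcan.synthcohort import (
    MedModel,
    SimSpec,
    simulate_cohort,
    simulate_cohorts,
    simulate_genotypes,
    simulate_medication,
    simulate_phenotype,
)


class TestSimSpecValidation:
    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            ({"maf_range": (0.0, 0.5)}, "maf_range"),
            ({"maf_range": (0.1, 0.6)}, "maf_range"),
            ({"n_individuals": 4}, "at least 8"),
            ({"interaction_effects": {(3, 3): 0.5}}, "distinct"),
            ({"interaction_effects": {(3, 99): 0.5}}, "unknown SNP pair"),
            ({"marginal_effects": {99: 0.5}}, "unknown SNP index"),
            ({"ld_blocks": ((100, 0.9),), "n_snps": 10}, "more SNPs"),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            SimSpec(**kwargs)


class TestGenotypeGeneration:
    def test_hwe_symmetry_at_half_maf(self):
        spec = SimSpec(n_individuals=20000, n_snps=1, maf_range=(0.5, 0.5), seed=1)
        G = simulate_genotypes(spec)
        assert G.counts.mean() == pytest.approx(1.0, abs=0.02)
        freqs = [(G.counts == k).mean() for k in (0, 1, 2)]
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)

    def test_zero_snps_gives_empty_matrix(self):
        G = simulate_genotypes(SimSpec(n_individuals=10, n_snps=0, seed=1))
        assert G.n_snps == 0

    def test_ld_block_hits_squared_correlation_target(self):
        # 100 seeded replicates; oracle is the sample correlation
        r2s = []
        for seed in range(100):
            spec = SimSpec(
                n_individuals=5000, n_snps=2, ld_blocks=((2, 0.95),), seed=seed
            )
            G = simulate_genotypes(spec)
            r = np.corrcoef(G.counts[0], G.counts[1])[0, 1]
            r2s.append(r * r)
        assert min(r2s) > 0.8
        assert np.mean(r2s) == pytest.approx(0.95, abs=0.02)

    def test_hwe_pvalues_uniform_across_null_snps(self):
        # exact-test p-values are discrete (atom at 1 for the conditional
        # mode), so the sample size must be large enough for the lattice to
        # be fine before KS against uniform is meaningful
        spec = SimSpec(n_individuals=5000, n_snps=1000, seed=5)
        G = simulate_genotypes(spec)
        pvals = np.array([hwe_exact_test(*c) for c in G.genotype_counts()])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_seed_determinism_bitwise_on_disk(self, tmp_path):
        spec = SimSpec(n_individuals=50, n_snps=20, seed=123,
                       interaction_effects={(1, 2): 0.3})
        for tag in ("a", "b"):
            simulate_cohort(spec, "c").write(
                tmp_path / f"g_{tag}", tmp_path / f"s_{tag}", tmp_path / f"p_{tag}"
            )
        for stem in ("g", "s", "p"):
            assert (tmp_path / f"{stem}_a").read_bytes() == (
                tmp_path / f"{stem}_b"
            ).read_bytes()


class TestPhenotype:
    def test_null_phenotype_uncorrelated_with_genotypes(self):
        spec = SimSpec(n_individuals=2000, n_snps=30, noise_sd=1.0, seed=17)
        c = simulate_cohort(spec, "null")
        y = c.table.hdl.to_numpy()
        bound = 4 / np.sqrt(len(y))
        for g in c.genotypes.counts:
            assert abs(np.corrcoef(g, y)[0, 1]) < bound

    def test_noise_free_marginal_is_exact_linear_function(self):
        spec = SimSpec(
            n_individuals=200, n_snps=5, noise_sd=0.0,
            marginal_effects={2: 0.7}, sex_effect=0.0, age_effect=0.0, seed=3,
        )
        c = simulate_cohort(spec, "det")
        y = c.table.hdl.to_numpy()
        g = c.genotypes.counts[2].astype(float)
        np.testing.assert_allclose(y, spec.intercept + 0.7 * g, atol=1e-12)

    def test_effect_on_unknown_snp_rejected(self):
        spec = SimSpec(n_individuals=50, n_snps=10, seed=1)
        G = simulate_genotypes(SimSpec(n_individuals=50, n_snps=3, seed=1))
        bad = SimSpec(n_individuals=50, n_snps=10, marginal_effects={8: 0.1}, seed=1)
        with pytest.raises(ValueError, match="unknown SNP"):
            simulate_phenotype(G, bad)

    def test_planted_interaction_recovered_at_scan_threshold(self):
        """Power oracle: the per-seed noncentral-t power at the generative
        effect predicts the empirical |t| > 5 recovery count.

        The planted effect's standardised size depends on the realised
        allele frequencies (the product column's residual spread), so the
        oracle is evaluated per seed and the recovery count is compared
        with the summed predicted power within binomial error.
        """
        n, eff, noise = 3000, 0.5, 1.0
        alpha5 = 2 * stats.t.sf(5, n - 4)
        hits = 0
        predicted = []
        for seed in range(100):
            spec = SimSpec(
                n_individuals=n, n_snps=4, noise_sd=noise,
                maf_range=(0.2, 0.5), interaction_effects={(0, 3): eff}, seed=seed,
            )
            c = simulate_cohort(spec, "p")
            G, adj = adjusted_cohort(c, scaled=True)
            d = G.dosage()
            fit = fit_single_pair(d[0], d[3], adj.residuals)
            hits += abs(fit.t) > 5
            # generative f for this draw: eff * sd(residualised product) / sd(y)
            prod = d[0] * d[3]
            X = np.column_stack([np.ones(d.shape[1]), d[0], d[3]])
            prod_resid = prod - X @ np.linalg.lstsq(X, prod, rcond=None)[0]
            y_sd = c.table.hdl.to_numpy()[adj.keep_mask].std()
            f_gen = eff * prod_resid.std() / y_sd
            q = PowerQuery(n=fit.n, alpha=alpha5, power=0.5, tails=2)
            predicted.append(power_of_effect(f_gen, q))
        predicted = np.array(predicted)
        assert hits >= 95
        envelope = 4 * np.sqrt((predicted * (1 - predicted)).sum() + 1)
        assert abs(hits - predicted.sum()) < envelope

    def test_effect_size_bookkeeping_matches_cohens_f(self):
        """Generative effect / phenotype SD approximates the f recovered from
        the observed t-score (f = t / sqrt(n)) within simulation error."""
        n = 5000
        spec = SimSpec(
            n_individuals=n, n_snps=2, noise_sd=1.0,
            interaction_effects={(0, 1): 0.4}, seed=8,
        )
        c = simulate_cohort(spec, "f")
        G, adj = adjusted_cohort(c, scaled=True)
        d = G.dosage()
        fit = fit_single_pair(d[0], d[1], adj.residuals)
        f_observed = abs(fit.t) / np.sqrt(fit.n)
        # generative f: beta_int * sd(g1*g2 residualised) / sd(y), estimated
        # from the realised draw
        prod = d[0] * d[1]
        X = np.column_stack([np.ones(d.shape[1]), d[0], d[1]])
        prod_resid = prod - X @ np.linalg.lstsq(X, prod, rcond=None)[0]
        y_sd = c.table.hdl.to_numpy()[adj.keep_mask].std()
        f_generative = 0.4 * prod_resid.std() / y_sd
        assert f_observed == pytest.approx(f_generative, rel=0.15)


class TestMedication:
    def test_constant_rate_when_slope_zero(self):
        logit = np.log(0.1 / 0.9)
        spec = SimSpec(
            n_individuals=20000, n_snps=2, seed=21,
            med_model=MedModel(intercept=logit, hdl_slope=0.0),
        )
        c = simulate_cohort(spec, "m")
        assert c.table.medication.mean() == pytest.approx(0.1, abs=0.01)

    def test_negative_hdl_slope_means_cases_have_lower_hdl(self):
        spec = SimSpec(n_individuals=5000, n_snps=2, seed=22)  # default slope -2
        c = simulate_cohort(spec, "m")
        t = c.table
        assert t.hdl[t.medication == 1].mean() < t.hdl[t.medication == 0].mean()

    def test_medication_requires_phenotype(self):
        spec = SimSpec(n_individuals=20, n_snps=2, seed=1)
        G = simulate_genotypes(spec)
        from episcan.synthcohort import CohortData
        import pandas as pd

        bare = CohortData("x", G, pd.DataFrame({"id": range(20)}))
        with pytest.raises(ValueError, match="phenotype"):
            simulate_medication(bare, spec)


class TestMultiCohort:
    def test_cohorts_are_independent_draws_with_shared_effects(self, planted_spec):
        cohorts = simulate_cohorts(planted_spec, ["A", "B"])
        assert not np.array_equal(
            cohorts[0].genotypes.counts, cohorts[1].genotypes.counts
        )

    def test_replication_effect_scale_zero_gives_null_cohorts(self):
        spec = SimSpec(
            n_individuals=3000, n_snps=4, noise_sd=0.35,
            interaction_effects={(0, 3): 0.5}, seed=4,
        )
        disc, rep = simulate_cohorts(
            spec, ["D", "R"], replication_effect_scale=0.0, n_replication_from=1
        )
        for cohort, expect_signal in ((disc, True), (rep, False)):
            G, adj = adjusted_cohort(cohort, scaled=True)
            d = G.dosage()
            fit = fit_single_pair(d[0], d[3], adj.residuals)
            assert (abs(fit.t) > 5) is expect_signal
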