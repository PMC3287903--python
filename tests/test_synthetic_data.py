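"""Unit and property tests for the genotype/trait simulator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import special

from oracles import max_corr_numeric, table_correlation
from winnerscurse import synthetic_data as sd


maf = st.floats(0.01, 0.5)


class TestRhoMax:
    def test_equal_mafs_permit_perfect_correlation(self):
        assert sd.rho_max(0.5, 0.5) == pytest.approx(1.0)
        assert sd.rho_max(0.2, 0.2) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "p_t,p_c",
        [(0.3, 0.1), (0.1, 0.3), (0.05, 0.001), (0.45, 0.02), (0.25, 0.25)],
    )
    def test_matches_numeric_maximization(self, p_t, p_c):
        assert sd.rho_max(p_t, p_c) == pytest.approx(
            max_corr_numeric(p_t, p_c), abs=1e-6
        )

    def test_frozen_derived_values(self):
        # maximizer over haplotype tables gives 0.50918 at (0.3, 0.1)
        assert sd.rho_max(0.3, 0.1) == pytest.approx(0.509175, abs=1e-6)
        # a common tag captures little variation at a very rare SNP
        assert sd.rho_max(0.05, 0.001) < 0.14

    @pytest.mark.parametrize("bad", [0.0, -0.1, 0.6, 1.0])
    def test_rejects_frequencies_outside_domain(self, bad):
        with pytest.raises(sd.DomainError):
            sd.rho_max(bad, 0.2)
        with pytest.raises(sd.DomainError):
            sd.rho_max(0.2, bad)

    @given(maf, maf)
    def test_bound_is_sharp(self, p_t, p_c):
        bound = sd.rho_max(p_t, p_c)
        sd.haplotype_freqs(sd.LdPairSpec(p_t, p_c, bound))  # feasible
        with pytest.raises(sd.FeasibilityError):
            sd.LdPairSpec(p_t, p_c, bound * (1 + 1e-6))

    @given(maf, maf)
    def test_repulsion_bound_is_sharp(self, p_t, p_c):
        lo, _ = sd.rho_bounds(p_t, p_c)
        f = sd.haplotype_freqs(sd.LdPairSpec(p_t, p_c, lo))  # feasible
        assert f[0] == pytest.approx(0.0, abs=1e-12)  # both-minor exhausted
        with pytest.raises(sd.FeasibilityError):
            sd.LdPairSpec(p_t, p_c, lo * (1 + 1e-6))


class TestHaplotypeFreqs:
    def test_independence(self):
        f = sd.haplotype_freqs(sd.LdPairSpec(0.5, 0.5, 0.0))
        assert f == pytest.approx([0.25, 0.25, 0.25, 0.25])

    def test_perfect_ld(self):
        f = sd.haplotype_freqs(sd.LdPairSpec(0.5, 0.5, 1.0))
        assert f == pytest.approx([0.5, 0.0, 0.0, 0.5])

    def test_implied_correlation_round_trips(self):
        f = sd.haplotype_freqs(sd.LdPairSpec(0.3, 0.1, 0.4))
        assert table_correlation(f) == pytest.approx(0.4, abs=1e-12)

    @given(maf, maf, st.floats(-1.0, 1.0))
    def test_marginals_conserved(self, p_t, p_c, frac):
        lo, hi = sd.rho_bounds(p_t, p_c)
        rho = frac * (hi if frac >= 0 else -lo)
        f = sd.haplotype_freqs(sd.LdPairSpec(p_t, p_c, rho))
        assert f.sum() == pytest.approx(1.0, abs=1e-12)
        assert f[0] + f[1] == pytest.approx(p_t, abs=1e-12)
        assert f[0] + f[2] == pytest.approx(p_c, abs=1e-12)
        assert (f >= 0).all()

    def test_negative_rho_repulsion(self):
        f = sd.haplotype_freqs(sd.LdPairSpec(0.3, 0.3, -0.3))
        assert table_correlation(f) == pytest.approx(-0.3, abs=1e-12)


class TestPairGenotypes:
    def test_perfect_ld_makes_columns_identical(self):
        g = sd.sample_pair_genotypes(sd.LdPairSpec(0.3, 0.3, 1.0), 500, 0)
        assert np.array_equal(g[:, 0], g[:, 1])

    def test_zero_correlation_at_large_n(self):
        g = sd.sample_pair_genotypes(sd.LdPairSpec(0.3, 0.2, 0.0), 100_000, 1)
        assert abs(np.corrcoef(g.T)[0, 1]) < 0.01

    def test_target_correlation_at_large_n(self):
        g = sd.sample_pair_genotypes(sd.LdPairSpec(0.3, 0.1, 0.4), 100_000, 2)
        assert np.corrcoef(g.T)[0, 1] == pytest.approx(0.4, abs=0.01)

    def test_deterministic_under_seed(self):
        spec = sd.LdPairSpec(0.3, 0.1, 0.4)
        assert np.array_equal(
            sd.sample_pair_genotypes(spec, 1000, 42),
            sd.sample_pair_genotypes(spec, 1000, 42),
        )

    def test_rejects_empty_cohort(self):
        with pytest.raises(ValueError):
            sd.sample_pair_genotypes(sd.LdPairSpec(0.3, 0.3, 0.0), 0, 0)


class TestGeneGenotypes:
    def test_independent_rare_loci_give_null_tag_burden_correlation(self):
        spec = sd.GeneSpec(0.2, (0.02,) * 5, (0.0,) * 5)
        g = sd.sample_gene_genotypes(spec, 100_000, 3)
        burden = (g[:, 1:] >= 1).mean(axis=1)
        assert abs(np.corrcoef(g[:, 0], burden)[0, 1]) < 0.01

    def test_maximal_rho_puts_rare_allele_on_tag_minor_haplotypes_only(self):
        rho = sd.rho_max(0.2, 0.02)
        spec = sd.GeneSpec(0.2, (0.02,), (rho,))
        g = sd.sample_gene_genotypes(spec, 100_000, 4)
        # every rare minor allele rides a tag-minor haplotype
        assert (g[:, 1] <= g[:, 0]).all()

    def test_positive_rho_gives_positive_reproducible_correlation(self):
        spec = sd.GeneSpec(0.2, (0.02,) * 5, (0.15,) * 5)
        g1 = sd.sample_gene_genotypes(spec, 100_000, 5)
        g2 = sd.sample_gene_genotypes(spec, 100_000, 5)
        assert np.array_equal(g1, g2)
        burden = (g1[:, 1:] >= 1).mean(axis=1)
        assert np.corrcoef(g1[:, 0], burden)[0, 1] > 0.2

    def test_per_pair_target_correlations_attained(self):
        spec = sd.GeneSpec(0.25, (0.03, 0.01), (0.2, 0.1))
        g = sd.sample_gene_genotypes(spec, 200_000, 6)
        for j, rho in enumerate(spec.tag_rare_rho):
            assert np.corrcoef(g[:, 0], g[:, 1 + j])[0, 1] == pytest.approx(
                rho, abs=0.015
            )

    def test_empirical_mafs_match_spec(self):
        spec = sd.GeneSpec(0.2, (0.04, 0.01), (0.1, 0.1))
        g = sd.sample_gene_genotypes(spec, 200_000, 7)
        assert g[:, 0].mean() / 2 == pytest.approx(0.2, abs=0.004)
        assert g[:, 1].mean() / 2 == pytest.approx(0.04, abs=0.002)
        assert g[:, 2].mean() / 2 == pytest.approx(0.01, abs=0.001)

    def test_infeasible_pair_names_locus(self):
        with pytest.raises(sd.FeasibilityError, match="rare locus 1|rare_mafs\\[1\\]"):
            sd.GeneSpec(0.4, (0.04, 0.001), (0.1, 0.5))

    def test_rare_maf_ceiling_enforced(self):
        with pytest.raises(ValueError, match="not rare"):
            sd.GeneSpec(0.2, (0.06,), (0.1,))


class TestCovariatesAndTraits:
    def test_covariates_rejected_for_empty_cohort(self):
        with pytest.raises(ValueError):
            sd.simulate_covariates(0, 0)

    def test_covariate_distributions(self):
        cov = sd.simulate_covariates(100_000, 8)
        assert cov[:, 0].min() >= 20 and cov[:, 0].max() <= 80
        # 3-sigma binomial band around the smoking probability
        assert cov[:, 1].mean() == pytest.approx(0.3, abs=3 * np.sqrt(0.21 / 1e5))
        assert np.array_equal(cov, sd.simulate_covariates(100_000, 8))

    def _data(self, n, seed, p=0.3, rho=1.0):
        g = sd.sample_pair_genotypes(sd.LdPairSpec(p, p, rho), n, seed)
        return sd.ReplicateData(
            genotypes=g, locus_roles=["tag", "causal"], locus_ids=["t", "c"],
            covariates=sd.simulate_covariates(n, seed + 1),
        )

    def test_null_model_centres_on_intercept(self):
        data = self._data(50_000, 10)
        model = sd.TraitModel(kind="quantitative", beta=0.0, sigma=1.0,
                              intercept=3.0)
        y = sd.simulate_trait(model, data, 11)
        assert y.mean() == pytest.approx(3.0, abs=3 / np.sqrt(5e4))
        slope = np.polyfit(data.genotypes[:, 1], y, 1)[0]
        assert abs(slope) < 0.02

    def test_causal_effect_recovered_by_ols(self):
        data = self._data(100_000, 12)
        model = sd.TraitModel(kind="quantitative", beta=0.5, sigma=1.0)
        y = sd.simulate_trait(model, data, 13)
        slope = np.polyfit(data.genotypes[:, 1], y, 1)[0]
        assert slope == pytest.approx(0.5, abs=0.02)

    def test_binary_null_case_fraction(self):
        data = self._data(100_000, 14)
        model = sd.TraitModel(kind="binary", beta=0.0,
                              intercept=special.logit(0.3))
        y = sd.simulate_trait(model, data, 15)
        assert set(np.unique(y)) <= {0.0, 1.0}
        assert y.mean() == pytest.approx(0.3, abs=3 * np.sqrt(0.21 / 1e5))

    def test_covariate_effects_enter_q1_like_traits(self):
        data = self._data(50_000, 16)
        model = sd.TraitModel(
            kind="quantitative_with_covariates", beta=0.0,
            covariate_effects=(0.05, 1.0), sigma=0.5,
        )
        y = sd.simulate_trait(model, data, 17)
        coef = np.linalg.lstsq(
            np.column_stack([np.ones(data.n), data.covariates]), y, rcond=None
        )[0]
        assert coef[1] == pytest.approx(0.05, abs=0.005)
        assert coef[2] == pytest.approx(1.0, abs=0.05)

    def test_burden_model_trait_uses_carrier_proportion(self):
        spec = sd.GeneSpec(0.2, (0.02,) * 4, (0.1,) * 4)
        g = sd.sample_gene_genotypes(spec, 20_000, 18)
        data = sd.ReplicateData(
            genotypes=g, locus_roles=["tag"] + ["rare_causal"] * 4,
            locus_ids=[f"l{j}" for j in range(5)],
        )
        model = sd.TraitModel(kind="quantitative", lambda_true=4.0, sigma=0.1)
        y = sd.simulate_trait(model, data, 19)
        burden = (g[:, 1:] >= 1).mean(axis=1)
        slope = np.polyfit(burden, y, 1)[0]
        assert slope == pytest.approx(4.0, abs=0.05)

    def test_beta_and_lambda_are_mutually_exclusive(self):
        with pytest.raises(ValueError, match="exactly one"):
            sd.TraitModel(kind="quantitative", beta=0.1, lambda_true=1.0)
        with pytest.raises(ValueError, match="exactly one"):
            sd.TraitModel(kind="quantitative")

    def test_mask_missing_rate(self):
        g = np.zeros((1000, 10))
        masked = sd.mask_missing(g, 0.2, 20)
        rate = np.isnan(masked).mean()
        assert rate == pytest.approx(0.2, abs=3 * np.sqrt(0.16 / 1e4))
        assert not np.isnan(g).any()  # input untouched
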