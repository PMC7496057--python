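"""Additive association and breed-permutation correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import breedgwas as bg
from breedgwas.association import assign_tiers
from breedgwas.datatypes import PermutationNull
from breedgwas.errors import ConfigError, MappingError, SchemaError

from conftest import toy_genotypes
from oracles import exhaustive_breed_min_p


def breed_pheno(values: dict):
    return pd.DataFrame(
        {
            "breed": list(values),
            "body_weight_kg": list(values.values()),
            "life_expectancy_years": [10.0 + i for i in range(len(values))],
            "cancer_mortality_pct": [20.0 + i for i in range(len(values))],
        }
    )


class TestAssignBreedValues:
    def test_within_breed_constant_expansion(self):
        g = toy_genotypes(np.zeros((6, 1)), breeds=["A"] * 3 + ["B"] * 3)
        y = bg.assign_breed_values(g, breed_pheno({"A": 1.0, "B": 2.0}), "body_weight_kg")
        np.testing.assert_array_equal(y, [1, 1, 1, 2, 2, 2])

    def test_missing_breed_listed(self):
        g = toy_genotypes(np.zeros((4, 1)), breeds=["A", "A", "C", "C"])
        with pytest.raises(MappingError, match="C"):
            bg.assign_breed_values(g, breed_pheno({"A": 1.0, "B": 2.0}), "body_weight_kg")


class TestAdditiveAssociation:
    def test_matches_statsmodels_per_snp(self, small_cohort):
        """Closed-form masked OLS agrees with scipy linregress fit by fit."""
        g, pheno, _ = small_cohort
        y = bg.assign_breed_values(g, pheno, "body_weight_kg")
        tab = bg.additive_association(g, y)
        rng = np.random.default_rng(0)
        for j in rng.choice(g.n_snps, 25, replace=False):
            x = g.dosages[:, j]
            m = ~np.isnan(x)
            if np.unique(x[m]).size < 2:
                assert np.isnan(tab.raw_p[j])
                continue
            fit = stats.linregress(x[m], y[m])
            assert tab.beta[j] == pytest.approx(fit.slope, rel=1e-9)
            assert tab.raw_p[j] == pytest.approx(fit.pvalue, rel=1e-9)
            assert tab.se[j] == pytest.approx(fit.stderr, rel=1e-9)
            assert tab.n_used[j] == m.sum()

    def test_scale_equivariance(self, small_cohort):
        g, pheno, _ = small_cohort
        y = bg.assign_breed_values(g, pheno, "body_weight_kg")
        a = bg.additive_association(g, y)
        b = bg.additive_association(g, 2.0 * y)
        np.testing.assert_allclose(b.beta, 2.0 * a.beta, rtol=1e-12)
        np.testing.assert_allclose(b.raw_p, a.raw_p, rtol=1e-12)

    def test_constant_trait_all_p_absent(self, small_cohort):
        g = small_cohort[0]
        tab = bg.additive_association(g, np.full(g.n_samples, 3.0))
        assert tab.raw_p.isna().all()

    def test_monomorphic_snp_emitted_without_p(self):
        d = np.column_stack([np.zeros(8), np.arange(8) % 3]).astype(float)
        g = toy_genotypes(d, breeds=["A"] * 4 + ["B"] * 4)
        tab = bg.additive_association(g, np.array([1.0] * 4 + [2.0] * 4))
        assert np.isnan(tab.raw_p[0])
        assert np.isfinite(tab.raw_p[1])


class TestPermutationNull:
    def test_two_breeds_one_snp_two_assignments(self):
        d = np.array([[0.0], [1.0], [2.0], [0.0], [1.0], [2.0]])
        g = toy_genotypes(d, breeds=["A"] * 3 + ["B"] * 3)
        null = bg.breed_permutation_null(
            g, breed_pheno({"A": 1.0, "B": 2.0}), "body_weight_kg", n_perm=50, seed=0
        )
        assert len(np.unique(np.round(null.min_p, 12))) <= 2

    def test_same_seed_identical(self, small_cohort):
        g, pheno, _ = small_cohort
        a = bg.breed_permutation_null(g, pheno, "body_weight_kg", n_perm=40, seed=9)
        b = bg.breed_permutation_null(g, pheno, "body_weight_kg", n_perm=40, seed=9)
        np.testing.assert_array_equal(a.min_p, b.min_p)

    def test_matches_exhaustive_four_breed_enumeration(self):
        """Sampled minima live on, and distribute as, the exact 24-permutation set."""
        cfg = bg.SimulationConfig(
            n_breeds=4, samples_per_breed=8, n_snps=6, missing_rate=0.0, seed=14
        )
        g = bg.simulate_genotypes(cfg)
        pheno = bg.simulate_phenotypes(cfg, g)
        values = pheno["body_weight_kg"].to_numpy()
        _, breed_idx = np.unique(g.samples["breed"].to_numpy(), return_inverse=True)
        exact = exhaustive_breed_min_p(g, values, breed_idx)

        null = bg.breed_permutation_null(g, pheno, "body_weight_kg", n_perm=2400, seed=3)
        support = np.unique(np.round(exact, 10))
        assert np.isin(np.round(null.min_p, 10), support).all()
        # empirical frequencies match the exhaustive (uniform over 24) distribution
        exact_freq = {v: (np.round(exact, 10) == v).mean() for v in support}
        emp_freq = {v: (np.round(null.min_p, 10) == v).mean() for v in support}
        tv = 0.5 * sum(abs(exact_freq[v] - emp_freq[v]) for v in support)
        assert tv < 0.05

    def test_breed_constant_trait_rejected(self, small_cohort):
        g = small_cohort[0]
        pheno = breed_pheno({b: 5.0 for b in g.breeds})
        with pytest.raises(bg.errors.DegenerateFitError):
            bg.breed_permutation_null(g, pheno, "body_weight_kg", n_perm=5, seed=0)

    def test_n_perm_positive(self, small_cohort):
        g, pheno, _ = small_cohort
        with pytest.raises(ConfigError):
            bg.breed_permutation_null(g, pheno, "body_weight_kg", n_perm=0, seed=0)


class TestCorrectedP:
    def null(self, values):
        return PermutationNull(n_perm=len(values), min_p=np.asarray(values, float))

    def test_floor(self):
        null = self.null(np.linspace(0.01, 0.9, 1000))
        assert bg.corrected_p(0.001, null) == pytest.approx(1 / 1001)

    def test_ceiling(self):
        null = self.null(np.linspace(0.01, 0.9, 1000))
        assert bg.corrected_p(0.95, null) == 1.0

    def test_single_exceedance_gives_two_over_1001(self):
        vals = np.concatenate([[1e-6], np.linspace(0.01, 0.9, 999)])
        assert bg.corrected_p(0.001, self.null(vals)) == pytest.approx(2 / 1001)

    def test_tie_counts_as_exceedance(self):
        vals = np.array([0.5, 0.6, 0.7, 0.8])
        assert bg.corrected_p(0.5, self.null(vals)) == pytest.approx(2 / 5)

    def test_absent_raw_p_propagates(self):
        null = self.null([0.1, 0.2])
        assert np.isnan(bg.corrected_p(np.array([np.nan]), null)[0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_and_bounded_property(self, seed):
        rng = np.random.default_rng(seed)
        null = self.null(rng.random(200))
        raw = np.sort(rng.random(50))
        corr = bg.corrected_p(raw, null)
        assert (np.diff(corr) >= 0).all()
        assert (corr >= 1 / 201).all() and (corr <= 1.0).all()


class TestTiers:
    def test_threshold_conventions_strict(self):
        tiers = assign_tiers(np.array([0.049, 0.05, 0.099, 0.1, np.nan]))
        assert list(tiers) == ["significant", "marginal", "marginal", "ns", "na"]


class TestModelResults:
    def test_candidate_subset_and_summary(self, small_cohort):
        g, pheno, _ = small_cohort
        snps = list(g.snps["snp"][:40])
        res = bg.run_association_experiment(
            g, pheno, "body_weight_kg", candidates=snps, n_perm=60, seed=5
        )
        assert res.model.genotypes.n_snps == 40
        text = res.summary()
        assert "body_weight_kg" in text and "Permutations: 60" in text
        man = res.manhattan_table()
        assert "genome_pos" in man.columns and len(man) == 40

    def test_unknown_candidate_ids_listed(self, small_cohort):
        g, pheno, _ = small_cohort
        with pytest.raises(SchemaError, match="nope"):
            bg.BreedGWAS(g, pheno, "body_weight_kg", candidates=["nope"])

    def test_planted_effect_recovered_at_study_scale(self):
        """A strong planted breed-level effect is the top raw-P SNP in a
        majority of seeds and reaches the significant tier, at the default
        63-breed design."""
        top = sig = 0
        R = 12
        for r in range(R):
            cfg = bg.SimulationConfig(
                n_breeds=63, samples_per_breed=20, n_snps=200, differentiation=0.2,
                seed=400 + r, planted_effects=[bg.PlantedEffect(100, "cancer_residual", 2.0)],
            )
            g, pheno, _ = bg.simulate_cohort(cfg)
            pheno = bg.add_residual_traits(pheno)
            res = bg.run_association_experiment(
                g, pheno, "cancer_residual", n_perm=200, seed=r
            )
            t = res.table.dropna(subset=["raw_p"])
            if t.nsmallest(1, "raw_p").iloc[0]["snp"] == "snp_000101":
                top += 1
            if t.set_index("snp").loc["snp_000101", "tier"] == "significant":
                sig += 1
        assert top >= 0.7 * R
        assert sig >= 0.7 * R

    def test_breed_permutation_calibrated_individual_permutation_inflated(self):
        """Under the global null with strong breed structure, breed-block
        permutation keeps the family-wise error near alpha while permuting
        individual samples inflates it."""
        breed_fwer = indiv_fwer = 0
        R = 12
        for r in range(R):
            cfg = bg.SimulationConfig(
                n_breeds=20, samples_per_breed=30, n_snps=150, differentiation=0.2,
                seed=700 + r,
            )
            g, pheno, _ = bg.simulate_cohort(cfg)
            pheno = bg.add_residual_traits(pheno)
            y = bg.assign_breed_values(g, pheno, "cancer_residual")
            raw = bg.additive_association(g, y)["raw_p"].to_numpy()
            for unit, counter in (("breed", "b"), ("sample", "s")):
                null = bg.breed_permutation_null(
                    g, pheno, "cancer_residual", n_perm=150, seed=r, unit=unit
                )
                hit = np.nanmin(bg.corrected_p(raw, null)) < 0.05
                if unit == "breed":
                    breed_fwer += hit
                else:
                    indiv_fwer += hit
        assert indiv_fwer > breed_fwer  # inflation direction, not magnitude
        assert breed_fwer <= 0.25 * R
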