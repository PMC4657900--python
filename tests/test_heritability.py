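"""ANOVA heritability, variance explained, two-model decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vgwas.data import PhenotypeTable, accession_means
from vgwas.heritability import (broad_sense_H2, decompose, locus_contribution,
                                narrow_sense_lower, variance_explained_R2)
from vgwas.kinship import KinshipMatrix, kinship
from vgwas.simulate import SimConfig, simulate_population


def balanced_table(genetic, reps, sd_within, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i, g in enumerate(genetic):
        for j in range(reps):
            rows.append((f"a{i}", j + 1, g + rng.normal(0, sd_within)))
    return PhenotypeTable(pd.DataFrame(rows, columns=["accession_id",
                                                      "replicate", "value"]),
                          require_positive=False)


class TestBroadSense:
    def test_balanced_closed_form(self):
        # between-variance 4, within-variance 1: H2 = 0.8
        rng = np.random.default_rng(1)
        genetic = rng.normal(10, 2.0, 2000)
        p = balanced_table(genetic, reps=6, sd_within=1.0, seed=2)
        assert broad_sense_H2(p) == pytest.approx(0.8, abs=0.02)

    def test_identical_replicates_give_one(self):
        p = balanced_table([1.0, 2.0, 3.0], reps=4, sd_within=0.0)
        assert broad_sense_H2(p) == pytest.approx(1.0)

    def test_shuffled_labels_destroy_heritability(self):
        rng = np.random.default_rng(3)
        genetic = rng.normal(10, 2.0, 300)
        p = balanced_table(genetic, reps=6, sd_within=1.0, seed=4)
        df = p.df.copy()
        df["value"] = rng.permutation(df["value"].to_numpy())
        shuffled = PhenotypeTable(df)
        assert broad_sense_H2(shuffled) < 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        p = balanced_table(rng.normal(5, 1.5, 100), reps=5, sd_within=0.8, seed=6)
        df = p.df.copy()
        df["value"] = df["value"] * 3.7 + 11.0
        assert broad_sense_H2(PhenotypeTable(df)) == pytest.approx(
            broad_sense_H2(p), rel=1e-10)

    def test_unbalanced_coefficient_reduces_to_replicate_count(self):
        # on a balanced design n0 == the common replicate count, so the
        # moment estimate equals the textbook balanced ANOVA component
        rng = np.random.default_rng(7)
        genetic = rng.normal(0, 2.0, 400)
        p = balanced_table(genetic, reps=6, sd_within=1.0, seed=8)
        df = p.df
        counts = df.groupby("accession_id")["value"].count()
        N, a = counts.sum(), len(counts)
        n0 = (N - (counts**2).sum() / N) / (a - 1)
        assert n0 == pytest.approx(6.0)


class TestNarrowSense:
    def test_identity_structured_kinship_gives_zero(self):
        rng = np.random.default_rng(9)
        K = KinshipMatrix([f"a{i}" for i in range(120)], np.eye(120), "genomic")
        r, note = narrow_sense_lower(rng.standard_normal(120), K)
        assert r == pytest.approx(0.0, abs=1e-6)

    def test_bound_bracket_formula(self):
        rng = np.random.default_rng(10)
        K = KinshipMatrix([f"a{i}" for i in range(50)], np.eye(50), "genomic")
        r, note = narrow_sense_lower(rng.standard_normal(50), K, H2=0.8)
        assert "r*H2" in note

    def test_simulated_truth_bracketed(self):
        # configured r = 0.63, H2 = 0.80; estimate respects r*H2 <= h2 <= r
        pop = simulate_population(SimConfig.default(seed=40))
        means = accession_means(pop.phenotypes)["mean"]
        K = kinship(pop.genotypes, "genomic", exclude_region=("2", 10.8e6, 11.6e6))
        r, _ = narrow_sense_lower(means, K, H2=0.8)
        assert 0.3 < r * 0.8 < 0.63 + 0.15
        assert r < 1.0


class TestVarianceExplained:
    def test_trivial_bounds(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = y[:, None]
        assert variance_explained_R2(y, X, np.array([0.0])) == 0.0
        assert variance_explained_R2(y, X, np.array([1.0])) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero phenotype variance"):
            variance_explained_R2(np.ones(4), np.ones((4, 1)), np.array([1.0]))

    def test_four_locus_R2_matches_generator_share(self):
        # R2 of the refit should approach the analytic locus-variance share
        from vgwas.multilocus import joint_refit
        
        r2s, shares = [], []
        for seed in range(20):
            pop = simulate_population(SimConfig.default(seed=seed + 300))
            means = accession_means(pop.phenotypes)["mean"]
            names = ["DEL", "DUP", "SNP1", "SNP2"]
            model = joint_refit(means, pop.genotypes, names)
            ids = pop.genotypes.marker_ids
            X = np.column_stack([pop.genotypes.calls[:, ids.index(n)] for n in names])
            r2s.append(variance_explained_R2(
                means.to_numpy() - means.mean(), X - X.mean(axis=0),
                model.effects[names].to_numpy()))
            vc = pop.truth["var_components"]
            total = (vc["locus_realized"] + vc["polygenic_realized"]
                     + vc["env_within"] / 6)
            shares.append(vc["locus_realized"] / total)
        assert abs(np.mean(r2s) - np.mean(shares)) < 0.05


class TestDecompose:
    def test_identities_exact(self):
        d = decompose(r1=0.6, r2=0.5, R2=0.4)
        assert d.r2_tot == pytest.approx(0.3)
        assert d.fraction_h2_explained == pytest.approx(0.5)
        d2 = decompose(r1=0.6, r2=0.46875, R2=0.36)
        assert d2.fraction_additive == pytest.approx(
            (0.6 - 0.46875 * (1 - 0.36)) / 0.36)

    @given(r1=st.floats(0.05, 1.0), r2=st.floats(0.0, 1.0),
           R2=st.floats(0.01, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_identities_hold_symbolically(self, r1, r2, R2):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # clipping by design
            d = decompose(r1=r1, r2=r2, R2=R2)
        assert d.raw["r2_tot"] == r2 * (1 - R2)
        assert d.raw["fraction_h2"] == (r1 - d.raw["r2_tot"]) / r1
        assert d.raw["fraction_additive"] == (r1 - d.raw["r2_tot"]) / R2

    def test_undefined_fractions_reported_absent(self):
        d = decompose(r1=0.0, r2=0.2, R2=0.0)
        assert d.fraction_h2_explained is None
        assert d.fraction_additive is None


class TestLocusContribution:
    def test_equal_classes_contribute_nothing(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        c = locus_contribution(y, x)
        assert c.mean_pct == pytest.approx(0.0)
        assert c.var_pct == pytest.approx(0.0)

    def test_pure_mean_difference_closed_form(self):
        y = np.concatenate([np.zeros(50), np.ones(50)])
        x = np.concatenate([np.zeros(50), np.ones(50)])
        rng = np.random.default_rng(11)
        noise = rng.normal(0, 0.5, 100)
        for sl in (slice(0, 50), slice(50, 100)):  # equal class variances
            noise[sl] -= noise[sl].mean()
            noise[sl] *= 0.5 / noise[sl].std()
        yv = y + noise
        c = locus_contribution(yv, x)
        v_within = 0.25  # both class variances forced to 0.5^2
        between = 0.25  # f0*f1*(mu1-mu0)^2 with f = 0.5, delta = 1
        assert c.mean_pct == pytest.approx(100 * between / (between + v_within),
                                           rel=1e-6)
        assert c.var_pct == pytest.approx(0.0, abs=1e-9)

    def test_scenario_c_variance_dominates(self):
        from vgwas.simulate import simulate_scenario

        s = simulate_scenario("c", n_per_group=170, effect=2.6, seed=12,
                              noise_sd=0.8)
        c = locus_contribution(s.y, s.x)
        assert c.var_pct > c.mean_pct
        assert c.var_pct > 10.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            locus_contribution(np.arange(4.0), np.zeros(4))
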