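"""Tests for the reaction-system builders and interval-model fitting."""

import numpy as np
import pytest

import multinoise as mn
from multinoise.summary_stats import batch_stat_se

from conftest import se_of_mean


def _by_name(model, name):
    (rx,) = [r for r in model if r.name == name]
    return rx


class TestMonomerGene:
    def test_structure_and_validation(self):
        p = mn.ExpressionParams(k_M=10, d_M=1, k_P=1)
        model = mn.build_monomer_gene(p)
        assert len(model) == 4
        tx = _by_name(model, "transcription_1")
        assert tx.rate is mn.INSTANT and tx.shared_delay
        assert tx.delays["S1"].family == "gamma"
        with pytest.raises(ValueError):
            mn.ExpressionParams(k_M=0, d_M=1, k_P=1)
        with pytest.raises(ValueError):
            mn.ExpressionParams(k_M=1, d_M=1, k_P=1, tau_P=-1)

    def test_mrna_is_poisson_for_exponential_initiation(self):
        p = mn.ExpressionParams(k_M=10, d_M=1, k_P=1, alpha_M=1)
        s = mn.simulate(mn.build_monomer_gene(p), mn.monomer_initial(), 5000, 2.0, seed=21)
        m = s["M1"]
        fano = lambda x: np.var(x) / np.mean(x)
        assert abs(m.mean() - 10.0) < 3 * se_of_mean(m)
        assert abs(fano(m) - 1.0) < 3 * batch_stat_se(m, fano)

    def test_sub_poissonian_for_large_shape(self):
        base = dict(k_M=10, d_M=1, k_P=1)
        runs = {}
        for alpha in (1.0, 10.0):
            p = mn.ExpressionParams(alpha_M=alpha, **base)
            s = mn.simulate(mn.build_monomer_gene(p), mn.monomer_initial(), 5000, 2.0,
                            seed=22)
            runs[alpha] = s["M1"]
        assert runs[10.0].var() < runs[1.0].var()
        assert abs(runs[10.0].mean() - runs[1.0].mean()) < 1.0

    def test_protein_mean_matches_rate_balance(self):
        p = mn.ExpressionParams(k_M=5, d_M=1, k_P=4)
        s = mn.simulate(mn.build_monomer_gene(p), mn.monomer_initial(), 8000, 1.0, seed=23)
        target = 5 * 4  # k_M k_P / (d_M d_P)
        assert abs(s["P1"].mean() - target) < 3 * se_of_mean(s["P1"])


class TestHomomerSystem:
    def test_dimer_adds_three_reactions(self):
        p = mn.ExpressionParams(k_M=1, d_M=1, k_P=1)
        added = mn.build_homomer_system(p, mn.MultimerParams(order=2))[4:]
        assert len(added) == 3
        for prefix in ("assoc", "dissoc", "multimer_decay"):
            assert sum(r.name.startswith(prefix) for r in added) == 1

    def test_tetramer_association_pairs(self):
        assert mn.MultimerParams(order=4).pairs() == [(2, 1), (3, 1), (4, 1), (4, 2)]

    def test_multimer_degradation_rate_scales_with_order(self):
        p = mn.ExpressionParams(k_M=1, d_M=1, k_P=1, d_P=2.0)
        model = mn.build_homomer_system(p, mn.MultimerParams(order=3))
        rx = _by_name(model, "multimer_decay_1_3")
        assert rx.rate == 3 * 2.0
        assert rx.reactants == {"P1x3": 1} and rx.products == {"P1x2": 1}

    def test_order_below_two_rejected(self):
        p = mn.ExpressionParams(k_M=1, d_M=1, k_P=1)
        with pytest.raises(ValueError):
            mn.build_homomer_system(p, mn.MultimerParams(order=1))

    def test_zero_association_reduces_to_monomer(self):
        """With association off the homomer system's X1 is the monomer
        model's P1 — bit-identical under a shared seed, since the inert
        assembly reactions are dropped at compile time."""
        p = mn.ExpressionParams(k_M=3, d_M=1, k_P=2)
        mono = mn.simulate(mn.build_monomer_gene(p), mn.monomer_initial(), 2000, 1.0,
                           seed=31)
        homo = mn.simulate(
            mn.build_homomer_system(p, mn.MultimerParams(order=2, association=0.0)),
            mn.monomer_initial(), 2000, 1.0, seed=31,
        )
        assert np.array_equal(homo["X1"], mono["P1"])
        assert np.all(homo["P1x2"] == 0)

    def test_subunit_conservation_identity(self):
        p = mn.ExpressionParams(k_M=5, d_M=1, k_P=5)
        s = mn.simulate(
            mn.build_homomer_system(p, mn.MultimerParams(order=3)),
            mn.monomer_initial(), 3000, 1.0, seed=32,
        )
        x = s["P1"] + 2 * s["P1x2"] + 3 * s["P1x3"]
        assert np.array_equal(x, s["X1"])


class TestHeterodimerSystem:
    def test_symmetric_genes_have_equal_means(self):
        p = mn.ExpressionParams(k_M=5, d_M=1, k_P=2)
        s = mn.simulate(mn.build_heterodimer_system(p, p), mn.heterodimer_initial(),
                        5000, 1.0, seed=41)
        x1, x2 = s["X1"], s["X2"]
        se = np.hypot(se_of_mean(x1), se_of_mean(x2))
        assert abs(x1.mean() - x2.mean()) < 3 * se
        assert np.array_equal(s["X1"], s["P1"] + s["P1_2"])

    def test_dimer_degradation_leaves_surviving_monomer(self):
        p = mn.ExpressionParams(k_M=1, d_M=1, k_P=1)
        model = mn.build_heterodimer_system(p, p)
        d1 = _by_name(model, "dimer_decay_1")
        assert d1.reactants == {"P1_2": 1} and d1.products == {"P2": 1}
        assert d1.tracked_deltas == {"X1": -1}

    def test_high_expression_is_mostly_dimeric(self):
        # the dimeric fraction 1 - E[(X1-X2)+]/E[X1] rises with expression:
        # ~0.85 at mean 100, and clearly above the low-expression fraction
        hi = mn.ExpressionParams(k_M=10, d_M=1, k_P=10)
        lo = mn.ExpressionParams(k_M=1, d_M=1, k_P=1)
        frac = {}
        for tag, p in (("hi", hi), ("lo", lo)):
            s = mn.simulate(mn.build_heterodimer_system(p, p), mn.heterodimer_initial(),
                            4000, 1.0, seed=42)
            frac[tag] = s["P1_2"].mean() / s["X1"].mean()
        assert frac["hi"] > 0.8
        assert frac["hi"] > frac["lo"]

    def test_invalid_rates_raise(self):
        p = mn.ExpressionParams(k_M=1, d_M=1, k_P=1)
        with pytest.raises(ValueError):
            mn.build_heterodimer_system(p, p, a12=-1.0)
        with pytest.raises(ValueError):
            mn.build_heterodimer_system(p, p, u12=-0.5)


class TestToggleSwitch:
    def test_repression_law_values(self):
        t = mn.ToggleParams.standard(order=2, C=1.0)
        law = mn.RepressionRate(t.k_M_max, t.K, "P1x2")
        assert law({"P1x2": 0}) == t.k_M_max
        assert law({"P1x2": int(t.K)}) == pytest.approx(t.k_M_max / 2)

    def test_standard_parameter_identities(self):
        t = mn.ToggleParams.standard(order=3, C=2.0)
        # expected transcripts per gene-equivalent k_M/(N d_M) = 5 and K = 25 C
        assert t.k_M_max / (3 * t.expression.d_M) == pytest.approx(5.0)
        assert t.K == pytest.approx(25.0 * 2.0)
        assert t.repressor("1") == "P1x3"

    def test_non_exponential_initiation_rejected(self):
        t = mn.ToggleParams.standard(order=2, C=1.0)
        bad = mn.ToggleParams(
            k_M_max=t.k_M_max, K=t.K, order=2,
            expression=mn.ExpressionParams(k_M=60, d_M=6, k_P=5, alpha_M=2.0),
        )
        with pytest.raises(ValueError, match="alpha_M"):
            mn.build_toggle_switch(bad)

    def test_symmetric_switch_occupancy_is_even(self):
        t = mn.ToggleParams.standard(order=2, C=1.0)
        s = mn.simulate(mn.build_toggle_switch(t), {}, 3000, 1 / 30, seed=51)
        ind = (s["P1x2"] > s["P2x2"]).astype(float)
        se = batch_stat_se(ind, np.mean, 20)
        assert abs(ind.mean() - 0.5) < 4 * se


class TestIntervalFitting:
    def test_gamma_parameter_recovery(self, rng):
        x = rng.gamma(2.27, 1070.0, 10000)
        r = mn.fit_interval_models(x)
        assert r.gamma_shape == pytest.approx(2.27, rel=0.10)
        assert r.gamma_scale == pytest.approx(1070.0, rel=0.10)
        assert r.preferred == "gamma"

    def test_exponential_sample_gives_shape_one(self, rng):
        x = rng.exponential(1.0, 10000)
        r = mn.fit_interval_models(x)
        # asymptotic SE of the gamma-shape MLE at shape 1, n = 1e4 is ~0.012
        assert abs(r.gamma_shape - 1.0) < 0.04

    def test_three_exponential_data_prefers_hypoexponential(self, rng):
        x = (rng.exponential(1.0, 10000) + rng.exponential(1 / 3, 10000)
             + rng.exponential(0.1, 10000))
        r = mn.fit_interval_models(x)
        assert r.preferred == "three_exponential"
        assert r.hypoexp_loglik >= r.gamma_loglik
        assert r.hypoexp_rates[0] == pytest.approx(1.0, rel=0.25)

    def test_degenerate_and_short_samples_raise(self):
        with pytest.raises(ValueError):
            mn.fit_interval_models([1.0] * 100)
        with pytest.raises(ValueError):
            mn.fit_interval_models([1.0, 2.0])
        with pytest.raises(ValueError):
            mn.fit_interval_models([1.0] * 9 + [-1.0])
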