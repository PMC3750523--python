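"""Unit and property tests for the delayed stochastic simulation engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import multinoise as mn
from multinoise.stochastic_engine import SimulationState
from multinoise.summary_stats import batch_stat_se

from conftest import se_of_mean


class TestSimulateBasics:
    def test_birth_death_matches_poisson_stationary(self, birth_death):
        s = mn.simulate(birth_death, {}, 5000, 1.0, seed=1)
        m = s["M"]
        se = se_of_mean(m)
        assert abs(m.mean() - 10.0) < 3 * se
        fano = lambda x: np.var(x) / np.mean(x)
        assert abs(fano(m) - 1.0) < 3 * batch_stat_se(m, fano)

    def test_empty_model_is_constant(self):
        s = mn.simulate([], {"A": 3}, 10, 1.0, seed=0)
        assert np.array_equal(s["A"], np.full(11, 3))
        assert len(s.grid) == 11 and s.grid[0] == 0.0 and s.grid[-1] == 10.0

    def test_fixed_delay_lower_bounds_release(self):
        model = [
            mn.ReactionSpec(
                {"A": 1}, {"B": 1}, 1000.0,
                delays={"B": mn.DelayDistribution.fixed(2.0)},
            )
        ]
        s = mn.simulate(model, {"A": 1}, 5, 0.25, seed=3)
        b = s["B"]
        assert np.all(b[s.grid < 2.0] == 0)
        assert b[-1] == 1

    @pytest.mark.parametrize("backend", ["numba", "python"])
    def test_identical_seed_identical_trajectory(self, birth_death, backend):
        a = mn.simulate(birth_death, {}, 200, 1.0, seed=42, backend=backend)
        b = mn.simulate(birth_death, {}, 200, 1.0, seed=42, backend=backend)
        assert np.array_equal(a.counts, b.counts)
        c = mn.simulate(birth_death, {}, 200, 1.0, seed=43, backend=backend)
        assert not np.array_equal(a.counts, c.counts)

    def test_backends_agree_statistically(self, birth_death):
        for backend, seed in (("numba", 5), ("python", 6)):
            s = mn.simulate(birth_death, {}, 3000, 1.0, seed=seed, backend=backend)
            assert abs(s["M"].mean() - 10.0) < 4 * se_of_mean(s["M"])

    def test_validation_errors(self, birth_death):
        with pytest.raises(ValueError):
            mn.simulate(birth_death, {}, -1, 1.0, seed=0)
        with pytest.raises(ValueError):
            mn.simulate(birth_death, {}, 10, 0.0, seed=0)
        with pytest.raises(ValueError):
            mn.simulate(birth_death, {"M": -2}, 10, 1.0, seed=0)
        with pytest.raises(ValueError):
            mn.ReactionSpec({"A": 1}, {}, -3.0)
        with pytest.raises(ValueError):
            mn.ReactionSpec({}, {}, 1.0)


class TestDelayedRelease:
    def test_release_series_is_firing_process_shifted(self):
        """The product series equals the firing counting process shifted by
        exactly tau.  Uses a deterministic renewal clock (instant reaction
        whose promoter-like species returns after exactly 1 time unit) so
        the firing process is identical across delays and backends."""
        def model(tau):
            return [
                mn.ReactionSpec(
                    {"S": 1}, {"S": 1, "B": 1}, mn.INSTANT,
                    delays={"S": mn.DelayDistribution.fixed(1.0),
                            "B": mn.DelayDistribution.fixed(tau)},
                )
            ]

        for backend in ("numba", "python"):
            ref = mn.simulate(model(0.5), {"S": 1}, 60, 1.0, seed=9, backend=backend)
            lag = mn.simulate(model(2.5), {"S": 1}, 60, 1.0, seed=9, backend=backend)
            assert np.array_equal(lag["B"][2:], ref["B"][:-2])
            assert np.all(lag["B"][:2] == 0)
            # firings at integer times 0,1,2,..., release 0.5 after each
            assert np.array_equal(ref["B"], np.floor(ref.grid - 0.5) + 1)

    def test_single_firing_shifted_by_random_delay_bounds(self):
        """One A -> B conversion: B appears exactly tau after the unique
        firing, so the delayed series is the zero-delay series shifted."""
        def model(tau):
            return [mn.ReactionSpec({"A": 1}, {"B": 1}, 2.0,
                                    delays={"B": mn.DelayDistribution.fixed(tau)})]

        ref = mn.simulate(model(0.0), {"A": 1}, 30, 0.5, seed=17)
        lag = mn.simulate(model(4.0), {"A": 1}, 30, 0.5, seed=17)
        assert np.array_equal(lag["B"][8:], ref["B"][:-8])

    def test_waitlist_conserves_molecules(self):
        model = [
            mn.ReactionSpec(
                {"A": 1}, {"B": 1}, 5.0,
                delays={"B": mn.DelayDistribution.gamma(2.0, 0.25)},
            )
        ]
        s = mn.simulate(model, {"A": 20}, 50, 0.5, seed=2)
        assert np.all(s["A"] + s["B"] <= 20)
        assert np.all(np.diff(s["B"]) >= 0)
        assert s["B"][-1] == 20 and s["A"][-1] == 0

    def test_shared_delay_releases_together(self):
        d = mn.DelayDistribution.gamma(1.0, 0.5)
        model = [
            mn.ReactionSpec(
                {"S": 1}, {"S": 1, "M": 1}, mn.INSTANT,
                delays={"S": d, "M": d}, shared_delay=True,
            ),
        ]
        s = mn.simulate(model, {"S": 1}, 200, 1.0, seed=4)
        # S is regenerated with M, so exactly one S exists whenever sampled,
        # and M grows as the renewal count
        assert np.all(s["S"] <= 1)
        assert np.all(np.diff(s["M"]) >= 0)
        assert abs(s["M"][-1] / 200 - 2.0) < 0.3  # renewal rate 1/mean = 2


class TestInstantReactions:
    def test_greedy_dimerization(self):
        model = [mn.ReactionSpec({"P1": 2}, {"P1x2": 1}, mn.INSTANT, priority=2)]
        st_ = mn.resolve_instant_reactions(SimulationState(counts={"P1": 5}), model)
        assert st_.counts["P1"] == 1 and st_.counts["P1x2"] == 2

    def test_trimer_priority_order(self):
        model = [
            mn.ReactionSpec({"P1": 2}, {"P1x2": 1}, mn.INSTANT, priority=2),
            mn.ReactionSpec({"P1": 1, "P1x2": 1}, {"P1x3": 1}, mn.INSTANT, priority=3),
        ]
        st_ = mn.resolve_instant_reactions(SimulationState(counts={"P1": 7}), model)
        assert (st_.counts["P1x3"], st_.counts["P1"], st_.counts["P1x2"]) == (2, 1, 0)

    def test_no_instants_is_identity(self, birth_death):
        st_ = mn.resolve_instant_reactions(SimulationState(counts={"M": 4}), birth_death)
        assert st_.counts == {"M": 4}

    def test_instant_cycle_raises(self):
        model = [
            mn.ReactionSpec({"A": 1}, {"B": 1}, mn.INSTANT),
            mn.ReactionSpec({"B": 1}, {"A": 1}, mn.INSTANT),
        ]
        with pytest.raises(RuntimeError, match="terminat"):
            mn.resolve_instant_reactions(SimulationState(counts={"A": 1}), model)
        with pytest.raises(RuntimeError, match="terminat"):
            mn.simulate(model, {"A": 1}, 10, 1.0, seed=0)

    @settings(max_examples=60, deadline=None)
    @given(n=st.integers(min_value=0, max_value=300))
    def test_trimer_settlement_invariants(self, n):
        """Assembly conserves subunits and leaves a settled remainder:
        at most one free monomer, and never a monomer next to a dimer."""
        model = [
            mn.ReactionSpec({"P1": 2}, {"P1x2": 1}, mn.INSTANT, priority=2),
            mn.ReactionSpec({"P1": 1, "P1x2": 1}, {"P1x3": 1}, mn.INSTANT, priority=3),
        ]
        st_ = mn.resolve_instant_reactions(SimulationState(counts={"P1": n}), model)
        c = st_.counts
        assert c["P1"] + 2 * c.get("P1x2", 0) + 3 * c.get("P1x3", 0) == n
        assert c["P1"] <= 1
        assert not (c["P1"] >= 1 and c.get("P1x2", 0) >= 1)


class TestDelayDraws:
    def test_gamma_transcription_moments(self, rng):
        d = mn.DelayDistribution.transcription_interval(alpha_m=1.0, k_m=2.0)
        x = np.array([mn.draw_delay(d, rng) for _ in range(100_000)])
        assert abs(x.mean() - 0.5) < 3 * x.std() / np.sqrt(len(x))
        assert abs(x.std() / x.mean() - 1.0) < 0.02

    def test_gamma_cv_is_inverse_sqrt_shape(self):
        assert mn.DelayDistribution.transcription_interval(4.0, 1.0).cv == 0.5
        assert mn.DelayDistribution.transcription_interval(4.0, 1.0).mean == 1.0

    def test_degenerate_is_exact(self, rng):
        d = mn.DelayDistribution.fixed(0.0)
        assert all(mn.draw_delay(d, rng) == 0.0 for _ in range(10))

    def test_truncated_normal_nonnegative(self, rng):
        d = mn.DelayDistribution.truncated_normal(0.1, 1.0)
        x = np.array([mn.draw_delay(d, rng) for _ in range(2000)])
        assert np.all(x >= 0)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            mn.DelayDistribution.transcription_interval(-1.0, 2.0)
        with pytest.raises(ValueError):
            mn.DelayDistribution.transcription_interval(1.0, 0.0)
        with pytest.raises(ValueError):
            mn.DelayDistribution.fixed(-0.5)


class TestStateDependentRates:
    def test_repression_law_requires_numba_compatible_or_python(self):
        model = [
            mn.ReactionSpec({}, {"M": 1}, mn.RepressionRate(10.0, 5.0, "R")),
            mn.ReactionSpec({"M": 1}, {}, 1.0),
        ]
        # with 5 repressors the rate halves: stationary mean 5
        s = mn.simulate(model, {"R": 5}, 4000, 1.0, seed=8)
        assert abs(s["M"].mean() - 5.0) < 4 * se_of_mean(s["M"])

    def test_callable_rate_runs_on_python_backend(self):
        model = [
            mn.ReactionSpec({}, {"M": 1}, lambda c: 3.0),
            mn.ReactionSpec({"M": 1}, {}, 1.0),
        ]
        s = mn.simulate(model, {}, 2000, 1.0, seed=1)
        assert abs(s["M"].mean() - 3.0) < 4 * se_of_mean(s["M"])
        with pytest.raises(ValueError, match="python backend"):
            mn.simulate(model, {}, 10, 1.0, seed=1, backend="numba")

    def test_negative_callable_rate_raises(self):
        model = [mn.ReactionSpec({}, {"M": 1}, lambda c: -1.0)]
        with pytest.raises(ArithmeticError):
            mn.simulate(model, {}, 10, 1.0, seed=1)


def test_trajectory_tidy_dataframe(birth_death):
    s = mn.simulate(birth_death, {}, 10, 1.0, seed=0)
    df = s.to_dataframe()
    assert set(df.columns) == {"time", "species", "count"}
    assert len(df) == len(s.grid) * len(s.species)
    assert s.seed == 0
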