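import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from szest.field_model import (
    Field,
    NeighborGraph,
    default_domain,
    make_pmf,
    uniform_pmf,
)
from szest.observer import ObserverConfig
from szest.priors import agnostic_priors
from szest.strategy import (
    LocationState,
    StrategyConfig,
    is_terminated,
    likelihood_seen,
    prune_edges_by_prediction,
    run_single_test,
    select_stimulus,
    update_pmf,
)

CFG = StrategyConfig()


class TestLikelihood:
    def test_half_probability_at_the_stimulus(self):
        l = likelihood_seen(20, default_domain(), CFG)
        assert l[20] == pytest.approx(0.03 + 0.94 * 0.5)

    def test_asymptotes(self):
        l = likelihood_seen(20, default_domain(), CFG)
        assert l[-1] == pytest.approx(0.97, abs=1e-3)
        assert l[0] == pytest.approx(0.03, abs=1e-3)
        assert np.all(l > 0.03 - 1e-12) and np.all(l < 0.97 + 1e-12)

    def test_value_three_db_above_stimulus(self):
        l = likelihood_seen(20, default_domain(), CFG)
        assert l[23] == pytest.approx(0.03 + 0.94 * norm.cdf(3), abs=1e-6)
        assert l[23] == pytest.approx(0.96873, abs=1e-5)

    def test_monotone_increasing_in_threshold(self):
        l = likelihood_seen(17, default_domain(), CFG)
        assert np.all(np.diff(l) >= 0)
        # strictly increasing where the CDF is not saturated in float
        central = slice(12, 23)
        assert np.all(np.diff(l[central]) > 0)


class TestUpdate:
    def test_weight_zero_is_no_evidence(self):
        p = uniform_pmf()
        q = update_pmf(p, 20, True, weight=0.0)
        np.testing.assert_allclose(q.mass, p.mass, atol=1e-15)

    def test_point_mass_prior_is_fixed(self):
        d = default_domain()
        p = make_pmf(d, (d == 25).astype(float))
        q = update_pmf(p, 20, False, weight=1.0)
        np.testing.assert_allclose(q.mass, p.mass, atol=1e-15)

    def test_seen_update_on_three_point_domain(self):
        # posterior ∝ uniform × l(x), l(x) = 0.03 + 0.94·Φ(x − 20)
        cfg = dataclasses.replace(CFG, domain_lo=19, domain_hi=21)
        p = uniform_pmf(np.array([19.0, 20.0, 21.0]))
        q = update_pmf(p, 20, True, 1.0, cfg)
        l = 0.03 + 0.94 * norm.cdf(np.array([-1.0, 0.0, 1.0]))
        np.testing.assert_allclose(q.mass, l / l.sum(), atol=1e-12)

    def test_power_updates_compose_additively(self):
        p = uniform_pmf()
        q1 = update_pmf(update_pmf(p, 17, True, 0.25), 17, True, 0.35)
        q2 = update_pmf(p, 17, True, 0.6)
        np.testing.assert_allclose(q1.mass, q2.mass, atol=1e-12)

    def test_linear_scaling_variant_flattens_toward_one(self):
        cfg = dataclasses.replace(CFG, neighbor_update="linear")
        p = uniform_pmf()
        q = update_pmf(p, 20, True, 0.2, cfg)
        lin = 0.2 * likelihood_seen(20, p.domain, cfg) + 0.8
        np.testing.assert_allclose(q.mass, (p.mass * lin) / (p.mass * lin).sum(), atol=1e-12)

    @settings(max_examples=30)
    @given(
        st.integers(min_value=0, max_value=40),
        st.booleans(),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_monotone_evidence_moves_the_mean_the_right_way(self, stim, seen, seed):
        rng = np.random.default_rng(seed)
        p = make_pmf(default_domain(), rng.random(41) + 1e-3)
        q = update_pmf(p, stim, seen, 1.0)
        if seen:
            assert q.mean() >= p.mean() - 1e-9
        else:
            assert q.mean() <= p.mean() + 1e-9


class TestStimulusAndTermination:
    def test_uniform_prior_gives_20(self):
        assert select_stimulus(uniform_pmf()) == 20

    def test_point_mass(self):
        d = default_domain()
        assert select_stimulus(make_pmf(d, (d == 7).astype(float))) == 7

    def test_round_half_up(self):
        p = make_pmf([17.0, 18.0], [0.5, 0.5])  # mean 17.5
        assert select_stimulus(p) == 18

    def test_clamped_to_domain(self):
        p = make_pmf([0.0, 40.0], [0.01, 0.99])
        assert 0 <= select_stimulus(p) <= 40

    @pytest.mark.parametrize(
        "sd_scale, n, expected",
        [(1.4, 3, True), (4.0, 10, True), (4.0, 9, False), (1.5, 1, True)],
    )
    def test_termination_rule(self, sd_scale, n, expected):
        d = np.array([20.0 - sd_scale, 20.0 + sd_scale])
        state = LocationState(pmf=make_pmf(d, [0.5, 0.5]), n_presented=n)
        assert state.pmf.sd() == pytest.approx(sd_scale)
        assert is_terminated(state, CFG) is expected


class TestEdgePruning:
    def graph(self):
        return NeighborGraph(edges=frozenset({(0, 1), (1, 2)}), weight=0.4)

    def test_edge_removed_when_more_than_3db_apart(self):
        pred = Field(values={0: 25.0, 1: 29.0, 2: 29.0})
        pruned = prune_edges_by_prediction(self.graph(), pred, 3.0)
        assert pruned.edges == frozenset({(1, 2)})

    def test_exactly_3db_is_kept(self):
        pred = Field(values={0: 25.0, 1: 28.0, 2: 28.0})
        assert prune_edges_by_prediction(self.graph(), pred, 3.0).edges == self.graph().edges

    def test_uniform_prediction_keeps_graph(self):
        pred = Field(values={0: 20.0, 1: 20.0, 2: 20.0})
        assert prune_edges_by_prediction(self.graph(), pred, 3.0).edges == self.graph().edges

    def test_missing_prediction_rejected(self):
        with pytest.raises(KeyError):
            prune_edges_by_prediction(self.graph(), Field(values={0: 20.0}), 3.0)


def scripted(responses):
    """response_fn replaying a per-location list of responses."""
    counters = {}

    def fn(lid, stim, t):
        k = counters.get(lid, 0)
        counters[lid] = k + 1
        return responses[lid][k]

    return fn


class TestSingleTest:
    def reliable(self):
        return ObserverConfig(fp=0.05, fn=0.05)

    def test_presentation_caps_hold(self, grid, graph):
        priors = agnostic_priors(grid)
        f = Field(values={l.id: 25.0 for l in grid.locations})
        res = run_single_test(f, priors, graph, StrategyConfig(spatial=True), self.reliable(), 7)
        assert all(1 <= n <= 10 for n in res.presentations_per_location.values())
        assert res.total_presentations == sum(res.presentations_per_location.values())
        assert res.total_presentations <= 520

    def test_deterministic_given_seed(self, grid):
        priors = agnostic_priors(grid)
        f = Field(values={l.id: 22.0 for l in grid.locations})
        a = run_single_test(f, priors, None, CFG, self.reliable(), 99)
        b = run_single_test(f, priors, None, CFG, self.reliable(), 99)
        assert a.estimates.values == b.estimates.values
        assert a.trials == b.trials

    def test_point_mass_priors_terminate_after_one_presentation(self, grid):
        d = default_domain()
        truth = {l.id: 25.0 for l in grid.locations}
        priors = {i: make_pmf(d, (d == 25).astype(float)) for i in truth}
        res = run_single_test(
            Field(values=truth), priors, None, CFG, self.reliable(), 3
        )
        # minimum one presentation each, estimate equals the prior mean
        assert all(n == 1 for n in res.presentations_per_location.values())
        assert all(v == pytest.approx(25.0) for v in res.estimates.values.values())

    def test_spatial_off_equals_independent_zest(self, grid):
        """Without a graph, locations evolve independently: replaying each
        location's own trial sequence through a per-location ZEST reproduces
        the engine's estimates exactly."""
        priors = agnostic_priors(grid)
        f = Field(values={l.id: 18.0 if l.y_deg > 0 else 30.0 for l in grid.locations})
        res = run_single_test(f, priors, None, CFG, self.reliable(), 11)
        for lid in f.values:
            p = priors[lid]
            for tr in res.trials:
                if tr.location_id == lid:
                    p = update_pmf(p, tr.stimulus_db, tr.seen, 1.0, CFG)
            assert res.estimates.values[lid] == pytest.approx(p.mean(), abs=1e-12)

    def test_scripted_posterior_matches_brute_force_product(self):
        """Engine posterior = prior × Π L^w on a 5-point domain, including
        scaled neighbour updates, for scripted responses."""
        cfg = StrategyConfig(
            spatial=True, spatial_weight=0.4, domain_lo=18, domain_hi=22,
            stop_sd=0.01, max_presentations=4,
        )
        d = cfg.domain()
        graph = NeighborGraph(edges=frozenset({(0, 1)}), weight=0.4)
        truth = Field(values={0: 20.0, 1: 20.0})
        for bits in range(16):
            responses = {0: [bool(bits >> k & 1) for k in range(4)],
                         1: [bool(bits >> k & 1) for k in range(4)][::-1]}
            priors = {0: uniform_pmf(d), 1: uniform_pmf(d)}
            res = run_single_test(
                truth, priors, graph, cfg, self.reliable(), 5,
                response_fn=scripted(responses),
            )
            # brute force from the trial log
            for lid in (0, 1):
                other = 1 - lid
                mass = np.ones(len(d)) / len(d)
                n_seen = 0
                for tr in res.trials:
                    lvec = 0.03 + 0.94 * norm.cdf(d - tr.stimulus_db)
                    if not tr.seen:
                        lvec = 1.0 - lvec
                    if tr.location_id == lid and n_seen < res.presentations_per_location[lid]:
                        mass = mass * lvec
                        n_seen += 1
                    elif tr.location_id == other:
                        # neighbour updates apply only while lid not terminated
                        if n_seen < res.presentations_per_location[lid]:
                            mass = mass * lvec**0.4
                mass /= mass.sum()
                est = float(mass @ d)
                assert res.estimates.values[lid] == pytest.approx(est, abs=1e-9)

    def test_neighbor_updates_never_touch_terminated_locations(self, grid, graph):
        priors = agnostic_priors(grid)
        f = Field(values={l.id: 28.0 for l in grid.locations})
        res = run_single_test(
            f, priors, graph, StrategyConfig(spatial=True), self.reliable(), 21
        )
        # replay: once a location terminates, its estimate must equal the
        # posterior mean at its own last presentation
        last_pres = {}
        count = dict.fromkeys(f.values, 0)
        for tr in res.trials:
            count[tr.location_id] += 1
            if count[tr.location_id] == res.presentations_per_location[tr.location_id]:
                last_pres[tr.location_id] = tr.presentation_index
        assert set(last_pres) == set(f.values)

    def test_prior_coverage_checked(self, grid):
        f = Field(values={l.id: 20.0 for l in grid.locations})
        with pytest.raises(ValueError, match="priors missing"):
            run_single_test(f, {0: uniform_pmf()}, None, CFG, self.reliable(), 0)

    def test_spatial_requires_graph(self, grid):
        f = Field(values={l.id: 20.0 for l in grid.locations})
        with pytest.raises(ValueError, match="graph"):
            run_single_test(
                f, agnostic_priors(grid), None, StrategyConfig(spatial=True),
                self.reliable(), 0,
            )

    def test_summary_renders(self, grid):
        priors = agnostic_priors(grid)
        f = Field(values={l.id: 25.0 for l in grid.locations})
        res = run_single_test(f, priors, None, CFG, self.reliable(), 1)
        text = res.summary()
        assert "total presentations" in text and str(res.total_presentations) in text
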