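"""Bootstrap statistic against enumeration oracles, plus call semantics."""

import itertools

import numpy as np
import pytest
from scipy import stats

import camtraits as ct
from camtraits.pathway_bootstrap import (
    BootstrapConfig,
    expected_hit_draws,
    median_difference,
    null_distribution,
    observed_hits,
    underrepresentation_screen,
)
from camtraits.synthetic_data import generate_enriched_sets


def _kos(n):
    return [f"K{i:05d}" for i in range(n)]


def exact_difference_pmf(N, K, n):
    """Oracle: pmf of hits(A) - hits(B) over all ordered subset pairs."""
    universe = _kos(N)
    pathway = set(universe[:K])
    hits = [len(pathway & set(sub)) for sub in itertools.combinations(universe, n)]
    diffs = {}
    for h1 in hits:
        for h2 in hits:
            diffs[h1 - h2] = diffs.get(h1 - h2, 0) + 1
    total = len(hits) ** 2
    return {d: c / total for d, c in sorted(diffs.items())}


class TestObservedHits:
    def test_intersection_counting(self):
        assert observed_hits({"k1", "k2", "k3"}, {"k1", "k2", "k3"}) == 3
        assert observed_hits({"a"}, {"b"}) == 0
        assert observed_hits({"k1", "k2", "k5"}, {"k2", "k5", "k9"}) == 2


class TestExpectedHitDraws:
    def test_mean_matches_hypergeometric(self):
        rng = np.random.default_rng(1)
        draws = expected_hit_draws(5, set(_kos(10)), set(_kos(4)), 10_000, rng)
        assert 1.9 <= draws.mean() <= 2.1  # nK/N = 5*4/10

    def test_full_draw_always_hits_k(self):
        rng = np.random.default_rng(2)
        draws = expected_hit_draws(10, set(_kos(10)), set(_kos(3)), 100, rng)
        assert (draws == 3).all()

    def test_empty_pathway_never_hits(self):
        rng = np.random.default_rng(3)
        draws = expected_hit_draws(5, set(_kos(10)), set(), 100, rng)
        assert (draws == 0).all()

    def test_rejects_n_larger_than_universe(self):
        with pytest.raises(ValueError):
            expected_hit_draws(11, set(_kos(10)), set(_kos(2)), 10,
                               np.random.default_rng(0))

    def test_pmf_matches_enumerated_hypergeometric(self):
        """Chi-square GOF of the sampler against the exact pmf, N <= 12."""
        N, K, n, reps = 10, 4, 5, 10_000
        rng = np.random.default_rng(11)
        draws = expected_hit_draws(n, set(_kos(N)), set(_kos(K)), reps, rng)
        support = np.arange(max(0, n - (N - K)), min(K, n) + 1)
        pmf = stats.hypergeom.pmf(support, N, K, n)
        observed = np.array([(draws == k).sum() for k in support])
        _, p = stats.chisquare(observed, reps * pmf / pmf.sum())
        assert p > 0.01


class TestMedianDifference:
    def test_exact_enumerated_median(self):
        # draws ~ Hypergeom(N=10, K=4, n=5): median 2 from the exact pmf.
        rng = np.random.default_rng(5)
        draws = expected_hit_draws(5, set(_kos(10)), set(_kos(4)), 10_001, rng)
        assert median_difference(4, draws) == 2.0

    def test_constant_draws(self):
        assert median_difference(3, np.array([3, 3, 3])) == 0.0

    def test_midpoint_convention(self):
        assert median_difference(5, np.array([1, 3])) == 3.0

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            median_difference(1, np.array([]))


class TestNullDistribution:
    def test_mean_near_zero_and_sorted(self):
        cfg = BootstrapConfig(n_reps=2000, lower_index=100, upper_index=1900, seed=4)
        diffs, lower, upper = null_distribution(10, set(_kos(50)), set(_kos(10)), cfg)
        assert abs(diffs.mean()) < 0.2
        assert (np.diff(diffs) >= 0).all() and lower <= upper

    def test_empty_pathway_gives_zero_limits(self):
        cfg = BootstrapConfig(seed=1)
        diffs, lower, upper = null_distribution(5, set(_kos(20)), set(), cfg)
        assert (diffs == 0).all() and (lower, upper) == (0.0, 0.0)

    def test_matches_exhaustive_subset_pair_enumeration(self):
        """KS distance between the sampled null and the exact difference law."""
        N, K, n = 6, 2, 3
        pmf = exact_difference_pmf(N, K, n)
        support = np.array(sorted(pmf))
        cdf = np.cumsum([pmf[d] for d in support])
        cfg = BootstrapConfig(n_reps=20_000, lower_index=1000, upper_index=19_000,
                              seed=8)
        diffs, _, _ = null_distribution(n, set(_kos(N)), set(_kos(K)), cfg)
        ecdf = np.array([(diffs <= d).mean() for d in support])
        assert np.abs(ecdf - cdf).max() < 0.02

    def test_limit_order_statistics_match_exact_quantile_law(self):
        """Ranks 50/950 of 1,000 sorted null differences for N=6, K=2, n=3.

        The exact difference pmf gives P(D=-2)=0.04 and P(D<=0)=0.72, so the
        rank-50 (rank-950) order statistic is -1 (+1) unless a binomial
        fluctuation pushes it to -2 (+2); the probability that the limits
        come out symmetric follows from those binomial tails. The observed
        rate over repeated seeds must match it within Monte-Carlo error.
        """
        N, K, n = 6, 2, 3
        pmf = exact_difference_pmf(N, K, n)
        p_low = 1 - stats.binom.cdf(49, 1000, pmf[-2])        # lower limit = -2
        p_high = 1 - stats.binom.cdf(49, 1000, pmf[2])        # upper limit = +2
        p_sym = (1 - p_low) * (1 - p_high) + p_low * p_high
        n_seeds = 40
        sym = 0
        for seed in range(n_seeds):
            cfg = BootstrapConfig(seed=seed)
            _, lower, upper = null_distribution(n, set(_kos(N)), set(_kos(K)), cfg)
            assert {lower, upper} <= {-2.0, -1.0, 0.0, 1.0, 2.0}
            sym += lower == -upper
        sd = np.sqrt(p_sym * (1 - p_sym) / n_seeds)
        assert abs(sym / n_seeds - p_sym) < 4 * sd + 1e-9


class TestMonotonicity:
    def test_exact_hypergeometric_median_increments_at_most_one(self):
        """Oracle for the monotonicity invariant.

        median_difference = observed - median(draws). Adding a pathway KO to
        the enriched set raises observed by 1 and n by 1; the statistic can
        only decrease if the hypergeometric median jumps by more than 1 when
        n grows by 1 — it never does.
        """
        N, K = 30, 8
        meds = [stats.hypergeom.median(N, K, n) for n in range(1, N + 1)]
        assert all(m2 - m1 <= 1 for m1, m2 in zip(meds, meds[1:]))

    def test_sampled_median_difference_is_monotone(self):
        universe, pathway = set(_kos(100)), set(_kos(20))
        cfg_reps = 4001
        enriched = set(_kos(100)[20:30])  # 10 KOs, none in the pathway
        vals = []
        for extra in range(4):  # grow the enriched set with pathway KOs
            e = enriched | set(_kos(20)[:extra])
            rng = np.random.default_rng(17)
            draws = expected_hit_draws(len(e), universe, pathway, cfg_reps, rng)
            vals.append(median_difference(observed_hits(e, pathway), draws))
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestCallPathways:
    def test_heavily_planted_pathway_is_called_enriched(self):
        kos = _kos(500)
        pmap = ct.PathwayMap({"pw": frozenset(kos[:20])}, frozenset(kos))
        sets = generate_enriched_sets(pmap, 25, "pw", 15, seed=3)
        calls = ct.call_pathways(sets, pmap, pmap.universe,
                                 BootstrapConfig(seed=5))
        (call,) = calls["treatment"]
        assert call.call == "enriched" and call.observed_hits == 15

    def test_disjoint_pathway_not_significant(self):
        kos = _kos(100)
        pmap = ct.PathwayMap({"pw": frozenset(kos[:5])}, frozenset(kos))
        sets = generate_enriched_sets(pmap, 10, "pw", 0, seed=9)
        calls = ct.call_pathways(sets, pmap, pmap.universe,
                                 BootstrapConfig(seed=1))
        assert calls["treatment"][0].call == "not_significant"

    def test_empty_enriched_set_yields_all_not_significant(self, caplog):
        kos = _kos(50)
        pmap = ct.PathwayMap({"pw": frozenset(kos[:5])}, frozenset(kos))
        sets = generate_enriched_sets(pmap, 6, seed=2)
        calls = ct.call_pathways(sets, pmap, pmap.universe,
                                 BootstrapConfig(seed=1))
        for c in calls["baseline"]:  # the baseline direction is empty
            assert c.call == "not_significant" and c.median_difference == 0.0

    def test_bit_identical_given_seed_and_unaffected_by_other_direction(self):
        kos = _kos(200)
        pmap = ct.PathwayMap(
            {"a": frozenset(kos[:15]), "b": frozenset(kos[15:40])},
            frozenset(kos),
        )
        sets = generate_enriched_sets(pmap, 20, "a", 5, seed=6)
        cfg = BootstrapConfig(seed=123)
        c1 = ct.call_pathways(sets, pmap, pmap.universe, cfg)
        c2 = ct.call_pathways(sets, pmap, pmap.universe, cfg)
        assert c1 == c2


class TestUnderrepresentationScreen:
    def test_full_metagenome_excludes_nothing(self):
        kos = _kos(60)
        pmap = ct.PathwayMap({"a": frozenset(kos[:10]), "b": frozenset(kos[10:30])},
                             frozenset(kos))
        res = underrepresentation_screen(pmap.universe, pmap, BootstrapConfig(seed=2))
        assert not res.excluded and res.retained == frozenset(pmap.pathways)

    def test_absent_large_pathway_is_excluded(self):
        # N=100, K=30, metagenome of 50 KOs disjoint from the pathway:
        # expected hits median 15, observed 0 -> far below the 5% limit.
        kos = _kos(100)
        pmap = ct.PathwayMap({"big": frozenset(kos[:30]), "tiny": frozenset(kos[30:33])},
                             frozenset(kos))
        metagenome = frozenset(kos[40:90])
        res = underrepresentation_screen(metagenome, pmap, BootstrapConfig(seed=4))
        assert "big" in res.excluded

    def test_fully_present_pathway_is_retained(self):
        kos = _kos(100)
        pmap = ct.PathwayMap({"pw": frozenset(kos[:10])}, frozenset(kos))
        metagenome = frozenset(kos[:50])
        res = underrepresentation_screen(metagenome, pmap, BootstrapConfig(seed=4))
        assert "pw" in res.retained

    def test_rejects_metagenome_outside_universe(self):
        kos = _kos(10)
        pmap = ct.PathwayMap({"pw": frozenset(kos[:3])}, frozenset(kos))
        with pytest.raises(ValueError):
            underrepresentation_screen({"K99999"}, pmap, BootstrapConfig(seed=0))


def test_bootstrap_config_rank_validation():
    with pytest.raises(ValueError):
        BootstrapConfig(n_reps=100, lower_index=0, upper_index=95)
    with pytest.raises(ValueError):
        BootstrapConfig(n_reps=100, lower_index=95, upper_index=5)
    cfg = BootstrapConfig.with_default_ranks(200, seed=1)
    assert (cfg.lower_index, cfg.upper_index) == (10, 190)
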