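"""Bootstrap pathway enrichment calls.

The core statistic: for each pathway, the observed number of enriched KOs
falling inside it ("KO hits") is compared with the hits of random KO lists
of the same size n drawn without replacement from the KO universe. The
median of observed-minus-expected differences over many resampling
replicates is the pathway's enrichment statistic. Its significance limits
come from a randomized null in which *both* the observed and the expected
KO lists are drawn at random: the replicate differences are sorted
ascending and the limits read off as order statistics (ranks 50 and 950 of
1,000 by default, giving 5% and 95% limits). A pathway is called enriched
when its median difference lies strictly above the upper limit, depleted
when strictly below the lower limit.

Because KOs are shared between pathways, a pathway can accumulate hits
purely through KO redundancy. The under-representation screen guards
against this: pathways whose representation in the predicted metagenome
itself falls below the null's 5% limit are excluded before any enrichment
call is made.

A single random n-subset's hit count is marginally hypergeometric
(N = universe size, K = pathway size, n), so replicate hit counts are
drawn directly from the hypergeometric distribution; enumeration tests
verify the equivalence.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from camtraits.ko_enrichment import EnrichedKOSets
from camtraits.synthetic_data import PathwayMap

__all__ = [
    "BootstrapConfig",
    "PathwayCall",
    "ScreenResult",
    "observed_hits",
    "expected_hit_draws",
    "median_difference",
    "null_distribution",
    "call_pathways",
    "underrepresentation_screen",
]

logger = logging.getLogger(__name__)

CALL_ENRICHED = "enriched"
CALL_DEPLETED = "depleted"
CALL_NS = "not_significant"


@dataclass(frozen=True)
class BootstrapConfig:
    """Replicate count, null order-statistic ranks, and master seed.

    The defaults (1,000 replicates, limits at 1-based ranks 50 and 950 of
    the sorted null) give 5%/95% limits. For other replicate counts use
    :meth:`with_default_ranks`, which generalizes the ranks to
    ceil(0.05 R) and floor(0.95 R).
    """

    n_reps: int = 1000
    lower_index: int = 50
    upper_index: int = 950
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")
        if not 1 <= self.lower_index < self.upper_index <= self.n_reps:
            raise ValueError("need 1 <= lower_index < upper_index <= n_reps")

    @classmethod
    def with_default_ranks(cls, n_reps: int, seed: int = 0) -> "BootstrapConfig":
        return cls(
            n_reps=n_reps,
            lower_index=max(1, math.ceil(0.05 * n_reps)),
            upper_index=math.floor(0.95 * n_reps),
            seed=seed,
        )


@dataclass(frozen=True)
class PathwayCall:
    pathway: str
    direction: str  # "treatment" or "baseline"
    n: int
    observed_hits: int
    median_difference: float
    lower_limit: float
    upper_limit: float
    call: str
    pathway_size: int  # KOs of the pathway inside the comparison universe

    def __post_init__(self) -> None:
        if self.lower_limit > self.upper_limit:
            raise ValueError("lower_limit must not exceed upper_limit")
        expected = CALL_NS
        if self.median_difference > self.upper_limit:
            expected = CALL_ENRICHED
        elif self.median_difference < self.lower_limit:
            expected = CALL_DEPLETED
        if self.call != expected:
            raise ValueError(
                f"call {self.call!r} inconsistent with limits for {self.pathway!r}"
            )

    @property
    def size_one(self) -> bool:
        """Single-KO pathways are legitimate but worth flagging."""
        return self.pathway_size == 1


@dataclass(frozen=True)
class ScreenResult:
    excluded: frozenset[str]
    retained: frozenset[str]
    details: tuple[PathwayCall, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.excluded & self.retained:
            raise ValueError("a pathway cannot be both excluded and retained")


def _substream(seed: int, *tags: str | int) -> np.random.Generator:
    """Independent RNG substream keyed by stable string/int tags.

    Strings are hashed with crc32 so the stream depends only on the tag
    text, never on interpreter hash randomization; adding comparisons or
    directions therefore never perturbs earlier streams.
    """
    key = [zlib.crc32(t.encode()) if isinstance(t, str) else int(t) for t in tags]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def observed_hits(enriched: frozenset[str] | set[str],
                  pathway_kos: frozenset[str] | set[str]) -> int:
    """Number of enriched KOs inside the pathway ("KO hits")."""
    return len(set(enriched) & set(pathway_kos))


def expected_hit_draws(
    n: int,
    universe: frozenset[str] | set[str],
    pathway_kos: frozenset[str] | set[str],
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hit counts of ``n_reps`` random n-subsets of the universe.

    Each replicate draws n KOs without replacement and counts how many
    fall in the pathway; the count is marginally hypergeometric with
    N = |universe|, K = |pathway|, and is sampled as such.
    """
    N = len(universe)
    if n > N:
        raise ValueError(f"cannot draw {n} KOs from a universe of {N}")
    if not set(pathway_kos) <= set(universe):
        raise ValueError("pathway KOs must be a subset of the universe")
    K = len(pathway_kos)
    if K == 0 or n == 0:
        return np.zeros(n_reps, dtype=np.int64)
    return rng.hypergeometric(ngood=K, nbad=N - K, nsample=n, size=n_reps)


def median_difference(observed: int, expected_draws: np.ndarray) -> float:
    """Median of (observed - draw); midpoint convention for even lengths."""
    draws = np.asarray(expected_draws)
    if draws.size == 0:
        raise ValueError("expected_draws must be non-empty")
    return float(np.median(observed - draws))


def null_distribution(
    n: int,
    universe: frozenset[str] | set[str],
    pathway_kos: frozenset[str] | set[str],
    config: BootstrapConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float, float]:
    """Randomized null: both KO lists drawn at random, differences sorted.

    Each replicate is hits(random n-subset) - hits(independent random
    n-subset); the sorted differences and the order-statistic limits at
    the configured 1-based ranks are returned.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    obs = expected_hit_draws(n, universe, pathway_kos, config.n_reps, rng)
    exp = expected_hit_draws(n, universe, pathway_kos, config.n_reps, rng)
    diffs = np.sort(obs - exp)
    lower = float(diffs[config.lower_index - 1])
    upper = float(diffs[config.upper_index - 1])
    return diffs, lower, upper


def _call_one(
    pathway: str,
    direction: str,
    n: int,
    enriched: frozenset[str],
    universe: frozenset[str],
    kos_in_universe: frozenset[str],
    config: BootstrapConfig,
    rng: np.random.Generator,
) -> PathwayCall:
    obs = observed_hits(enriched, kos_in_universe)
    if n == 0:
        return PathwayCall(pathway, direction, 0, 0, 0.0, 0.0, 0.0, CALL_NS,
                           pathway_size=len(kos_in_universe))
    draws = expected_hit_draws(n, universe, kos_in_universe, config.n_reps, rng)
    md = median_difference(obs, draws)
    _, lower, upper = null_distribution(n, universe, kos_in_universe, config, rng)
    if md > upper:
        call = CALL_ENRICHED
    elif md < lower:
        call = CALL_DEPLETED
    else:
        call = CALL_NS
    return PathwayCall(pathway, direction, n, obs, md, lower, upper, call,
                       pathway_size=len(kos_in_universe))


def call_pathways(
    enriched_sets: EnrichedKOSets,
    pathway_map: PathwayMap,
    universe: frozenset[str] | set[str],
    config: BootstrapConfig,
    retained: frozenset[str] | set[str] | None = None,
) -> dict[str, list[PathwayCall]]:
    """Enrichment/depletion calls for both directions of one comparison.

    ``universe`` is the collective predicted functional genome of the
    comparison (KOs observed in at least one of its samples); pathway KO
    sets are restricted to it. Each direction uses its own RNG substream
    derived from (seed, comparison label, direction), and pathways are
    processed in sorted id order, so results are reproducible and
    insensitive to unrelated comparisons. ``retained`` (typically the
    under-representation screen's survivors) limits which pathways are
    called.
    """
    universe = frozenset(universe)
    pathway_ids = sorted(pathway_map.pathways)
    if retained is not None:
        pathway_ids = [p for p in pathway_ids if p in retained]

    directions = {
        "treatment": enriched_sets.enriched_in_treatment,
        "baseline": enriched_sets.enriched_in_baseline,
    }
    out: dict[str, list[PathwayCall]] = {}
    for d_idx, (direction, enriched) in enumerate(directions.items()):
        enriched = frozenset(enriched) & universe
        n = len(enriched)
        if n > len(universe):
            raise ValueError("enriched set larger than the universe")
        if n == 0:
            logger.warning(
                "comparison %s: empty %s-enriched KO set; all calls not_significant",
                enriched_sets.comparison.label, direction,
            )
        rng = _substream(config.seed, enriched_sets.comparison.label, d_idx)
        calls = []
        for pid in pathway_ids:
            kos = pathway_map.pathways[pid] & universe
            calls.append(_call_one(pid, direction, n, enriched, universe, kos,
                                   config, rng))
        out[direction] = calls
        logger.info(
            "comparison %s, %s direction: n=%d enriched KOs, %d/%d pathways called",
            enriched_sets.comparison.label, direction, n,
            sum(c.call != CALL_NS for c in calls), len(calls),
        )
    return out


def underrepresentation_screen(
    metagenome_kos: frozenset[str] | set[str],
    full_map: PathwayMap,
    config: BootstrapConfig,
) -> ScreenResult:
    """Exclude pathways under-represented in the predicted metagenome.

    Runs the same bootstrap with the metagenome's KO list as "observed"
    and random lists of the same size from the full reference universe as
    "expected". Pathways whose difference of medians falls strictly below
    the null's 5% limit are excluded from all later enrichment calls —
    their apparent KO hits are attributable to KO redundancy rather than
    genuine pathway representation.
    """
    metagenome_kos = frozenset(metagenome_kos)
    if not metagenome_kos <= full_map.universe:
        raise ValueError("metagenome KOs must be a subset of the reference universe")
    universe = full_map.universe
    n = len(metagenome_kos)

    excluded: set[str] = set()
    details: list[PathwayCall] = []
    for pid in sorted(full_map.pathways):
        rng = _substream(config.seed, "underrepresentation_screen", pid)
        call = _call_one(pid, "screen", n, metagenome_kos, universe,
                         full_map.pathways[pid], config, rng)
        details.append(call)
        if call.call == CALL_DEPLETED:
            excluded.add(pid)
    retained = frozenset(full_map.pathways) - excluded
    logger.info("under-representation screen: %d excluded, %d retained",
                len(excluded), len(retained))
    return ScreenResult(excluded=frozenset(excluded), retained=retained,
                        details=tuple(details))
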