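"""Synthetic inputs with planted ground truth.

Generates the three objects the pipeline consumes — a KO->pathway map, a
factorial study design (soil compartment x Cd dose), and a sample x KO
count table — with known pathway-level enrichment effects planted into the
counts, so that every downstream stage (KO testing, bootstrap pathway
calls, CSR scoring) can be validated against ground truth without any
external data.

Counts are negative-binomial with the mean/dispersion parameterisation
``Var = mu + alpha * mu**2``, matching the analysis model. Library-size
factors are log-normal with a chosen coefficient of variation and are
renormalised to geometric mean 1, so size-factor estimation downstream is
non-trivial but identifiable.

Random-draw order within :func:`generate_counts` is fixed and documented
(library factors, then per-effect affected-KO subsets in effect-list order,
then the count matrix row-major), so fixtures are stable across versions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids circular import
    from camtraits.ko_enrichment import EnrichedKOSets

__all__ = [
    "PathwayMap",
    "StudyDesign",
    "PlantedEffect",
    "GroundTruth",
    "KOCountTable",
    "factorial_design",
    "generate_pathway_map",
    "generate_counts",
    "generate_enriched_sets",
]

#: Factor levels of the microcosm design: soil compartment and Cd dose
#: (mg Cd per kg soil; labels only — doses are never used numerically).
COMPARTMENTS = ("bulk", "rhizosphere")
CD_DOSES = (0, 20, 100)

Cell = tuple[str, int]


@dataclass(frozen=True)
class PathwayMap:
    """Many-to-many map from pathway ids to KO sets.

    ``universe`` holds every KO id that exists in the predicted functional
    repertoire, including KOs mapped to no pathway (pathway-free KOs are
    legitimate: real KO universes contain orthologs outside every screened
    pathway). A KO may belong to several pathways; this redundancy is a
    core property of KEGG-style maps and the reason the under-representation
    screen exists.
    """

    pathways: Mapping[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for pid, kos in self.pathways.items():
            if not kos:
                raise ValueError(f"pathway {pid!r} has an empty KO set")
            if not kos <= self.universe:
                raise ValueError(f"pathway {pid!r} references KOs outside the universe")

    def multiplicity(self) -> dict[str, int]:
        """Number of pathways each assigned KO belongs to."""
        counts: dict[str, int] = {}
        for kos in self.pathways.values():
            for ko in kos:
                counts[ko] = counts.get(ko, 0) + 1
        return counts

    def sizes(self) -> dict[str, int]:
        return {pid: len(kos) for pid, kos in self.pathways.items()}


@dataclass(frozen=True)
class StudyDesign:
    """Grouped factorial sample design.

    Each sample carries exactly one level of each factor. The baseline cell
    ``("bulk", 0)`` — uncontaminated bulk soil — must be populated because
    every pairwise comparison is made against it.
    """

    samples: tuple[str, ...]
    compartment: Mapping[str, str]
    cd_dose: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in design")
        for s in self.samples:
            if s not in self.compartment or s not in self.cd_dose:
                raise ValueError(f"sample {s!r} is missing a factor level")
            if self.compartment[s] not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {self.compartment[s]!r}")
        if not self.samples_in(("bulk", 0)):
            raise ValueError("baseline cell (bulk, 0) is empty")

    def cell_of(self, sample: str) -> Cell:
        return (self.compartment[sample], self.cd_dose[sample])

    def samples_in(self, cell: Cell) -> tuple[str, ...]:
        return tuple(s for s in self.samples if self.cell_of(s) == cell)

    def cells(self) -> tuple[Cell, ...]:
        seen: list[Cell] = []
        for s in self.samples:
            c = self.cell_of(s)
            if c not in seen:
                seen.append(c)
        return tuple(seen)


def factorial_design(
    replicates: int = 5,
    compartments: Sequence[str] = COMPARTMENTS,
    cd_doses: Sequence[int] = CD_DOSES,
) -> StudyDesign:
    """Fully crossed compartment x dose design with equal replication.

    The default (2 compartments x 3 doses x 5 replicates = 30 samples)
    mirrors the microcosm layout the pipeline targets.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    samples: list[str] = []
    comp: dict[str, str] = {}
    dose: dict[str, int] = {}
    for c in compartments:
        for d in cd_doses:
            for r in range(1, replicates + 1):
                sid = f"{c}_{d}mg_r{r}"
                samples.append(sid)
                comp[sid] = c
                dose[sid] = d
    return StudyDesign(tuple(samples), comp, dose)


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth enrichment planted into one pathway in one design cell.

    ``log2fc`` is a positive magnitude; ``direction`` gives its sign
    (``up`` multiplies affected-KO means by ``2**log2fc`` in the target
    cell, ``down`` by ``2**-log2fc``).
    """

    pathway: str
    direction: str
    affected_fraction: float
    log2fc: float
    target: Cell

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")
        if self.log2fc <= 0:
            raise ValueError("log2fc must be a positive magnitude; use direction for sign")

    @property
    def signed_log2fc(self) -> float:
        return self.log2fc if self.direction == "up" else -self.log2fc


@dataclass(frozen=True)
class GroundTruth:
    """Record of which KOs each planted effect actually touched."""

    effect: PlantedEffect
    affected_kos: tuple[str, ...]


@dataclass(frozen=True)
class KOCountTable:
    """Samples x KOs non-negative integer counts joined with the design."""

    counts: pd.DataFrame  # index = sample ids, columns = KO ids
    design: StudyDesign

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("sample and KO labels must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if set(self.counts.index) != set(self.design.samples):
            raise ValueError("count-table samples do not match the design")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.counts.index)

    @property
    def ko_ids(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    def nonzero_kos(self, samples: Sequence[str] | None = None) -> frozenset[str]:
        """KOs with a nonzero count in at least one of the given samples.

        This is the "collective predicted functional genome": the KO
        universe actually observed in a set of samples.
        """
        sub = self.counts if samples is None else self.counts.loc[list(samples)]
        present = sub.sum(axis=0) > 0
        return frozenset(sub.columns[present])


def generate_pathway_map(
    n_pathways: int,
    n_kos: int,
    size_range: tuple[int, int],
    overlap_prob: float,
    seed: int,
) -> PathwayMap:
    """Random KO->pathway map with controllable redundancy.

    Pathway sizes are drawn uniformly from ``size_range`` (inclusive). Each
    KO slot is filled from already-assigned KOs with probability
    ``overlap_prob`` (creating multi-pathway KOs) and from unassigned KOs
    otherwise. All ``n_kos`` KOs form the universe, so KOs left unassigned
    are pathway-free.
    """
    lo, hi = size_range
    if lo < 1:
        raise ValueError("pathway sizes must be >= 1")
    if hi < lo:
        raise ValueError("size_range upper bound below lower bound")
    if n_pathways < 1:
        raise ValueError("need at least one pathway")
    if n_kos < hi:
        raise ValueError("n_kos must be >= the maximum pathway size")
    if not 0.0 <= overlap_prob <= 1.0:
        raise ValueError("overlap_prob must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    ko_ids = [f"K{i:05d}" for i in range(n_kos)]
    sizes = rng.integers(lo, hi + 1, size=n_pathways)
    if overlap_prob == 0.0 and int(sizes.sum()) > n_kos:
        raise ValueError(
            f"{n_kos} KOs cannot host disjoint pathways totalling {int(sizes.sum())} slots"
        )

    unassigned = list(ko_ids)
    assigned: list[str] = []
    pathways: dict[str, frozenset[str]] = {}
    for p, size in enumerate(sizes):
        members: set[str] = set()
        for _ in range(int(size)):
            reuse_pool = [k for k in assigned if k not in members]
            use_reuse = bool(reuse_pool) and rng.random() < overlap_prob
            if not use_reuse and not unassigned:
                if not reuse_pool:
                    raise ValueError("ran out of KOs while building pathway map")
                use_reuse = True
            if use_reuse:
                ko = reuse_pool[int(rng.integers(len(reuse_pool)))]
            else:
                ko = unassigned.pop(int(rng.integers(len(unassigned))))
                assigned.append(ko)
            members.add(ko)
        pathways[f"path{p:04d}"] = frozenset(members)

    return PathwayMap(pathways=pathways, universe=frozenset(ko_ids))


def _library_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Log-normal library-size factors with geometric mean 1.

    When ``cv == 0`` no random draw is consumed (factors are exactly 1).
    """
    if cv < 0:
        raise ValueError("libsize_cv must be non-negative")
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return raw / np.exp(np.mean(np.log(raw)))


def generate_counts(
    pathway_map: PathwayMap,
    design: StudyDesign,
    effects: Sequence[PlantedEffect] = (),
    base_mean: float = 500.0,
    dispersion: float = 0.1,
    libsize_cv: float = 0.3,
    seed: int = 0,
) -> tuple[KOCountTable, list[GroundTruth]]:
    """NB count table over the map's universe with planted effects.

    Each count is NB with mean ``base_mean * library_factor *
    2**signed_log2fc`` (the fold-change applying only to a fixed random
    subset of the effect pathway's KOs, only in samples of the effect's
    target cell) and the given dispersion. Returns the table together with
    the exact affected-KO subsets so recovery can be checked.
    """
    if base_mean <= 0:
        raise ValueError("base_mean must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    for eff in effects:
        if eff.pathway not in pathway_map.pathways:
            raise ValueError(f"effect targets unknown pathway {eff.pathway!r}")

    rng = np.random.default_rng(seed)
    samples = list(design.samples)
    kos = sorted(pathway_map.universe)
    n_s, n_k = len(samples), len(kos)

    # Draw 1: library factors, in design sample order.
    lib = _library_factors(rng, n_s, libsize_cv)

    # Draw 2: affected subsets, in effect-list order.
    truths: list[GroundTruth] = []
    log2fc = np.zeros((n_s, n_k))
    ko_index = {k: i for i, k in enumerate(kos)}
    for eff in effects:
        members = sorted(pathway_map.pathways[eff.pathway])
        n_aff = int(round(eff.affected_fraction * len(members)))
        chosen = tuple(sorted(str(k) for k in rng.choice(members, size=n_aff, replace=False)))
        truths.append(GroundTruth(effect=eff, affected_kos=chosen))
        rows = [i for i, s in enumerate(samples) if design.cell_of(s) == eff.target]
        cols = [ko_index[k] for k in chosen]
        if rows and cols:
            log2fc[np.ix_(rows, cols)] += eff.signed_log2fc

    # Draw 3: the count matrix, row-major over (sample, KO).
    mu = base_mean * lib[:, None] * np.exp2(log2fc)
    size = 1.0 / dispersion  # NB shape: Var = mu + mu^2 / size
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p)

    table = KOCountTable(
        counts=pd.DataFrame(counts, index=pd.Index(samples, name="sample_id"),
                            columns=pd.Index(kos, name="ko_id")),
        design=design,
    )
    return table, truths


def generate_enriched_sets(
    pathway_map: PathwayMap,
    n_enriched: int,
    planted_pathway: str | None = None,
    planted_count: int = 0,
    seed: int = 0,
    comparison: "PairwiseComparison | None" = None,
) -> "EnrichedKOSets":
    """Directional enriched-KO set with a controlled pathway overlap.

    Builds an enriched set of ``n_enriched`` KOs containing exactly
    ``planted_count`` members of ``planted_pathway`` (the remainder drawn
    uniformly without replacement from the rest of the universe), so the
    bootstrap pathway stage can be exercised without running the NB test.
    """
    from camtraits.ko_enrichment import EnrichedKOSets, PairwiseComparison

    universe = sorted(pathway_map.universe)
    if n_enriched > len(universe):
        raise ValueError("n_enriched exceeds the KO universe size")
    if planted_pathway is None:
        if planted_count:
            raise ValueError("planted_count requires a planted pathway")
        members: list[str] = []
    else:
        members = sorted(pathway_map.pathways[planted_pathway])
        if planted_count > min(n_enriched, len(members)):
            raise ValueError("planted_count exceeds n_enriched or the pathway size")

    rng = np.random.default_rng(seed)
    chosen = [str(k) for k in rng.choice(members, size=planted_count, replace=False)] \
        if planted_count else []
    rest_pool = sorted(set(universe) - set(members))
    n_rest = n_enriched - planted_count
    if n_rest > len(rest_pool):
        raise ValueError("not enough KOs outside the planted pathway")
    chosen += [str(k) for k in rng.choice(rest_pool, size=n_rest, replace=False)]

    if comparison is None:
        comparison = PairwiseComparison(
            treatment_cell=("rhizosphere", 100),
            baseline_cell=("bulk", 0),
            treatment_samples=("sim_t1", "sim_t2"),
            baseline_samples=("sim_b1", "sim_b2"),
        )
    return EnrichedKOSets(
        comparison=comparison,
        enriched_in_treatment=frozenset(chosen),
        enriched_in_baseline=frozenset(),
    )
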