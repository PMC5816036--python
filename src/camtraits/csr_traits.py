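"""Grime CSR life-strategy classification and net-change scores.

Pathways called enriched or depleted by the bootstrap stage are mapped to
Competitor (C), Stress-tolerator (S) or Ruderal (R) trait classes through
a frozen, package-shipped registry of curated assignments, then summarised
per treatment as net-change scores

    delta_X = (|X traits enriched| - |X traits depleted|) / N_X * 100

where N_X is the number of registry traits in class X, so each axis is
scaled by the number of traits detected for that class and runs from -100
(every class trait depleted) to +100 (every class trait enriched). The
(delta_C, delta_S, delta_R) triple per treatment is the coordinate of that
treatment in the CSR triangle's change space.

Registry conventions
--------------------
* One trait (ABC transporters) is conditionally C or S depending on the
  nature of the enriched transporters; it is tallied under both classes
  (class counts C=9, S=6, R=9) and resolves to a single class at
  classification time via ``conditional_as`` (default ``"S"``).
* Two central-carbon pathways (Carbon metabolism, TCA cycle) share one
  trait name, so the ruderal tally is 9 traits over 10 pathway names.
* Six foraging-related pathways (chemotaxis, motility, sensing) sit
  outside the C/S/R axes entirely, as does anything not in the registry
  (reported as unclassified, never silently dropped).
* Name matching is case-insensitive and whitespace/punctuation-tolerant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from camtraits.pathway_bootstrap import CALL_ENRICHED, PathwayCall

__all__ = [
    "TraitRegistry",
    "TreatmentTraitProfile",
    "CSRScore",
    "load_trait_registry",
    "classify_calls",
    "csr_score",
    "csr_coordinates",
]

CSR_CLASSES = ("C", "S", "R")
VALID_LABELS = ("C", "S", "R", "conditional_CS", "foraging", "unclassified")

#: Expected class tallies of the packaged registry (the conditional trait
#: counts toward both C and S).
PACKAGED_TALLIES = {"C": 9, "S": 6, "R": 9, "conditional_CS": 1, "foraging": 6}


def _normalize(name: str) -> str:
    name = re.sub(r"\s+", " ", name.strip().lower())
    return name.strip(" '\"`’‘.;,")


@dataclass(frozen=True)
class RegistryEntry:
    pathway_name: str
    trait_name: str
    csr_class: str
    provenance: str


@dataclass(frozen=True)
class TraitRegistry:
    """Frozen pathway-name -> trait-class assignments."""

    entries: tuple[RegistryEntry, ...]
    _by_name: Mapping[str, RegistryEntry] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_name: dict[str, RegistryEntry] = {}
        for e in self.entries:
            if e.csr_class not in VALID_LABELS:
                raise ValueError(f"unknown class label {e.csr_class!r} for {e.pathway_name!r}")
            key = _normalize(e.pathway_name)
            if key in by_name:
                raise ValueError(f"duplicate registry pathway {e.pathway_name!r}")
            by_name[key] = e
        object.__setattr__(self, "_by_name", by_name)

    def lookup(self, pathway_name: str) -> RegistryEntry | None:
        return self._by_name.get(_normalize(pathway_name))

    def traits_in_class(self, label: str, conditional_as: str | None = None) -> frozenset[str]:
        """Distinct trait names under a class label.

        For C and S the conditional trait is included (it belongs to both
        tallies) unless ``conditional_as`` pins it to the other class.
        """
        names = {e.trait_name for e in self.entries if e.csr_class == label}
        if label in ("C", "S"):
            include = conditional_as is None or conditional_as == label
            if include:
                names |= {e.trait_name for e in self.entries
                          if e.csr_class == "conditional_CS"}
        return frozenset(names)

    def class_counts(self) -> dict[str, int]:
        """Distinct-trait tallies per label; conditional counts in C and S."""
        counts = {lbl: len({e.trait_name for e in self.entries if e.csr_class == lbl})
                  for lbl in ("conditional_CS", "foraging", "R")}
        counts["C"] = len(self.traits_in_class("C"))
        counts["S"] = len(self.traits_in_class("S"))
        return counts

    def class_size(self, label: str) -> int:
        return self.class_counts()[label]

    @property
    def total_csr_traits(self) -> int:
        """Global denominator option: summed C + S + R tallies."""
        c = self.class_counts()
        return c["C"] + c["S"] + c["R"]


def load_trait_registry(path: str | Path | None = None,
                        validate_tallies: bool | None = None) -> TraitRegistry:
    """Load the packaged registry (or a user TSV with the same columns).

    The packaged registry's class tallies are asserted at load: 9
    competitive, 6 stress-tolerant and 9 ruderal traits, one conditional
    C/S trait and six foraging pathways.
    """
    if path is None:
        source = resources.files("camtraits.data") / "trait_registry.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
        if validate_tallies is None:
            validate_tallies = True
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        validate_tallies = bool(validate_tallies)

    required = {"pathway_name", "trait_name", "csr_class", "provenance"}
    if not required <= set(df.columns):
        raise ValueError(f"registry file must have columns {sorted(required)}")
    if df[["pathway_name", "csr_class"]].isna().any().any():
        raise ValueError("registry file has missing pathway names or class labels")

    entries = tuple(
        RegistryEntry(
            pathway_name=row.pathway_name,
            trait_name=row.trait_name if isinstance(row.trait_name, str) else row.pathway_name,
            csr_class=row.csr_class,
            provenance=row.provenance if isinstance(row.provenance, str) else "",
        )
        for row in df.itertuples()
    )
    registry = TraitRegistry(entries=entries)
    if validate_tallies:
        counts = registry.class_counts()
        if counts != PACKAGED_TALLIES:
            raise ValueError(f"registry tallies {counts} != expected {PACKAGED_TALLIES}")
    return registry


@dataclass(frozen=True)
class TreatmentTraitProfile:
    """Class-wise enriched/depleted trait sets for one treatment.

    ``depleted`` holds traits whose pathways were called enriched in the
    baseline direction of the pairwise comparison (the "decreased" side).
    Pathways absent from the registry are reported under ``unclassified``.
    """

    treatment: str
    enriched: Mapping[str, frozenset[str]]  # class -> trait names
    depleted: Mapping[str, frozenset[str]]
    unclassified_enriched: frozenset[str] = frozenset()
    unclassified_depleted: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for cls in CSR_CLASSES:
            both = self.enriched.get(cls, frozenset()) & self.depleted.get(cls, frozenset())
            if both:
                raise ValueError(
                    f"traits {sorted(both)} are both enriched and depleted in class {cls}"
                )

    def swapped(self) -> "TreatmentTraitProfile":
        """Mirror profile with enriched and depleted exchanged."""
        return TreatmentTraitProfile(
            treatment=self.treatment,
            enriched=dict(self.depleted),
            depleted=dict(self.enriched),
            unclassified_enriched=self.unclassified_depleted,
            unclassified_depleted=self.unclassified_enriched,
        )


@dataclass(frozen=True)
class CSRScore:
    treatment: str
    delta_c: float
    delta_s: float
    delta_r: float

    def __post_init__(self) -> None:
        for v in (self.delta_c, self.delta_s, self.delta_r):
            if not -100.0 <= v <= 100.0:
                raise ValueError("CSR deltas must lie in [-100, 100]")


def classify_calls(
    calls: Mapping[str, Iterable[PathwayCall]],
    registry: TraitRegistry,
    treatment: str | None = None,
    conditional_as: str = "S",
) -> TreatmentTraitProfile:
    """Map one comparison's pathway calls onto CSR trait classes.

    ``calls`` is the per-direction output of the bootstrap stage:
    pathways called enriched in the ``"treatment"`` direction populate
    class-wise enriched sets, pathways called enriched in the
    ``"baseline"`` direction populate depleted sets. The conditional C/S
    trait resolves to ``conditional_as``. A trait whose pathways are
    called in both directions would be contradictory and raises.
    """
    if conditional_as not in ("C", "S"):
        raise ValueError("conditional_as must be 'C' or 'S'")

    def bucket(direction: str) -> tuple[dict[str, set[str]], set[str]]:
        by_class: dict[str, set[str]] = {cls: set() for cls in CSR_CLASSES}
        unclassified: set[str] = set()
        for call in calls.get(direction, ()):
            if call.call != CALL_ENRICHED:
                continue
            entry = registry.lookup(call.pathway)
            if entry is None:
                unclassified.add(call.pathway)
                continue
            cls = entry.csr_class
            if cls == "conditional_CS":
                cls = conditional_as
            if cls in CSR_CLASSES:
                by_class[cls].add(entry.trait_name)
            else:  # foraging / unclassified registry labels sit off-axis
                unclassified.add(call.pathway)
        return by_class, unclassified

    enr, unc_e = bucket("treatment")
    dep, unc_d = bucket("baseline")
    if treatment is None:
        treatment = "treatment"
    return TreatmentTraitProfile(
        treatment=treatment,
        enriched={c: frozenset(v) for c, v in enr.items()},
        depleted={c: frozenset(v) for c, v in dep.items()},
        unclassified_enriched=frozenset(unc_e),
        unclassified_depleted=frozenset(unc_d),
    )


def csr_score(
    profile: TreatmentTraitProfile,
    registry: TraitRegistry,
    denominator: str = "per_class",
) -> CSRScore:
    """Net-change score per CSR axis, on a -100..100 percentage scale.

    ``denominator="per_class"`` scales each axis by its own registry
    tally (C=9, S=6, R=9); ``"global"`` uses the summed CSR tally
    instead, which keeps axes comparable in absolute trait counts at the
    cost of the +/-100 range.
    """
    if denominator not in ("per_class", "global"):
        raise ValueError("denominator must be 'per_class' or 'global'")
    deltas = {}
    for cls in CSR_CLASSES:
        n_cls = registry.class_size(cls) if denominator == "per_class" \
            else registry.total_csr_traits
        if n_cls == 0:
            raise ValueError(f"registry has no traits in class {cls}")
        n_enr = len(profile.enriched.get(cls, frozenset()))
        n_dep = len(profile.depleted.get(cls, frozenset()))
        deltas[cls] = (n_enr / n_cls - n_dep / n_cls) * 100.0
    return CSRScore(treatment=profile.treatment,
                    delta_c=deltas["C"], delta_s=deltas["S"], delta_r=deltas["R"])


def csr_coordinates(scores: Iterable[CSRScore]) -> pd.DataFrame:
    """Tidy (treatment, delta_C, delta_S, delta_R) table, sorted by label."""
    scores = list(scores)
    labels = [s.treatment for s in scores]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate treatment labels in CSR scores")
    df = pd.DataFrame(
        {
            "treatment": labels,
            "delta_C": [s.delta_c for s in scores],
            "delta_S": [s.delta_s for s in scores],
            "delta_R": [s.delta_r for s in scores],
        }
    )
    return df.sort_values("treatment", kind="stable").reset_index(drop=True)


def plot_csr_coordinates(coords: pd.DataFrame, path: str | Path) -> None:
    """Static 3-D scatter of treatment coordinates in CSR change space."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    ax.scatter(coords["delta_C"], coords["delta_S"], coords["delta_R"], s=40)
    for _, row in coords.iterrows():
        ax.text(row["delta_C"], row["delta_S"], row["delta_R"],
                row["treatment"], fontsize=7)
    ax.set_xlabel("delta C (%)")
    ax.set_ylabel("delta S (%)")
    ax.set_zlabel("delta R (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
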