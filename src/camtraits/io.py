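"""Readers, writers, configuration and the end-to-end pipeline.

Canonical interchange is plain TSV (tab-separated, header row, UTF-8, no
quoting): a KO count table laid out observations x samples (rows = KO ids,
columns = sample ids; the BIOM-style dense layout) or the transpose, a
sample-metadata table, a two-column pathway map, and the stage outputs.
The full pipeline is a pure function of (input files, config, seed):
repeated runs produce byte-identical artifacts, recorded in a manifest
with input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from camtraits.csr_traits import (
    CSRScore,
    classify_calls,
    csr_coordinates,
    csr_score,
    load_trait_registry,
)
from camtraits.ko_enrichment import (
    EnrichedKOSets,
    PairwiseComparison,
    estimate_size_factors,
    extract_enriched_sets,
    nb_wald_test,
)
from camtraits.pathway_bootstrap import (
    BootstrapConfig,
    PathwayCall,
    call_pathways,
    underrepresentation_screen,
)
from camtraits.synthetic_data import Cell, KOCountTable, PathwayMap, StudyDesign

__all__ = [
    "PipelineConfig",
    "PipelineValidationError",
    "read_ko_table",
    "write_ko_table",
    "read_metadata",
    "write_metadata",
    "read_pathway_map",
    "write_pathway_map",
    "write_pathway_calls",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class PipelineValidationError(ValueError):
    """Invalid inputs or configuration, detected before any computation."""


# ---------------------------------------------------------------------------
# readers / writers


def read_metadata(path: str | Path) -> StudyDesign:
    """Sample metadata TSV: sample_id, compartment, cd_dose."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "compartment": str})
    required = {"sample_id", "compartment", "cd_dose"}
    if not required <= set(df.columns):
        raise PipelineValidationError(
            f"metadata {path} must have columns {sorted(required)}"
        )
    if df["sample_id"].duplicated().any():
        raise PipelineValidationError(f"duplicate sample ids in {path}")
    return StudyDesign(
        samples=tuple(df["sample_id"]),
        compartment=dict(zip(df["sample_id"], df["compartment"])),
        cd_dose=dict(zip(df["sample_id"], df["cd_dose"].astype(int))),
    )


def write_metadata(design: StudyDesign, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": design.samples,
            "compartment": [design.compartment[s] for s in design.samples],
            "cd_dose": [design.cd_dose[s] for s in design.samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_ko_table(
    counts_path: str | Path,
    metadata_path: str | Path,
    orientation: str = "ko_by_sample",
) -> KOCountTable:
    """KO count TSV joined with sample metadata.

    ``orientation="ko_by_sample"`` (default, the BIOM-style layout this
    package writes) expects rows = KO ids and columns = sample ids;
    ``"sample_by_ko"`` the transpose. Cells must be non-negative integers
    and every sample must have metadata.
    """
    if orientation not in ("ko_by_sample", "sample_by_ko"):
        raise PipelineValidationError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if orientation == "ko_by_sample":
        df = df.T  # -> samples x KOs
    df.index = df.index.astype(str).rename("sample_id")
    df.columns = df.columns.astype(str).rename("ko_id")
    if df.index.has_duplicates:
        raise PipelineValidationError(f"duplicate sample ids in {counts_path}")
    if df.columns.has_duplicates:
        raise PipelineValidationError(f"duplicate KO ids in {counts_path}")

    values = df.to_numpy()
    if not pd.api.types.is_integer_dtype(df.to_numpy().dtype):
        rounded = values.round()
        if (abs(values - rounded) > 0).any():
            bad = [(df.index[i], df.columns[j])
                   for i, j in zip(*((abs(values - rounded) > 0).nonzero()))][:3]
            raise PipelineValidationError(
                f"non-integer counts in {counts_path}, e.g. at {bad}"
            )
        df = df.astype(int)
    neg = df.lt(0)
    if neg.any().any():
        i, j = next(zip(*neg.to_numpy().nonzero()))
        raise PipelineValidationError(
            f"negative count in {counts_path} at sample {df.index[i]!r}, "
            f"KO {df.columns[j]!r}"
        )

    design = read_metadata(metadata_path)
    missing = set(df.index) - set(design.samples)
    if missing:
        raise PipelineValidationError(
            f"samples without metadata: {sorted(missing)[:5]}"
        )
    design = StudyDesign(
        samples=tuple(s for s in design.samples if s in set(df.index)),
        compartment=design.compartment,
        cd_dose=design.cd_dose,
    )
    return KOCountTable(counts=df.loc[list(design.samples)], design=design)


def write_ko_table(table: KOCountTable, counts_path: str | Path,
                   metadata_path: str | Path | None = None) -> None:
    """Write counts as rows = KO ids, columns = sample ids."""
    table.counts.T.to_csv(counts_path, sep="\t")
    if metadata_path is not None:
        write_metadata(table.design, metadata_path)


def read_pathway_map(path: str | Path) -> PathwayMap:
    """Two-column TSV (pathway_id, ko_id); duplicate rows collapse."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise PipelineValidationError(f"pathway map {path} is empty")
    required = {"pathway_id", "ko_id"}
    if not required <= set(df.columns):
        raise PipelineValidationError(
            f"pathway map {path} must have columns {sorted(required)}"
        )
    if df[["pathway_id", "ko_id"]].isna().any().any():
        raise PipelineValidationError(f"pathway map {path} has missing fields")
    pathways = {
        pid: frozenset(group["ko_id"])
        for pid, group in df.groupby("pathway_id", sort=True)
    }
    return PathwayMap(pathways=pathways,
                      universe=frozenset(df["ko_id"]))


def write_pathway_map(pathway_map: PathwayMap, path: str | Path) -> None:
    rows = [(pid, ko) for pid in sorted(pathway_map.pathways)
            for ko in sorted(pathway_map.pathways[pid])]
    pd.DataFrame(rows, columns=["pathway_id", "ko_id"]).to_csv(
        path, sep="\t", index=False
    )


def _calls_frame(calls: Sequence[PathwayCall], excluded: frozenset[str],
                 directions: Sequence[str]) -> pd.DataFrame:
    rows = [
        {
            "pathway_id": c.pathway,
            "direction": c.direction,
            "n": c.n,
            "observed_hits": c.observed_hits,
            "median_difference": c.median_difference,
            "lower_limit": c.lower_limit,
            "upper_limit": c.upper_limit,
            "call": c.call,
            "pathway_size": c.pathway_size,
            "size_one_flag": c.size_one,
            "excluded_by_screen": False,
        }
        for c in calls
    ]
    for pid in sorted(excluded):
        for direction in directions:
            rows.append(
                {
                    "pathway_id": pid,
                    "direction": direction,
                    "n": "",
                    "observed_hits": "",
                    "median_difference": "",
                    "lower_limit": "",
                    "upper_limit": "",
                    "call": "screen_excluded",
                    "pathway_size": "",
                    "size_one_flag": "",
                    "excluded_by_screen": True,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["direction", "pathway_id"], kind="stable").reset_index(drop=True)


def write_pathway_calls(calls: dict[str, list[PathwayCall]],
                        excluded: frozenset[str], path: str | Path) -> None:
    flat = [c for direction in sorted(calls) for c in calls[direction]]
    _calls_frame(flat, excluded, sorted(calls)).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def _write_ko_results(results, dropped, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "ko_id": [r.ko for r in results],
            "log2fc": [r.log2fc for r in results],
            "se": [r.se for r in results],
            "pvalue": [r.pvalue for r in results],
            "padj": [r.padj for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if dropped:
        Path(str(path) + ".dropped").write_text("\n".join(dropped) + "\n")


def _write_enriched_sets(sets: EnrichedKOSets, path: str | Path) -> None:
    rows = [("treatment", ko) for ko in sorted(sets.enriched_in_treatment)]
    rows += [("baseline", ko) for ko in sorted(sets.enriched_in_baseline)]
    pd.DataFrame(rows, columns=["direction", "ko_id"]).to_csv(path, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; loadable from a YAML file."""

    counts: Path
    metadata: Path
    pathway_map: Path
    output_dir: Path
    registry: Path | None = None  # None -> packaged registry
    alpha: float = 0.05
    n_reps: int = 1000
    lower_index: int | None = None  # None -> default ranks for n_reps
    upper_index: int | None = None
    seed: int = 0
    comparisons: list[tuple[Cell, Cell]] = field(default_factory=list)
    conditional_as: str = "S"
    denominator: str = "per_class"
    pseudocount_fallback: bool = False
    orientation: str = "ko_by_sample"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        comparisons = [
            ((c["treatment"][0], int(c["treatment"][1])),
             (c["baseline"][0], int(c["baseline"][1])))
            for c in raw.pop("comparisons", [])
        ]
        for key in ("counts", "metadata", "pathway_map", "output_dir", "registry"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(comparisons=comparisons, **raw)

    def bootstrap_config(self) -> BootstrapConfig:
        if self.lower_index is None or self.upper_index is None:
            cfg = BootstrapConfig.with_default_ranks(self.n_reps, seed=self.seed)
            lower = self.lower_index if self.lower_index is not None else cfg.lower_index
            upper = self.upper_index if self.upper_index is not None else cfg.upper_index
            return BootstrapConfig(self.n_reps, lower, upper, self.seed)
        return BootstrapConfig(self.n_reps, self.lower_index, self.upper_index, self.seed)

    def validate(self) -> None:
        for key in ("counts", "metadata", "pathway_map"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise PipelineValidationError(f"{key} file not found: {p}")
        if self.registry is not None and not Path(self.registry).exists():
            raise PipelineValidationError(f"registry file not found: {self.registry}")
        if not 0.0 < self.alpha < 1.0:
            raise PipelineValidationError("alpha must lie in (0, 1)")
        if self.n_reps < 100:
            raise PipelineValidationError("n_reps must be >= 100")
        self.bootstrap_config()  # rank sanity


# ---------------------------------------------------------------------------
# the pipeline


def _default_comparisons(design: StudyDesign,
                         baseline: Cell = ("bulk", 0)) -> list[tuple[Cell, Cell]]:
    return [(cell, baseline) for cell in design.cells() if cell != baseline]


def run_pipeline(config: PipelineConfig) -> dict:
    """KO tests -> screen -> bootstrap pathway calls -> CSR scores.

    Executes every configured pairwise comparison against its baseline
    cell, writes all stage TSVs plus a manifest (input checksums, seed,
    version, output list) into the output directory, and returns the
    manifest. Deterministic: identical inputs + config + seed give
    byte-identical outputs.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = read_ko_table(config.counts, config.metadata, config.orientation)
    pmap = read_pathway_map(config.pathway_map)
    registry = load_trait_registry(config.registry)
    bconfig = config.bootstrap_config()

    comparisons = config.comparisons or _default_comparisons(table.design)
    for t_cell, b_cell in comparisons:
        if not table.design.samples_in(t_cell):
            raise PipelineValidationError(f"treatment cell {t_cell} has no samples")
        if not table.design.samples_in(b_cell):
            raise PipelineValidationError(f"baseline cell {b_cell} has no samples")

    # Under-representation screen on the whole study's predicted metagenome,
    # against the full reference map universe.
    metagenome = table.nonzero_kos() & pmap.universe
    screen = underrepresentation_screen(metagenome, pmap, bconfig)
    screen_df = _calls_frame(list(screen.details), frozenset(), ["screen"])
    screen_df["excluded_by_screen"] = screen_df["pathway_id"].isin(screen.excluded)
    screen_df.to_csv(out / "screen.tsv", sep="\t", index=False, float_format="%.6g")

    scores: list[CSRScore] = []
    artifacts: list[Path] = [out / "screen.tsv"]
    baseline_labels: set[str] = set()
    for t_cell, b_cell in comparisons:
        comparison = PairwiseComparison.from_design(table.design, t_cell, b_cell)
        label = comparison.label
        logger.info("running comparison %s", label)

        sub_samples = list(comparison.treatment_samples + comparison.baseline_samples)
        # Size factors come from the full table so all comparisons share scale.
        size_factors = estimate_size_factors(table, pseudocount=config.pseudocount_fallback)

        results, dropped = nb_wald_test(table, comparison, size_factors)
        _write_ko_results(results, dropped, out / f"ko_results_{label}.tsv")
        sets = extract_enriched_sets(results, comparison, config.alpha)
        _write_enriched_sets(sets, out / f"enriched_kos_{label}.tsv")
        logger.info("comparison %s: n_treatment=%d n_baseline=%d (dropped %d all-zero KOs)",
                    label, sets.n_treatment, sets.n_baseline, len(dropped))

        universe = table.nonzero_kos(sub_samples)
        calls = call_pathways(sets, pmap, universe, bconfig, retained=screen.retained)
        write_pathway_calls(calls, screen.excluded, out / f"pathway_calls_{label}.tsv")

        treatment_label = f"{t_cell[0]}_{t_cell[1]}mg"
        profile = classify_calls(calls, registry, treatment=treatment_label,
                                 conditional_as=config.conditional_as)
        if profile.unclassified_enriched or profile.unclassified_depleted:
            logger.info(
                "comparison %s: unclassified pathways enriched=%s depleted=%s",
                label, sorted(profile.unclassified_enriched),
                sorted(profile.unclassified_depleted),
            )
        scores.append(csr_score(profile, registry, config.denominator))
        baseline_labels.add(f"{b_cell[0]}_{b_cell[1]}mg")
        artifacts += [out / f"ko_results_{label}.tsv",
                      out / f"enriched_kos_{label}.tsv",
                      out / f"pathway_calls_{label}.tsv"]

    # The baseline scored against itself sits at the origin of CSR space.
    for b in sorted(baseline_labels):
        if b not in {s.treatment for s in scores}:
            scores.append(CSRScore(treatment=b, delta_c=0.0, delta_s=0.0, delta_r=0.0))

    coords = csr_coordinates(scores)
    coords.to_csv(out / "csr_scores.tsv", sep="\t", index=False, float_format="%.6g")
    artifacts.append(out / "csr_scores.tsv")

    from camtraits import __version__

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "n_reps": bconfig.n_reps,
        "limit_ranks": [bconfig.lower_index, bconfig.upper_index],
        "conditional_as": config.conditional_as,
        "denominator": config.denominator,
        "inputs": {
            name: _sha256(Path(getattr(config, name)))
            for name in ("counts", "metadata", "pathway_map")
        },
        "comparisons": [f"{t[0]}_{t[1]}mg_vs_{b[0]}_{b[1]}mg" for t, b in comparisons],
        "screen_excluded": sorted(screen.excluded),
        "outputs": sorted(str(p.relative_to(out)) for p in artifacts),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
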