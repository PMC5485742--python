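"""Candidate transcriptional-regulator family selection and pipeline driver.

A family is a *candidate regulator family* when (1) more than half of its
members are predicted nuclear, (2) the mean disorder ratio of its members
exceeds the TF-derived cutoff (0.341 for Arabidopsis), and (3) at least one
member autoactivates transcription in yeast.  Only families of unknown
molecular function (every member annotated at most to the MF root term
GO:0003674) with at least ``min_family_size`` members enter the filter; a
``singleton_mode`` admits 1-2-member families under the same rules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd
import yaml

from trscout.features import (
    ARABIDOPSIS_DISORDER_CUTOFF,
    FamilyFeatureSummary,
    summarize_families,
)
from trscout.io import GO_MF_ROOT, AnnotationSet, ProteinRecord
from trscout.mcl import FamilySet, MclParams, mcl_cluster

logger = logging.getLogger(__name__)

VENN_REGIONS = ("100", "010", "001", "110", "101", "011", "111", "000")


@dataclass
class PipelineConfig:
    """All thresholds and switches of the prediction pipeline."""

    min_family_size: int = 3
    nuclear_fraction_gt: float = 0.5
    disorder_mean_gt: float = ARABIDOPSIS_DISORDER_CUTOFF
    require_autoactivator: bool = True
    unknown_root_term: str = GO_MF_ROOT
    evalue_cutoff: float = 1e-5
    inflation: float = 4.0
    singleton_mode: bool = False

    def __post_init__(self) -> None:
        if self.min_family_size < 1:
            raise ValueError("min_family_size must be >= 1")
        if not 0 <= self.nuclear_fraction_gt <= 1:
            raise ValueError("nuclear_fraction_gt must be in [0, 1]")
        if not 0 <= self.disorder_mean_gt <= 1:
            raise ValueError("disorder_mean_gt must be in [0, 1]")

    @property
    def effective_min_size(self) -> int:
        return 1 if self.singleton_mode else self.min_family_size

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)


def select_unknown_families(
    families: Mapping[str, set[str]],
    annotations: AnnotationSet,
    config: PipelineConfig | None = None,
) -> tuple[set[str], set[str]]:
    """Return (unknown family ids, unknown ids surviving the size filter).

    A family is of unknown molecular function iff *every* member is unknown
    (no MF annotation, or annotated only to the root term).
    """
    config = config or PipelineConfig()
    unknown = {
        fam
        for fam, members in families.items()
        if all(annotations.is_unknown(pid, config.unknown_root_term) for pid in members)
    }
    size_filtered = {
        fam for fam in unknown if len(families[fam]) >= config.effective_min_size
    }
    return unknown, size_filtered


def apply_feature_filters(
    family_ids: set[str],
    summaries: Mapping[str, FamilyFeatureSummary],
    config: PipelineConfig | None = None,
) -> tuple[set[str], dict[str, set[str]]]:
    """Apply the three feature filters; return candidates and per-filter pass sets.

    All three thresholds are strict inequalities.  Families without any
    member disorder prediction fail the disorder filter (logged); families
    with no tested member fail the autoactivation filter but stay in the
    universe (the tested/untested distinction matters only for enrichment
    denominators downstream).
    """
    config = config or PipelineConfig()
    missing = family_ids - set(summaries)
    if missing:
        raise ValueError(f"no feature summary for families: {sorted(missing)}")
    pass_nuclear, pass_disorder, pass_autoact = set(), set(), set()
    for fam in family_ids:
        s = summaries[fam]
        if s.nuclear_fraction > config.nuclear_fraction_gt:
            pass_nuclear.add(fam)
        if s.mean_disorder is None:
            logger.info("family %s has no member disorder prediction; fails filter", fam)
        elif s.mean_disorder > config.disorder_mean_gt:
            pass_disorder.add(fam)
        if s.has_autoactivator:
            pass_autoact.add(fam)
    candidates = pass_nuclear & pass_disorder
    if config.require_autoactivator:
        candidates &= pass_autoact
    pass_sets = {
        "nuclear": pass_nuclear,
        "disorder": pass_disorder,
        "autoactivation": pass_autoact,
    }
    return candidates, pass_sets


def venn_region_counts(
    universe: set[str], pass_sets: Mapping[str, set[str]]
) -> dict[str, int]:
    """Counts of the 8 regions of the three-filter Venn diagram.

    Region keys are bit strings over (nuclear, disorder, autoactivation);
    "000" is the outside-all-circles region, so the counts sum to the
    universe size.
    """
    counts = dict.fromkeys(VENN_REGIONS, 0)
    for fam in universe:
        key = "".join(
            "1" if fam in pass_sets[name] else "0"
            for name in ("nuclear", "disorder", "autoactivation")
        )
        counts[key] += 1
    return counts


@dataclass
class PredictionResult:
    """Candidate families plus the bookkeeping of every filter stage."""

    candidates: list[str]
    summaries: dict[str, FamilyFeatureSummary]
    families: FamilySet
    stage_counts: dict[str, int]
    venn_counts: dict[str, int]
    config: PipelineConfig
    warnings: list[str] = field(default_factory=list)

    @property
    def candidate_proteins(self) -> set[str]:
        return {pid for fam in self.candidates for pid in self.families[fam]}

    def to_dict(self) -> dict:
        return {
            "candidates": sorted(self.candidates),
            "summaries": {
                fam: asdict(s) for fam, s in sorted(self.summaries.items())
            },
            "families": {fam: sorted(m) for fam, m in sorted(self.families.items())},
            "stage_counts": self.stage_counts,
            "venn_counts": self.venn_counts,
            "config": asdict(self.config),
            "warnings": self.warnings,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictionResult":
        with open(path) as handle:
            data = json.load(handle)
        return cls(
            candidates=list(data["candidates"]),
            summaries={
                fam: FamilyFeatureSummary(**s) for fam, s in data["summaries"].items()
            },
            families={fam: set(m) for fam, m in data["families"].items()},
            stage_counts=data["stage_counts"],
            venn_counts=data["venn_counts"],
            config=PipelineConfig(**data["config"]),
            warnings=list(data.get("warnings", [])),
        )


def run_pipeline(
    proteome: Mapping[str, ProteinRecord],
    similarity: nx.Graph,
    annotations: AnnotationSet,
    features: pd.DataFrame,
    config: PipelineConfig | None = None,
    families: FamilySet | None = None,
) -> PredictionResult:
    """Run the full screen: cluster, select unknown families, filter.

    ``families`` may supply a precomputed partition (e.g. OrthoMCL output);
    otherwise MCL is run at ``config.inflation``.  Proteome proteins absent
    from the similarity graph become singleton families; feature-table ids
    absent from the proteome only raise a warning.  The result is fully
    deterministic given inputs and config.
    """
    config = config or PipelineConfig()
    warnings_log: list[str] = []

    orphan_features = set(features.index) - set(proteome)
    if orphan_features:
        msg = f"{len(orphan_features)} feature rows lack a proteome entry"
        logger.warning(msg)
        warnings_log.append(msg)

    if families is None:
        graph = similarity.copy()
        graph.add_nodes_from(proteome.keys())  # singletons for unmatched proteins
        families = mcl_cluster(graph, MclParams(inflation=config.inflation))
    else:
        families = {fam: set(members) for fam, members in families.items()}
        clustered = {pid for members in families.values() for pid in members}
        loose = sorted(set(proteome) - clustered)
        width = max(4, len(str(len(families) + len(loose))))
        for i, pid in enumerate(loose):
            families[f"S{i + 1:0{width}d}"] = {pid}

    unknown, size_filtered = select_unknown_families(families, annotations, config)
    summaries = summarize_families(
        {fam: families[fam] for fam in size_filtered}, features
    )
    candidates, pass_sets = apply_feature_filters(size_filtered, summaries, config)

    stage_counts = {
        "families_total": len(families),
        "unknown": len(unknown),
        "unknown_size_filtered": len(size_filtered),
        "pass_nuclear": len(pass_sets["nuclear"]),
        "pass_disorder": len(pass_sets["disorder"]),
        "pass_autoactivation": len(pass_sets["autoactivation"]),
        "candidates": len(candidates),
    }
    return PredictionResult(
        candidates=sorted(candidates),
        summaries=summaries,
        families=families,
        stage_counts=stage_counts,
        venn_counts=venn_region_counts(size_filtered, pass_sets),
        config=config,
        warnings=warnings_log,
    )
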