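"""Taxon specificity of candidate regulator families.

Two complementary summaries: (1) for meta-genome clusterings, how many
distinct species each family draws members from (categories 1, 2, 3, 4+);
(2) from a precomputed ortholog-presence table, the deepest taxonomic scope
at which each family is conserved (e.g. green algae > early land plants >
flowering plants for a plant candidate set), with aggregate percentages per
scope.  Ortholog presence is an input table — this module only aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

SPECIES_CATEGORIES = ("1", "2", "3", "4+")

#: Scope assigned to families without an ortholog at any supplied rank.
OWN_SPECIES_SCOPE = "own_species_only"


@dataclass(frozen=True)
class SpeciesDistribution:
    """Species-count category tallies for all families and for candidates."""

    counts_all: dict[str, int]
    percentages_all: dict[str, float]
    counts_candidates: dict[str, int]
    percentages_candidates: dict[str, float]


def _tally(species_counts: Sequence[int]) -> tuple[dict[str, int], dict[str, float]]:
    counts = dict.fromkeys(SPECIES_CATEGORIES, 0)
    for n in species_counts:
        counts["4+" if n >= 4 else str(n)] += 1
    total = sum(counts.values())
    percentages = {
        cat: (100.0 * n / total if total else 0.0) for cat, n in counts.items()
    }
    return counts, percentages


def species_count_distribution(
    families: Mapping[str, set[str]],
    species_of: Mapping[str, str],
    candidate_ids: set[str],
) -> SpeciesDistribution:
    """Distribution of per-family distinct-species counts.

    Every member must carry a species tag in ``species_of`` (hard error
    otherwise).  Percentages are computed separately over all families and
    over the candidate subset.
    """
    per_family: dict[str, int] = {}
    for fam, members in families.items():
        species = set()
        for pid in members:
            if pid not in species_of or not species_of[pid]:
                raise ValueError(f"protein {pid!r} in family {fam!r} lacks a species tag")
            species.add(species_of[pid])
        per_family[fam] = len(species)
    unknown_candidates = candidate_ids - set(families)
    if unknown_candidates:
        raise ValueError(f"candidate ids not in family set: {sorted(unknown_candidates)}")
    counts_all, pct_all = _tally(list(per_family.values()))
    counts_cand, pct_cand = _tally([per_family[f] for f in candidate_ids])
    return SpeciesDistribution(counts_all, pct_all, counts_cand, pct_cand)


@dataclass(frozen=True)
class TaxonSummary:
    """Per-family conservation scope and aggregate percentages.

    ``rank_order`` lists ranks from deepest (most inclusive) to shallowest;
    each family's scope is the deepest rank with an ortholog, or
    ``own_species_only`` when none.  ``percentage_of`` sums scope
    percentages over a group of ranks (e.g. the whole plant kingdom).
    """

    rank_order: tuple[str, ...]
    scopes: dict[str, str]
    counts: dict[str, int]
    percentages: dict[str, float]
    n_families: int

    def percentage_of(self, ranks: Sequence[str]) -> float:
        return sum(self.percentages.get(r, 0.0) for r in ranks)

    def consistency_check(self, tol: float = 0.01) -> None:
        """Scope percentages must sum to 100 and sub-scopes to their total."""
        total = sum(self.percentages.values())
        if abs(total - 100.0) > tol:
            raise AssertionError(f"scope percentages sum to {total}, not 100")
        in_ranks = self.percentage_of(self.rank_order)
        enclosing = 100.0 - self.percentages.get(OWN_SPECIES_SCOPE, 0.0)
        if abs(in_ranks - enclosing) > tol:
            raise AssertionError(
                f"sub-scope percentages sum to {in_ranks}, enclosing total {enclosing}"
            )


def taxon_conservation_summary(
    presence: Mapping[str, Mapping[str, bool]],
    rank_order: Sequence[str],
) -> TaxonSummary:
    """Assign each family its deepest conserved rank and aggregate percentages.

    ``presence`` maps family id -> {rank: has_ortholog}; ``rank_order`` lists
    the ranks from deepest/most inclusive to shallowest and must cover every
    rank used.  Families without any presence fall into ``own_species_only``.
    """
    rank_order = tuple(rank_order)
    if len(set(rank_order)) != len(rank_order) or not rank_order:
        raise ValueError("rank_order must be a non-empty list of distinct ranks")
    scopes: dict[str, str] = {}
    for fam, flags in presence.items():
        stray = set(flags) - set(rank_order)
        if stray:
            raise ValueError(f"family {fam!r} has ranks outside rank_order: {sorted(stray)}")
        scope = OWN_SPECIES_SCOPE
        for rank in rank_order:
            if flags.get(rank, False):
                scope = rank
                break
        scopes[fam] = scope
    counts = dict.fromkeys(rank_order + (OWN_SPECIES_SCOPE,), 0)
    for scope in scopes.values():
        counts[scope] += 1
    n = len(scopes)
    percentages = {s: (100.0 * c / n if n else 0.0) for s, c in counts.items()}
    summary = TaxonSummary(rank_order, scopes, counts, percentages, n)
    summary.consistency_check()
    return summary
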