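"""Statistics used to validate the regulator-prediction pipeline.

Protein-level precision/recall against an annotated TF/TR gold standard,
hypergeometric fold-enrichment of each filter criterion (with the special
autoactivation-tested denominator), the Yates-corrected chi-square for 2x2
proportion comparisons, Welch t-tests with Bonferroni adjustment, and the
protein-protein-interaction analysis asking whether candidates interact with
TFs/TRs more often than the background proteome (Fisher exact test).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import special, stats as sps


def precision_recall(
    predicted_proteins: set[str],
    gold: set[str],
    universe: set[str] | None = None,
) -> tuple[float, float]:
    """Protein-level precision and recall of a prediction against a gold set.

    Prediction happens at the family level but is scored at the protein level
    (every member of a predicted family counts as predicted), the more
    conservative choice.  ``universe`` restricts the gold set to eligible
    proteins (those in families of at least the minimum size); recall is
    ``|predicted ∩ gold| / |gold ∩ universe|``.  Undefined values (empty
    prediction or empty eligible gold set) are returned as NaN.
    """
    eligible_gold = gold if universe is None else gold & universe
    if universe is not None and not predicted_proteins <= universe:
        raise ValueError("predicted proteins must lie within the universe")
    hits = len(predicted_proteins & eligible_gold)
    if predicted_proteins:
        precision = hits / len(predicted_proteins)
    else:
        warnings.warn("empty prediction: precision undefined", UserWarning, stacklevel=2)
        precision = math.nan
    if eligible_gold:
        recall = hits / len(eligible_gold)
    else:
        warnings.warn("empty eligible gold set: recall undefined", UserWarning, stacklevel=2)
        recall = math.nan
    return precision, recall


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric fold-enrichment of one filter criterion.

    k candidate families meet the criterion, out of n criterion families;
    K candidate families exist in the denominator universe of size N.
    ``fold = (k/n) / (K/N)``; ``p`` is the upper-tail hypergeometric
    probability P[X >= k].
    """

    k: int
    n: int
    K: int
    N: int
    fold: float
    p: float


def fold_enrichment(
    criterion_families: set[str],
    candidate_families: set[str],
    universe_families: set[str],
    tested_families: set[str] | None = None,
    restrict_to_tested: bool = False,
) -> EnrichmentResult:
    """Fold enrichment of candidates within a criterion-passing family set.

    For the autoactivation criterion and the final candidate set, only
    families with at least one autoactivation-tested member belong in the
    denominator: pass ``tested_families`` and set ``restrict_to_tested``.
    """
    universe = set(universe_families)
    criterion = set(criterion_families)
    if restrict_to_tested:
        if tested_families is None:
            raise ValueError("restrict_to_tested requires tested_families")
        universe &= tested_families
        criterion &= tested_families
    if not criterion <= universe:
        raise ValueError("criterion families must lie within the universe")
    candidates = set(candidate_families) & universe
    N, K, n = len(universe), len(candidates), len(criterion)
    k = len(criterion & candidates)
    if n == 0 or K == 0:
        warnings.warn(
            "fold enrichment undefined (empty criterion or candidate set)",
            UserWarning,
            stacklevel=2,
        )
        return EnrichmentResult(k, n, K, N, math.nan, math.nan)
    fold = (k / n) / (K / N)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(k, n, K, N, fold, p)


def yates_chi_square(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-corrected chi-square statistic and p-value for a 2x2 table.

    statistic = N * (max(0, |ad - bc| - N/2))^2 / ((a+b)(c+d)(a+c)(b+d)),
    with the continuity correction clamped at zero; p from chi-square with
    one degree of freedom.  Any zero margin leaves the statistic undefined
    (NaN, with a warning).
    """
    for value in (a, b, c, d):
        if value < 0 or value != int(value):
            raise ValueError("table entries must be non-negative integers")
    n = a + b + c + d
    if n < 1:
        raise ValueError("table total must be >= 1")
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        warnings.warn("zero margin: chi-square undefined", UserWarning, stacklevel=2)
        return math.nan, math.nan
    statistic = n * max(0.0, abs(a * d - b * c) - n / 2) ** 2 / margins
    return statistic, float(special.chdtrc(1, statistic))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value by the point-mass rule.

    Sums the hypergeometric probability of every table with the observed
    margins whose probability does not exceed the observed table's (with the
    customary 1 + 1e-7 relative slack for floating-point ties) — the common
    two-sided convention.  Evaluates the whole margin support in one
    vectorized pass, so it stays fast inside exhaustive sweeps.
    """
    for value in (a, b, c, d):
        if value < 0 or value != int(value):
            raise ValueError("table entries must be non-negative integers")
    N = a + b + c + d
    if N < 1:
        raise ValueError("table total must be >= 1")
    row, col = a + b, a + c
    support = np.arange(max(0, row + col - N), min(row, col) + 1)
    pmf = sps.hypergeom.pmf(support, N, col, row)
    p_obs = pmf[np.searchsorted(support, a)]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def welch_t_test(
    x: Sequence[float],
    y: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided t-test; Welch (Satterthwaite df) by default.

    Degenerate input with zero variance in both samples and equal means is
    reported as (0, 1) rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        return 0.0, 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        result = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(result.statistic), float(result.pvalue)


def bonferroni(p_values: Iterable[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: ``min(1, m * p)`` per value (m defaults to count)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return [min(1.0, m * p) for p in p_values]


@dataclass(frozen=True)
class TfInteractionResult:
    """Comparison of TF/TR-interaction rates: candidates vs background.

    ``rate_all`` is the fraction of all proteins with interaction data that
    interact with at least one annotated TF/TR; ``rate_candidates`` is the
    same fraction over candidate proteins; ``fold = rate_candidates /
    rate_all``; ``fisher_p`` is the two-sided Fisher exact p-value on the
    candidate-vs-rest x interacts-vs-not table (a, b, c, d).
    """

    rate_all: float
    rate_candidates: float
    fold: float
    fisher_p: float
    n_with_data: int
    n_candidates_with_data: int
    table: tuple[int, int, int, int]


def tf_interaction_enrichment(
    ppi_edges: Iterable[tuple[str, str]],
    tf_tr_set: set[str],
    candidate_set: set[str],
) -> TfInteractionResult:
    """Do candidate proteins interact with TFs/TRs more than the proteome?

    The universe is every protein with at least one interaction.  A protein
    "interacts with a TF/TR" when at least one of its partners is in
    ``tf_tr_set``.  The background rate includes the candidates, matching
    the proteome-wide denominator convention; the Fisher table contrasts
    candidates with the rest.
    """
    neighbors: dict[str, set[str]] = {}
    for u, v in ppi_edges:
        if u == v:
            continue
        neighbors.setdefault(u, set()).add(v)
        neighbors.setdefault(v, set()).add(u)
    with_data = set(neighbors)
    if not with_data:
        raise ValueError("no interaction edges supplied")
    interacts_tf = {p for p, partners in neighbors.items() if partners & tf_tr_set}
    candidates = candidate_set & with_data
    if not candidates:
        warnings.warn(
            "no candidate protein has interaction data", UserWarning, stacklevel=2
        )
    rate_all = len(interacts_tf) / len(with_data)
    rate_candidates = (
        len(candidates & interacts_tf) / len(candidates) if candidates else math.nan
    )
    fold = rate_candidates / rate_all if rate_all > 0 and candidates else math.nan
    a = len(candidates & interacts_tf)
    b = len(candidates) - a
    c = len(interacts_tf) - a
    d = len(with_data) - len(candidates) - c
    fisher_p = fisher_exact_two_sided(a, b, c, d)
    return TfInteractionResult(
        rate_all=rate_all,
        rate_candidates=rate_candidates,
        fold=fold,
        fisher_p=fisher_p,
        n_with_data=len(with_data),
        n_candidates_with_data=len(candidates),
        table=(a, b, c, d),
    )
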