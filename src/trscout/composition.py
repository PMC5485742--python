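"""Sliding-window amino-acid composition statistics.

Transcriptional activation domains are enriched in particular residues
(acidic D/E, and N, Q, S, P).  For each protein we record, per residue set,
the maximum count observed in 20-residue sliding windows (overlap 19, i.e.
step 1); group means of these per-protein maxima are then compared between
candidate regulators, TFs, and the proteome background with Welch t-tests
under Bonferroni correction over the seven residue sets tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from trscout.stats import bonferroni, welch_t_test

#: The seven residue sets tested: six single residues plus acidic (D+E).
RESIDUE_SETS: dict[str, frozenset[str]] = {
    "D": frozenset("D"),
    "E": frozenset("E"),
    "N": frozenset("N"),
    "Q": frozenset("Q"),
    "S": frozenset("S"),
    "P": frozenset("P"),
    "DE": frozenset("DE"),
}


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry; step = window - overlap."""

    window: int = 20
    overlap: int = 19

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.window:
            raise ValueError("need 0 <= overlap < window")

    @property
    def step(self) -> int:
        return self.window - self.overlap


def window_max_count(
    sequence: str,
    residue_set: Iterable[str],
    spec: WindowSpec | None = None,
) -> int:
    """Maximum count of ``residue_set`` residues in any sliding window.

    Sequences shorter than the window use the whole sequence as the single
    window.  Non-standard letters (X, *) never match.  Implemented with a
    cumulative-sum rolling count; equivalent to the naive scan.
    """
    spec = spec or WindowSpec()
    if not sequence:
        raise ValueError("empty sequence")
    members = frozenset(residue_set)
    hits = np.fromiter((ch in members for ch in sequence), dtype=np.int64)
    if len(sequence) <= spec.window:
        return int(hits.sum())
    csum = np.concatenate(([0], np.cumsum(hits)))
    starts = np.arange(0, len(sequence) - spec.window + 1, spec.step)
    return int((csum[starts + spec.window] - csum[starts]).max())


def composition_profiles(
    sequences: Mapping[str, str],
    residue_sets: Mapping[str, frozenset[str]] = RESIDUE_SETS,
    spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Per-protein window maxima for every residue set (proteins x sets)."""
    spec = spec or WindowSpec()
    data = {
        name: [window_max_count(seq, members, spec) for seq in sequences.values()]
        for name, members in residue_sets.items()
    }
    return pd.DataFrame(data, index=pd.Index(sequences.keys(), name="protein_id"))


def composition_enrichment(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    residue_sets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Compare mean window maxima between two groups per residue set.

    ``group_a``/``group_b`` are profile frames from
    :func:`composition_profiles` (e.g. candidates vs background).  Returns a
    frame with columns mean_a, mean_b, t, p_raw, p_bonferroni; the Bonferroni
    family size is the number of residue sets tested (7 by default).
    """
    if residue_sets is None:
        residue_sets = [c for c in group_a.columns if c in group_b.columns]
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 proteins")
    rows = []
    raw_ps = []
    for name in residue_sets:
        a = group_a[name].to_numpy(dtype=float)
        b = group_b[name].to_numpy(dtype=float)
        t, p = welch_t_test(a, b)
        rows.append({"residue_set": name, "mean_a": a.mean(), "mean_b": b.mean(), "t": t})
        raw_ps.append(p)
    adjusted = bonferroni(raw_ps, m=len(residue_sets))
    result = pd.DataFrame(rows).set_index("residue_set")
    result["p_raw"] = raw_ps
    result["p_bonferroni"] = adjusted
    return result
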