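"""Readers and writers for every external format the pipeline touches.

Formats handled here: plain multi-record FASTA proteomes, GO
molecular-function annotations (GAF 2.x and the TAIR ``ATH_GO_GOSLIM`` tab
dialect), 12-column tabular BLAST output (outfmt 6), per-protein feature
tables, and two-column family membership files.  Identifiers are treated as
opaque tokens; the caller is expected to supply one sequence per gene
(no isoform collapsing is performed here).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

GO_MF_ROOT = "GO:0003674"

#: column layout of BLAST -outfmt 6
BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

FEATURE_COLUMNS = [
    "protein_id",
    "nuclear",
    "disorder_ratio",
    "autoact_tested",
    "autoact_positive",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein: unique id, species tag, amino-acid sequence."""

    protein_id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotationSet:
    """GO molecular-function annotations keyed by protein id.

    ``mf_terms`` maps protein id -> set of aspect-F GO term ids.  ``seen_ids``
    records every protein id that appeared in the source file regardless of
    aspect, so that "present in input but without MF annotation" is
    distinguishable from "never seen".
    """

    mf_terms: dict[str, set[str]] = field(default_factory=dict)
    seen_ids: set[str] = field(default_factory=set)

    def has_any_mf_annotation(self, protein_id: str) -> bool:
        return bool(self.mf_terms.get(protein_id))

    def is_unknown(self, protein_id: str, root_term: str = GO_MF_ROOT) -> bool:
        """True when the protein has no MF annotation or only the root term."""
        terms = self.mf_terms.get(protein_id, set())
        return terms <= {root_term}

    def add(self, protein_id: str, term: str) -> None:
        self.mf_terms.setdefault(protein_id, set()).add(term)
        self.seen_ids.add(protein_id)


def read_fasta(path: str | Path, species: str = "") -> dict[str, ProteinRecord]:
    """Read a FASTA proteome into an id-keyed mapping of :class:`ProteinRecord`.

    The header token before the first whitespace is the protein id.  Duplicate
    ids and empty sequences are hard errors.  ``species`` tags every record
    (per-file tag; use one call per species file for meta-genomes).
    """
    records: dict[str, ProteinRecord] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = entry.id
        if pid in records:
            raise ValueError(f"duplicate protein id in {path}: {pid!r}")
        seq = str(entry.seq)
        if not seq:
            raise ValueError(f"empty sequence for {pid!r} in {path}")
        records[pid] = ProteinRecord(pid, seq, species)
    return records


def _parse_go_line(fields: list[str], dialect: str) -> tuple[str, str, str] | None:
    """Return (protein_id, go_id, aspect) or None for a malformed line."""
    if dialect == "gaf":
        # GAF 2.x: DB, DB_Object_ID, Symbol, Qualifier, GO_ID, Ref, Evidence,
        # With, Aspect, ...
        if len(fields) < 9:
            return None
        pid, go_id, aspect = fields[1], fields[4], fields[8]
    elif dialect == "tair_goslim":
        # ATH_GO_GOSLIM.txt: locus, TAIR acc, object name, relationship,
        # GO term name, GO ID, TAIR keyword id, aspect, ...
        if len(fields) < 8:
            return None
        pid, go_id, aspect = fields[0], fields[5], fields[7]
    else:
        raise ValueError(f"unknown GO dialect {dialect!r}")
    if not pid or not go_id.startswith("GO:") or aspect not in {"F", "P", "C"}:
        return None
    return pid, go_id, aspect


def read_go_mf(path: str | Path, dialect: str = "gaf") -> AnnotationSet:
    """Parse molecular-function (aspect F) annotations from a GO file.

    Lines of other aspects mark the protein as seen but contribute no MF
    term; comment lines (leading ``!``) are ignored; malformed lines are
    logged and skipped.  A file yielding zero parsed data lines is an error.
    """
    annotations = AnnotationSet()
    n_parsed = n_skipped = n_comment = 0
    with open(path) as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("!"):
                n_comment += 1
                continue
            parsed = _parse_go_line(line.split("\t"), dialect)
            if parsed is None:
                n_skipped += 1
                continue
            pid, go_id, aspect = parsed
            n_parsed += 1
            annotations.seen_ids.add(pid)
            if aspect == "F":
                annotations.mf_terms.setdefault(pid, set()).add(go_id)
    if n_skipped:
        logger.warning("read_go_mf(%s): skipped %d malformed lines", path, n_skipped)
    logger.info(
        "read_go_mf(%s): parsed=%d skipped=%d comments=%d",
        path, n_parsed, n_skipped, n_comment,
    )
    if n_parsed == 0:
        raise ValueError(f"no parsable annotation lines in {path}")
    return annotations


def similarity_graph_from_hits(
    hits: Iterable[tuple[str, str, float]],
    evalue_cutoff: float = 1e-5,
    weight_scheme: str = "neglog10",
) -> nx.Graph:
    """Build the similarity graph from directed (query, subject, e-value) hits.

    Hits with e-value above ``evalue_cutoff`` and self-hits are discarded.
    Multiple HSPs per directed pair keep the best (lowest) e-value.  Under
    ``neglog10`` the directed weight is ``-log10(max(e, 1e-180))``; under
    ``unit`` it is 1.  Reciprocal hits are merged into one undirected edge
    whose weight is the mean of the directed weights present, which makes the
    result independent of input order.
    """
    if weight_scheme not in {"neglog10", "unit"}:
        raise ValueError(f"unknown weight scheme {weight_scheme!r}")
    best: dict[tuple[str, str], float] = {}
    for q, s, evalue in hits:
        if q == s or evalue > evalue_cutoff:
            continue
        key = (q, s)
        if key not in best or evalue < best[key]:
            best[key] = evalue

    def directed_weight(evalue: float) -> float:
        if weight_scheme == "unit":
            return 1.0
        return -math.log10(max(evalue, 1e-180))

    graph = nx.Graph()
    merged: dict[tuple[str, str], list[float]] = {}
    for (q, s), evalue in best.items():
        pair = (q, s) if q < s else (s, q)
        merged.setdefault(pair, []).append(directed_weight(evalue))
    for (u, v), weights in merged.items():
        graph.add_edge(u, v, weight=sum(weights) / len(weights))
    return graph


def read_similarity(
    path: str | Path,
    evalue_cutoff: float = 1e-5,
    weight_scheme: str = "neglog10",
) -> nx.Graph:
    """Read 12-column tabular BLAST output into a weighted similarity graph.

    See :func:`similarity_graph_from_hits` for the cutoff, weighting and
    reciprocal-merge rules.  Lines with an unparsable e-value are skipped
    with a warning.
    """

    def parse() -> Iterable[tuple[str, str, float]]:
        with open(path) as handle:
            for lineno, raw in enumerate(handle, 1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 12:
                    logger.warning(
                        "read_similarity: line %d has <12 columns, skipped", lineno
                    )
                    continue
                try:
                    evalue = float(fields[10])
                except ValueError:
                    logger.warning(
                        "read_similarity: bad e-value on line %d, skipped", lineno
                    )
                    continue
                yield fields[0], fields[1], evalue

    return similarity_graph_from_hits(parse(), evalue_cutoff, weight_scheme)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read the per-protein feature TSV into a DataFrame indexed by protein id.

    Columns: ``nuclear`` (boolean, NA allowed), ``disorder_ratio`` (float in
    [0, 1], NaN allowed), ``autoact_tested`` and ``autoact_positive``
    (booleans).  A positive autoactivation call on an untested protein and a
    disorder ratio outside [0, 1] are contract violations and hard errors.
    """
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"feature table {path} lacks columns: {sorted(missing)}")
    table = table.set_index("protein_id")

    def to_bool(col: str, allow_na: bool) -> pd.Series:
        mapping = {"0": False, "1": True, "false": False, "true": True}
        raw = table[col]

        def convert(v: object) -> object:
            if pd.isna(v) or (isinstance(v, str) and not v.strip()):
                if allow_na:
                    return pd.NA
                raise ValueError(f"missing value in required column {col!r}")
            key = str(v).strip().lower()
            if key.endswith(".0"):
                key = key[:-2]
            if key not in mapping:
                raise ValueError(f"unparsable boolean {v!r} in column {col!r}")
            return mapping[key]

        return raw.map(convert).astype("boolean")

    table["nuclear"] = to_bool("nuclear", allow_na=True)
    table["autoact_tested"] = to_bool("autoact_tested", allow_na=False).astype(bool)
    table["autoact_positive"] = to_bool("autoact_positive", allow_na=False).astype(bool)
    table["disorder_ratio"] = pd.to_numeric(table["disorder_ratio"], errors="raise")

    ratios = table["disorder_ratio"].dropna()
    if ((ratios < 0) | (ratios > 1)).any():
        bad = ratios[(ratios < 0) | (ratios > 1)].index.tolist()
        raise ValueError(f"disorder_ratio outside [0, 1] for {bad}")
    inconsistent = table.index[table["autoact_positive"] & ~table["autoact_tested"]]
    if len(inconsistent):
        raise ValueError(
            f"autoact_positive without autoact_tested for {inconsistent.tolist()}"
        )
    return table[["nuclear", "disorder_ratio", "autoact_tested", "autoact_positive"]]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table in the dialect :func:`read_feature_table` reads."""
    out = table.copy()
    for col in ("nuclear", "autoact_tested", "autoact_positive"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(bool(v))))
    out["disorder_ratio"] = out["disorder_ratio"].map(
        lambda v: "" if pd.isna(v) else f"{v:.6f}"
    )
    out.index.name = "protein_id"
    out.reset_index().to_csv(path, sep="\t", index=False)


def read_family_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column ``family_id<TAB>protein_id`` membership file."""
    families: dict[str, set[str]] = {}
    assigned: dict[str, str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            fam, pid = fields
            if pid in assigned and assigned[pid] != fam:
                raise ValueError(
                    f"{path}:{lineno}: protein {pid!r} assigned to two families"
                )
            assigned[pid] = fam
            families.setdefault(fam, set()).add(pid)
    return families


def write_family_tsv(families: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for fam in sorted(families):
            for pid in sorted(families[fam]):
                handle.write(f"{fam}\t{pid}\n")
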