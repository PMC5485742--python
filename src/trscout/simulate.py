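"""Seeded synthetic input bundles with planted regulator families.

The generator emulates the statistical structure the screen assumes: protein
families with dense within-family similarity and sparse weak between-family
hits; a *planted* regulator class whose members are preferentially nuclear,
highly disordered, and autoactivating; background families that are either
functionally annotated ("known") or unannotated; plus GO files, feature
tables, a protein-protein-interaction edge list, species tags, and ortholog
presence tables — every external format the pipeline reads.  Everything is
deterministic given the seed (one global seed, per-stage substreams).

Ground truth is recorded in the bundle: the true family partition, the ids
of planted regulator families, and the subset of those whose *realized*
feature draws satisfy the three filter criteria (the planted candidate set
the pipeline is expected to recover).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from trscout.features import summarize_family
from trscout.io import (
    AnnotationSet,
    ProteinRecord,
    similarity_graph_from_hits,
    write_family_tsv,
    write_feature_table,
)
from trscout.predict import PipelineConfig, PredictionResult

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ACTIVATION_RESIDUES = "DENQSP"

#: small fixed vocabulary of non-root MF terms for "known" families
KNOWN_MF_TERMS = ("GO:0003700", "GO:0003677", "GO:0016301", "GO:0004672", "GO:0005515")

PLANT_RANKS = ("green_algae", "early_land_plants", "flowering_plants")


@dataclass(frozen=True)
class ClassModel:
    """Feature model of one protein class (planted regulators or background)."""

    nuclear_prob: float
    disorder_beta: tuple[float, float]
    autoact_positive_prob: float

    def __post_init__(self) -> None:
        for p in (self.nuclear_prob, self.autoact_positive_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if min(self.disorder_beta) <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def disorder_mean(self) -> float:
        a, b = self.disorder_beta
        return a / (a + b)


@dataclass
class SimulationParams:
    """Knobs of the synthetic-bundle generator.

    Defaults are the "recoverable" study conditions: a clear feature
    separation between the planted regulator class (nuclear prob 0.95,
    disorder Beta(4, 4) with mean 0.5, autoactivation positivity 0.9) and the
    background (0.25, Beta(2, 8) with mean 0.2, 0.02), autoactivation testing
    coverage 0.5, within-family similarity about ten-fold stronger than the
    sparse between-family hits.
    """

    seed: int = 0
    n_families: int = 200
    family_size_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.10, 3: 0.35, 4: 0.25, 5: 0.15, 6: 0.10}
    )
    fraction_planted: float = 0.15
    fraction_background_known: float = 0.5
    fraction_known_tf: float = 0.25
    planted: ClassModel = field(
        default_factory=lambda: ClassModel(0.95, (4.0, 4.0), 0.9)
    )
    background: ClassModel = field(
        default_factory=lambda: ClassModel(0.25, (2.0, 8.0), 0.02)
    )
    autoact_coverage: float = 0.5
    length_log_mean: float = 5.7  # exp(5.7) ~ 300 residues
    length_log_sigma: float = 0.4
    length_min: int = 50
    length_max: int = 1500
    fraction_long: float = 0.0  # forces lengths in (2500, 6000] to exercise splitting
    within_exponent_range: tuple[float, float] = (30.0, 80.0)
    between_edge_prob: float = 0.02
    between_exponent_range: tuple[float, float] = (5.0, 6.5)
    noise_edge_prob: float = 0.01
    noise_exponent_range: tuple[float, float] = (0.0, 4.5)
    residue_bias: float = 1.8
    n_species: int = 1
    cross_species_prob: float = 0.2
    ppi_coverage: float = 0.35
    ppi_tf_prob_planted: float = 0.37
    ppi_tf_prob_background: float = 0.22
    taxon_scope_probs: tuple[float, float, float, float] = (0.12, 0.42, 0.28, 0.18)
    evalue_cutoff: float = 1e-5

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_planted <= 1:
            raise ValueError("fraction_planted must be in [0, 1]")
        if abs(sum(self.family_size_probs.values()) - 1.0) > 1e-9:
            raise ValueError("family_size_probs must sum to 1")
        if any(s < 1 for s in self.family_size_probs):
            raise ValueError("family sizes must be >= 1")
        if abs(sum(self.taxon_scope_probs) - 1.0) > 1e-9:
            raise ValueError("taxon_scope_probs must sum to 1")


def preset_params(
    name: str,
    seed: int = 17,
    n_families: int = 200,
    separation: float = 1.0,
) -> SimulationParams:
    """Named study conditions.

    ``recoverable``: the defaults above — planted families should be
    recovered exactly.  ``hard``: the planted class models are interpolated
    toward the background by ``separation`` in [0, 1] (1 = recoverable
    separation, 0 = indistinguishable classes), so measured precision/recall
    degrade as the separation shrinks.
    """
    params = SimulationParams(seed=seed, n_families=n_families)
    if name == "recoverable":
        return params
    if name == "hard":
        if not 0 <= separation <= 1:
            raise ValueError("separation must be in [0, 1]")
        bg = params.background
        full = params.planted
        concentration = 10.0
        mean = bg.disorder_mean + separation * (full.disorder_mean - bg.disorder_mean)
        params.planted = ClassModel(
            nuclear_prob=bg.nuclear_prob
            + separation * (full.nuclear_prob - bg.nuclear_prob),
            disorder_beta=(mean * concentration, (1 - mean) * concentration),
            autoact_positive_prob=bg.autoact_positive_prob
            + separation * (full.autoact_positive_prob - bg.autoact_positive_prob),
        )
        return params
    raise ValueError(f"unknown preset {name!r}")


@dataclass
class SyntheticBundle:
    """All generated inputs plus ground truth, with file writers."""

    params: SimulationParams
    proteome: dict[str, ProteinRecord]
    graph: nx.Graph
    blast_rows: list[str]
    annotations: AnnotationSet
    go_lines: list[str]
    features: pd.DataFrame
    true_families: dict[str, set[str]]
    planted_family_ids: set[str]
    planted_candidate_ids: set[str]
    tf_gold: set[str]
    species_of: dict[str, str]
    ppi_edges: list[tuple[str, str]]
    ortholog_presence: dict[str, dict[str, bool]]

    @property
    def planted_candidate_proteins(self) -> set[str]:
        return {
            pid
            for fam in self.planted_candidate_ids
            for pid in self.true_families[fam]
        }

    def write(self, out_dir: str | Path) -> None:
        """Write every file format the io module reads, plus a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "proteome.fasta", "w") as fh:
            for pid in sorted(self.proteome):
                rec = self.proteome[pid]
                fh.write(f">{pid}\n")
                for i in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[i : i + 60] + "\n")
        with open(out / "similarity.tsv", "w") as fh:
            fh.write("\n".join(self.blast_rows) + ("\n" if self.blast_rows else ""))
        with open(out / "annotations.gaf", "w") as fh:
            fh.write("!gaf-version: 2.2\n")
            fh.write("\n".join(self.go_lines) + ("\n" if self.go_lines else ""))
        write_feature_table(self.features, out / "features.tsv")
        write_family_tsv(self.true_families, out / "families_true.tsv")
        with open(out / "tf_gold.txt", "w") as fh:
            for pid in sorted(self.tf_gold):
                fh.write(pid + "\n")
        with open(out / "planted_proteins.txt", "w") as fh:
            for pid in sorted(self.planted_candidate_proteins):
                fh.write(pid + "\n")
        with open(out / "ppi_edges.tsv", "w") as fh:
            for u, v in sorted(self.ppi_edges):
                fh.write(f"{u}\t{v}\n")
        with open(out / "species.tsv", "w") as fh:
            for pid in sorted(self.species_of):
                fh.write(f"{pid}\t{self.species_of[pid]}\n")
        with open(out / "orthologs.tsv", "w") as fh:
            for fam in sorted(self.ortholog_presence):
                for rank in PLANT_RANKS:
                    present = int(self.ortholog_presence[fam].get(rank, False))
                    fh.write(f"{fam}\t{rank}\t{present}\n")
        manifest = {
            "seed": self.params.seed,
            "params": _params_to_jsonable(self.params),
            "planted_family_ids": sorted(self.planted_family_ids),
            "planted_candidate_ids": sorted(self.planted_candidate_ids),
            "tf_gold": sorted(self.tf_gold),
            "n_proteins": len(self.proteome),
            "n_families": len(self.true_families),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _params_to_jsonable(params: SimulationParams) -> dict:
    data = asdict(params)
    data["family_size_probs"] = {str(k): v for k, v in data["family_size_probs"].items()}
    return data


def _draw_sequence(rng: np.random.Generator, length: int, planted: bool, bias: float) -> str:
    freqs = np.full(20, 1.0 / 20)
    if planted:
        for ch in ACTIVATION_RESIDUES:
            freqs[AMINO_ACIDS.index(ch)] *= bias
        freqs /= freqs.sum()
    letters = rng.choice(list(AMINO_ACIDS), size=length, p=freqs)
    return "".join(letters)


def _blast_row(q: str, s: str, evalue: float) -> str:
    # pident/length/bitscore are cosmetic; only ids and e-value matter downstream
    return (
        f"{q}\t{s}\t50.0\t100\t50\t0\t1\t100\t1\t100\t{evalue:.3e}\t200.0"
    )


def generate_bundle(params: SimulationParams | None = None) -> SyntheticBundle:
    """Generate a complete synthetic input bundle (see module docstring)."""
    params = params or SimulationParams()
    streams = np.random.SeedSequence(params.seed).spawn(7)
    rng_fam, rng_seq, rng_sim, rng_feat, rng_go, rng_ppi, rng_tax = (
        np.random.default_rng(s) for s in streams
    )

    # -- families and classes ------------------------------------------------
    sizes_support = sorted(params.family_size_probs)
    size_probs = [params.family_size_probs[s] for s in sizes_support]
    sizes = rng_fam.choice(sizes_support, size=params.n_families, p=size_probs)
    order = rng_fam.permutation(params.n_families)
    n_planted = int(round(params.fraction_planted * params.n_families))
    planted_idx = set(order[:n_planted].tolist())
    n_background = params.n_families - n_planted
    n_known = int(round(params.fraction_background_known * n_background))
    known_idx = set(order[n_planted : n_planted + n_known].tolist())
    n_tf_families = int(round(params.fraction_known_tf * n_known))
    tf_idx = set(order[n_planted : n_planted + n_tf_families].tolist())

    fam_width = max(4, len(str(params.n_families)))
    family_ids = [f"T{i + 1:0{fam_width}d}" for i in range(params.n_families)]
    true_families: dict[str, set[str]] = {}
    protein_class: dict[str, bool] = {}  # True = planted regulator
    family_of: dict[str, str] = {}
    proteins: list[str] = []
    counter = 0
    for i, fam in enumerate(family_ids):
        members = set()
        for _ in range(int(sizes[i])):
            counter += 1
            pid = f"P{counter:06d}"
            members.add(pid)
            proteins.append(pid)
            protein_class[pid] = i in planted_idx
            family_of[pid] = fam
        true_families[fam] = members
    planted_family_ids = {family_ids[i] for i in planted_idx}
    known_family_ids = {family_ids[i] for i in known_idx}
    tf_family_ids = {family_ids[i] for i in tf_idx}
    tf_gold = {pid for fam in tf_family_ids for pid in true_families[fam]}

    # -- species tags --------------------------------------------------------
    species_names = [f"sp{j + 1}" for j in range(params.n_species)]
    species_of: dict[str, str] = {}
    for i, fam in enumerate(family_ids):
        primary = species_names[int(rng_fam.integers(params.n_species))]
        for pid in sorted(true_families[fam]):
            if params.n_species > 1 and rng_fam.random() < params.cross_species_prob:
                species_of[pid] = species_names[int(rng_fam.integers(params.n_species))]
            else:
                species_of[pid] = primary

    # -- sequences -----------------------------------------------------------
    proteome: dict[str, ProteinRecord] = {}
    for pid in proteins:
        if params.fraction_long > 0 and rng_seq.random() < params.fraction_long:
            length = int(rng_seq.integers(2501, 6001))
        else:
            length = int(
                np.clip(
                    rng_seq.lognormal(params.length_log_mean, params.length_log_sigma),
                    params.length_min,
                    params.length_max,
                )
            )
        seq = _draw_sequence(rng_seq, length, protein_class[pid], params.residue_bias)
        proteome[pid] = ProteinRecord(pid, seq, species_of[pid])

    # -- similarity graph ----------------------------------------------------
    hits: list[tuple[str, str, float]] = []
    for fam in family_ids:
        members = sorted(true_families[fam])
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                u = rng_sim.uniform(*params.within_exponent_range)
                jitter = rng_sim.uniform(0.0, 2.0)
                hits.append((members[a_i], members[b_i], 10.0 ** -(u + jitter / 2)))
                hits.append((members[b_i], members[a_i], 10.0 ** -(u - jitter / 2)))
    for f_i in range(len(family_ids)):
        for f_j in range(f_i + 1, len(family_ids)):
            r = rng_sim.random()
            if r < params.between_edge_prob:
                exponent_range = params.between_exponent_range
            elif r < params.between_edge_prob + params.noise_edge_prob:
                exponent_range = params.noise_exponent_range
            else:
                continue
            u = sorted(true_families[family_ids[f_i]])[
                int(rng_sim.integers(len(true_families[family_ids[f_i]])))
            ]
            v = sorted(true_families[family_ids[f_j]])[
                int(rng_sim.integers(len(true_families[family_ids[f_j]])))
            ]
            evalue = 10.0 ** -rng_sim.uniform(*exponent_range)
            hits.append((u, v, evalue))
    blast_rows = [_blast_row(q, s, e) for q, s, e in hits]
    graph = similarity_graph_from_hits(hits, params.evalue_cutoff)
    graph.add_nodes_from(proteins)

    # -- per-protein features ------------------------------------------------
    rows = []
    for pid in proteins:
        model = params.planted if protein_class[pid] else params.background
        nuclear = bool(rng_feat.random() < model.nuclear_prob)
        ratio = float(rng_feat.beta(*model.disorder_beta))
        tested = bool(rng_feat.random() < params.autoact_coverage)
        positive = bool(tested and rng_feat.random() < model.autoact_positive_prob)
        rows.append(
            {
                "protein_id": pid,
                "nuclear": nuclear,
                "disorder_ratio": ratio,
                "autoact_tested": tested,
                "autoact_positive": positive,
            }
        )
    features = pd.DataFrame(rows).set_index("protein_id")
    features["nuclear"] = features["nuclear"].astype("boolean")

    # -- GO annotations ------------------------------------------------------
    go_lines: list[str] = []
    annotations = AnnotationSet()

    def gaf_line(pid: str, term: str, aspect: str) -> str:
        return "\t".join(
            [
                "SYN", pid, pid, "", term, "SYN:0001", "IEA", "", aspect,
                pid, "", "protein", "taxon:0", "20200101", "SYN", "", "",
            ]
        )

    for fam in family_ids:
        known = fam in known_family_ids
        members = sorted(true_families[fam])
        for j, pid in enumerate(members):
            if known:
                if j == 0 or rng_go.random() < 0.9:
                    term = KNOWN_MF_TERMS[int(rng_go.integers(len(KNOWN_MF_TERMS)))]
                    go_lines.append(gaf_line(pid, term, "F"))
                    annotations.add(pid, term)
            else:
                r = rng_go.random()
                if r < 0.4:
                    go_lines.append(gaf_line(pid, "GO:0003674", "F"))
                    annotations.add(pid, "GO:0003674")
                elif r < 0.6:
                    go_lines.append(gaf_line(pid, "GO:0008150", "P"))
                    annotations.seen_ids.add(pid)

    # -- planted candidate ground truth (consistent with realized features) --
    config = PipelineConfig()
    planted_candidate_ids = set()
    for fam in planted_family_ids:
        if len(true_families[fam]) < config.min_family_size:
            continue
        s = summarize_family(fam, true_families[fam], features)
        if (
            s.nuclear_fraction > config.nuclear_fraction_gt
            and s.mean_disorder is not None
            and s.mean_disorder > config.disorder_mean_gt
            and s.has_autoactivator
        ):
            planted_candidate_ids.add(fam)

    # -- protein-protein interactions ----------------------------------------
    sampled = [pid for pid in proteins if rng_ppi.random() < params.ppi_coverage]
    ppi_edges: list[tuple[str, str]] = []
    tf_pool = sorted(tf_gold)
    non_tf_pool = [pid for pid in sampled if pid not in tf_gold]
    for pid in sampled:
        p_tf = (
            params.ppi_tf_prob_planted
            if protein_class[pid]
            else params.ppi_tf_prob_background
        )
        if tf_pool and rng_ppi.random() < p_tf:
            partner = tf_pool[int(rng_ppi.integers(len(tf_pool)))]
        elif len(non_tf_pool) > 1:
            partner = pid
            while partner == pid:
                partner = non_tf_pool[int(rng_ppi.integers(len(non_tf_pool)))]
        else:
            continue
        ppi_edges.append((pid, partner))

    # -- ortholog presence ---------------------------------------------------
    ortholog_presence: dict[str, dict[str, bool]] = {}
    scope_choices = list(PLANT_RANKS) + [None]
    for fam in sorted(planted_family_ids):
        pick = rng_tax.choice(4, p=list(params.taxon_scope_probs))
        scope = scope_choices[int(pick)]
        flags = dict.fromkeys(PLANT_RANKS, False)
        if scope is not None:
            # presence nests: conserved at a deep rank implies the shallower ones
            depth = PLANT_RANKS.index(scope)
            for rank in PLANT_RANKS[depth:]:
                flags[rank] = True
        ortholog_presence[fam] = flags

    return SyntheticBundle(
        params=params,
        proteome=proteome,
        graph=graph,
        blast_rows=blast_rows,
        annotations=annotations,
        go_lines=go_lines,
        features=features,
        true_families=true_families,
        planted_family_ids=planted_family_ids,
        planted_candidate_ids=planted_candidate_ids,
        tf_gold=tf_gold,
        species_of=species_of,
        ppi_edges=ppi_edges,
        ortholog_presence=ortholog_presence,
    )


def expected_feature_gap(params: SimulationParams) -> dict[str, dict]:
    """Closed-form per-class feature expectations for calibration checks.

    For each class: the expected nuclear fraction (= nuclear probability),
    the disorder mean a/(a+b) of the Beta model, the per-member probability
    of a *detected* autoactivator (coverage x positivity), and the
    probability that a family of size s has at least one detected positive,
    1 - (1 - coverage * positivity)^s.
    """
    out: dict[str, dict] = {}
    sizes = sorted(params.family_size_probs)
    for name, model in (("planted", params.planted), ("background", params.background)):
        detected = params.autoact_coverage * model.autoact_positive_prob
        out[name] = {
            "nuclear_fraction": model.nuclear_prob,
            "disorder_mean": model.disorder_mean,
            "member_detected_positive": detected,
            "family_any_positive_by_size": {
                s: 1.0 - (1.0 - detected) ** s for s in sizes
            },
        }
    return out


def recovery_scores(
    result: PredictionResult, bundle: SyntheticBundle
) -> tuple[float, float]:
    """Family-level precision/recall of a pipeline run against planted truth.

    A predicted candidate family counts as a true positive iff its member set
    equals a planted candidate family's member set exactly.
    """
    truth = {frozenset(bundle.true_families[f]) for f in bundle.planted_candidate_ids}
    predicted = {frozenset(result.families[f]) for f in result.candidates}
    hits = len(truth & predicted)
    precision = hits / len(predicted) if predicted else (1.0 if not truth else 0.0)
    recall = hits / len(truth) if truth else 1.0
    return precision, recall


def detection_scores(
    result: PredictionResult, bundle: SyntheticBundle
) -> tuple[float, float]:
    """Family-level precision/recall against *all* eligible planted families.

    Unlike :func:`recovery_scores`, the gold set here is every planted
    regulator family large enough to enter the screen, regardless of whether
    its realized feature draws pass the filters.  This is the score that
    degrades as the class separation of the generator shrinks (under weak
    separation planted families become indistinguishable from background and
    are missed).
    """
    min_size = result.config.effective_min_size
    truth = {
        frozenset(bundle.true_families[f])
        for f in bundle.planted_family_ids
        if len(bundle.true_families[f]) >= min_size
    }
    predicted = {frozenset(result.families[f]) for f in result.candidates}
    hits = len(truth & predicted)
    precision = hits / len(predicted) if predicted else (1.0 if not truth else 0.0)
    recall = hits / len(truth) if truth else 1.0
    return precision, recall
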