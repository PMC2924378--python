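"""Seeded synthetic benchmarks: ontology, annotations, sequences, pairs.

Real evaluations of the function filters need a GO release, a GAF, an
alias table and a curated minimotif database.  This module fabricates
statistically controlled stand-ins for all of them so every other
module is testable offline:

* a rooted random DAG (each term picks 1..max_parents parents among
  earlier terms, acyclic by construction);
* per-protein random term sets;
* a positive minimotif set where, with *plant probability* q, the
  target protein is given a term within pair distance ``plant_distance``
  of a source term — the planted signal a function filter should pick
  up;
* a negative set of uniform random ordered pairs resampled until
  disjoint from the positives;
* uniform random protein sequences with each positive's consensus
  implanted at a recorded site.

Every artifact is a pure function of :class:`SyntheticConfig`; all
randomness flows through one ``numpy`` generator seeded from
``config.seed``.  Writers emit the same formats the real pipeline reads
(OBO, GAF, alias TSV, FASTA, minimotif/pairs TSV), so end-to-end tests
exercise the parsers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations import AliasTable, AnnotationSet
from .motifs import AMINO_ACIDS, Minimotif, MotifPattern, parse_pattern
from .ontology import OntologyGraph, TermRecord

__all__ = [
    "GenerationError",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dag",
    "generate_pairs",
    "generate_sequences_with_motifs",
    "generate_dataset",
    "terms_within",
    "write_fixture",
]


class GenerationError(Exception):
    """The requested dataset cannot be generated under the config."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic benchmark.

    The defaults emulate a desk-scale version of a filter evaluation: a
    few hundred ontology terms, a few thousand proteins with a handful
    of annotations each, a thousand verified and a thousand random
    pairs, and average-length protein sequences carrying short
    consensus motifs.
    """

    seed: int = 0
    n_terms: int = 250
    max_parents: int = 2
    n_proteins: int = 2500
    terms_per_protein: int = 3
    n_pos: int = 1000
    n_neg: int = 1000
    plant_distance: int = 1  # d_pos: target pair distance for planted positives
    plant_probability: float = 0.6  # q: chance a positive is planted
    sequence_length: int = 400
    motif_length: int = 4
    degenerate_prob: float = 0.2  # chance a motif position is a 2-letter class
    unannotated_fraction: float = 0.0
    alias_fraction: float = 0.1  # proteins referenced via an alias accession
    namespace: str = "biological_process"
    resample_factor: int = 100  # negative resampling cap, x n_neg

    def __post_init__(self) -> None:
        if min(self.n_terms, self.n_proteins, self.n_pos, self.n_neg) < 1:
            raise ValueError("all counts must be positive")
        if not 1 <= self.max_parents <= 2:
            raise ValueError("max_parents must be 1 or 2")
        if not 0.0 <= self.plant_probability <= 1.0:
            raise ValueError("plant_probability must lie in [0, 1]")
        if self.motif_length > self.sequence_length:
            raise GenerationError("motif_length exceeds sequence_length")


@dataclass
class SyntheticDataset:
    """Everything one benchmark run needs, plus the planted ground truth."""

    config: SyntheticConfig
    graph: OntologyGraph
    annotations: AnnotationSet = None  # type: ignore[assignment]
    aliases: AliasTable = field(default_factory=AliasTable)
    sequences: dict[str, str] = field(default_factory=dict)
    positives: list[Minimotif] = field(default_factory=list)
    negatives: list[Minimotif] = field(default_factory=list)
    truth: list[bool] = field(default_factory=list)  # per-positive planted flag
    implant_sites: list[tuple[str, int]] = field(default_factory=list)

    def pair_set(self, motifs: list[Minimotif]) -> set[tuple[str, str]]:
        return {(m.source, m.target) for m in motifs}


def _term_name(i: int) -> str:
    return f"SYN:{i:07d}"


def _protein_name(i: int) -> str:
    return f"P{i:05d}"


def generate_dag(config: SyntheticConfig, rng: np.random.Generator) -> OntologyGraph:
    """Random rooted DAG: term 0 is the root, later terms attach upward."""
    records: dict[str, TermRecord] = {}
    edges: list[tuple[str, str]] = []
    names = [_term_name(i) for i in range(config.n_terms)]
    for i, term in enumerate(names):
        parent_ids: list[tuple[str, str]] = []
        if i > 0:
            k = int(rng.integers(1, config.max_parents + 1))
            k = min(k, i)
            choice = rng.choice(i, size=k, replace=False)
            for j in sorted(int(c) for c in choice):
                parent_ids.append((names[j], "is_a"))
                edges.append((term, names[j]))
        records[term] = TermRecord(
            id=term,
            name=f"synthetic term {i}",
            namespace=config.namespace,
            parents=tuple(parent_ids),
        )
    return OntologyGraph(records, edges, namespace=config.namespace)


def terms_within(graph: OntologyGraph, term: str, d: int) -> list[str]:
    """All terms at pair distance <= d from *term* (sorted).

    A term w is within total distance d iff some ancestor c satisfies
    dist(term, c) + dist(w, c) <= d, so we walk up from *term* and back
    down from each ancestor within the remaining budget.
    """
    within: set[str] = set()
    for ancestor, up in graph.ancestor_distances(term).items():
        if up > d:
            continue
        frontier = {ancestor}
        within.add(ancestor)
        for _ in range(d - up):
            frontier = {c for t in frontier for c in graph.children(t)}
            within.update(frontier)
    return sorted(within)


def _random_pattern(config: SyntheticConfig, rng: np.random.Generator) -> MotifPattern:
    parts = []
    for _ in range(config.motif_length):
        if rng.random() < config.degenerate_prob:
            pair = rng.choice(len(AMINO_ACIDS), size=2, replace=False)
            parts.append("[" + "".join(AMINO_ACIDS[int(i)] for i in sorted(pair)) + "]")
        else:
            parts.append(AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))])
    return parse_pattern("".join(parts))


def generate_pairs(
    config: SyntheticConfig, graph: OntologyGraph, rng: np.random.Generator
) -> SyntheticDataset:
    """Annotate a protein pool and draw positive/negative minimotif sets.

    Positives use distinct target proteins so each planting is
    independent; negatives are uniform ordered pairs resampled until
    disjoint from the positive (source, target) set, erroring out after
    ``resample_factor * n_neg`` rejected draws.
    """
    if config.n_pos > config.n_proteins - 1:
        raise GenerationError("need more proteins than positives for distinct targets")
    proteins = [_protein_name(i) for i in range(config.n_proteins)]
    terms = graph.terms

    n_unannotated = int(round(config.unannotated_fraction * config.n_proteins))
    unannotated = set(
        proteins[int(i)]
        for i in rng.choice(config.n_proteins, size=n_unannotated, replace=False)
    ) if n_unannotated else set()

    annotations = AnnotationSet(namespace=config.namespace)
    protein_terms: dict[str, list[str]] = {}
    for p in proteins:
        if p in unannotated:
            protein_terms[p] = []
            continue
        idx = rng.choice(len(terms), size=min(config.terms_per_protein, len(terms)),
                         replace=False)
        chosen = [terms[int(i)] for i in idx]
        protein_terms[p] = chosen
        for t in chosen:
            annotations.add(p, t)

    # positives: distinct targets, sources drawn from the non-target pool
    # (a planting rewrites target annotations; keeping sources out of the
    # target set means no later plant can disturb an earlier one)
    target_idx = rng.choice(config.n_proteins, size=config.n_pos, replace=False)
    target_set = {int(i) for i in target_idx}
    source_pool = [i for i in range(config.n_proteins) if i not in target_set]
    positives: list[Minimotif] = []
    truth: list[bool] = []
    for ti in target_idx:
        target = proteins[int(ti)]
        source = proteins[source_pool[int(rng.integers(len(source_pool)))]]
        planted = False
        if rng.random() < config.plant_probability:
            src_terms = protein_terms[source]
            tgt_terms = protein_terms[target]
            if src_terms and tgt_terms:
                s = src_terms[int(rng.integers(len(src_terms)))]
                nearby = terms_within(graph, s, config.plant_distance)
                w = nearby[int(rng.integers(len(nearby)))]
                # replace one target term so set sizes stay comparable
                victim = tgt_terms[int(rng.integers(len(tgt_terms)))]
                annotations.by_accession[target].discard(victim)
                annotations.by_accession[target].add(w)
                protein_terms[target] = sorted(annotations.by_accession[target])
                planted = True
        positives.append(
            Minimotif(source=source, pattern=_random_pattern(config, rng),
                      activity="binds", target=target)
        )
        truth.append(planted)

    pos_pairs = {(m.source, m.target) for m in positives}
    negatives: list[Minimotif] = []
    neg_pairs: set[tuple[str, str]] = set()
    attempts = 0
    cap = config.resample_factor * config.n_neg
    while len(negatives) < config.n_neg:
        attempts += 1
        if attempts > cap:
            raise GenerationError(
                f"could not draw {config.n_neg} negatives disjoint from the "
                f"positives within {cap} attempts"
            )
        si, ti = (int(i) for i in rng.integers(config.n_proteins, size=2))
        if si == ti:
            continue
        pair = (proteins[si], proteins[ti])
        if pair in pos_pairs or pair in neg_pairs:
            continue
        neg_pairs.add(pair)
        negatives.append(
            Minimotif(source=pair[0], pattern=_random_pattern(config, rng),
                      activity="binds", target=pair[1])
        )

    # alias layer: a fraction of proteins are referenced (in the motif
    # tables only) through an alias; the GAF keeps canonical accessions
    aliases = AliasTable()
    n_alias = int(round(config.alias_fraction * config.n_proteins))
    if n_alias:
        for i in rng.choice(config.n_proteins, size=n_alias, replace=False):
            canonical = proteins[int(i)]
            aliases.entries[f"ALIAS:{canonical}"] = canonical

        def aliased(acc: str) -> str:
            alias = f"ALIAS:{acc}"
            return alias if alias in aliases.entries else acc

        positives = [
            dataclasses.replace(m, source=aliased(m.source), target=aliased(m.target))
            for m in positives
        ]
        negatives = [
            dataclasses.replace(m, source=aliased(m.source), target=aliased(m.target))
            for m in negatives
        ]

    return SyntheticDataset(
        config=config,
        graph=graph,
        annotations=annotations,
        aliases=aliases,
        positives=positives,
        negatives=negatives,
        truth=truth,
    )


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    idx = rng.integers(len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[int(i)] for i in idx)


def _realisation(pattern: MotifPattern, rng: np.random.Generator) -> str:
    letters = []
    for cls in pattern.positions:
        options = sorted(cls)
        letters.append(options[int(rng.integers(len(options)))])
    return "".join(letters)


def generate_sequences_with_motifs(
    config: SyntheticConfig, dataset: SyntheticDataset, rng: np.random.Generator
) -> SyntheticDataset:
    """Give every referenced protein a random sequence; implant each
    positive's consensus at a recorded 1-based site in its source."""
    if config.motif_length > config.sequence_length:
        raise GenerationError("motif_length exceeds sequence_length")
    referenced: set[str] = set()
    for m in dataset.positives + dataset.negatives:
        referenced.add(dataset.aliases.resolve(m.source))
        referenced.add(dataset.aliases.resolve(m.target))
    for acc in sorted(referenced):
        dataset.sequences[acc] = _random_sequence(config.sequence_length, rng)
    dataset.implant_sites = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for m in dataset.positives:
        acc = dataset.aliases.resolve(m.source)
        seq = dataset.sequences[acc]
        k = len(m.pattern)
        taken = occupied.setdefault(acc, [])
        # non-overlapping windows so one implant cannot clobber another
        for _ in range(200):
            start = int(rng.integers(len(seq) - k + 1))  # 0-based
            if all(start + k <= lo or start >= hi for lo, hi in taken):
                break
        else:
            raise GenerationError(
                f"no free implant window left in source {acc} "
                f"(sequence_length too small for the motif load)"
            )
        taken.append((start, start + k))
        realised = _realisation(m.pattern, rng)
        dataset.sequences[acc] = seq[:start] + realised + seq[start + k :]
        dataset.implant_sites.append((acc, start + 1))
    return dataset


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """One-call pipeline: DAG -> annotated pairs -> sequences."""
    rng = np.random.default_rng(config.seed)
    graph = generate_dag(config, rng)
    dataset = generate_pairs(config, graph, rng)
    return generate_sequences_with_motifs(config, dataset, rng)


# ---------------------------------------------------------------------------
# Writers: the same formats the real pipeline parses.

_ASPECT = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}


def _write_obo(dataset: SyntheticDataset, path: Path) -> None:
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for term in dataset.graph.terms:
        rec = dataset.graph.records[term]
        lines.append("[Term]")
        lines.append(f"id: {rec.id}")
        lines.append(f"name: {rec.name or rec.id}")
        lines.append(f"namespace: {rec.namespace}")
        for parent, rel in rec.parents:
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


def _write_gaf(dataset: SyntheticDataset, path: Path) -> None:
    aspect = _ASPECT[dataset.annotations.namespace]
    rows = ["!gaf-version: 2.1"]
    for acc in sorted(dataset.annotations.by_accession):
        for term in sorted(dataset.annotations.by_accession[acc]):
            cols = ["SYN", acc, acc, "", term, "SYN:0000001", "IEA", "",
                    aspect, "", "", "protein", "taxon:0000", "20100101", "SYN", "", ""]
            rows.append("\t".join(cols))
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def _write_alias(dataset: SyntheticDataset, path: Path) -> None:
    rows = ["alias\tcanonical"]
    for alias in sorted(dataset.aliases.entries):
        rows.append(f"{alias}\t{dataset.aliases.entries[alias]}")
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def _write_fasta(dataset: SyntheticDataset, path: Path, width: int = 60) -> None:
    chunks = []
    for acc in sorted(dataset.sequences):
        seq = dataset.sequences[acc]
        chunks.append(f">{acc}")
        chunks.extend(seq[i : i + width] for i in range(0, len(seq), width))
    path.write_text("\n".join(chunks) + "\n", encoding="utf-8")


def _write_motifs(motifs: list[Minimotif], path: Path) -> None:
    rows = ["source_accession\tmotif\tactivity\ttarget_accession"]
    for m in motifs:
        rows.append(f"{m.source}\t{m.pattern.text}\t{m.activity}\t{m.target}")
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def _write_pairs(motifs: list[Minimotif], path: Path) -> None:
    rows = ["source_accession\ttarget_accession"]
    for m in motifs:
        rows.append(f"{m.source}\t{m.target}")
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def write_fixture(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the full benchmark to *directory*; returns the file map.

    Emits ``ontology.obo``, ``annotations.gaf``, ``aliases.tsv``,
    ``sequences.fasta``, ``positives.tsv``, ``negatives.tsv``,
    ``negative_pairs.tsv`` and a ``manifest.json`` echoing the config.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "ontology": directory / "ontology.obo",
        "gaf": directory / "annotations.gaf",
        "aliases": directory / "aliases.tsv",
        "fasta": directory / "sequences.fasta",
        "positives": directory / "positives.tsv",
        "negatives": directory / "negatives.tsv",
        "negative_pairs": directory / "negative_pairs.tsv",
        "manifest": directory / "manifest.json",
    }
    _write_obo(dataset, files["ontology"])
    _write_gaf(dataset, files["gaf"])
    _write_alias(dataset, files["aliases"])
    _write_fasta(dataset, files["fasta"])
    _write_motifs(dataset.positives, files["positives"])
    _write_motifs(dataset.negatives, files["negatives"])
    _write_pairs(dataset.negatives, files["negative_pairs"])
    manifest = {
        "config": dataclasses.asdict(dataset.config),
        "truth": dataset.truth,
        "implant_sites": dataset.implant_sites,
    }
    files["manifest"].write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return files
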