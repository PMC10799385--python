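"""Cross-lingual mapping proposal and mapping-based hierarchy induction.

A Chinese source concept carries one or more English names (collected
during definition work or from translation tools).  Those names are looked
up in a lexical index of an English target ontology (e.g. a SNOMED-CT-like
graph): an exact label hit yields an ``exact`` mapping, a hit after
normalisation (case/punctuation/word-order folding, SNOMED-style
"(disorder)" suffix removal) yields a ``normalized`` one.

Once mappings are established, the target ontology's own is_a hierarchy is
transferred back: for any two source concepts mapped into the *same*
target ontology whose target classes stand in a subsumption relation, a
child-parent edge is proposed for the source.  Evidence is never chained
across two different target ontologies — English ontologies disagree with
each other often enough that mixed evidence is unreliable.  Proposed edges
that would create a cycle, or that contradict an existing source edge, are
returned flagged instead of applied.

Similarity scores from alignment tools ride along as metadata only; no
automatic acceptance threshold is applied (lexical aligners happily score
a wrong match at 0.93).
"""

from __future__ import annotations

import csv
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx

from cdmo.onto_core import Concept, OntologyGraph, OntologyError, is_subclass_of

__all__ = [
    "MappingRecord",
    "TargetLexicon",
    "InducedEdge",
    "normalize_name",
    "build_lexical_index",
    "propose_mappings",
    "induce_hierarchy",
    "read_mappings",
    "write_mappings",
    "mapping_counts",
]

MATCH_TYPES = ("exact", "normalized", "manual")

_PAREN_SUFFIX = re.compile(r"\s*\([^()]*\)\s*$")
_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


@dataclass
class MappingRecord:
    """A cross-lingual link from a source concept to a target class."""

    source_iri: str
    target_ontology: str
    target_id: str
    match_type: str = "manual"
    similarity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.match_type not in MATCH_TYPES:
            raise ValueError(f"bad match_type {self.match_type!r}")
        if self.similarity is not None and not 0.0 <= self.similarity <= 1.0:
            raise ValueError("similarity must be in [0, 1]")


@dataclass
class TargetLexicon:
    """Normalised-name index plus the target ontology's is_a graph."""

    index: dict[str, set[str]]
    exact: dict[str, set[str]]
    graph: OntologyGraph


@dataclass
class InducedEdge:
    child_iri: str
    parent_iri: str
    evidence: tuple[str, str, str]  # (target_ontology, child_id, parent_id)
    status: str = "accepted"  # accepted | rejected_cycle | rejected_conflict


def normalize_name(name: str, sort_tokens: bool = True) -> str:
    """Fold a concept name to a collision key.

    Lowercases, strips a trailing parenthesised qualifier such as
    "(disorder)", replaces punctuation by spaces, collapses whitespace
    and (by default) sorts tokens so word-order variants like
    "hyperosmolar hyperglycemic state" / "hyperglycemic hyperosmolar
    state" collide.
    """
    s = _PAREN_SUFFIX.sub("", name).lower()
    s = s.translate(_PUNCT_TABLE)
    tokens = s.split()
    if sort_tokens:
        tokens = sorted(tokens)
    return " ".join(tokens)


def build_lexical_index(target: OntologyGraph, sort_tokens: bool = True) -> TargetLexicon:
    """Index every target label and synonym under its normalised key."""
    index: dict[str, set[str]] = {}
    exact: dict[str, set[str]] = {}
    for c in target.concepts.values():
        names = [c.label_zh] + list(c.labels_en) + list(c.synonyms_zh)
        for name in names:
            exact.setdefault(name, set()).add(c.iri)
            index.setdefault(normalize_name(name, sort_tokens), set()).add(c.iri)
    return TargetLexicon(index=index, exact=exact, graph=target)


def propose_mappings(
    concept: Concept,
    lexicon: TargetLexicon,
    target_ontology: str = "TARGET",
    sort_tokens: bool = True,
) -> list[MappingRecord]:
    """Propose mappings for one concept's English names.

    Exact label hits rank before normalised-key hits; within a match type
    results are sorted by target id.  A concept without any English name
    needs a (manual) translation first and yields no records.
    """
    import logging

    if not concept.labels_en:
        logging.getLogger(__name__).info(
            "concept %s (%s) has no English names: needs translation",
            concept.iri,
            concept.label_zh,
        )
        return []
    exact_ids: set[str] = set()
    norm_ids: set[str] = set()
    for name in concept.labels_en:
        exact_ids |= lexicon.exact.get(name, set())
        norm_ids |= lexicon.index.get(normalize_name(name, sort_tokens), set())
    norm_ids -= exact_ids
    records = [
        MappingRecord(concept.iri, target_ontology, tid, "exact")
        for tid in sorted(exact_ids)
    ] + [
        MappingRecord(concept.iri, target_ontology, tid, "normalized")
        for tid in sorted(norm_ids)
    ]
    return records


def induce_hierarchy(
    source: OntologyGraph,
    mappings: Sequence[MappingRecord],
    targets: dict[str, OntologyGraph],
    mode: str = "transitive",
    apply: bool = False,
) -> list[InducedEdge]:
    """Transfer target-ontology subsumptions onto the source graph.

    For every pair of source concepts (c, p) mapped into the same target
    ontology, propose ``c is_a p`` when the target asserts the
    corresponding subsumption — a direct parent link in ``direct`` mode,
    reachability in ``transitive`` mode (output then transitively
    reduced).  Edges that would create a cycle in the source are flagged
    ``rejected_cycle``; edges contradicting an existing source edge
    (p already strictly below c) are flagged ``rejected_conflict``.
    Accepted edges are added to ``source`` only when ``apply`` is true.
    """
    if mode not in ("direct", "transitive"):
        raise ValueError(f"bad mode {mode!r}")
    for m in mappings:
        tg = targets.get(m.target_ontology)
        if tg is None or m.target_id not in tg.concepts:
            raise OntologyError(
                f"mapping {m.source_iri} -> {m.target_ontology}:{m.target_id} "
                "does not resolve in its target graph"
            )

    by_onto: dict[str, list[MappingRecord]] = {}
    for m in mappings:
        by_onto.setdefault(m.target_ontology, []).append(m)

    proposals: dict[tuple[str, str], tuple[str, str, str]] = {}
    for onto_name, recs in sorted(by_onto.items()):
        tg = targets[onto_name]
        for child in recs:
            for parent in recs:
                if child.source_iri == parent.source_iri:
                    continue
                if child.target_id == parent.target_id:
                    continue
                if mode == "direct":
                    related = parent.target_id in tg.concepts[child.target_id].parents
                else:
                    related = is_subclass_of(tg, child.target_id, parent.target_id)
                if related:
                    key = (child.source_iri, parent.source_iri)
                    proposals.setdefault(
                        key, (onto_name, child.target_id, parent.target_id)
                    )

    if mode == "transitive" and proposals:
        g = nx.DiGraph(list(proposals))
        if nx.is_directed_acyclic_graph(g):
            keep = set(nx.transitive_reduction(g).edges())
            proposals = {k: v for k, v in proposals.items() if k in keep}

    original = source.copy()  # conflicts are judged against pre-existing edges
    work = source if apply else source.copy()
    edges: list[InducedEdge] = []
    for (child, parent), evidence in sorted(proposals.items()):
        if parent != child and is_subclass_of(original, parent, child):
            status = "rejected_conflict"
        else:
            status = "accepted"
            try:
                work.add_parent(child, parent)
            except OntologyError:
                status = "rejected_cycle"
        edges.append(InducedEdge(child, parent, evidence, status))
    work.validate()  # the source graph is never left cyclic
    return edges


# ---------------------------------------------------------------------
# CSV I/O

_CSV_FIELDS = ["source_iri", "target_ontology", "target_id", "match_type", "similarity"]


def write_mappings(records: Sequence[MappingRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for r in records:
            writer.writerow(
                [
                    r.source_iri,
                    r.target_ontology,
                    r.target_id,
                    r.match_type,
                    "" if r.similarity is None else repr(r.similarity),
                ]
            )


def read_mappings(path) -> list[MappingRecord]:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _CSV_FIELDS:
            raise ValueError(f"{path}: line 1: bad header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_CSV_FIELDS):
                raise ValueError(f"{path}: line {lineno}: expected "
                                 f"{len(_CSV_FIELDS)} columns, got {len(row)}")
            try:
                sim = float(row[4]) if row[4] else None
                records.append(MappingRecord(row[0], row[1], row[2], row[3], sim))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records


def mapping_counts(records: Sequence[MappingRecord]) -> dict[str, int]:
    """Per-target-ontology mapping tallies (the usual summary table)."""
    counts: dict[str, int] = {}
    for r in records:
        counts[r.target_ontology] = counts.get(r.target_ontology, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
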