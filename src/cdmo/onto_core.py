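"""Core ontology data model, OWL-subset I/O, subsumption and QC.

The model is deliberately restricted to the expressivity a
terminology-centred clinical ontology actually uses: named classes with a
Chinese preferred label, English names, Chinese synonyms, one definition
with a provenance source, free-form annotations, and simple named-class
``rdfs:subClassOf`` links.  Class expressions and restrictions found in an
input file are skipped with a warning, never an error.

Three serialisations are supported: Turtle and RDF/XML through rdflib
(``rdfs:label``, ``skos:altLabel``, ``skos:definition``,
``rdfs:subClassOf``), and a JSON dialect that mirrors the in-memory fields
exactly and therefore round-trips losslessly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
from rdflib import Graph as RDFGraph
from rdflib import Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL, SKOS

log = logging.getLogger(__name__)

CDMO = Namespace("https://w3id.org/cdmo/")
#: annotation predicates live under their own sub-namespace so arbitrary
#: (Chinese) annotation names can be percent-encoded into stable IRIs
ANN = Namespace("https://w3id.org/cdmo/ann/")

#: definition provenance sources, best first (see :func:`select_definition`)
DEFINITION_PRIORITY = ("termonline", "baidu", "CHPO", "MedDRA", "manual")


class OntologyError(Exception):
    """Raised for unresolvable references or invariant violations."""


@dataclass
class DefinitionRecord:
    """A definition string together with its provenance source."""

    text: str
    source: str = "manual"

    def __post_init__(self) -> None:
        if self.source not in DEFINITION_PRIORITY:
            raise ValueError(
                f"unknown definition source {self.source!r}; "
                f"expected one of {DEFINITION_PRIORITY}"
            )


@dataclass
class Concept:
    """A bilingual ontology class.

    Parameters
    ----------
    iri
        Opaque identifier, unique within an ontology.
    label_zh
        Chinese preferred label (non-empty).
    labels_en
        English names; the first is the preferred English name.
    synonyms_zh
        Chinese synonyms (``skos:altLabel@zh``).
    definition
        Optional :class:`DefinitionRecord`.
    annotations
        Free annotation-property map, e.g. ``"正常参考值"`` (normal
        reference value) or ``"诊断切点"`` (diagnostic cut-off).
    parents
        IRIs of direct is_a parents.
    """

    iri: str
    label_zh: str
    labels_en: list[str] = field(default_factory=list)
    synonyms_zh: list[str] = field(default_factory=list)
    definition: Optional[DefinitionRecord] = None
    annotations: dict[str, str] = field(default_factory=dict)
    parents: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label_zh:
            raise ValueError(f"concept {self.iri}: empty Chinese label")
        if self.iri in self.parents:
            raise ValueError(f"concept {self.iri}: self-parent")


@dataclass
class PropertyDef:
    """An object or annotation property with optional hierarchy and typing."""

    name_zh: str
    name_en: str = ""
    kind: str = "object"  # object | annotation
    parent: Optional[str] = None
    domain: list[str] = field(default_factory=list)
    range: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("object", "annotation"):
            raise ValueError(f"property {self.name_zh}: bad kind {self.kind!r}")


@dataclass
class QCReport:
    """Result of :func:`qc_report`; empty on a clean ontology."""

    cycles: list[list[str]] = field(default_factory=list)
    orphans: list[str] = field(default_factory=list)
    missing_definitions: list[str] = field(default_factory=list)
    duplicate_labels: list[tuple[str, list[str]]] = field(default_factory=list)
    domain_range_violations: list[tuple[tuple, str, str]] = field(default_factory=list)

    def is_clean(self) -> bool:
        return not (
            self.cycles
            or self.orphans
            or self.missing_definitions
            or self.duplicate_labels
            or self.domain_range_violations
        )

    def to_dict(self) -> dict:
        return {
            "cycles": self.cycles,
            "orphans": self.orphans,
            "missing_definitions": self.missing_definitions,
            "duplicate_labels": [[l, iris] for l, iris in self.duplicate_labels],
            "domain_range_violations": [
                [list(a), p, r] for a, p, r in self.domain_range_violations
            ],
            "clean": self.is_clean(),
        }


def _name_key(name: str) -> str:
    return " ".join(name.lower().replace("_", " ").replace("-", " ").replace("/", " ").split())


class OntologyGraph:
    """A set of concepts and properties forming an acyclic is_a DAG."""

    def __init__(self) -> None:
        self.concepts: dict[str, Concept] = {}
        self.properties: dict[str, PropertyDef] = {}
        self.roots: list[str] = []

    # -- construction -------------------------------------------------

    def add_concept(self, concept: Concept) -> None:
        if concept.iri in self.concepts:
            raise OntologyError(f"duplicate IRI {concept.iri}")
        self.concepts[concept.iri] = concept
        if not concept.parents and concept.iri not in self.roots:
            self.roots.append(concept.iri)

    def add_parent(self, child: str, parent: str) -> None:
        """Add an is_a edge; fails atomically if it would create a cycle."""
        for iri in (child, parent):
            if iri not in self.concepts:
                raise OntologyError(f"unknown IRI {iri}")
        if child == parent:
            raise OntologyError(f"self-parent {child}")
        if parent in self.concepts[child].parents:
            return
        if is_subclass_of(self, parent, child):
            raise OntologyError(f"edge {child} -> {parent} would create a cycle")
        self.concepts[child].parents.append(parent)
        if child in self.roots:
            self.roots.remove(child)

    # -- queries ------------------------------------------------------

    def children(self, iri: str) -> list[str]:
        return sorted(c.iri for c in self.concepts.values() if iri in c.parents)

    def find_by_label_zh(self, label: str) -> Optional[Concept]:
        for c in self.concepts.values():
            if c.label_zh == label:
                return c
        return None

    def find_by_name_en(self, name: str) -> Optional[Concept]:
        """Case-insensitive English-name lookup.

        Underscores and hyphens match spaces, so a rule predicate like
        ``glucagon_like_peptide_1_receptor_agonist`` resolves against the
        label "glucagon-like peptide-1 receptor agonist".
        """
        key = _name_key(name)
        for c in sorted(self.concepts.values(), key=lambda c: c.iri):
            for en in c.labels_en:
                if _name_key(en) == key:
                    return c
        return None

    def find_property(self, name: str) -> Optional[PropertyDef]:
        if name in self.properties:
            return self.properties[name]
        key = _name_key(name)
        for p in sorted(self.properties.values(), key=lambda p: p.name_zh):
            if p.name_en and _name_key(p.name_en) == key:
                return p
        return None

    def validate(self) -> None:
        """Check referential integrity and acyclicity; raise on failure."""
        for c in self.concepts.values():
            for p in c.parents:
                if p not in self.concepts:
                    raise OntologyError(f"{c.iri}: unresolved parent {p}")
        cyc = _find_cycles(self)
        if cyc:
            raise OntologyError(f"is_a cycle: {' -> '.join(cyc[0])}")
        for prop in self.properties.values():
            if prop.parent is not None:
                other = self.properties.get(prop.parent)
                if other is None or other.kind != prop.kind:
                    raise OntologyError(
                        f"property {prop.name_zh}: bad parent {prop.parent!r}"
                    )
            for iri in list(prop.domain) + list(prop.range):
                if iri not in self.concepts:
                    raise OntologyError(
                        f"property {prop.name_zh}: unresolved domain/range {iri}"
                    )

    def copy(self) -> "OntologyGraph":
        import copy as _copy

        return _copy.deepcopy(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyGraph):
            return NotImplemented
        return (
            {i: _concept_key(c) for i, c in self.concepts.items()}
            == {i: _concept_key(c) for i, c in other.concepts.items()}
            and self.properties.keys() == other.properties.keys()
            and sorted(self.roots) == sorted(other.roots)
        )


def _concept_key(c: Concept) -> tuple:
    d = (c.definition.text, c.definition.source) if c.definition else None
    return (
        c.label_zh,
        tuple(sorted(c.labels_en)),
        tuple(sorted(c.synonyms_zh)),
        d,
        tuple(sorted(c.annotations.items())),
        tuple(sorted(c.parents)),
    )


def _find_cycles(graph: OntologyGraph) -> list[list[str]]:
    g = nx.DiGraph()
    g.add_nodes_from(graph.concepts)
    for c in graph.concepts.values():
        for p in c.parents:
            if p in graph.concepts:
                g.add_edge(c.iri, p)
    return [sorted(cyc) for cyc in nx.simple_cycles(g)]


# ---------------------------------------------------------------------
# subsumption


def is_subclass_of(graph: OntologyGraph, a: str, b: str) -> bool:
    """Reflexive-transitive is_a: ``b`` reachable from ``a`` via parents."""
    for iri in (a, b):
        if iri not in graph.concepts:
            raise OntologyError(f"unknown IRI {iri}")
    if a == b:
        return True
    seen = {a}
    stack = [a]
    while stack:
        cur = stack.pop()
        for p in graph.concepts[cur].parents:
            if p == b:
                return True
            if p not in seen:
                seen.add(p)
                stack.append(p)
    return False


# ---------------------------------------------------------------------
# definition selection


def select_definition(candidates: list[DefinitionRecord]) -> DefinitionRecord:
    """Pick the definition with the best provenance source.

    Priority is termonline > baidu > CHPO > MedDRA > manual; ties within a
    source are broken by list order (first wins).
    """
    if not candidates:
        raise ValueError("no definition candidates")
    rank = {s: i for i, s in enumerate(DEFINITION_PRIORITY)}
    best = min(range(len(candidates)), key=lambda i: (rank[candidates[i].source], i))
    return candidates[best]


# ---------------------------------------------------------------------
# QC


def qc_report(graph: OntologyGraph, abox=None) -> QCReport:
    """Run structural quality checks; report-only, never raises.

    Checks: is_a cycles, orphans (non-root concepts without parents),
    missing definitions, duplicate Chinese labels, and — when an ABox is
    given — object-property assertions whose subject/object type does not
    fall under the property's declared domain/range.
    """
    report = QCReport()
    report.cycles = _find_cycles(graph)
    root_set = set(graph.roots)
    for c in sorted(graph.concepts.values(), key=lambda c: c.iri):
        if not c.parents and c.iri not in root_set:
            report.orphans.append(c.iri)
        if c.definition is None:
            report.missing_definitions.append(c.iri)
    by_label: dict[str, list[str]] = {}
    for c in graph.concepts.values():
        by_label.setdefault(c.label_zh, []).append(c.iri)
    for label, iris in sorted(by_label.items()):
        if len(iris) > 1:
            report.duplicate_labels.append((label, sorted(iris)))
    if abox is not None:
        report.domain_range_violations = _check_domain_range(graph, abox)
    return report


def _types_of(abox, individual: str) -> set[str]:
    return set(abox.individuals.get(individual, set()))


def _under_any(graph: OntologyGraph, types: set[str], allowed: list[str]) -> bool:
    for t in types:
        if t not in graph.concepts:
            continue
        for a in allowed:
            if a in graph.concepts and is_subclass_of(graph, t, a):
                return True
    return False


def _check_domain_range(graph, abox) -> list[tuple[tuple, str, str]]:
    out = []
    for prop_name, subj, obj in sorted(abox.object_assertions):
        prop = graph.find_property(prop_name)
        if prop is None:
            continue
        assertion = (prop_name, subj, obj)
        if prop.domain and not _under_any(graph, _types_of(abox, subj), prop.domain):
            out.append((assertion, prop_name, f"subject {subj} outside domain"))
        if prop.range and not _under_any(graph, _types_of(abox, obj), prop.range):
            out.append((assertion, prop_name, f"object {obj} outside range"))
    return out


# ---------------------------------------------------------------------
# I/O


def load_ontology(path, format: str = None) -> OntologyGraph:
    """Load an ontology from Turtle, RDF/XML or the JSON dialect.

    ``format`` is inferred from the suffix (.ttl/.rdf/.owl/.json) when not
    given.  Non-simple subclass axioms (restrictions, class expressions)
    are skipped with a logged warning.  A cyclic is_a after load raises.
    """
    path = Path(path)
    fmt = format or {"ttl": "turtle", "rdf": "rdfxml", "owl": "rdfxml", "json": "json"}.get(
        path.suffix.lstrip("."), "turtle"
    )
    if fmt == "json":
        graph = _from_json(json.loads(path.read_text(encoding="utf-8")))
    elif fmt in ("turtle", "rdfxml"):
        rg = RDFGraph()
        rg.parse(path, format="turtle" if fmt == "turtle" else "xml")
        graph = _from_rdf(rg)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    graph.validate()
    return graph


def save_ontology(graph: OntologyGraph, path, format: str = None) -> None:
    """Write an ontology; output is deterministic (concepts sorted by IRI)."""
    graph.validate()
    path = Path(path)
    fmt = format or {"ttl": "turtle", "rdf": "rdfxml", "owl": "rdfxml", "json": "json"}.get(
        path.suffix.lstrip("."), "turtle"
    )
    if fmt == "json":
        path.write_text(
            json.dumps(_to_json(graph), ensure_ascii=False, indent=1, sort_keys=True),
            encoding="utf-8",
        )
        return
    rg = _to_rdf(graph)
    data = rg.serialize(format="turtle" if fmt == "turtle" else "xml")
    path.write_text(data, encoding="utf-8")


# JSON dialect — mirrors the dataclass fields exactly


def _to_json(graph: OntologyGraph) -> dict:
    return {
        "concepts": [
            {
                "iri": c.iri,
                "label_zh": c.label_zh,
                "labels_en": list(c.labels_en),
                "synonyms_zh": list(c.synonyms_zh),
                "definition": (
                    {"text": c.definition.text, "source": c.definition.source}
                    if c.definition
                    else None
                ),
                "annotations": dict(c.annotations),
                "parents": sorted(c.parents),
            }
            for c in sorted(graph.concepts.values(), key=lambda c: c.iri)
        ],
        "properties": [
            {
                "name_zh": p.name_zh,
                "name_en": p.name_en,
                "kind": p.kind,
                "parent": p.parent,
                "domain": sorted(p.domain),
                "range": sorted(p.range),
            }
            for p in sorted(graph.properties.values(), key=lambda p: p.name_zh)
        ],
        "roots": sorted(graph.roots),
    }


def _from_json(data: dict) -> OntologyGraph:
    graph = OntologyGraph()
    for cd in data.get("concepts", []):
        d = cd.get("definition")
        graph.add_concept(
            Concept(
                iri=cd["iri"],
                label_zh=cd["label_zh"],
                labels_en=list(cd.get("labels_en", [])),
                synonyms_zh=list(cd.get("synonyms_zh", [])),
                definition=DefinitionRecord(d["text"], d["source"]) if d else None,
                annotations=dict(cd.get("annotations", {})),
                parents=list(cd.get("parents", [])),
            )
        )
    for pd in data.get("properties", []):
        graph.properties[pd["name_zh"]] = PropertyDef(
            name_zh=pd["name_zh"],
            name_en=pd.get("name_en", ""),
            kind=pd.get("kind", "object"),
            parent=pd.get("parent"),
            domain=list(pd.get("domain", [])),
            range=list(pd.get("range", [])),
        )
    graph.roots = sorted(
        data.get("roots")
        or [c.iri for c in graph.concepts.values() if not c.parents]
    )
    return graph


# RDF (Turtle / RDF-XML)

DEF_SOURCE = ANN["definition_source"]


def _ann_iri(name: str, prefix: str = "x") -> URIRef:
    # hex-encoded local names stay valid XML QNames (RDF/XML output),
    # unlike percent-encoding; prefix 'x' = annotation, 'p' = property
    return ANN[prefix + name.encode("utf-8").hex()]


def _ann_name(iri: str) -> Optional[tuple[str, str]]:
    """Reverse of :func:`_ann_iri`: (kind prefix, decoded name) or None."""
    if not iri.startswith(str(ANN)):
        return None
    local = iri[len(str(ANN)):]
    if len(local) < 2 or local[0] not in "xp":
        return None
    try:
        return local[0], bytes.fromhex(local[1:]).decode("utf-8")
    except ValueError:
        return None


def _to_rdf(graph: OntologyGraph) -> RDFGraph:
    rg = RDFGraph()
    rg.bind("cdmo", CDMO)
    rg.bind("cdmoa", ANN)
    rg.bind("skos", SKOS)
    rg.bind("owl", OWL)
    for c in sorted(graph.concepts.values(), key=lambda c: c.iri):
        node = URIRef(c.iri)
        rg.add((node, RDF.type, OWL.Class))
        rg.add((node, RDFS.label, Literal(c.label_zh, lang="zh")))
        for en in sorted(c.labels_en):
            rg.add((node, RDFS.label, Literal(en, lang="en")))
        for syn in sorted(c.synonyms_zh):
            rg.add((node, SKOS.altLabel, Literal(syn, lang="zh")))
        if c.definition:
            rg.add((node, SKOS.definition, Literal(c.definition.text, lang="zh")))
            rg.add((node, DEF_SOURCE, Literal(c.definition.source)))
        for name, value in sorted(c.annotations.items()):
            rg.add((node, _ann_iri(name), Literal(value)))
        for p in sorted(c.parents):
            rg.add((node, RDFS.subClassOf, URIRef(p)))
    for p in sorted(graph.properties.values(), key=lambda p: p.name_zh):
        node = _ann_iri(p.name_zh, "p")
        kind = OWL.ObjectProperty if p.kind == "object" else OWL.AnnotationProperty
        rg.add((node, RDF.type, kind))
        rg.add((node, RDFS.label, Literal(p.name_zh, lang="zh")))
        if p.name_en:
            rg.add((node, RDFS.label, Literal(p.name_en, lang="en")))
        if p.parent:
            rg.add((node, RDFS.subPropertyOf, _ann_iri(p.parent, "p")))
        for d in sorted(p.domain):
            rg.add((node, RDFS.domain, URIRef(d)))
        for r in sorted(p.range):
            rg.add((node, RDFS.range, URIRef(r)))
    return rg


def _from_rdf(rg: RDFGraph) -> OntologyGraph:
    graph = OntologyGraph()
    class_nodes = sorted(set(rg.subjects(RDF.type, OWL.Class)) | set(rg.subjects(RDF.type, RDFS.Class)))
    class_nodes = [n for n in class_nodes if isinstance(n, URIRef)]
    for node in class_nodes:
        label_zh, labels_en, synonyms = "", [], []
        for lab in rg.objects(node, RDFS.label):
            if getattr(lab, "language", None) == "en":
                labels_en.append(str(lab))
            elif not label_zh:
                label_zh = str(lab)
        for alt in rg.objects(node, SKOS.altLabel):
            if getattr(alt, "language", None) == "en":
                labels_en.append(str(alt))
            else:
                synonyms.append(str(alt))
        definition = None
        deftext = next(iter(rg.objects(node, SKOS.definition)), None)
        if deftext is not None:
            src = next(iter(rg.objects(node, DEF_SOURCE)), None)
            definition = DefinitionRecord(str(deftext), str(src) if src else "manual")
        annotations = {}
        for pred, obj in rg.predicate_objects(node):
            decoded = _ann_name(str(pred))
            if decoded and decoded[0] == "x":
                annotations[decoded[1]] = str(obj)
        parents = []
        for parent in rg.objects(node, RDFS.subClassOf):
            if isinstance(parent, URIRef):
                parents.append(str(parent))
            else:
                log.warning("skipping non-simple subclass axiom on %s", node)
        graph.add_concept(
            Concept(
                iri=str(node),
                label_zh=label_zh or str(node),
                labels_en=sorted(set(labels_en)),
                synonyms_zh=sorted(set(synonyms)),
                definition=definition,
                annotations=annotations,
                parents=sorted(parents),
            )
        )
    for kind, owl_kind in (("object", OWL.ObjectProperty), ("annotation", OWL.AnnotationProperty)):
        for node in sorted(rg.subjects(RDF.type, owl_kind)):
            name_zh, name_en = "", ""
            for lab in rg.objects(node, RDFS.label):
                if getattr(lab, "language", None) == "en":
                    name_en = str(lab)
                else:
                    name_zh = str(lab)
            if not name_zh:
                continue
            parent_node = next(iter(rg.objects(node, RDFS.subPropertyOf)), None)
            parent = None
            if parent_node is not None:
                decoded = _ann_name(str(parent_node))
                if decoded and decoded[0] == "p":
                    parent = decoded[1]
            graph.properties[name_zh] = PropertyDef(
                name_zh=name_zh,
                name_en=name_en,
                kind=kind,
                parent=parent,
                domain=sorted(str(d) for d in rg.objects(node, RDFS.domain)),
                range=sorted(str(r) for r in rg.objects(node, RDFS.range)),
            )
    if not class_nodes:
        log.warning("ontology file declared no classes")
    graph.roots = sorted(c.iri for c in graph.concepts.values() if not c.parents)
    return graph


def concept_iri(label_zh: str) -> str:
    """Stable opaque IRI for a concept: prefix + hash of the Chinese label.

    Labels can then change English names or synonyms without breaking
    links; two distinct Chinese labels collide with negligible probability.
    """
    import hashlib

    h = hashlib.sha1(label_zh.encode("utf-8")).hexdigest()[:12]
    return str(CDMO[f"C{h}"])
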