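"""SWRL-style rule parser and forward-chaining reasoner.

The rule dialect is positive Horn clauses over an ontology vocabulary::

    Diagnosis_1: patient(?p) ^ polyphagia(?s1) ^ ... ^
        patient_has_symptom(?p, ?s1) ^ test_has_value(?t1, ?v1) ^
        swrlb:greaterThanOrEqual(?v1, 7.0) -> patient_has_diagnosis(?p, ?d1)

Atoms are ``pred(arg, ...)``: one argument means a class atom, two a
property atom, ``swrlb:``-prefixed predicates are numeric builtins.
Arguments are variables (``?x``), numeric literals, or individual names.
``CDMO:``/``cdmo:`` namespace prefixes are stripped; both ``->`` and the
typographic ``—>`` arrow are accepted, and a stray right single quote
after a predicate name (an OCR-style artifact seen in published rule
tables) is tolerated.  ``#`` comment lines directly above a rule become
the rule's natural-language explanation.

Evaluation is classic set-at-a-time semi-naive fixpoint iteration:

- class atoms match every individual whose asserted (or derived) type is
  the atom's class *or any subclass of it* (subsumption-aware, OWL
  semantics);
- object-property atoms match only the asserted property by default; an
  option expands sub-properties using the TBox property hierarchy;
- data-property atoms bind variables to :class:`Quantity` values (number
  plus unit string); builtins compare raw numbers and refuse to compare
  two values carrying different non-empty units;
- consequent atoms add type or object-property assertions, which may
  trigger further rules, until a fixpoint is reached.

Every derived assertion keeps a trace (rule, full variable binding) so a
clinician-facing front end can show *why* a recommendation was made.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from cdmo.onto_core import OntologyGraph, OntologyError, is_subclass_of

__all__ = [
    "Atom",
    "Rule",
    "Variable",
    "Quantity",
    "KnowledgeBase",
    "InferenceResult",
    "ParseError",
    "EvaluationError",
    "parse_rule",
    "parse_rules",
    "load_rules",
    "match_class_atom",
    "eval_builtin",
    "forward_chain",
    "explain",
    "load_abox",
    "save_inferences",
    "BUILTINS",
]


class ParseError(ValueError):
    pass


class EvaluationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Variable:
    name: str

    def __repr__(self) -> str:
        return f"?{self.name}"


@dataclass(frozen=True)
class Quantity:
    """A numeric value with an (optionally empty) unit string."""

    value: float
    unit: str = ""


Term = Union[Variable, Quantity, str]


@dataclass(frozen=True)
class Atom:
    kind: str  # class | object_property | data_property | builtin
    predicate: str
    args: tuple

    def variables(self) -> set[str]:
        return {a.name for a in self.args if isinstance(a, Variable)}


@dataclass
class Rule:
    name: str
    antecedent: list[Atom]
    consequent: list[Atom]
    comment: str = ""

    def validate(self) -> None:
        bound = set().union(*(a.variables() for a in self.antecedent)) if self.antecedent else set()
        for atom in self.consequent:
            if atom.kind == "builtin":
                raise ParseError(f"rule {self.name}: builtin in consequent")
            unbound = atom.variables() - bound
            if unbound:
                raise ParseError(
                    f"rule {self.name}: unbound consequent variable "
                    f"?{sorted(unbound)[0]}"
                )


# ---------------------------------------------------------------------
# parsing

_ARROW_RE = re.compile(r"—>|->")
_ATOM_RE = re.compile(r"\s*([^\s(^]+)\s*\(([^)]*)\)\s*")
_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)$")


def _parse_term(token: str) -> Term:
    token = token.strip()
    if token.startswith("?"):
        return Variable(token[1:])
    if _NUM_RE.match(token):
        return Quantity(float(token))
    return token


def _clean_predicate(pred: str) -> tuple[str, bool]:
    pred = pred.strip().rstrip("'’")  # tolerate stray apostrophes
    builtin = False
    if pred.lower().startswith("swrlb:"):
        builtin = True
        pred = pred.split(":", 1)[1]
    elif ":" in pred:
        prefix, rest = pred.split(":", 1)
        if prefix.lower() == "cdmo":
            pred = rest
    return pred, builtin


def _parse_atoms(text: str, rule_name: str, side: str) -> list[Atom]:
    atoms = []
    offset = 0
    for chunk in text.split("^"):
        chunk_stripped = chunk.strip()
        if not chunk_stripped:
            offset += len(chunk) + 1
            continue
        m = _ATOM_RE.fullmatch(chunk)
        if not m:
            raise ParseError(
                f"rule {rule_name}: malformed atom in {side} at offset {offset}: "
                f"{chunk_stripped!r}"
            )
        pred, is_builtin = _clean_predicate(m.group(1))
        args = tuple(
            _parse_term(t) for t in m.group(2).split(",") if t.strip()
        )
        if is_builtin:
            if len(args) < 2:
                raise ParseError(
                    f"rule {rule_name}: builtin {pred} needs >= 2 arguments"
                )
            kind = "builtin"
        elif len(args) == 1:
            kind = "class"
        elif len(args) == 2:
            kind = "object_property"  # data vs object resolved at evaluation
        else:
            raise ParseError(
                f"rule {rule_name}: atom {pred} has {len(args)} arguments"
            )
        atoms.append(Atom(kind, pred, args))
        offset += len(chunk) + 1
    return atoms


def parse_rule(text: str, comment: str = "") -> Rule:
    """Parse ``name: antecedent -> consequent`` into a :class:`Rule`."""
    text = text.strip()
    if ":" not in text:
        raise ParseError("rule is missing a 'name:' prefix")
    name, body = text.split(":", 1)
    name = name.strip()
    parts = _ARROW_RE.split(body)
    if len(parts) != 2:
        raise ParseError(f"rule {name}: expected exactly one '->'")
    rule = Rule(
        name=name,
        antecedent=_parse_atoms(parts[0], name, "antecedent"),
        consequent=_parse_atoms(parts[1], name, "consequent"),
        comment=comment,
    )
    rule.validate()
    return rule


def parse_rules(text: str) -> list[Rule]:
    """Parse a rule file: blank-line-separated blocks, ``#`` comments.

    Comment lines directly above a rule are joined into the rule's
    natural-language explanation.  A rule may span multiple lines.
    """
    rules: list[Rule] = []
    names = set()
    comment_lines: list[str] = []
    block: list[str] = []

    def flush() -> None:
        if not block:
            return
        rule = parse_rule(" ".join(block), comment=" ".join(comment_lines))
        if rule.name in names:
            raise ParseError(f"duplicate rule name {rule.name}")
        names.add(rule.name)
        rules.append(rule)
        block.clear()
        comment_lines.clear()

    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            flush()
        elif stripped.startswith("#"):
            flush()
            comment_lines.append(stripped.lstrip("# "))
        else:
            block.append(stripped)
    flush()
    return rules


def load_rules(path) -> list[Rule]:
    return parse_rules(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------
# knowledge base

ObjAssertion = tuple[str, str, str]  # (property, subject, object)
DataAssertion = tuple[str, str, float, str]  # (property, subject, value, unit)


class KnowledgeBase:
    """TBox (ontology) + ABox (individuals and assertions)."""

    def __init__(self, tbox: OntologyGraph):
        self.tbox = tbox
        self.individuals: dict[str, set[str]] = {}
        self.object_assertions: set[ObjAssertion] = set()
        self.data_assertions: set[DataAssertion] = set()

    def add_individual(self, name: str, *type_iris: str) -> None:
        types = self.individuals.setdefault(name, set())
        for iri in type_iris:
            if iri not in self.tbox.concepts:
                raise OntologyError(f"individual {name}: unknown type {iri}")
            types.add(iri)

    def assert_object(self, prop: str, subject: str, obj: str) -> None:
        for ind in (subject, obj):
            self.individuals.setdefault(ind, set())
        self.object_assertions.add((prop, subject, obj))

    def assert_data(self, prop: str, subject: str, value: float, unit: str = "") -> None:
        if not (value == value and abs(value) != float("inf")):
            raise ValueError(f"non-finite value for {prop}({subject})")
        self.individuals.setdefault(subject, set())
        self.data_assertions.add((prop, subject, float(value), unit))

    def data_properties(self) -> set[str]:
        return {p for p, *_ in self.data_assertions}

    def copy(self) -> "KnowledgeBase":
        kb = KnowledgeBase(self.tbox)
        kb.individuals = {k: set(v) for k, v in self.individuals.items()}
        kb.object_assertions = set(self.object_assertions)
        kb.data_assertions = set(self.data_assertions)
        return kb


@dataclass
class InferenceResult:
    derived: set = field(default_factory=set)
    trace: list = field(default_factory=list)  # (rule, binding dict, assertion)
    iterations: int = 0


# ---------------------------------------------------------------------
# matching

BUILTINS = {
    "greaterThanOrEqual": lambda a, b: a >= b,
    "greaterThan": lambda a, b: a > b,
    "lessThanOrEqual": lambda a, b: a <= b,
    "lessThan": lambda a, b: a < b,
    "equal": lambda a, b: a == b,
    "notEqual": lambda a, b: a != b,
}


def eval_builtin(predicate: str, args: Sequence) -> bool:
    """Evaluate a numeric builtin on fully bound arguments."""
    fn = BUILTINS.get(predicate)
    if fn is None:
        raise EvaluationError(f"unknown builtin {predicate}")
    values, units = [], []
    for a in args:
        if isinstance(a, Variable):
            raise EvaluationError(
                f"builtin {predicate}: unbound argument ?{a.name} "
                "(builtins never bind variables)"
            )
        if isinstance(a, Quantity):
            values.append(a.value)
            if a.unit:
                units.append(a.unit)
        elif isinstance(a, (int, float)):
            values.append(float(a))
        else:
            raise EvaluationError(f"builtin {predicate}: non-numeric argument {a!r}")
    if len(set(units)) > 1:
        raise EvaluationError(
            f"builtin {predicate}: incomparable units {sorted(set(units))}"
        )
    return fn(*values[:2])


def _resolve_class(tbox: OntologyGraph, predicate: str) -> str:
    concept = tbox.find_by_name_en(predicate) or tbox.find_by_label_zh(predicate)
    if concept is None and predicate in tbox.concepts:
        return predicate
    if concept is None:
        raise OntologyError(f"class atom predicate {predicate!r} not in ontology")
    return concept.iri


def _class_members(kb: KnowledgeBase, class_iri: str) -> list[str]:
    out = []
    for ind, types in kb.individuals.items():
        for t in types:
            if is_subclass_of(kb.tbox, t, class_iri):
                out.append(ind)
                break
    return sorted(out)


def match_class_atom(kb: KnowledgeBase, atom: Atom, binding: dict) -> Iterable[dict]:
    """Extend ``binding`` over individuals typed under the atom's class."""
    class_iri = _resolve_class(kb.tbox, atom.predicate)
    (arg,) = atom.args
    if isinstance(arg, Variable):
        if arg.name in binding:
            if binding[arg.name] in _class_members(kb, class_iri):
                yield binding
            return
        for ind in _class_members(kb, class_iri):
            yield {**binding, arg.name: ind}
    else:
        if arg in _class_members(kb, class_iri):
            yield binding


def _unify(term, value, binding: dict) -> Optional[dict]:
    if isinstance(term, Variable):
        if term.name in binding:
            return binding if binding[term.name] == value else None
        return {**binding, term.name: value}
    if isinstance(term, Quantity) and isinstance(value, Quantity):
        return binding if term.value == value.value else None
    return binding if term == value else None


def _sub_properties(tbox: OntologyGraph, prop_name: str) -> set[str]:
    """prop_name plus every (transitive) sub-property, by zh or en name."""
    prop = tbox.find_property(prop_name)
    if prop is None:
        return {prop_name}
    names = {prop.name_zh, prop.name_en} - {""}
    frontier = {prop.name_zh}
    while frontier:
        nxt = set()
        for p in tbox.properties.values():
            if p.parent in frontier and p.name_zh not in names:
                names |= {p.name_zh, p.name_en} - {""}
                nxt.add(p.name_zh)
        frontier = nxt
    return names | {prop_name}


def _match_atom(
    kb: KnowledgeBase,
    atom: Atom,
    binding: dict,
    restrict: Optional[set] = None,
    expand_subproperties: bool = False,
) -> Iterable[dict]:
    """Extend a binding over one atom; ``restrict`` limits the assertion
    pool (semi-naive delta evaluation)."""
    if atom.kind == "class":
        if restrict is not None:
            class_iri = _resolve_class(kb.tbox, atom.predicate)
            (arg,) = atom.args
            for item in restrict:
                if item[0] != "type":
                    continue
                _, ind, type_iri = item
                if not is_subclass_of(kb.tbox, type_iri, class_iri):
                    continue
                nb = _unify(arg, ind, binding)
                if nb is not None:
                    yield nb
        else:
            yield from match_class_atom(kb, atom, binding)
        return
    if atom.kind == "builtin":
        bound_args = [
            binding.get(a.name, a) if isinstance(a, Variable) else a for a in atom.args
        ]
        if eval_builtin(atom.predicate, bound_args):
            yield binding
        return
    preds = (
        _sub_properties(kb.tbox, atom.predicate)
        if expand_subproperties
        else {atom.predicate}
    )
    s_term, o_term = atom.args
    if atom.predicate in kb.data_properties():
        pool = kb.data_assertions if restrict is None else {
            i[1:] for i in restrict if i[0] == "data"
        }
        for prop, subj, value, unit in sorted(pool):
            if prop not in preds:
                continue
            nb = _unify(s_term, subj, binding)
            if nb is None:
                continue
            nb = _unify(o_term, Quantity(value, unit), nb)
            if nb is not None:
                yield nb
    else:
        pool = kb.object_assertions if restrict is None else {
            i[1:] for i in restrict if i[0] == "obj"
        }
        for prop, subj, obj in sorted(pool):
            if prop not in preds:
                continue
            nb = _unify(s_term, subj, binding)
            if nb is None:
                continue
            nb = _unify(o_term, obj, nb)
            if nb is not None:
                yield nb


def _match_rule(
    kb: KnowledgeBase,
    rule: Rule,
    delta: Optional[set],
    expand_subproperties: bool,
) -> Iterable[dict]:
    """All satisfying bindings; with a delta, at least one non-builtin atom
    must match a delta assertion (standard semi-naive restriction)."""
    non_builtin = [i for i, a in enumerate(rule.antecedent) if a.kind != "builtin"]
    delta_positions: Sequence[Optional[int]] = (
        [None] if delta is None else non_builtin
    )
    seen: set[tuple] = set()
    for dpos in delta_positions:
        # reorder: evaluate builtins only after other atoms (their variables
        # must be bound); printed rules already satisfy this but reordering
        # makes evaluation order-insensitive
        order = non_builtin + [
            i for i, a in enumerate(rule.antecedent) if a.kind == "builtin"
        ]
        results = [{}]
        for idx in order:
            atom = rule.antecedent[idx]
            restrict = delta if (dpos is not None and idx == dpos) else None
            nxt = []
            for b in results:
                nxt.extend(
                    _match_atom(kb, atom, b, restrict, expand_subproperties)
                )
            results = nxt
            if not results:
                break
        for b in results:
            key = tuple(sorted(b.items()))
            if key not in seen:
                seen.add(key)
                yield b


def _instantiate(kb: KnowledgeBase, atom: Atom, binding: dict):
    """Ground a consequent atom into a ('type'|'obj', ...) assertion."""
    def ground(term):
        if isinstance(term, Variable):
            return binding[term.name]
        return term

    if atom.kind == "class":
        class_iri = _resolve_class(kb.tbox, atom.predicate)
        return ("type", ground(atom.args[0]), class_iri)
    s, o = (ground(t) for t in atom.args)
    return ("obj", atom.predicate, s, o)


def _holds(kb: KnowledgeBase, assertion) -> bool:
    if assertion[0] == "type":
        _, ind, iri = assertion
        return iri in kb.individuals.get(ind, set())
    _, prop, s, o = assertion
    return (prop, s, o) in kb.object_assertions


def _add(kb: KnowledgeBase, assertion) -> None:
    if assertion[0] == "type":
        kb.add_individual(assertion[1], assertion[2])
    else:
        kb.assert_object(assertion[1], assertion[2], assertion[3])


def forward_chain(
    kb: KnowledgeBase,
    rules: Sequence[Rule],
    max_iterations: int = 100,
    expand_subproperties: bool = False,
    in_place: bool = False,
) -> InferenceResult:
    """Run all rules to fixpoint (semi-naive evaluation).

    Returns the set of newly derived type/object assertions with a trace
    entry per (rule, binding) firing.  Re-running on the closure derives
    nothing; the closure is independent of rule and assertion order.
    """
    work = kb if in_place else kb.copy()
    result = InferenceResult()
    delta: Optional[set] = None  # None = first pass over everything
    while True:
        result.iterations += 1
        if result.iterations > max_iterations:
            last = sorted(delta or [])[:10]
            raise EvaluationError(
                f"forward chaining did not converge in {max_iterations} "
                f"iterations; last added: {last}"
            )
        new_delta: set = set()
        trace_keys = {
            (r, frozenset(b.items()), a) for r, b, a in result.trace
        }
        for rule in rules:
            for binding in _match_rule(work, rule, delta, expand_subproperties):
                for atom in rule.consequent:
                    assertion = _instantiate(work, atom, binding)
                    if assertion in result.derived:
                        # alternative derivation of a known fact: keep trace
                        key = (rule.name, frozenset(binding.items()), assertion)
                        if key not in trace_keys:
                            trace_keys.add(key)
                            result.trace.append((rule.name, dict(binding), assertion))
                        continue
                    if _holds(work, assertion):
                        continue  # initially asserted, never counts as derived
                    new_delta.add(assertion)
                    result.derived.add(assertion)
                    trace_keys.add((rule.name, frozenset(binding.items()), assertion))
                    result.trace.append((rule.name, dict(binding), assertion))
        if not new_delta:
            break
        for assertion in new_delta:
            _add(work, assertion)
        delta = new_delta
    return result


def explain(result: InferenceResult, assertion) -> list[tuple]:
    """Trace entries (rule name, binding, assertion) for a derived fact."""
    if assertion not in result.derived:
        raise LookupError(f"assertion {assertion!r} was not derived")
    return [t for t in result.trace if t[2] == assertion]


# ---------------------------------------------------------------------
# ABox JSON I/O

def load_abox(path, tbox: OntologyGraph) -> KnowledgeBase:
    """Read a patient ABox JSON file into a knowledge base.

    Schema: ``{"individuals": [{"name", "types": [...]}],
    "object_assertions": [[prop, s, o]],
    "data_assertions": [[prop, s, value, unit]]}``.  Types may be IRIs,
    Chinese labels, or English names.
    """
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    kb = KnowledgeBase(tbox)
    for ind in data.get("individuals", []):
        iris = []
        for t in ind.get("types", []):
            if t in tbox.concepts:
                iris.append(t)
            else:
                c = tbox.find_by_label_zh(t) or tbox.find_by_name_en(t)
                if c is None:
                    raise OntologyError(f"individual {ind['name']}: unknown type {t!r}")
                iris.append(c.iri)
        kb.add_individual(ind["name"], *iris)
    for prop, s, o in data.get("object_assertions", []):
        kb.assert_object(prop, s, o)
    for prop, s, value, *unit in data.get("data_assertions", []):
        kb.assert_data(prop, s, value, unit[0] if unit else "")
    return kb


def save_inferences(result: InferenceResult, path, kb: Optional[KnowledgeBase] = None,
                    include_trace: bool = True) -> None:
    out = {
        "derived": sorted(list(a) for a in result.derived),
        "iterations": result.iterations,
    }
    if include_trace:
        out["trace"] = [
            {"rule": r, "binding": {k: _json_term(v) for k, v in b.items()},
             "assertion": list(a)}
            for r, b, a in result.trace
        ]
    Path(path).write_text(
        json.dumps(out, ensure_ascii=False, indent=1), encoding="utf-8"
    )


def _json_term(v):
    if isinstance(v, Quantity):
        return {"value": v.value, "unit": v.unit}
    return v
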