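"""Independent brute-force oracles, deliberately naive.

Each re-implements a checked operation from first principles with no code
shared with the package internals: substring scanning by trying every
position, reachability by depth-first search, rule evaluation by naive
fixpoint over explicit nested matching, BM25 by writing the formula out
term by term.
"""

from __future__ import annotations

import math


def naive_substring_scan(lexicon, text):
    """Every (end_index, entry) pair, by trying all positions."""
    hits = []
    for i in range(len(text)):
        for entry in sorted(set(lexicon)):
            start = i - len(entry) + 1
            if start >= 0 and text[start : i + 1] == entry:
                hits.append((i, entry))
    return hits


def reachable(parent_map, a, b):
    """Depth-first reflexive reachability over a child->parents map."""
    if a == b:
        return True
    seen, stack = set(), [a]
    while stack:
        cur = stack.pop()
        if cur == b:
            return True
        if cur in seen:
            continue
        seen.add(cur)
        stack.extend(parent_map.get(cur, []))
    return False


# ---------------------------------------------------------------------
# naive rule evaluation (full re-scan each pass, no deltas)


def _ancestors(parent_map, node):
    out, stack = {node}, [node]
    while stack:
        for p in parent_map.get(stack.pop(), []):
            if p not in out:
                out.add(p)
                stack.append(p)
    return out


def _naive_match(atoms, state, tbox_parents, class_of, binding):
    """Yield bindings satisfying the atom list, left to right."""
    if not atoms:
        yield dict(binding)
        return
    atom, rest = atoms[0], atoms[1:]
    kind, pred, args = atom

    def unify(term, value, b):
        if isinstance(term, str) and term.startswith("?"):
            if term in b:
                return b if b[term] == value else None
            nb = dict(b)
            nb[term] = value
            return nb
        return b if term == value else None

    if kind == "class":
        class_iri = class_of(pred)
        for ind, types in sorted(state["types"].items()):
            if any(class_iri in _ancestors(tbox_parents, t) for t in types):
                nb = unify(args[0], ind, binding)
                if nb is not None:
                    yield from _naive_match(rest, state, tbox_parents, class_of, nb)
    elif kind == "builtin":
        ops = {
            "greaterThanOrEqual": lambda a, b: a >= b,
            "greaterThan": lambda a, b: a > b,
            "lessThanOrEqual": lambda a, b: a <= b,
            "lessThan": lambda a, b: a < b,
            "equal": lambda a, b: a == b,
            "notEqual": lambda a, b: a != b,
        }
        vals = [binding[a] if isinstance(a, str) and a.startswith("?") else a for a in args]
        if ops[pred](*vals):
            yield from _naive_match(rest, state, tbox_parents, class_of, binding)
    elif pred in state["data_props"]:
        for (p, s, v, _u) in sorted(state["data"]):
            if p != pred:
                continue
            nb = unify(args[0], s, binding)
            if nb is None:
                continue
            nb = unify(args[1], v, nb)
            if nb is not None:
                yield from _naive_match(rest, state, tbox_parents, class_of, nb)
    else:
        for (p, s, o) in sorted(state["obj"]):
            if p != pred:
                continue
            nb = unify(args[0], s, binding)
            if nb is None:
                continue
            nb = unify(args[1], o, nb)
            if nb is not None:
                yield from _naive_match(rest, state, tbox_parents, class_of, nb)


def naive_forward_chain(kb, rules, class_of):
    """Naive fixpoint: re-evaluate every rule over everything each pass.

    ``kb`` is a cdmo KnowledgeBase (read only); rules are cdmo Rules,
    translated here into plain tuples.  Returns the set of derived
    assertions in the package's ('type'|'obj', ...) shape.
    """
    tbox_parents = {i: list(c.parents) for i, c in kb.tbox.concepts.items()}

    def tr_term(t):
        from cdmo.rule_engine import Quantity, Variable

        if isinstance(t, Variable):
            return "?" + t.name
        if isinstance(t, Quantity):
            return t.value
        return t

    def tr_atoms(atoms):
        out = []
        for a in atoms:
            kind = "builtin" if a.kind == "builtin" else (
                "class" if a.kind == "class" else "prop"
            )
            out.append((kind, a.predicate, [tr_term(t) for t in a.args]))
        # builtins last so their variables are bound
        return [a for a in out if a[0] != "builtin"] + [a for a in out if a[0] == "builtin"]

    state = {
        "types": {i: set(ts) for i, ts in kb.individuals.items()},
        "obj": set(kb.object_assertions),
        "data": {(p, s, v, u) for (p, s, v, u) in kb.data_assertions},
        "data_props": {p for (p, *_r) in kb.data_assertions},
    }
    initial_obj = set(state["obj"])
    initial_types = {(i, t) for i, ts in state["types"].items() for t in ts}
    derived = set()
    changed = True
    while changed:
        changed = False
        for rule in rules:
            for binding in _naive_match(
                tr_atoms(rule.antecedent), state, tbox_parents, class_of, {}
            ):
                for atom in rule.consequent:
                    kind = "class" if atom.kind == "class" else "prop"
                    args = [
                        binding["?" + t.name] if hasattr(t, "name") else t
                        for t in atom.args
                    ]
                    if kind == "class":
                        fact = ("type", args[0], class_of(atom.predicate))
                        if fact[2] not in state["types"].setdefault(args[0], set()):
                            state["types"][args[0]].add(fact[2])
                            if (args[0], fact[2]) not in initial_types:
                                derived.add(fact)
                            changed = True
                    else:
                        triple = (atom.predicate, args[0], args[1])
                        if triple not in state["obj"]:
                            state["obj"].add(triple)
                            state["types"].setdefault(args[0], set())
                            state["types"].setdefault(args[1], set())
                            if triple not in initial_obj:
                                derived.add(("obj",) + triple)
                            changed = True
    return derived


def bm25_direct(query_tokens, doc_token_lists, k1, b):
    """Okapi BM25 written out longhand, one score per document."""
    n = len(doc_token_lists)
    avgdl = sum(len(d) for d in doc_token_lists) / n
    scores = []
    for tokens in doc_token_lists:
        score = 0.0
        for t in query_tokens:
            tf = tokens.count(t)
            if tf == 0:
                continue
            df = sum(1 for d in doc_token_lists if t in d)
            idf = math.log(1 + (n - df + 0.5) / (df + 0.5))
            score += idf * (tf * (k1 + 1)) / (tf + k1 * (1 - b + b * len(tokens) / avgdl))
        scores.append(score)
    return scores
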