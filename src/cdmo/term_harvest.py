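"""Dictionary-automaton term harvesting from a Chinese corpus.

Pipeline (order matters and is part of the contract):

1. :func:`build_matcher` / :func:`scan_corpus` — Aho-Corasick matching of a
   term lexicon against every document, counting *document* frequency
   (distinct documents containing the surface, not occurrences);
2. :func:`exclude_pattern_terms` — drop grade/degree surfaces such as
   "1级" (grade 1) or "3期" (stage 3) and an editable stoplist
   (seeded with "全部", "all");
3. :func:`frequency_filter` — keep a candidate only if it has a lexicon /
   term-bank / encyclopedia entry AND appears in at least ``min_docs``
   distinct documents (both conditions conjunctive);
4. :func:`merge_synonyms` — union-find merging of surfaces that share an
   English name (e.g. 黑棘皮症 / 黑棘皮病 → "acanthosis nigricans") or are
   listed as literal synonym pairs.

The Aho-Corasick automaton is implemented here (trie + BFS failure links);
its match set is required to equal a naive all-positions substring scan,
which the test suite asserts on randomised inputs.
"""

from __future__ import annotations

import re
import unicodedata
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "Document",
    "TermCandidate",
    "HarvestReport",
    "Matcher",
    "build_matcher",
    "scan_corpus",
    "exclude_pattern_terms",
    "frequency_filter",
    "merge_synonyms",
    "harvest_report",
    "DEFAULT_STOPLIST",
    "GRADE_DEGREE_RE",
]

DEFAULT_STOPLIST = ["全部"]

# digits (ASCII or fullwidth) or Chinese numerals followed by a
# grade/stage/degree/type suffix, as the *entire* surface
GRADE_DEGREE_RE = re.compile(r"^[0-9０-９一二三四五六七八九十百]+[级期度型]$")


@dataclass
class Document:
    doc_id: str
    text: str
    source: str = ""


@dataclass
class TermCandidate:
    """A harvested surface form with document-level bookkeeping."""

    surface: str
    doc_ids: set[str] = field(default_factory=set)
    lexicon_sources: set[str] = field(default_factory=set)
    merged_into: Optional[str] = None

    @property
    def doc_frequency(self) -> int:
        return len(self.doc_ids)


@dataclass
class HarvestReport:
    n_scanned: int
    n_after_exclusion: int
    n_after_filter: int
    n_after_merge: int
    retention_pct: float


class Matcher:
    """Aho-Corasick automaton over Unicode codepoints.

    Both the lexicon and scanned text are NFC-normalised first so that
    composed/decomposed variants (a common OCR artifact) match.
    """

    def __init__(self, lexicon: Iterable[str]):
        entries = sorted({unicodedata.normalize("NFC", e) for e in lexicon})
        if not entries or any(not e for e in entries):
            raise ValueError("lexicon must be non-empty strings")
        self._entries = entries
        # trie: list of dicts char -> state; output: entries ending at state
        self._goto: list[dict[str, int]] = [{}]
        self._out: list[list[str]] = [[]]
        for entry in entries:
            state = 0
            for ch in entry:
                nxt = self._goto[state].get(ch)
                if nxt is None:
                    self._goto.append({})
                    self._out.append([])
                    nxt = len(self._goto) - 1
                    self._goto[state][ch] = nxt
                state = nxt
            self._out[state].append(entry)
        # failure links by BFS
        self._fail = [0] * len(self._goto)
        queue = deque(self._goto[0].values())
        while queue:
            state = queue.popleft()
            for ch, nxt in self._goto[state].items():
                queue.append(nxt)
                f = self._fail[state]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                self._fail[nxt] = self._goto[f].get(ch, 0)
                if self._fail[nxt] == nxt:
                    self._fail[nxt] = 0
                self._out[nxt] = self._out[nxt] + self._out[self._fail[nxt]]

    @property
    def entries(self) -> list[str]:
        return list(self._entries)

    def find(self, text: str) -> list[tuple[int, str]]:
        """All (end_index, entry) hits, overlapping included, in scan order."""
        text = unicodedata.normalize("NFC", text)
        hits: list[tuple[int, str]] = []
        state = 0
        for i, ch in enumerate(text):
            while state and ch not in self._goto[state]:
                state = self._fail[state]
            state = self._goto[state].get(ch, 0)
            for entry in self._out[state]:
                hits.append((i, entry))
        return hits


def build_matcher(lexicon: Sequence[str]) -> Matcher:
    """Build an automaton recognising every lexicon entry as a substring."""
    if not lexicon:
        raise ValueError("empty lexicon")
    return Matcher(lexicon)


def scan_corpus(corpus: Sequence[Document], matcher: Matcher) -> list[TermCandidate]:
    """One candidate per distinct matched surface, with its document set."""
    by_surface: dict[str, TermCandidate] = {}
    for doc in corpus:
        for _, surface in matcher.find(doc.text):
            cand = by_surface.get(surface)
            if cand is None:
                cand = by_surface[surface] = TermCandidate(surface)
            cand.doc_ids.add(doc.doc_id)
    return [by_surface[s] for s in sorted(by_surface)]


def exclude_pattern_terms(
    candidates: Sequence[TermCandidate],
    stoplist: Sequence[str] = DEFAULT_STOPLIST,
) -> list[TermCandidate]:
    """Drop grade/degree surfaces (e.g. "1级", "3期") and stoplisted ones."""
    stop = set(stoplist)
    return [
        c
        for c in candidates
        if c.surface not in stop and not GRADE_DEGREE_RE.match(c.surface)
    ]


def frequency_filter(
    candidates: Sequence[TermCandidate],
    lexicon_presence: set[str],
    min_docs: int = 3,
) -> list[TermCandidate]:
    """Keep candidates with a known entry AND >= ``min_docs`` documents."""
    if min_docs < 1:
        raise ValueError("min_docs must be >= 1")
    return [
        c
        for c in candidates
        if c.surface in lexicon_presence and c.doc_frequency >= min_docs
    ]


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_synonyms(
    candidates: Sequence[TermCandidate],
    english_names: dict[str, set[str]] | None = None,
    synonym_pairs: Sequence[tuple[str, str]] = (),
) -> list[TermCandidate]:
    """Group candidates that share an English name or are listed as synonyms.

    Union-find over the relation {share >= 1 English name} ∪ {listed
    pairs}.  Each group's canonical surface is the lexicographically
    smallest member; ``merged_into`` is set on non-canonical members and
    the canonical candidate absorbs the group's doc_ids and sources.
    """
    english_names = english_names or {}
    surfaces = {c.surface for c in candidates}
    uf = _UnionFind()
    for s in surfaces:
        uf.find(s)
    by_en: dict[str, list[str]] = {}
    for surface, names in english_names.items():
        if surface not in surfaces:
            continue
        for name in names:
            by_en.setdefault(name.lower(), []).append(surface)
    for members in by_en.values():
        for other in members[1:]:
            uf.union(members[0], other)
    for a, b in synonym_pairs:
        if a in surfaces and b in surfaces:
            uf.union(a, b)
    groups: dict[str, list[TermCandidate]] = {}
    for c in candidates:
        groups.setdefault(uf.find(c.surface), []).append(c)
    out: list[TermCandidate] = []
    for members in groups.values():
        canonical = min(m.surface for m in members)
        all_docs = set().union(*(m.doc_ids for m in members))
        all_sources = set().union(*(m.lexicon_sources for m in members))
        for m in members:
            merged = TermCandidate(
                surface=m.surface,
                doc_ids=set(all_docs) if m.surface == canonical else set(m.doc_ids),
                lexicon_sources=set(all_sources)
                if m.surface == canonical
                else set(m.lexicon_sources),
                merged_into=None if m.surface == canonical else canonical,
            )
            out.append(merged)
    return sorted(out, key=lambda c: c.surface)


def harvest_report(n_recognized: int, stage_counts: dict[str, int]) -> HarvestReport:
    """Summarise the pipeline; retention_pct = 100 * retained / recognized.

    ``stage_counts`` carries ``after_exclusion``, ``after_filter`` and
    ``after_merge``; the retained count is the final (after_merge) one.
    """
    if n_recognized <= 0:
        raise ValueError("n_recognized must be positive")
    retained = stage_counts["after_merge"]
    return HarvestReport(
        n_scanned=n_recognized,
        n_after_exclusion=stage_counts["after_exclusion"],
        n_after_filter=stage_counts["after_filter"],
        n_after_merge=retained,
        retention_pct=round(100.0 * retained / n_recognized, 2),
    )
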