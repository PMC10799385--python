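"""Ontology-knowledge injection for question answering.

Given a Chinese medical question, the most relevant concept definitions
are retrieved from the ontology with Okapi BM25 and concatenated into a
prompt of the form ``Question: {Q}, Evidences: {D1}, ..., {Dn}`` for a
downstream text-to-text model (whose training/inference is outside this
package).  ROUGE-1/2/L F1 utilities score generated answers against
references at the character level, the standard unit for Chinese.

Tokenisation defaults to overlapping character bigrams, which behaves
well for Chinese without a word segmenter; a crude regex ``word`` mode
(CJK characters as singletons, latin runs as words) is also provided.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from cdmo.onto_core import OntologyGraph

__all__ = [
    "EvidenceDoc",
    "RetrievalConfig",
    "RougeScores",
    "tokenize",
    "bm25_rank",
    "retrieve_evidence",
    "build_prompt",
    "parse_prompt",
    "rouge_scores",
]


@dataclass
class EvidenceDoc:
    concept_iri: str
    text: str
    tokens: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("evidence text must be non-empty")


@dataclass
class RetrievalConfig:
    """BM25 retrieval settings.

    ``n`` evidences are returned; ``k1`` (term-frequency saturation) and
    ``b`` (length normalisation) default to the standard Okapi values.
    """

    n: int = 3
    k1: float = 1.5
    b: float = 0.75
    tokenizer: str = "char_bigram"

    def __post_init__(self) -> None:
        if self.n < 1 or self.k1 <= 0 or not 0 <= self.b <= 1:
            raise ValueError("invalid retrieval config")


@dataclass
class RougeScores:
    rouge1: float
    rouge2: float
    rougeL: float


_WORD_RE = re.compile(r"[a-zA-Z0-9]+|[一-鿿]")


def tokenize(text: str, mode: str = "char_bigram") -> list[str]:
    """Deterministic tokenisation; ``char_bigram`` is the default.

    char_bigram emits overlapping character bigrams (a single character
    for length-1 text); ``word`` emits latin/digit runs and individual
    CJK characters; ``char`` emits single characters.
    """
    if mode == "char_bigram":
        if len(text) <= 1:
            return [text] if text else []
        return [text[i : i + 2] for i in range(len(text) - 1)]
    if mode == "char":
        return list(text)
    if mode == "word":
        return _WORD_RE.findall(text)
    raise ValueError(f"unknown tokenizer mode {mode!r}")


def bm25_rank(
    query: str,
    docs: Sequence[EvidenceDoc],
    config: Optional[RetrievalConfig] = None,
) -> list[tuple[EvidenceDoc, float]]:
    """Score all docs against the query with Okapi BM25, best first.

    IDF is the smoothed, non-negative variant
    ``log(1 + (N - df + 0.5) / (df + 0.5))``.  Ties keep document order.
    """
    config = config or RetrievalConfig()
    if not docs:
        raise ValueError("empty document list")
    for d in docs:
        if not d.tokens:
            d.tokens = tokenize(d.text, config.tokenizer)
    n_docs = len(docs)
    avg_len = sum(len(d.tokens) for d in docs) / n_docs
    df: dict[str, int] = {}
    for d in docs:
        for t in set(d.tokens):
            df[t] = df.get(t, 0) + 1
    q_tokens = tokenize(query, config.tokenizer)
    scored = []
    for pos, d in enumerate(docs):
        tf: dict[str, int] = {}
        for t in d.tokens:
            tf[t] = tf.get(t, 0) + 1
        score = 0.0
        for t in q_tokens:
            f = tf.get(t, 0)
            if f == 0:
                continue
            idf = math.log(1.0 + (n_docs - df[t] + 0.5) / (df[t] + 0.5))
            denom = f + config.k1 * (
                1.0 - config.b + config.b * len(d.tokens) / avg_len
            )
            score += idf * f * (config.k1 + 1.0) / denom
        scored.append((pos, d, score))
    scored.sort(key=lambda x: (-x[2], x[0]))
    return [(d, s) for _, d, s in scored]


def evidence_docs(ontology: OntologyGraph) -> list[EvidenceDoc]:
    """One evidence document per concept definition, sorted by IRI."""
    return [
        EvidenceDoc(c.iri, c.definition.text)
        for c in sorted(ontology.concepts.values(), key=lambda c: c.iri)
        if c.definition and c.definition.text
    ]


def retrieve_evidence(
    question: str,
    ontology: OntologyGraph,
    config: Optional[RetrievalConfig] = None,
) -> list[EvidenceDoc]:
    """Top-n concept definitions for a question, by BM25."""
    config = config or RetrievalConfig()
    docs = evidence_docs(ontology)
    if not docs:
        raise ValueError("ontology has no concept definitions to retrieve from")
    ranked = bm25_rank(question, docs, config)
    return [d for d, _ in ranked[: config.n]]


def build_prompt(question: str, evidences: Sequence[EvidenceDoc]) -> str:
    """``Question: {Q}, Evidences: {D1}, ..., {Dn}`` in retrieval order."""
    body = ", ".join(e.text for e in evidences)
    return f"Question: {question}, Evidences: {body}"


def parse_prompt(prompt: str) -> tuple[str, list[str]]:
    """Inverse of :func:`build_prompt` (for prompt auditing)."""
    m = re.fullmatch(r"Question: (.*), Evidences: (.*)", prompt, re.DOTALL)
    if not m:
        raise ValueError("not a recognised prompt")
    evidences = [e for e in m.group(2).split(", ") if e]
    return m.group(1), evidences


# ---------------------------------------------------------------------
# ROUGE


def _ngram_counts(tokens: Sequence[str], n: int) -> dict[tuple, int]:
    counts: dict[tuple, int] = {}
    for i in range(len(tokens) - n + 1):
        g = tuple(tokens[i : i + n])
        counts[g] = counts.get(g, 0) + 1
    return counts


def _f1(match: float, cand_total: float, ref_total: float) -> float:
    if cand_total == 0 or ref_total == 0 or match == 0:
        return 0.0
    p = match / cand_total
    r = match / ref_total
    return 2 * p * r / (p + r)


def _rouge_n(cand: Sequence[str], ref: Sequence[str], n: int) -> float:
    c = _ngram_counts(cand, n)
    r = _ngram_counts(ref, n)
    match = sum(min(cnt, r.get(g, 0)) for g, cnt in c.items())
    return _f1(match, sum(c.values()), sum(r.values()))


def _lcs_len(a: Sequence[str], b: Sequence[str]) -> int:
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]


def rouge_scores(candidate: str, reference: str, mode: str = "char") -> RougeScores:
    """ROUGE-1/2 n-gram F1 and ROUGE-L LCS F1, character-level by default."""
    cand = tokenize(candidate, mode)
    ref = tokenize(reference, mode)
    if not cand or not ref:
        raise ValueError("empty text after tokenization")
    lcs = _lcs_len(cand, ref)
    return RougeScores(
        rouge1=_rouge_n(cand, ref, 1),
        rouge2=_rouge_n(cand, ref, 2),
        rougeL=_f1(lcs, len(cand), len(ref)),
    )
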