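"""Fuzzy phenotype search by keyword cosine similarity.

Records are tokenized (lowercase, split on non-alphanumeric runs) into plain
term-frequency vectors over the corpus vocabulary; a query is ranked by
cosine similarity against every record and the top-k hits (default 10) are
returned. No idf weighting, stemming or synonym expansion is applied — the
score is a purely lexical keyword overlap measure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import DuplicateIdError

__all__ = ["SearchIndex", "SearchHit", "tokenize", "build_index",
           "cosine_similarity", "query"]

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> List[str]:
    return [t for t in _TOKEN_RE.split(text.lower()) if t]


@dataclass(frozen=True)
class SearchHit:
    record_id: str
    score: float
    text: str


@dataclass
class SearchIndex:
    records: List[Tuple[str, str]] = field(default_factory=list)
    vocabulary: Dict[str, int] = field(default_factory=dict)
    matrix: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))


def build_index(corpus: Sequence[Tuple[str, str]]) -> SearchIndex:
    """Build a term-frequency index over ``(id, text)`` records.

    Raises :class:`DuplicateIdError` on repeated ids. Empty texts are
    allowed; they simply never score above zero.
    """
    seen: set[str] = set()
    for record_id, _ in corpus:
        if record_id in seen:
            raise DuplicateIdError(f"duplicate record id {record_id!r}")
        seen.add(record_id)

    vocab: Dict[str, int] = {}
    token_lists = []
    for _, text in corpus:
        toks = tokenize(text)
        token_lists.append(toks)
        for t in toks:
            if t not in vocab:
                vocab[t] = len(vocab)

    matrix = np.zeros((len(corpus), len(vocab)))
    for row, toks in enumerate(token_lists):
        for t in toks:
            matrix[row, vocab[t]] += 1.0
    return SearchIndex(records=list(corpus), vocabulary=vocab, matrix=matrix)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u·v / (‖u‖‖v‖); zero when either vector has zero norm."""
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    # clamp: rounding can push identical nonzero vectors a ulp above 1
    return min(1.0, float(np.dot(u, v) / (nu * nv)))


def _query_vector(index: SearchIndex, text: str) -> np.ndarray:
    vec = np.zeros(len(index.vocabulary))
    for t in tokenize(text):
        col = index.vocabulary.get(t)
        if col is not None:
            vec[col] += 1.0
    return vec


def query(index: SearchIndex, text: str, k: int = 10) -> List[SearchHit]:
    """Top-*k* records by cosine similarity to *text*.

    Zero-score records are suppressed; ties are broken lexicographically by
    record text so results are independent of corpus order.
    """
    if not index.records:
        return []
    qvec = _query_vector(index, text)
    hits = []
    for row, (record_id, record_text) in enumerate(index.records):
        score = cosine_similarity(qvec, index.matrix[row])
        if score > 0.0:
            hits.append(SearchHit(record_id=record_id, score=score, text=record_text))
    hits.sort(key=lambda h: (-h.score, h.text, h.record_id))
    return hits[: max(k, 0)]
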