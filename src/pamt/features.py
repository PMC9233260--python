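"""TF-IDF feature engineering and boolean document vectors.

Every distinct term in a preprocessed corpus is scored by term
frequency-inverse document frequency and the top-K terms become the
feature space; the feature space can then be extended with an
expert-provided keyword list.  Documents are represented as boolean
presence vectors over the feature space (term multiplicity is
deliberately discarded — the downstream classifier is Bernoulli).

The default weighting is the textbook form: raw-count tf and
idf(t) = ln(N / df(t)).  Alternatives (sub-linear tf, smoothed idf, and
summing rather than maximising tf·idf over documents) are configuration
options.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Corpus

__all__ = [
    "FeatureConfig",
    "TermStats",
    "FeatureSpace",
    "DocVector",
    "compute_tf",
    "compute_idf",
    "compute_term_stats",
    "rank_and_select",
    "union_with_expert",
    "vectorize",
    "vectorize_corpus",
    "export_matrix_csv",
]

ORIGIN_TFIDF = "tfidf_selected"
ORIGIN_EXPERT = "expert"
ORIGIN_BOTH = "both"


@dataclass(frozen=True)
class FeatureConfig:
    """TF-IDF variant switches.

    tf:       "raw" (count) or "log" (1 + ln count).
    idf:      "plain" (ln(N/df)) or "smoothed" (ln((1+N)/(1+df)) + 1).
    ranking:  "max" (max over documents of tf*idf) or "sum".
    """

    tf: str = "raw"
    idf: str = "plain"
    ranking: str = "max"

    def __post_init__(self) -> None:
        if self.tf not in ("raw", "log"):
            raise ValueError(f"tf must be 'raw' or 'log', got {self.tf!r}")
        if self.idf not in ("plain", "smoothed"):
            raise ValueError(f"idf must be 'plain' or 'smoothed', got {self.idf!r}")
        if self.ranking not in ("max", "sum"):
            raise ValueError(f"ranking must be 'max' or 'sum', got {self.ranking!r}")


@dataclass
class TermStats:
    """Corpus-level statistics for one term."""

    term: str
    df: int
    per_doc_tf: dict[str, int]
    max_tfidf: float


@dataclass
class FeatureSpace:
    """Ordered vocabulary of selected terms with per-term origin tags."""

    terms: list[str]
    origin: list[str]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.terms) != len(self.origin):
            raise ValueError("terms and origin must have equal length")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("feature space contains duplicate terms")
        self._index = {t: i for i, t in enumerate(self.terms)}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def index(self, term: str) -> int:
        return self._index[term]

    def to_json(self) -> str:
        return json.dumps(
            {"terms": self.terms, "origin": self.origin, "config": self.config},
            ensure_ascii=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSpace":
        d = json.loads(text)
        return cls(terms=d["terms"], origin=d["origin"], config=d.get("config", {}))


@dataclass
class DocVector:
    """Boolean presence vector for one document, aligned to a feature space."""

    doc_id: str
    bits: np.ndarray  # bool, shape (n_terms,)


def compute_tf(doc: list[str]) -> dict[str, int]:
    """Raw occurrence count of every term in one document."""
    return dict(Counter(doc))


def compute_idf(corpus: Corpus, variant: str = "plain") -> dict[str, float]:
    """Inverse document frequency for every term observed in the corpus.

    plain:    idf(t) = ln(N / df(t))        (0 for a term in every document)
    smoothed: idf(t) = ln((1+N)/(1+df)) + 1 (strictly positive)
    """
    if len(corpus) == 0:
        raise ValueError("cannot compute idf on an empty corpus")
    n = len(corpus)
    df: Counter[str] = Counter()
    for t in corpus:
        df.update(set(t.tokens))
    if variant == "plain":
        return {term: math.log(n / d) for term, d in df.items()}
    if variant == "smoothed":
        return {term: math.log((1 + n) / (1 + d)) + 1.0 for term, d in df.items()}
    raise ValueError(f"unknown idf variant {variant!r}")


def _tf_value(count: int, variant: str) -> float:
    if variant == "raw":
        return float(count)
    return 1.0 + math.log(count)  # "log", count >= 1 by construction


def compute_term_stats(
    corpus: Corpus, config: FeatureConfig = FeatureConfig()
) -> dict[str, TermStats]:
    """Per-term df, per-document tf and the max tf·idf over documents."""
    idf = compute_idf(corpus, config.idf)
    per_doc: dict[str, dict[str, int]] = {}
    df: Counter[str] = Counter()
    for t in corpus:
        counts = compute_tf(t.tokens)
        df.update(counts.keys())
        for term, c in counts.items():
            per_doc.setdefault(term, {})[t.id] = c
    return {
        term: TermStats(
            term=term,
            df=df[term],
            per_doc_tf=per_doc[term],
            max_tfidf=max(
                _tf_value(c, config.tf) * idf[term] for c in per_doc[term].values()
            ),
        )
        for term in per_doc
    }


def rank_and_select(
    corpus: Corpus, k: int, config: FeatureConfig = FeatureConfig()
) -> FeatureSpace:
    """Select the K most important terms by tf·idf.

    Each term's importance is the max (or sum) over documents of
    tf(t,d)·idf(t); the K highest-scoring terms are retained, ties
    broken by lexicographic term order (bytewise, locale-independent).
    K at or above the vocabulary size keeps everything.
    """
    if len(corpus) == 0:
        raise ValueError("cannot select features from an empty corpus")
    if k < 1:
        raise ValueError("k must be >= 1")
    idf = compute_idf(corpus, config.idf)
    scores: dict[str, float] = {}
    for t in corpus:
        for term, c in compute_tf(t.tokens).items():
            w = _tf_value(c, config.tf) * idf[term]
            if config.ranking == "max":
                scores[term] = max(scores.get(term, -math.inf), w)
            else:
                scores[term] = scores.get(term, 0.0) + w
    ranked = sorted(scores, key=lambda term: (-scores[term], term))
    chosen = ranked[:k]
    return FeatureSpace(
        terms=chosen,
        origin=[ORIGIN_TFIDF] * len(chosen),
        config={"k": k, "tf": config.tf, "idf": config.idf, "ranking": config.ranking},
    )


def union_with_expert(fs: FeatureSpace, expert_keywords: set[str]) -> FeatureSpace:
    """Extend a feature space with expert keywords.

    Terms already selected keep their position and are re-tagged
    ``both``; genuinely new expert terms are appended in lexicographic
    order.
    """
    origin = [
        ORIGIN_BOTH if (term in expert_keywords and tag == ORIGIN_TFIDF) else tag
        for term, tag in zip(fs.terms, fs.origin)
    ]
    new_terms = sorted(set(expert_keywords) - set(fs.terms))
    return FeatureSpace(
        terms=fs.terms + new_terms,
        origin=origin + [ORIGIN_EXPERT] * len(new_terms),
        config=dict(fs.config),
    )


def vectorize(doc: list[str], fs: FeatureSpace) -> np.ndarray:
    """Boolean presence vector: bit i is set iff fs.terms[i] occurs in doc."""
    present = set(doc)
    return np.fromiter(
        (term in present for term in fs.terms), dtype=bool, count=len(fs)
    )


def vectorize_corpus(corpus: Corpus, fs: FeatureSpace) -> tuple[np.ndarray, list[str]]:
    """Stack document vectors into a (n_docs, n_terms) boolean matrix."""
    x = np.zeros((len(corpus), len(fs)), dtype=bool)
    ids = []
    for i, t in enumerate(corpus):
        x[i] = vectorize(t.tokens, fs)
        ids.append(t.id)
    return x, ids


def export_matrix_csv(
    x: np.ndarray, doc_ids: list[str], fs: FeatureSpace, path: str | Path
) -> None:
    """Write the 0/1 document-term matrix as dense CSV (docs x terms)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id," + ",".join(fs.terms) + "\n")
        for doc_id, row in zip(doc_ids, x):
            fh.write(doc_id + "," + ",".join(str(int(b)) for b in row) + "\n")
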