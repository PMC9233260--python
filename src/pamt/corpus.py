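"""Transcript corpora, lexicons and text preprocessing.

A *transcript* is the text of one emergency call, carrying a binary
severity label (``pamt`` = prehospital-activated major trauma,
``non_pamt`` = everything else) and, optionally, six per-rater certainty
votes collected from human dispatchers.

Preprocessing follows the classic three-stage recipe for short-message
classification: word segmentation, stop-word removal, and synonym
grouping.  Segmentation is a pluggable contract (string in, token list
out, deterministic); the default tokenizer casefolds, splits on
whitespace, and then greedily merges adjacent units that form a term of
the segmentation dictionary (longest match first).  Real Mandarin text
can plug in an external segmenter behind the same contract.
"""

from __future__ import annotations

import json
from collections.abc import Callable, Iterable, Iterator
from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "N_RATERS",
    "CorpusError",
    "LexiconError",
    "Transcript",
    "Lexicon",
    "Corpus",
    "load_corpus",
    "write_corpus",
    "segment",
    "remove_stopwords",
    "map_synonyms",
    "preprocess",
    "whitespace_tokenizer",
]

POSITIVE = "pamt"
NEGATIVE = "non_pamt"
#: Number of human raters contributing certainty votes per case.
N_RATERS = 6

Tokenizer = Callable[[str], list[str]]


class CorpusError(ValueError):
    """Malformed corpus file or inconsistent corpus contents."""


class LexiconError(ValueError):
    """Invalid lexicon contents (bad weights, chained synonyms, ...)."""


@dataclass
class Transcript:
    """One emergency call.

    Parameters
    ----------
    id :
        Unique case identifier within a corpus.
    raw_text :
        Unsegmented call text ("" when the record was created at token
        level, e.g. by the synthetic generator).
    tokens :
        Token sequence after preprocessing (empty before it).
    label :
        ``"pamt"``, ``"non_pamt"`` or ``None`` for unlabeled.
    certainty_votes :
        Six 0/1 flags (one per rater: 1 = rater was certain), or None.
    """

    id: str
    raw_text: str = ""
    tokens: list[str] = field(default_factory=list)
    label: str | None = None
    certainty_votes: list[int] | None = None

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE, None):
            raise CorpusError(
                f"transcript {self.id!r}: label must be {POSITIVE!r}, "
                f"{NEGATIVE!r} or None, got {self.label!r}"
            )
        if self.certainty_votes is not None:
            votes = list(self.certainty_votes)
            if len(votes) != N_RATERS or any(v not in (0, 1) for v in votes):
                raise CorpusError(
                    f"transcript {self.id!r}: certainty_votes must be "
                    f"{N_RATERS} binary flags, got {self.certainty_votes!r}"
                )
            self.certainty_votes = votes

    @property
    def is_positive(self) -> bool:
        return self.label == POSITIVE

    @property
    def certainty_level(self) -> int | None:
        """Number of raters certain of their judgment (0-6), or None."""
        if self.certainty_votes is None:
            return None
        return sum(self.certainty_votes)


@dataclass
class Lexicon:
    """Segmentation dictionary, stop words, synonyms and expert keywords.

    The synonym map must be single-step: no canonical term may itself
    appear as a variant key, so applying the map once per token is
    exhaustive and order-independent.
    """

    seg_dict: dict[str, float] = field(default_factory=dict)
    stopwords: set[str] = field(default_factory=set)
    synonyms: dict[str, str] = field(default_factory=dict)
    expert_keywords: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for term, weight in self.seg_dict.items():
            if not weight > 0:
                raise LexiconError(
                    f"seg_dict weight for {term!r} must be > 0, got {weight}"
                )
        chained = set(self.synonyms) & set(self.synonyms.values())
        if chained:
            raise LexiconError(
                "synonym map must be single-step; these canonical terms also "
                f"appear as variant keys: {sorted(chained)}"
            )

    @classmethod
    def from_paths(
        cls,
        seg_dict: str | Path | None = None,
        stopwords: str | Path | None = None,
        synonyms: str | Path | None = None,
        expert_keywords: str | Path | None = None,
    ) -> "Lexicon":
        """Build a lexicon from plain-text files (UTF-8 throughout).

        Word lists (stopwords, expert keywords) are one term per line;
        the segmentation dictionary is 2-column TSV ``term<TAB>weight``;
        the synonym map is 2-column TSV ``variant<TAB>canonical``.
        Blank lines and ``#`` comment lines are ignored.
        """
        return cls(
            seg_dict=_read_tsv_map(seg_dict, float) if seg_dict else {},
            stopwords=set(_read_wordlist(stopwords)) if stopwords else set(),
            synonyms=_read_tsv_map(synonyms, str) if synonyms else {},
            expert_keywords=(
                set(_read_wordlist(expert_keywords)) if expert_keywords else set()
            ),
        )


def _read_wordlist(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def _read_tsv_map(path: str | Path, value_type):
    out = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LexiconError(f"{path}:{lineno}: expected 2 tab-separated columns")
        out[parts[0]] = value_type(parts[1])
    return out


class Corpus:
    """An ordered collection of transcripts with unique ids."""

    def __init__(
        self,
        transcripts: Iterable[Transcript],
        provenance: dict | None = None,
    ) -> None:
        self.transcripts: list[Transcript] = list(transcripts)
        self.provenance: dict = dict(provenance or {})
        self._index: dict[str, Transcript] = {}
        for t in self.transcripts:
            if t.id in self._index:
                raise CorpusError(f"duplicate transcript id {t.id!r}")
            self._index[t.id] = t
        self._n_pos = sum(1 for t in self.transcripts if t.label == POSITIVE)
        self._n_neg = sum(1 for t in self.transcripts if t.label == NEGATIVE)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts)

    def __getitem__(self, case_id: str) -> Transcript:
        return self._index[case_id]

    def __contains__(self, case_id: str) -> bool:
        return case_id in self._index

    @property
    def n_positive(self) -> int:
        return self._n_pos

    @property
    def n_negative(self) -> int:
        return self._n_neg

    def ids(self) -> list[str]:
        return [t.id for t in self.transcripts]

    def subset(self, case_ids: Iterable[str]) -> "Corpus":
        """Sub-corpus containing the given cases, in the given order."""
        return Corpus([self._index[i] for i in case_ids], self.provenance)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.transcripts == other.transcripts


# ---------------------------------------------------------------------------
# I/O

def load_corpus(path: str | Path, format: str = "jsonl") -> Corpus:
    """Read a corpus from JSON-lines or 3-column TSV.

    JSONL records are ``{"id", "text" and/or "tokens", "label",
    "certainty_votes"}``; missing labels are kept as unlabeled.  The TSV
    dialect is ``id<TAB>label<TAB>space-joined tokens`` with an empty
    label column for unlabeled cases.
    """
    path = Path(path)
    if format == "jsonl":
        transcripts = _load_jsonl(path)
    elif format == "tsv":
        transcripts = _load_tsv(path)
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    return Corpus(transcripts, provenance={"source": str(path)})


def _load_jsonl(path: Path) -> list[Transcript]:
    out = []
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
        if not isinstance(rec, dict) or "id" not in rec:
            raise CorpusError(f"{path}:{lineno}: record missing 'id'")
        if "text" not in rec and "tokens" not in rec:
            raise CorpusError(f"{path}:{lineno}: record needs 'text' or 'tokens'")
        try:
            out.append(
                Transcript(
                    id=str(rec["id"]),
                    raw_text=rec.get("text") or "",
                    tokens=list(rec.get("tokens") or []),
                    label=rec.get("label"),
                    certainty_votes=rec.get("certainty_votes"),
                )
            )
        except CorpusError as exc:
            raise CorpusError(f"{path}:{lineno}: {exc}") from exc
    return out


def _load_tsv(path: Path) -> list[Transcript]:
    out = []
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise CorpusError(f"{path}:{lineno}: expected 3 tab-separated columns")
        case_id, label, joined = parts
        if not case_id:
            raise CorpusError(f"{path}:{lineno}: record missing 'id'")
        out.append(
            Transcript(
                id=case_id,
                tokens=joined.split() if joined else [],
                label=label or None,
            )
        )
    return out


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> None:
    """Write a corpus as JSONL or 3-column TSV (inverse of :func:`load_corpus`).

    The TSV dialect stores only id, label and tokens; raw text and
    certainty votes survive the JSONL round-trip only.
    """
    path = Path(path)
    lines = []
    if format == "jsonl":
        for t in corpus:
            rec = {"id": t.id}
            if t.raw_text:
                rec["text"] = t.raw_text
            rec["tokens"] = t.tokens
            rec["label"] = t.label
            rec["certainty_votes"] = t.certainty_votes
            lines.append(json.dumps(rec, ensure_ascii=False))
    elif format == "tsv":
        for t in corpus:
            joined = " ".join(t.tokens)
            if any("\t" in tok or "\n" in tok for tok in t.tokens):
                raise CorpusError(f"transcript {t.id!r}: tokens not TSV-safe")
            lines.append(f"{t.id}\t{t.label or ''}\t{joined}")
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Preprocessing

def whitespace_tokenizer(
    raw_text: str, seg_dict: dict[str, float] | None = None
) -> list[str]:
    """Default tokenizer: casefold, split on whitespace, merge dictionary terms.

    Adjacent whitespace units are merged (greedy, longest match first)
    whenever the space-joined run is a segmentation-dictionary term.  Any
    dictionary term forces a merge; weight magnitude beyond presence is
    not interpreted.
    """
    units = raw_text.casefold().split()
    if not seg_dict:
        return units
    max_n = max(len(term.split()) for term in seg_dict)
    out: list[str] = []
    i = 0
    while i < len(units):
        matched = False
        for n in range(min(max_n, len(units) - i), 1, -1):
            cand = " ".join(units[i : i + n])
            if cand in seg_dict:
                out.append(cand)
                i += n
                matched = True
                break
        if not matched:
            out.append(units[i])
            i += 1
    return out


def segment(
    raw_text: str,
    seg_dict: dict[str, float] | None = None,
    tokenizer: Tokenizer | None = None,
) -> list[str]:
    """Segment raw text into tokens.

    A custom ``tokenizer`` (string in, token list out, deterministic)
    replaces the default entirely and receives only the raw text; the
    segmentation dictionary then belongs to that tokenizer's own
    configuration.
    """
    if tokenizer is not None:
        return list(tokenizer(raw_text))
    return whitespace_tokenizer(raw_text, seg_dict)


def remove_stopwords(tokens: list[str], stopwords: set[str]) -> list[str]:
    """Order-preserving removal of stop-word tokens."""
    if not stopwords:
        return list(tokens)
    return [t for t in tokens if t not in stopwords]


def map_synonyms(tokens: list[str], synonyms: dict[str, str]) -> list[str]:
    """Replace each token by its canonical form, applied exactly once."""
    if not synonyms:
        return list(tokens)
    return [synonyms.get(t, t) for t in tokens]


def preprocess(
    t: Transcript, lex: Lexicon, tokenizer: Tokenizer | None = None
) -> Transcript:
    """Segmentation -> stop-word removal -> synonym grouping.

    Returns a new transcript with ``tokens`` filled in; the input is not
    modified.  With an empty lexicon this reduces to a casefolded
    whitespace split of the raw text.
    """
    toks = segment(t.raw_text, lex.seg_dict, tokenizer)
    toks = remove_stopwords(toks, lex.stopwords)
    toks = map_synonyms(toks, lex.synonyms)
    return replace(t, tokens=toks)
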