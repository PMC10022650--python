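"""Document ingestion, filtering, tokenization and the sparse document-term matrix.

The corpus layer turns raw short documents (social-media posts) into the
sparse counts matrix consumed by latent semantic scaling.  Documents carry
platform flags (retweet, language, link-only) so the exclusion rules used in
survey-linked Twitter studies can be applied before any scoring.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "Document",
    "Vocabulary",
    "DocumentTermMatrix",
    "FilterConfig",
    "tokenize",
    "detect_link_only",
    "filter_documents",
    "build_dtm",
    "read_documents_jsonl",
    "write_documents_jsonl",
    "read_documents_csv",
    "save_dtm",
    "load_dtm",
]

# URLs first so they survive as single tokens; then words (optionally led by
# # or @ so hashtags/mentions stay intact); then any emoji / pictograph.
_TOKEN_RE = re.compile(
    r"https?://\S+"
    r"|[#@]?[\w']+"
    r"|[☀-➿\U0001F000-\U0001FAFF\U00002B00-\U00002BFF]",
    re.UNICODE,
)

_URL_PREFIXES = ("http://", "https://")


def tokenize(text: str, tokenizer: Callable[[str], list[str]] | None = None) -> list[str]:
    """Split ``text`` into an ordered list of lowercase terms.

    The default tokenizer lowercases, splits on whitespace/punctuation,
    keeps URLs, hashtags and mentions as single tokens, and preserves each
    emoji as its own token (emojis are scored like any other term).  A
    language-specific tokenizer (e.g. a Japanese morphological analyzer) can
    be plugged in via ``tokenizer``.
    """
    if tokenizer is not None:
        return tokenizer(text)
    if not text:
        return []
    return [t if t.startswith(_URL_PREFIXES) else t.lower() for t in _TOKEN_RE.findall(text)]


def detect_link_only(tokens: Sequence[str]) -> bool:
    """True when nothing remains after removing URL tokens (link-only post)."""
    return all(t.startswith(_URL_PREFIXES) for t in tokens) if tokens else False


def _parse_timestamp(value) -> datetime:
    if isinstance(value, datetime):
        return value
    if isinstance(value, date):
        return datetime(value.year, value.month, value.day)
    return datetime.fromisoformat(str(value))


@dataclass
class Document:
    """One post: identity, author, time, content and platform filter flags."""

    doc_id: str
    user_id: str
    timestamp: datetime
    text: str | None = None
    tokens: list[str] | None = None
    is_retweet: bool = False
    language: str = "und"
    link_only: bool | None = None

    def __post_init__(self) -> None:
        self.timestamp = _parse_timestamp(self.timestamp)
        if self.text is None and self.tokens is None:
            raise ValueError(f"document {self.doc_id!r} has neither text nor tokens")

    def tokenized(self, tokenizer: Callable[[str], list[str]] | None = None) -> "Document":
        """Return a copy with ``tokens`` populated (and link_only derived if unset)."""
        tokens = self.tokens if self.tokens is not None else tokenize(self.text or "", tokenizer)
        link_only = self.link_only if self.link_only is not None else detect_link_only(tokens)
        return replace(self, tokens=tokens, link_only=link_only)


@dataclass(frozen=True)
class Vocabulary:
    """Ordered unique terms with a term → column-position map."""

    terms: tuple[str, ...]
    term_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.term_index:
            object.__setattr__(self, "term_index", {t: i for i, t in enumerate(self.terms)})
        if len(self.term_index) != len(self.terms):
            raise ValueError("vocabulary terms are not unique")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.term_index


@dataclass
class DocumentTermMatrix:
    """Sparse documents × terms count matrix with row and column labels."""

    counts: sp.csr_matrix
    doc_ids: list[str]
    vocabulary: Vocabulary

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.doc_ids):
            raise ValueError("row count does not match number of doc_ids")
        if self.counts.shape[1] != len(self.vocabulary):
            raise ValueError("column count does not match vocabulary size")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class FilterConfig:
    """Which exclusion rules to apply and their parameters.

    Setting a field to ``None`` disables that rule.  ``min_docs_per_user``
    implements the "inactive user" exclusion as a minimum number of documents
    per author within the analysis window (the decision is recorded in the
    exclusion report).
    """

    drop_retweets: bool = True
    allowed_languages: set[str] | None = None
    drop_link_only: bool = True
    min_docs_per_user: int | None = 10
    date_window: tuple[datetime | str, datetime | str] | None = None

    _KNOWN = {"drop_retweets", "allowed_languages", "drop_link_only",
              "min_docs_per_user", "date_window"}

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown filter rule(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def disabled(cls) -> "FilterConfig":
        return cls(drop_retweets=False, allowed_languages=None,
                   drop_link_only=False, min_docs_per_user=None, date_window=None)


def filter_documents(
    documents: Sequence[Document], config: FilterConfig | dict | None = None
) -> tuple[list[Document], dict[str, int]]:
    """Apply exclusion rules; return (retained documents, exclusion report).

    Rules run in order retweet → language → link_only → date window →
    inactive user; each document is charged to the first rule it fails.
    The report maps rule name → number of excluded documents and records the
    inactivity threshold used.
    """
    if config is None:
        config = FilterConfig()
    elif isinstance(config, dict):
        config = FilterConfig.from_dict(config)

    window = None
    if config.date_window is not None:
        window = tuple(_parse_timestamp(b) for b in config.date_window)

    report: Counter[str] = Counter()
    survivors: list[Document] = []
    for doc in documents:
        if config.drop_retweets and doc.is_retweet:
            report["retweet"] += 1
        elif config.allowed_languages is not None and doc.language not in config.allowed_languages:
            report["language"] += 1
        elif config.drop_link_only and bool(doc.link_only):
            report["link_only"] += 1
        elif window is not None and not (window[0] <= doc.timestamp <= window[1]):
            report["date_window"] += 1
        else:
            survivors.append(doc)

    if config.min_docs_per_user is not None:
        per_user = Counter(d.user_id for d in survivors)
        active = {u for u, n in per_user.items() if n >= config.min_docs_per_user}
        n_before = len(survivors)
        survivors = [d for d in survivors if d.user_id in active]
        if n_before - len(survivors):
            report["inactive_user"] = n_before - len(survivors)
        report["_min_docs_per_user"] = config.min_docs_per_user

    return survivors, dict(report)


def build_dtm(
    documents: Sequence[Document],
    min_term_count: int = 5,
    tokenizer: Callable[[str], list[str]] | None = None,
) -> DocumentTermMatrix:
    """Count terms into a sparse matrix over the pruned vocabulary.

    Terms occurring fewer than ``min_term_count`` times corpus-wide are
    dropped.  Rows follow document input order; a document left with no
    in-vocabulary tokens keeps its (all-zero) row so document identity is
    preserved — such rows receive no score downstream.
    """
    if not documents:
        raise ValueError("empty corpus")
    if min_term_count < 1:
        raise ValueError("min_term_count must be >= 1")

    docs = [d if d.tokens is not None else d.tokenized(tokenizer) for d in documents]
    seen = set()
    if any((d.doc_id in seen or seen.add(d.doc_id)) for d in docs):
        raise ValueError("duplicate doc_id in corpus")

    totals: Counter[str] = Counter()
    for d in docs:
        totals.update(d.tokens)
    vocab = Vocabulary(tuple(sorted(t for t, n in totals.items() if n >= min_term_count)))

    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    index = vocab.term_index
    for i, d in enumerate(docs):
        for term, n in Counter(d.tokens).items():
            j = index.get(term)
            if j is not None:
                rows.append(i)
                cols.append(j)
                data.append(n)
    counts = sp.csr_matrix(
        (np.asarray(data, dtype=np.int64), (rows, cols)),
        shape=(len(docs), len(vocab)),
    )
    return DocumentTermMatrix(counts, [d.doc_id for d in docs], vocab)


# ---------------------------------------------------------------------------
# I/O


def _doc_from_record(rec: dict) -> Document:
    tokens = rec.get("tokens")
    if isinstance(tokens, str):
        tokens = tokens.split() if tokens else []
    return Document(
        doc_id=str(rec["doc_id"]),
        user_id=str(rec["user_id"]),
        timestamp=rec["timestamp"],
        text=rec.get("text"),
        tokens=tokens,
        is_retweet=_as_bool(rec.get("is_retweet", False)),
        language=rec.get("language", "und") or "und",
        link_only=None if rec.get("link_only") in (None, "") else _as_bool(rec.get("link_only")),
    )


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"1", "true", "t", "yes"}
    return bool(v)


def read_documents_jsonl(path: str | Path) -> list[Document]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                docs.append(_doc_from_record(json.loads(line)))
    return docs


def write_documents_jsonl(documents: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in documents:
            rec = {
                "doc_id": d.doc_id,
                "user_id": d.user_id,
                "timestamp": d.timestamp.isoformat(),
                "is_retweet": d.is_retweet,
                "language": d.language,
                "link_only": d.link_only,
            }
            if d.tokens is not None:
                rec["tokens"] = d.tokens
            if d.text is not None:
                rec["text"] = d.text
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_documents_csv(path: str | Path) -> list[Document]:
    with open(path, encoding="utf-8", newline="") as fh:
        return [_doc_from_record(rec) for rec in csv.DictReader(fh)]


def save_dtm(dtm: DocumentTermMatrix, directory: str | Path) -> None:
    """Write counts as Matrix Market plus sidecar doc-id and vocabulary lists."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "counts.mtx"), dtm.counts)
    (directory / "doc_ids.txt").write_text("\n".join(dtm.doc_ids) + "\n", encoding="utf-8")
    (directory / "vocabulary.txt").write_text(
        "\n".join(dtm.vocabulary.terms) + "\n", encoding="utf-8"
    )


def load_dtm(directory: str | Path) -> DocumentTermMatrix:
    directory = Path(directory)
    counts = sp.csr_matrix(mmread(str(directory / "counts.mtx")))
    doc_ids = (directory / "doc_ids.txt").read_text(encoding="utf-8").splitlines()
    terms = (directory / "vocabulary.txt").read_text(encoding="utf-8").splitlines()
    return DocumentTermMatrix(counts, doc_ids, Vocabulary(tuple(terms)))
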