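"""Latent semantic scaling (LSS).

LSS places every term of a corpus on a one-dimensional polarity axis defined
by a handful of seed words, then scores each document as the frequency-
weighted mean polarity of its terms.  The axis is estimated semisupervised:
a truncated SVD of the document-term count matrix yields word vectors, and a
term's polarity is its average cosine similarity to the "worse" (distress)
seeds minus its average similarity to the "better" (well-being) seeds.
Positive scores indicate higher emotional distress.

The estimator follows the scikit-learn fit/transform protocol::

    scaler = LatentSemanticScaler(seeds, embedding_dim=200).fit(dtm)
    scores = scaler.transform(dtm)        # standardized; NaN when unscorable

Document scores are standardized to mean 0, SD 1 over the scored documents
of the fitting corpus; held-out documents are standardized with the stored
fitting-corpus constants.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from sklearn.base import BaseEstimator
from sklearn.utils.extmath import randomized_svd

from .corpus import Document, DocumentTermMatrix, Vocabulary, build_dtm

__all__ = [
    "LSSConfig",
    "SeedLexicon",
    "WordEmbedding",
    "LatentSemanticScaler",
    "cosine",
    "fit_embedding",
    "compute_word_polarity",
    "score_document",
    "standardize",
    "fit_lss",
    "score_corpus",
    "load_seed_lexicon",
]


@dataclass(frozen=True)
class LSSConfig:
    """Hyperparameters of the scaling model.

    embedding_dim
        Rank of the truncated SVD (the paper-style default is 200, chosen to
        capture coarse rather than topical semantics); clipped with a warning
        when it exceeds min(n_docs, n_terms).
    sv_weighting
        ``"singular_values"`` multiplies each term vector elementwise by the
        singular values (standard latent-semantic-analysis practice);
        ``"none"`` uses raw right-singular-vector rows, kept as a
        sensitivity option.
    """

    embedding_dim: int = 200
    sv_weighting: str = "singular_values"
    min_term_count: int = 5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be positive")
        if self.sv_weighting not in ("none", "singular_values"):
            raise ValueError("sv_weighting must be 'none' or 'singular_values'")


class SeedLexicon:
    """Seed terms with sign +1 (worse / distress) or -1 (better / well-being)."""

    def __init__(self, entries: Mapping[str, int]):
        entries = {str(t): int(p) for t, p in entries.items()}
        if any(p not in (1, -1) for p in entries.values()):
            raise ValueError("seed polarity must be +1 or -1")
        if not any(p == 1 for p in entries.values()) or not any(
            p == -1 for p in entries.values()
        ):
            raise ValueError("seed lexicon needs at least one 'worse' and one 'better' term")
        self.entries: dict[str, int] = entries

    @classmethod
    def from_sets(cls, worse: Sequence[str], better: Sequence[str]) -> "SeedLexicon":
        overlap = set(worse) & set(better)
        if overlap:
            raise ValueError(f"terms in both seed sets: {sorted(overlap)}")
        return cls({**{t: 1 for t in worse}, **{t: -1 for t in better}})

    @property
    def worse(self) -> list[str]:
        return [t for t, p in self.entries.items() if p == 1]

    @property
    def better(self) -> list[str]:
        return [t for t, p in self.entries.items() if p == -1]

    def swapped(self) -> "SeedLexicon":
        """Exchange the worse/better sets (negates every downstream score)."""
        return SeedLexicon({t: -p for t, p in self.entries.items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SeedLexicon":
        """Read a two-column TSV: term <tab> worse|better (or +1/-1)."""
        entries = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, label = line.split("\t")
            label = label.strip().lower()
            entries[term.strip()] = (
                1 if label in {"worse", "+1", "1"} else -1 if label in {"better", "-1"} else None
            )
        if None in entries.values():
            raise ValueError("seed labels must be 'worse'/'better' or +1/-1")
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for t, p in self.entries.items():
                fh.write(f"{t}\t{'worse' if p == 1 else 'better'}\n")

    def __len__(self) -> int:
        return len(self.entries)


def load_seed_lexicon(name: str = "ja") -> SeedLexicon:
    """Load a packaged seed lexicon: ``"ja"`` (Japanese emotional-distress
    seeds) or ``"synthetic_en"`` (an English toy lexicon for tests/demos)."""
    fname = {"ja": "seeds_ja.tsv", "synthetic_en": "seeds_synthetic_en.tsv"}[name]
    ref = resources.files("lsspanel.data") / fname
    with resources.as_file(ref) as path:
        return SeedLexicon.from_tsv(path)


@dataclass
class WordEmbedding:
    """Term vectors from the truncated SVD of the counts matrix."""

    terms: tuple[str, ...]
    matrix: np.ndarray  # (n_terms, k), singular-value weighting already applied
    singular_values: np.ndarray
    term_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.term_index:
            self.term_index = {t: i for i, t in enumerate(self.terms)}

    def vector(self, term: str) -> np.ndarray:
        return self.matrix[self.term_index[term]]

    @property
    def embedding_dim(self) -> int:
        return self.matrix.shape[1]


def cosine(v_x: np.ndarray, v_y: np.ndarray) -> float:
    """Cosine similarity; defined as 0 for a zero-norm vector (logged)."""
    nx = float(np.linalg.norm(v_x))
    ny = float(np.linalg.norm(v_y))
    if nx == 0.0 or ny == 0.0:
        warnings.warn("cosine of zero-norm vector defined as 0", stacklevel=2)
        return 0.0
    return float(np.dot(v_x, v_y) / (nx * ny))


def fit_embedding(dtm: DocumentTermMatrix, config: LSSConfig = LSSConfig()) -> WordEmbedding:
    """Truncated rank-k SVD of the counts matrix; word vectors are rows of the
    term-side singular matrix, optionally scaled by singular values.

    Deterministic given ``config.random_seed``; the sign of each singular
    vector is fixed by making its largest-magnitude term loading positive.
    """
    counts = sp.csr_matrix(dtm.counts, dtype=np.float64)
    n_docs, n_terms = counts.shape
    k = config.embedding_dim
    max_k = min(n_docs, n_terms)
    if k > max_k:
        warnings.warn(
            f"embedding_dim={k} exceeds min(n_docs, n_terms)={max_k}; clipping",
            stacklevel=2,
        )
        k = max_k
    _, s, vt = randomized_svd(
        counts, n_components=k, n_iter=7, random_state=config.random_seed
    )
    # Deterministic sign: largest-|loading| term of each component positive.
    anchor = np.abs(vt).argmax(axis=1)
    signs = np.sign(vt[np.arange(k), anchor])
    signs[signs == 0] = 1.0
    vt = vt * signs[:, None]
    vectors = vt.T
    if config.sv_weighting == "singular_values":
        vectors = vectors * s[None, :]
    return WordEmbedding(dtm.vocabulary.terms, np.ascontiguousarray(vectors), s)


def compute_word_polarity(
    embedding: WordEmbedding, seeds: SeedLexicon
) -> tuple[pd.Series, list[str]]:
    """Signed average cosine similarity of every term to the seed sets.

    g_f = (1/|S'|) * sum over in-vocabulary seeds s of p_s * cos(v_f, v_s),
    with p_s = +1 for worse and -1 for better seeds.  Returns the polarity
    series (indexed by term) and the list of in-vocabulary seeds used.
    """
    in_vocab = [t for t in seeds.entries if t in embedding.term_index]
    missing = [t for t in seeds.entries if t not in embedding.term_index]
    if missing:
        warnings.warn(f"seed terms absent from vocabulary: {missing}", stacklevel=2)
    signs = np.array([seeds.entries[t] for t in in_vocab], dtype=float)
    if not (signs == 1).any() or not (signs == -1).any():
        raise ValueError("seed coverage: need at least one in-vocabulary seed of each sign")

    norms = np.linalg.norm(embedding.matrix, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = embedding.matrix / safe[:, None]
    unit[norms == 0] = 0.0  # zero-norm vectors contribute cosine 0

    seed_rows = np.array([embedding.term_index[t] for t in in_vocab])
    direction = (unit[seed_rows] * signs[:, None]).sum(axis=0) / len(in_vocab)
    g = unit @ direction
    return pd.Series(g, index=list(embedding.terms), name="polarity"), in_vocab


def score_document(term_counts: Mapping[str, int], polarity: pd.Series) -> float:
    """Frequency-weighted mean polarity of one document's in-vocabulary terms.

    raw = (sum_f g_f * h_f) / N with N the in-vocabulary token count; NaN
    (undefined, not zero) when N = 0.
    """
    num = 0.0
    n = 0
    for term, h in term_counts.items():
        if term in polarity.index:
            num += float(polarity[term]) * h
            n += h
    return num / n if n > 0 else float("nan")


def standardize(raw_scores: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Center and rescale raw scores to mean 0, SD 1 (population SD) over the
    scored (non-NaN) documents; returns (scores, center, scale)."""
    raw = np.asarray(raw_scores, dtype=float)
    scored = raw[~np.isnan(raw)]
    if scored.size < 2:
        raise ValueError("degenerate corpus: fewer than 2 scored documents")
    center = float(scored.mean())
    scale = float(scored.std())  # population SD
    if scale == 0.0:
        raise ValueError("degenerate corpus: zero score variance")
    return (raw - center) / scale, center, scale


class LatentSemanticScaler(BaseEstimator):
    """Fit an LSS model on a document-term matrix and score documents.

    Parameters
    ----------
    seeds
        SeedLexicon anchoring the polarity axis.
    embedding_dim, sv_weighting, random_seed
        See :class:`LSSConfig`.

    Attributes (after fit)
    ----------------------
    embedding_ : WordEmbedding
    polarity_ : pd.Series                term → g_f, higher = more distress
    seed_coverage_ : list[str]           in-vocabulary seeds actually used
    center_, scale_ : float              fitting-corpus standardization
    coverage_ : float                    fraction of fitting docs scored
    """

    def __init__(
        self,
        seeds: SeedLexicon | None = None,
        embedding_dim: int = 200,
        sv_weighting: str = "singular_values",
        random_seed: int = 0,
    ):
        self.seeds = seeds
        self.embedding_dim = embedding_dim
        self.sv_weighting = sv_weighting
        self.random_seed = random_seed

    def _config(self) -> LSSConfig:
        return LSSConfig(
            embedding_dim=self.embedding_dim,
            sv_weighting=self.sv_weighting,
            random_seed=self.random_seed,
        )

    def fit(self, X: DocumentTermMatrix, y=None) -> "LatentSemanticScaler":
        if self.seeds is None:
            raise ValueError("a SeedLexicon is required")
        self.embedding_ = fit_embedding(X, self._config())
        self.polarity_, self.seed_coverage_ = compute_word_polarity(self.embedding_, self.seeds)
        raw = self._raw_scores(X.counts)
        lss, self.center_, self.scale_ = standardize(raw)
        self.coverage_ = float(np.mean(~np.isnan(raw)))
        self._fit_scores = lss
        return self

    def _polarity_vector(self) -> np.ndarray:
        return self.polarity_.to_numpy()

    def _raw_scores(self, counts: sp.spmatrix) -> np.ndarray:
        counts = sp.csr_matrix(counts, dtype=np.float64)
        if counts.shape[1] != len(self.embedding_.terms):
            raise ValueError("counts matrix not aligned with fitted vocabulary")
        n = np.asarray(counts.sum(axis=1)).ravel()
        num = counts @ self._polarity_vector()
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(n > 0, num / np.where(n > 0, n, 1.0), np.nan)
        return raw

    def transform(self, X: DocumentTermMatrix | sp.spmatrix) -> np.ndarray:
        """Standardized scores (NaN for documents with no in-vocabulary token),
        using the fitting corpus's center/scale."""
        counts = X.counts if isinstance(X, DocumentTermMatrix) else X
        return (self._raw_scores(counts) - self.center_) / self.scale_

    def fit_transform(self, X: DocumentTermMatrix, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def score_documents(self, documents: Sequence[Document]) -> pd.DataFrame:
        """Score raw documents against the fitted vocabulary.

        Returns a DataFrame (doc_id, user_id, timestamp, raw_score,
        lss_score, n_scored_tokens); ``attrs["coverage"]`` holds the scored
        fraction.
        """
        index = self.embedding_.term_index
        g = self._polarity_vector()
        rows = []
        for doc in documents:
            d = doc if doc.tokens is not None else doc.tokenized()
            num = 0.0
            n = 0
            for t in d.tokens:
                j = index.get(t)
                if j is not None:
                    num += g[j]
                    n += 1
            raw = num / n if n else float("nan")
            rows.append((d.doc_id, d.user_id, d.timestamp, raw, n))
        out = pd.DataFrame(rows, columns=["doc_id", "user_id", "timestamp", "raw_score",
                                          "n_scored_tokens"])
        out["lss_score"] = (out["raw_score"] - self.center_) / self.scale_
        out = out[["doc_id", "user_id", "timestamp", "raw_score", "lss_score",
                   "n_scored_tokens"]]
        out.attrs["coverage"] = float((out["n_scored_tokens"] > 0).mean())
        return out

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.yaml").write_text(
            yaml.safe_dump(
                {
                    "embedding_dim": self.embedding_dim,
                    "sv_weighting": self.sv_weighting,
                    "random_seed": self.random_seed,
                }
            ),
            encoding="utf-8",
        )
        (directory / "vocabulary.txt").write_text(
            "\n".join(self.embedding_.terms) + "\n", encoding="utf-8"
        )
        with open(directory / "polarity.tsv", "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            for term, gf in self.polarity_.items():
                w.writerow([term, repr(float(gf))])
        (directory / "standardization.json").write_text(
            json.dumps({"center": self.center_, "scale": self.scale_,
                        "coverage": self.coverage_}),
            encoding="utf-8",
        )
        np.save(directory / "embedding.npy", self.embedding_.matrix)
        np.save(directory / "singular_values.npy", self.embedding_.singular_values)
        self.seeds.to_tsv(directory / "seeds.tsv")

    @classmethod
    def load(cls, directory: str | Path) -> "LatentSemanticScaler":
        directory = Path(directory)
        cfg = yaml.safe_load((directory / "config.yaml").read_text(encoding="utf-8"))
        model = cls(seeds=SeedLexicon.from_tsv(directory / "seeds.tsv"), **cfg)
        terms = tuple((directory / "vocabulary.txt").read_text(encoding="utf-8").splitlines())
        model.embedding_ = WordEmbedding(
            terms,
            np.load(directory / "embedding.npy"),
            np.load(directory / "singular_values.npy"),
        )
        pol = {}
        with open(directory / "polarity.tsv", encoding="utf-8", newline="") as fh:
            for term, gf in csv.reader(fh, delimiter="\t"):
                pol[term] = float(gf)
        model.polarity_ = pd.Series([pol[t] for t in terms], index=list(terms), name="polarity")
        model.seed_coverage_ = [t for t in model.seeds.entries if t in model.embedding_.term_index]
        std = json.loads((directory / "standardization.json").read_text(encoding="utf-8"))
        model.center_ = std["center"]
        model.scale_ = std["scale"]
        model.coverage_ = std["coverage"]
        return model


def fit_lss(
    dtm: DocumentTermMatrix,
    seeds: SeedLexicon,
    config: LSSConfig = LSSConfig(),
) -> LatentSemanticScaler:
    """Fit embedding → word polarity → document scores → standardization."""
    return LatentSemanticScaler(
        seeds=seeds,
        embedding_dim=config.embedding_dim,
        sv_weighting=config.sv_weighting,
        random_seed=config.random_seed,
    ).fit(dtm)


def score_corpus(
    model: LatentSemanticScaler,
    data: DocumentTermMatrix | Sequence[Document],
    doc_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score a corpus (documents, or a DTM aligned to the fitted vocabulary).

    Returns the scored-document table; ``attrs["coverage"]`` reports the
    fraction of documents that received a score.
    """
    if isinstance(data, DocumentTermMatrix):
        raw = model._raw_scores(data.counts)
        n = np.asarray(data.counts.sum(axis=1)).ravel().astype(int)
        out = pd.DataFrame(
            {
                "doc_id": data.doc_ids,
                "raw_score": raw,
                "lss_score": (raw - model.center_) / model.scale_,
                "n_scored_tokens": n,
            }
        )
        if doc_meta is not None:
            out = out.merge(doc_meta, on="doc_id", how="left")
        out.attrs["coverage"] = float((n > 0).mean())
        return out
    return model.score_documents(list(data))
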