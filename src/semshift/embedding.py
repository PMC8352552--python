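"""Document vectors: preprocessing, a deterministic reference embedder,
and delimited-text vector I/O.

External sentence embedders (e.g. a 700-d BioSentVec model run offline)
plug in through ``load_vectors``; everything downstream consumes only an
:class:`EmbeddedCorpus`, never the embedder, so swapping embedders changes
no analysis code.  The built-in :class:`HashingEmbedder` is a seeded
signed feature-hashing bag-of-words embedder: fully deterministic, with
cosine similarity tracking token overlap — enough to exercise and test the
whole novelty pipeline without any external model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import TokenizerConfig, WindowedCorpus, tokenize

#: preprocessing used ahead of embedding: lowercase, strip punctuation,
#: drop stop-words.
EMBED_TOKENIZER = TokenizerConfig(remove_stopwords=True)


@dataclass
class EmbeddedCorpus:
    """Per-document vectors aligned to corpus windows."""

    doc_ids: list[str]
    vectors: np.ndarray
    window_of: dict[str, int]
    embedder_tag: str = "unknown"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.doc_ids):
            raise ValueError("vectors must be (#docs, dim)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite vector entries")
        missing = [i for i in self.doc_ids if i not in self.window_of]
        if missing:
            raise ValueError(f"doc ids without window assignment: {missing[:5]}")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_windows(self) -> int:
        return max(self.window_of.values()) + 1 if self.window_of else 0

    def window_mask(self, index: int) -> np.ndarray:
        return np.array([self.window_of[i] == index for i in self.doc_ids])

    def past_mask(self, index: int) -> np.ndarray:
        return np.array([self.window_of[i] < index for i in self.doc_ids])


def preprocess_for_embedding(text: str, config: TokenizerConfig = EMBED_TOKENIZER) -> str:
    """Lowercase, strip punctuation, drop stop-words; space-join the tokens.

    Idempotent: running it on its own output is a no-op.
    """
    return " ".join(tokenize(text, config))


def _token_hash(token: str, seed: int) -> tuple[int, int]:
    """(bucket_entropy, sign_bit) from a keyed blake2b digest; stable across runs."""
    h = hashlib.blake2b(token.encode("utf-8"), digest_size=8, salt=str(seed).encode()[:8].ljust(8, b"\0"))
    v = int.from_bytes(h.digest(), "big")
    return v >> 1, v & 1


class HashingEmbedder(BaseEstimator, TransformerMixin):
    """Seeded signed feature hashing of token bags into ``dim`` buckets.

    Stateless (fit is a no-op); identical text always maps to the identical
    vector for a fixed (dim, seed), token order is irrelevant, and texts
    with disjoint vocabularies have zero inner product in expectation over
    seeds.
    """

    def __init__(self, dim: int = 64, seed: int = 0, config: TokenizerConfig = EMBED_TOKENIZER):
        self.dim = dim
        self.seed = seed
        self.config = config

    def fit(self, X, y=None):
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        self.n_features_out_ = self.dim
        return self

    def transform(self, X) -> np.ndarray:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        out = np.zeros((len(X), self.dim))
        for row, text in enumerate(X):
            for tok in tokenize(text, self.config):
                v, sign = _token_hash(tok, self.seed)
                out[row, v % self.dim] += 1.0 if sign else -1.0
        return out

    @property
    def tag(self) -> str:
        return f"hashing-embedder(dim={self.dim},seed={self.seed})"


def embed_reference(texts: list[str], dim: int = 64, seed: int = 0) -> np.ndarray:
    """Reference embedding of raw texts (functional wrapper over
    :class:`HashingEmbedder`)."""
    return HashingEmbedder(dim=dim, seed=seed).fit(texts).transform(texts)


def embed_corpus(
    wc: WindowedCorpus, field_name: str = "title", dim: int = 64, seed: int = 0
) -> EmbeddedCorpus:
    """Embed every document of a windowed corpus with the reference embedder."""
    texts, ids = [], []
    for d in wc.documents:
        text = d.title if field_name == "title" else d.abstract
        if text is None:
            continue
        texts.append(text)
        ids.append(d.doc_id)
    emb = HashingEmbedder(dim=dim, seed=seed)
    return EmbeddedCorpus(
        doc_ids=ids,
        vectors=emb.fit(texts).transform(texts),
        window_of={i: wc.assignment[i] for i in ids},
        embedder_tag=emb.tag,
    )


def save_vectors(path, ids: list[str], vectors: np.ndarray, header: bool = False) -> None:
    """Write a vector TSV: one row per doc, id then the float coordinates."""
    vectors = np.asarray(vectors, dtype=float)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write("id\t" + "\t".join(f"v{j}" for j in range(vectors.shape[1])) + "\n")
        for i, row in zip(ids, vectors):
            fh.write(i + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def load_vectors(path, ids: list[str] | None = None, header: bool = False) -> tuple[list[str], np.ndarray]:
    """Read a vector TSV and (optionally) align rows to an expected id list.

    Missing or extra ids, inconsistent dimensions and non-finite entries
    are all hard errors.
    """
    rows: dict[str, np.ndarray] = {}
    order: list[str] = []
    dim = None
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh):
            if header and ln == 0:
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            vec = np.array([float(p) for p in parts[1:]])
            if dim is None:
                dim = len(vec)
            elif len(vec) != dim:
                raise ValueError(f"row {parts[0]!r}: dimension {len(vec)} != {dim}")
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"row {parts[0]!r}: non-finite entries")
            if parts[0] in rows:
                raise ValueError(f"duplicate id {parts[0]!r} in vector file")
            rows[parts[0]] = vec
            order.append(parts[0])
    if ids is None:
        ids = order
    missing = [i for i in ids if i not in rows]
    extra = [i for i in order if i not in set(ids)]
    if missing or extra:
        raise ValueError(f"vector file mismatch: missing ids {missing[:5]}, extra ids {extra[:5]}")
    return list(ids), np.vstack([rows[i] for i in ids])


def pairwise_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two equal-dimension vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))
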