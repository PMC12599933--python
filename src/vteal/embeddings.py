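"""Text vectorization: term frequency, TF-IDF, dense embeddings, cosine.

Three document-vector schemes are provided:

* term-frequency counts over an index vocabulary (sparse),
* TF-IDF reweighting with the smoothed idf ``ln((1+N)/(1+df)) + 1``,
* dense vectors, either by averaging co-occurrence-trained word vectors
  (``mode="word_average"``) or by a per-document latent-semantic projection
  (``mode="document"``).

The dense models are trained deterministically (PPMI / TF-IDF matrices
factorized by truncated SVD with a seeded start vector and sign-fixed
components), which keeps runs byte-reproducible without any external
pretrained tables.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

__all__ = [
    "tokenize",
    "Vocabulary",
    "tf_vectorize",
    "tfidf_weight",
    "DenseEmbedder",
    "cosine_similarity",
]

_PUNCT_RE = re.compile(r"[^\w\s]")


def tokenize(text: str, lowercase: bool = True, strip_punct: bool = True) -> list[str]:
    """Deterministic whitespace tokenizer (default: lowercase, no punctuation)."""
    if lowercase:
        text = text.lower()
    if strip_punct:
        text = _PUNCT_RE.sub(" ", text)
    return text.split()


@dataclass
class Vocabulary:
    """Token -> contiguous index map with per-token document frequencies.

    Built from the training pool only; transforming unseen documents never
    extends it.
    """

    index: dict[str, int]
    doc_freq: np.ndarray
    n_docs: int

    @classmethod
    def from_texts(
        cls, texts: Iterable[str], min_count: int = 1
    ) -> "Vocabulary":
        counts: dict[str, int] = {}
        dfs: dict[str, int] = {}
        n_docs = 0
        for text in texts:
            n_docs += 1
            toks = tokenize(text)
            for t in toks:
                counts[t] = counts.get(t, 0) + 1
            for t in set(toks):
                dfs[t] = dfs.get(t, 0) + 1
        tokens = sorted(t for t, c in counts.items() if c >= min_count)
        index = {t: i for i, t in enumerate(tokens)}
        doc_freq = np.array([dfs[t] for t in tokens], dtype=np.int64)
        return cls(index=index, doc_freq=doc_freq, n_docs=n_docs)

    def __len__(self) -> int:
        return len(self.index)

    def save(self, path: str | Path) -> None:
        lines = [f"{t}\t{i}\t{self.doc_freq[i]}" for t, i in sorted(self.index.items(), key=lambda kv: kv[1])]
        Path(path).write_text(f"#n_docs\t{self.n_docs}\n" + "\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        n_docs = int(lines[0].split("\t")[1])
        index: dict[str, int] = {}
        dfs: list[int] = []
        for line in lines[1:]:
            tok, idx, df = line.split("\t")
            index[tok] = int(idx)
            dfs.append(int(df))
        return cls(index=index, doc_freq=np.array(dfs, dtype=np.int64), n_docs=n_docs)


def tf_vectorize(texts: Sequence[str], vocab: Vocabulary) -> sp.csr_matrix:
    """Term-frequency count matrix (docs x vocab); OOV tokens are dropped."""
    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    for d, text in enumerate(texts):
        counts: dict[int, int] = {}
        for tok in tokenize(text):
            j = vocab.index.get(tok)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(d)
            cols.append(j)
            data.append(c)
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(len(texts), len(vocab)), dtype=np.float64
    )


def idf_vector(vocab: Vocabulary) -> np.ndarray:
    """Smoothed inverse document frequency: ``ln((1+N)/(1+df)) + 1``."""
    return np.log((1.0 + vocab.n_docs) / (1.0 + vocab.doc_freq)) + 1.0


def tfidf_weight(tf: sp.spmatrix, vocab: Vocabulary) -> sp.csr_matrix:
    """Apply smoothed idf weights to a TF matrix; sparsity is preserved."""
    return sp.csr_matrix(tf.multiply(idf_vector(vocab)))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors; 0 if either has zero norm."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def _fix_signs(u: np.ndarray) -> np.ndarray:
    # flip each component so its max-|.| coordinate is positive: SVD sign
    # ambiguity otherwise breaks cross-run determinism
    flips = np.sign(u[np.abs(u).argmax(axis=0), np.arange(u.shape[1])])
    flips[flips == 0] = 1.0
    return u * flips


def _seeded_svds(mat: sp.spmatrix, k: int, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(mat.shape))
    u, s, vt = svds(mat.astype(np.float64), k=k, v0=v0)
    order = np.argsort(-s)
    return u[:, order], s[order], vt[order, :]


class DenseEmbedder:
    """Dense document embeddings.

    ``mode="word_average"``: word vectors from a windowed co-occurrence
    PPMI matrix factorized by truncated SVD; a document vector is the mean
    of its in-vocabulary word vectors (zero vector if all tokens are OOV).

    ``mode="document"``: latent-semantic document vectors — the TF-IDF
    matrix is factorized and unseen documents are folded into the latent
    space by projection.
    """

    def __init__(
        self,
        mode: str = "word_average",
        dim: int = 100,
        window: int = 5,
        min_count: int = 1,
        seed: int = 0,
    ) -> None:
        if mode not in ("word_average", "document"):
            raise ValueError(f"unknown embedding mode: {mode!r}")
        if dim <= 0:
            raise ValueError("dim must be positive")
        if window <= 0:
            raise ValueError("window must be positive")
        self.mode = mode
        self.dim = dim
        self.window = window
        self.min_count = min_count
        self.seed = seed
        self.vocab: Optional[Vocabulary] = None
        self.word_vectors: Optional[np.ndarray] = None
        self._vt: Optional[np.ndarray] = None

    def fit(self, texts: Sequence[str]) -> "DenseEmbedder":
        self.vocab = Vocabulary.from_texts(texts, min_count=self.min_count)
        v = len(self.vocab)
        if v < 2:
            raise ValueError("need at least 2 vocabulary tokens to embed")
        k = min(self.dim, v - 1)
        if k < self.dim:
            warnings.warn(
                f"embedding dim reduced from {self.dim} to {k} (vocab size {v})",
                stacklevel=2,
            )
        if self.mode == "word_average":
            cooc = self._cooccurrence(texts)
            ppmi = self._ppmi(cooc)
            u, s, _ = _seeded_svds(ppmi, k, self.seed)
            self.word_vectors = _fix_signs(u) * np.sqrt(s)
        else:
            tfidf = tfidf_weight(tf_vectorize(texts, self.vocab), self.vocab)
            k = min(k, tfidf.shape[0] - 1)
            _, _, vt = _seeded_svds(tfidf, k, self.seed)
            self._vt = _fix_signs(vt.T).T
        return self

    def _cooccurrence(self, texts: Sequence[str]) -> sp.csr_matrix:
        assert self.vocab is not None
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        for text in texts:
            ids = [self.vocab.index[t] for t in tokenize(text) if t in self.vocab.index]
            for i, wi in enumerate(ids):
                lo = max(0, i - self.window)
                for j in range(lo, i):
                    rows.append(wi)
                    cols.append(ids[j])
                    vals.append(1.0)
                    rows.append(ids[j])
                    cols.append(wi)
                    vals.append(1.0)
        v = len(self.vocab)
        return sp.csr_matrix((vals, (rows, cols)), shape=(v, v))

    @staticmethod
    def _ppmi(cooc: sp.csr_matrix) -> sp.csr_matrix:
        total = cooc.sum()
        if total == 0:
            return cooc
        row = np.asarray(cooc.sum(axis=1)).ravel()
        col = np.asarray(cooc.sum(axis=0)).ravel()
        coo = cooc.tocoo()
        with np.errstate(divide="ignore"):
            pmi = np.log(
                (coo.data * total) / (row[coo.row] * col[coo.col])
            )
        pmi = np.maximum(pmi, 0.0)
        return sp.csr_matrix((pmi, (coo.row, coo.col)), shape=cooc.shape)

    def transform(self, texts: Sequence[str]) -> np.ndarray:
        if self.vocab is None:
            raise RuntimeError("embedder is not fitted")
        if self.mode == "word_average":
            assert self.word_vectors is not None
            out = np.zeros((len(texts), self.word_vectors.shape[1]))
            for d, text in enumerate(texts):
                ids = [
                    self.vocab.index[t]
                    for t in tokenize(text)
                    if t in self.vocab.index
                ]
                if ids:
                    out[d] = self.word_vectors[ids].mean(axis=0)
            return out
        assert self._vt is not None
        tfidf = tfidf_weight(tf_vectorize(texts, self.vocab), self.vocab)
        return np.asarray(tfidf @ self._vt.T)

    def fit_transform(self, texts: Sequence[str]) -> np.ndarray:
        return self.fit(texts).transform(texts)

    def save_vectors(self, path: str | Path) -> None:
        """Write word vectors as ``token v1 ... vD`` lines (word mode only)."""
        if self.mode != "word_average" or self.word_vectors is None:
            raise RuntimeError("save_vectors requires a fitted word_average model")
        assert self.vocab is not None
        lines = []
        for tok, i in sorted(self.vocab.index.items(), key=lambda kv: kv[1]):
            vals = " ".join(f"{x:.6g}" for x in self.word_vectors[i])
            lines.append(f"{tok} {vals}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_word_vectors(path: str | Path) -> dict[str, np.ndarray]:
    """Read a ``token v1 ... vD`` one-per-line word-vector table."""
    table: dict[str, np.ndarray] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        parts = line.rstrip().split(" ")
        if len(parts) < 2:
            continue
        table[parts[0]] = np.array([float(x) for x in parts[1:]])
    return table
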