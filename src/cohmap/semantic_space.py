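"""Latent-semantic-analysis word-vector spaces.

A :class:`SemanticSpace` maps a vocabulary of lowercase words to k-dimensional
real vectors obtained by truncated SVD of a weighted term-document matrix.
All coherence scores downstream are cosines in this space; vectors are
L2-normalized at build time so cosine reduces to a dot product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["SemanticSpace", "build_space", "save_space", "load_space", "MISSING"]

#: Sentinel returned by :meth:`SemanticSpace.get_vector` for out-of-vocabulary
#: words. Distinguishable from any real vector; truthiness is False.
MISSING = None

_WEIGHTINGS = ("log-entropy", "tf-idf", "raw")


@dataclass
class SemanticSpace:
    """Vocabulary mapped to unit-norm k-dimensional vectors.

    Parameters
    ----------
    words : list of str
        Lowercase vocabulary, one entry per row of ``matrix``.
    matrix : ndarray, shape (n_words, k)
        Row i is the vector of ``words[i]``; every row has unit L2 norm.
    provenance : str
        Free-text descriptor of corpus, weighting and dimensionality.
    """

    words: list[str]
    matrix: np.ndarray
    provenance: str = ""
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.words):
            raise ValueError("matrix must be (n_words, k)")
        norms = np.linalg.norm(self.matrix, axis=1)
        if np.any(norms == 0):
            raise ValueError("all-zero vector in semantic space")
        self._index = {w: i for i, w in enumerate(self.words)}

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    @property
    def vocabulary(self) -> set[str]:
        return set(self.words)

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._index

    def get_vector(self, word: str):
        """Return the stored vector for ``word`` (case-insensitive), or
        :data:`MISSING` if the word is out of vocabulary. Never raises."""
        i = self._index.get(word.lower())
        if i is None:
            return MISSING
        return self.matrix[i]


def _weight_matrix(counts: sp.csr_matrix, weighting: str) -> sp.csr_matrix:
    """Apply a term-document weighting scheme to a raw count matrix.

    ``counts`` is terms x documents. log-entropy: log(1+tf) * (1 - H_t/log n_docs)
    where H_t is the normalized entropy of term t's document distribution;
    tf-idf: tf * log(n_docs / df_t); raw: unchanged.
    """
    if weighting == "raw":
        return counts.astype(float)
    counts = counts.astype(float)
    n_docs = counts.shape[1]
    if weighting == "tf-idf":
        df = np.asarray((counts > 0).sum(axis=1)).ravel()
        idf = np.log(n_docs / df)
        return sp.diags(idf) @ counts
    if weighting == "log-entropy":
        row_sums = np.asarray(counts.sum(axis=1)).ravel()
        # p_td = tf_td / gf_t; entropy term per row
        entropy = np.zeros(counts.shape[0])
        coo = counts.tocoo()
        p = coo.data / row_sums[coo.row]
        np.add.at(entropy, coo.row, p * np.log(p))
        if n_docs > 1:
            g = 1.0 + entropy / math.log(n_docs)
        else:
            g = np.ones_like(entropy)
        logged = counts.copy()
        logged.data = np.log1p(logged.data)
        return sp.diags(g) @ logged
    raise ValueError(f"unknown weighting {weighting!r}; choose from {_WEIGHTINGS}")


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Deterministic SVD sign convention: per column, make the
    largest-magnitude entry positive (first such entry on ties)."""
    u = u.copy()
    for j in range(u.shape[1]):
        col = u[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            u[:, j] = -col
    return u


def build_space(
    documents: Sequence[Sequence[str]],
    k: int = 300,
    weighting: str = "log-entropy",
    min_count: int = 2,
    provenance: str = "",
) -> SemanticSpace:
    """Build an LSA space from tokenized documents.

    The term-document count matrix is weighted per ``weighting``, factored by
    truncated SVD, and each term's k-dimensional left-singular row is
    L2-normalized. Deterministic given inputs: the sign of each singular
    vector is fixed by making its largest-magnitude loading positive.

    Parameters
    ----------
    documents : sequence of token lists
        At least two documents. Tokens are lowercased.
    k : int
        Dimensionality; must not exceed min(#documents, #vocabulary after the
        ``min_count`` filter).
    weighting : {"log-entropy", "tf-idf", "raw"}
    min_count : int
        A term must occur in at least this many documents to enter the
        vocabulary.
    """
    if len(documents) == 0 or all(len(d) == 0 for d in documents):
        raise ValueError("empty corpus")
    if len(documents) < 2:
        raise ValueError("need at least 2 documents")
    if weighting not in _WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}; choose from {_WEIGHTINGS}")

    # document frequency filter
    df: dict[str, int] = {}
    docs_lower = [[t.lower() for t in d] for d in documents]
    for d in docs_lower:
        for t in set(d):
            df[t] = df.get(t, 0) + 1
    vocab = sorted(t for t, c in df.items() if c >= min_count)
    if not vocab:
        raise ValueError("empty vocabulary after min_count filtering")
    kmax = min(len(docs_lower), len(vocab))
    if k > kmax:
        raise ValueError(f"k={k} too large; attainable maximum is {kmax}")

    index = {t: i for i, t in enumerate(vocab)}
    rows, cols, vals = [], [], []
    for j, d in enumerate(docs_lower):
        counts: dict[int, int] = {}
        for t in d:
            i = index.get(t)
            if i is not None:
                counts[i] = counts.get(i, 0) + 1
        for i, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
    tdm = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(vocab), len(docs_lower)), dtype=float
    )
    weighted = _weight_matrix(tdm, weighting)

    if k < kmax:
        # svds is deterministic with a fixed start vector
        v0 = np.ones(min(weighted.shape))
        u, s, _ = spla.svds(weighted, k=k, v0=v0)
        order = np.argsort(s)[::-1]
        u = u[:, order]
    else:
        u_full, s, _ = np.linalg.svd(weighted.toarray(), full_matrices=False)
        u = u_full[:, :k]
    u = _fix_signs(u)

    # drop terms that project to the zero vector (cannot happen at full rank)
    norms = np.linalg.norm(u, axis=1)
    keep = norms > 1e-12
    u = u[keep] / norms[keep, None]
    words = [w for w, m in zip(vocab, keep) if m]
    if not provenance:
        provenance = f"built from {len(docs_lower)} documents, {weighting}, k={k}"
    return SemanticSpace(words=words, matrix=u, provenance=provenance)


def save_space(space: SemanticSpace, path: str | Path) -> None:
    """Write a space as TSV: header ``#k=<int>``, then one word per row
    followed by its k coordinates at full precision."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"#k={space.k}\n")
        for word, vec in zip(space.words, space.matrix):
            coords = "\t".join(repr(float(x)) for x in vec)
            fh.write(f"{word}\t{coords}\n")


def load_space(path: str | Path) -> SemanticSpace:
    """Read a space written by :func:`save_space`. Round-trips bit-exactly."""
    path = Path(path)
    words: list[str] = []
    vectors: list[list[float]] = []
    k = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#k="):
                k = int(line[3:])
                continue
            parts = line.split("\t")
            if k is None:
                k = len(parts) - 1
            if len(parts) != k + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {k + 1} fields, got {len(parts)}"
                )
            words.append(parts[0])
            vectors.append([float(x) for x in parts[1:]])
    if not words:
        raise ValueError("no vocabulary")
    return SemanticSpace(words=words, matrix=np.array(vectors), provenance=str(path))
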