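"""Document-level co-occurrence, PPMI weighting, and truncated-SVD embeddings.

The context unit is the whole document (a global context): two concepts
co-occur when they both appear in a document, counted once per document no
matter how often either is mentioned. With N filtered documents, concept
document frequencies d_i and pair counts c_ij, probabilities are estimated
as document proportions and weighted by positive pointwise mutual
information

    PMI(i, j)  = ln( p(i, j) / (p(i) p(j)) ),   p(i) = d_i / N,  p(i, j) = c_ij / N
    PPMI(i, j) = max(PMI(i, j), 0)

with zero co-occurrence mapped to 0 rather than -inf. The log base is a
convention: cosine relatedness downstream is invariant to positive scaling
of the PPMI matrix. The PPMI matrix M is factored by truncated SVD,
M_k = U_k S_k V_k^T, and each concept's k-dimensional vector is the
corresponding row of U_k S_k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd

from .corpus_io import AnnotatedDocument, ConceptVocabulary
from .errors import DegenerateMatrixError, EmptyCorpusError

__all__ = [
    "CooccurrenceMatrix",
    "PPMIMatrix",
    "EmbeddingMatrix",
    "incidence_matrix",
    "build_cooccurrence",
    "compute_ppmi",
    "embed_svd",
]

#: Above this vocabulary size embed_svd switches from exact dense SVD to a
#: seeded randomized algorithm.
DENSE_SVD_MAX_N = 2000


@dataclass
class CooccurrenceMatrix:
    """Symmetric document co-occurrence counts; diagonal = document frequency."""

    counts: sp.csr_matrix  # n x n, int64
    n_docs: int
    vocab: ConceptVocabulary


@dataclass
class PPMIMatrix:
    """Symmetric non-negative PPMI weights over the same vocabulary."""

    values: sp.csr_matrix  # n x n, float64
    vocab: ConceptVocabulary


@dataclass
class EmbeddingMatrix:
    """Rows of U_k S_k, ordered by vocabulary index.

    ``k`` is the effective dimension after clamping to the number of
    strictly positive singular values; ``singular_values`` and ``vt`` are
    kept for diagnostics and low-rank reconstruction checks.
    """

    vectors: np.ndarray  # n x k
    k: int
    vocab: ConceptVocabulary
    singular_values: np.ndarray  # length k, non-increasing
    vt: np.ndarray  # k x n


def incidence_matrix(docs: list[AnnotatedDocument], vocab: ConceptVocabulary) -> sp.csr_matrix:
    """Binary document-by-concept presence matrix.

    A concept is present in a document iff at least one of its mentions
    scores strictly above the vocabulary's recorded cutoff; mentions of
    concepts outside the vocabulary are ignored.
    """
    rows, cols = [], []
    for d, doc in enumerate(docs):
        seen: set[int] = set()
        for m in doc.mentions:
            if m.score <= vocab.score_cutoff or m.concept_id not in vocab:
                continue
            seen.add(vocab.index_of(m.concept_id))
        rows.extend([d] * len(seen))
        cols.extend(sorted(seen))
    data = np.ones(len(rows), dtype=np.int64)
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(len(docs), vocab.n), dtype=np.int64
    )


def build_cooccurrence(
    docs: list[AnnotatedDocument], vocab: ConceptVocabulary
) -> CooccurrenceMatrix:
    """Count, per concept pair, the documents containing both concepts.

    Presence-based: repeated mentions in one document contribute once. The
    diagonal holds each concept's document frequency and N is the number of
    documents passed in (the filtered corpus size).
    """
    if not docs:
        raise EmptyCorpusError("cannot build a co-occurrence matrix from zero documents")
    X = incidence_matrix(docs, vocab)
    counts = (X.T @ X).tocsr()
    counts.eliminate_zeros()
    return CooccurrenceMatrix(counts=counts, n_docs=len(docs), vocab=vocab)


def compute_ppmi(cooc: CooccurrenceMatrix, keep_diagonal: bool = False) -> PPMIMatrix:
    """Positive pointwise mutual information of the co-occurrence counts.

    Evaluated only on stored nonzero pairs (a zero count has PMI -inf and
    clamps to 0 anyway, so no dense pass and no log-of-zero warnings). The
    diagonal is zeroed by default so a concept's vector reflects its
    neighbourhood rather than its own frequency.
    """
    N = cooc.n_docs
    if N < 1:
        raise EmptyCorpusError("co-occurrence matrix has N = 0 documents")
    counts = cooc.counts.tocoo()
    d = cooc.counts.diagonal().astype(np.float64)
    if np.any(d[: cooc.vocab.n] == 0) and cooc.vocab.n > 0:
        zero = [cooc.vocab.entries[i].concept_id for i in np.flatnonzero(d == 0)]
        raise DegenerateMatrixError(f"concepts with zero document count: {zero[:5]}")
    # PMI = ln(c_ij * N / (d_i * d_j)) on nonzeros
    with np.errstate(divide="ignore"):
        pmi = np.log(counts.data.astype(np.float64) * N / (d[counts.row] * d[counts.col]))
    data = np.maximum(pmi, 0.0)
    if not keep_diagonal:
        data[counts.row == counts.col] = 0.0
    out = sp.coo_matrix((data, (counts.row, counts.col)), shape=counts.shape).tocsr()
    out.eliminate_zeros()
    return PPMIMatrix(values=out, vocab=cooc.vocab)


def _fix_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # convention: largest-magnitude entry of each left singular vector positive
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, Vt * signs[:, None]


def embed_svd(ppmi: PPMIMatrix, k: int = 300, seed: int = 0) -> EmbeddingMatrix:
    """Truncated SVD of the PPMI matrix; returns rows of U_k S_k.

    ``k`` is clamped to the number of strictly positive singular values
    (and to n). For vocabularies up to ``DENSE_SVD_MAX_N`` the exact dense
    SVD is used; beyond that a randomized SVD seeded by ``seed`` keeps runs
    reproducible. Column signs follow the convention that the
    largest-magnitude entry of each left singular vector is positive.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    M = ppmi.values
    n = M.shape[0]
    if M.nnz == 0:
        raise DegenerateMatrixError("PPMI matrix is identically zero; nothing to embed")
    if n <= DENSE_SVD_MAX_N:
        U, s, Vt = np.linalg.svd(M.toarray(), full_matrices=False)
    else:
        U, s, Vt = randomized_svd(
            M, n_components=min(k, n), n_iter=7, random_state=int(seed) % (2**31)
        )
    tol = s[0] * max(M.shape) * np.finfo(np.float64).eps
    n_pos = int(np.sum(s > tol))
    k_eff = min(k, n_pos)
    U, s, Vt = U[:, :k_eff], s[:k_eff], Vt[:k_eff, :]
    U, Vt = _fix_signs(U, Vt)
    return EmbeddingMatrix(
        vectors=U * s, k=k_eff, vocab=ppmi.vocab, singular_values=s, vt=Vt
    )


def save_sparse_coo(matrix: sp.spmatrix, path) -> None:
    """Write a sparse matrix as 'row<TAB>col<TAB>value' text with a shape header."""
    coo = sp.coo_matrix(matrix)
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# shape {coo.shape[0]} {coo.shape[1]}\n")
        for r, c, v in zip(coo.row[order], coo.col[order], coo.data[order]):
            fh.write(f"{r}\t{c}\t{float(v)!r}\n")


def load_sparse_coo(path) -> sp.csr_matrix:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        shape = (int(header[-2]), int(header[-1]))
        rows, cols, data = [], [], []
        for line in fh:
            r, c, v = line.split("\t")
            rows.append(int(r))
            cols.append(int(c))
            data.append(float(v))
    return sp.coo_matrix((data, (rows, cols)), shape=shape).tocsr()
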