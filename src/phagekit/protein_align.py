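"""Affine-gap global/local protein alignment with identity, similarity and E-values.

Gap cost convention: a gap of length g costs ``gap_open + gap_extend * g``
(the BLAST/EMBOSS convention where the first gap residue pays both the
opening and one extension). Global mode penalizes end gaps. Identity and
similarity percentages use the total number of alignment columns (gap
columns included) as denominator by default; ``denominator="shorter"``
divides by the shorter sequence length instead (CD-HIT convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

GLOBAL_GAP_OPEN = 10.0
GLOBAL_GAP_EXTEND = 0.5
LOCAL_GAP_OPEN = 11.0
LOCAL_GAP_EXTEND = 1.0

#: gapped Karlin-Altschul parameters for BLOSUM62 with gap 11/1
DEFAULT_K = 0.041
DEFAULT_LAMBDA = 0.267


class AlignError(ValueError):
    pass


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer scoring matrix over an amino-acid alphabet."""

    name: str
    alphabet: str
    scores: np.ndarray

    def score(self, a: str, b: str) -> float:
        ia = self.alphabet.find(a)
        ib = self.alphabet.find(b)
        if ia < 0 or ib < 0:
            # unknown symbols behave like X
            ia = self.alphabet.find("X") if ia < 0 else ia
            ib = self.alphabet.find("X") if ib < 0 else ib
        return float(self.scores[ia, ib])


@lru_cache(maxsize=4)
def load_matrix(name: str = "BLOSUM62", x_neutral: bool = True) -> SubstitutionMatrix:
    """Load a named substitution matrix; X is rescored to 0 vs everything."""
    m = substitution_matrices.load(name)
    alphabet = str(m.alphabet)
    arr = np.array(m, dtype=float)
    if x_neutral and "X" in alphabet:
        ix = alphabet.index("X")
        arr[ix, :] = 0.0
        arr[:, ix] = 0.0
    return SubstitutionMatrix(name=name, alphabet=alphabet, scores=arr)


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    mode: str
    score: float
    aligned_cols: int
    n_identical: int
    n_positive: int
    identity_pct: float
    similarity_pct: float
    aligned_query: str
    aligned_subject: str


@dataclass
class LocalHit:
    result: AlignmentResult
    evalue: float
    m: int
    n: int
    K: float
    lam: float


def _sanitize(seq: str, alphabet: str) -> str:
    s = seq.upper().rstrip("*")
    if not s:
        raise AlignError("empty protein sequence")
    return "".join(c if c in alphabet else "X" for c in s)


def _make_aligner(matrix: SubstitutionMatrix, gap_open: float, gap_extend: float, mode: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    sm = substitution_matrices.Array(alphabet=matrix.alphabet, dims=2, data=matrix.scores)
    aligner.substitution_matrix = sm
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _finalize(query_id, subject_id, mode, score, qa, qb, matrix, denominator, qlen, slen):
    cols = len(qa)
    ident = sum(1 for x, y in zip(qa, qb) if x == y and x != "-")
    pos = sum(
        1 for x, y in zip(qa, qb) if x != "-" and y != "-" and matrix.score(x, y) > 0
    )
    denom = min(qlen, slen) if denominator == "shorter" else cols
    identity = 100.0 * ident / denom if denom else 0.0
    similarity = 100.0 * pos / denom if denom else 0.0
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        mode=mode,
        score=score,
        aligned_cols=cols,
        n_identical=ident,
        n_positive=pos,
        identity_pct=identity,
        similarity_pct=similarity,
        aligned_query=qa,
        aligned_subject=qb,
    )


def _align(
    a, b, matrix, gap_open, gap_extend, mode, query_id, subject_id, denominator
) -> AlignmentResult:
    sa = _sanitize(a, matrix.alphabet)
    sb = _sanitize(b, matrix.alphabet)
    aligner = _make_aligner(matrix, gap_open, gap_extend, mode)
    alignments = aligner.align(sa, sb)
    if mode == "local" and alignments.score <= 0:
        return _finalize(
            query_id, subject_id, mode, 0.0, "", "", matrix, denominator, len(sa), len(sb)
        )
    aln = alignments[0]
    qa, qb = str(aln[0]), str(aln[1])
    return _finalize(
        query_id, subject_id, mode, float(alignments.score), qa, qb, matrix,
        denominator, len(sa), len(sb),
    )


def global_align(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = GLOBAL_GAP_OPEN,
    gap_extend: float = GLOBAL_GAP_EXTEND,
    query_id: str = "query",
    subject_id: str = "subject",
    denominator: str = "columns",
) -> AlignmentResult:
    """Optimal Needleman-Wunsch alignment with affine gaps (end gaps penalized)."""
    matrix = matrix or load_matrix()
    return _align(a, b, matrix, gap_open, gap_extend, "global", query_id, subject_id, denominator)


def local_align(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = LOCAL_GAP_OPEN,
    gap_extend: float = LOCAL_GAP_EXTEND,
    query_id: str = "query",
    subject_id: str = "subject",
    denominator: str = "columns",
) -> AlignmentResult:
    """Optimal Smith-Waterman segment; empty alignment (score 0) allowed."""
    matrix = matrix or load_matrix()
    return _align(a, b, matrix, gap_open, gap_extend, "local", query_id, subject_id, denominator)


def evalue(
    score: float,
    query_len: int,
    db_len: int,
    K: float = DEFAULT_K,
    lam: float = DEFAULT_LAMBDA,
) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S).

    No composition-based adjustment and no finite-length correction.
    """
    if query_len <= 0 or db_len <= 0:
        raise AlignError("sequence/search-space lengths must be positive")
    return K * query_len * db_len * math.exp(-lam * score)


def local_hit(
    a: str,
    b: str,
    db_len: int | None = None,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = LOCAL_GAP_OPEN,
    gap_extend: float = LOCAL_GAP_EXTEND,
    K: float = DEFAULT_K,
    lam: float = DEFAULT_LAMBDA,
    query_id: str = "query",
    subject_id: str = "subject",
) -> LocalHit:
    """Local alignment of a vs b with a database-style E-value attached."""
    res = local_align(
        a, b, matrix, gap_open, gap_extend, query_id=query_id, subject_id=subject_id
    )
    m = len(a.rstrip("*"))
    n = db_len if db_len is not None else len(b.rstrip("*"))
    return LocalHit(result=res, evalue=evalue(res.score, m, n, K, lam), m=m, n=n, K=K, lam=lam)
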