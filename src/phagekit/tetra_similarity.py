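"""Z-score-normalized tetranucleotide signatures and pairwise R² comparison.

Observed tetramer counts are taken on the sequence plus its reverse
complement (counted independently, no chimeric k-mers at the junction);
expectations come from the maximal-order Markov model built from the tri-
and dinucleotide counts of the same data:

    E(n1n2n3n4)   = N(n1n2n3) * N(n2n3n4) / N(n2n3)
    var(n1n2n3n4) = E * (1 - N(n1n2n3)/N(n2n3)) * (1 - N(n2n3n4)/N(n2n3))
    z             = (N - E) / sqrt(var)        (z = 0 when E = 0 or var <= 0)
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from phagekit.genome_core import CircularSequence, reverse_complement

#: all 256 tetramers in lexicographic order
TETRAMERS = ["".join(p) for p in itertools.product("ACGT", repeat=4)]


class TetraError(ValueError):
    pass


@dataclass
class TetraProfile:
    genome_id: str
    z: dict[str, float]
    counts: dict[str, int]

    def z_vector(self) -> np.ndarray:
        return np.array([self.z[t] for t in TETRAMERS])

    def freq_vector(self) -> np.ndarray:
        v = np.array([self.counts[t] for t in TETRAMERS], dtype=float)
        total = v.sum()
        return v / total if total else v


@dataclass
class SimilarityMatrix:
    genome_ids: list[str]
    r2: np.ndarray
    nearest: dict[str, str]


def _kmer_counts(strings: list[str], k: int, circular: bool) -> dict[str, int]:
    """k-mer counts over every string (windows containing N are skipped)."""
    counts: dict[str, int] = {}
    for s in strings:
        if circular:
            s = s + s[: k - 1]
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if "N" in w:
                continue
            counts[w] = counts.get(w, 0) + 1
    return counts


def tetra_zscores(seq: CircularSequence, k: int = 4) -> TetraProfile:
    """Tetranucleotide z-score profile of one genome (strand-symmetric)."""
    if len(seq.residues) < k + 3:
        raise TetraError(f"sequence {seq.id!r} shorter than {k + 3} nt")
    strands = [seq.residues, reverse_complement(seq.residues)]
    circ = seq.is_circular
    n4 = _kmer_counts(strands, k, circ)
    n3 = _kmer_counts(strands, k - 1, circ)
    n2 = _kmer_counts(strands, k - 2, circ)
    kmers = (
        TETRAMERS if k == 4 else ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    )
    z: dict[str, float] = {}
    counts: dict[str, int] = {}
    for w in kmers:
        obs = n4.get(w, 0)
        counts[w] = obs
        left, right, mid = w[:-1], w[1:], w[1:-1]
        nm = n2.get(mid, 0)
        if nm == 0:
            z[w] = 0.0
            continue
        nl, nr = n3.get(left, 0), n3.get(right, 0)
        exp = nl * nr / nm
        var = exp * (1.0 - nl / nm) * (1.0 - nr / nm)
        if exp == 0.0 or var <= 0.0:
            z[w] = 0.0
        else:
            z[w] = (obs - exp) / math.sqrt(var)
    return TetraProfile(genome_id=seq.id, z=z, counts=counts)


def pairwise_r2(profiles: list[TetraProfile], raw_freq: bool = False) -> SimilarityMatrix:
    """Squared Pearson correlation between signatures, plus nearest matches."""
    if len(profiles) < 2:
        raise TetraError("need at least two profiles")
    keysets = {frozenset(p.z) for p in profiles}
    if len(keysets) != 1:
        raise TetraError("profiles have mismatching k-mer key sets")
    vectors = [p.freq_vector() if raw_freq else p.z_vector() for p in profiles]
    ids = [p.genome_id for p in profiles]
    for gid, v in zip(ids, vectors):
        if np.allclose(v, v[0]):
            raise TetraError(f"profile of {gid!r} has zero variance")
    m = len(ids)
    r2 = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            r = np.corrcoef(vectors[i], vectors[j])[0, 1]
            r2[i, j] = r2[j, i] = r * r
    nearest = {}
    for i, gid in enumerate(ids):
        others = [(r2[i, j], ids[j]) for j in range(m) if j != i]
        nearest[gid] = max(others)[1]
    return SimilarityMatrix(genome_ids=ids, r2=r2, nearest=nearest)
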