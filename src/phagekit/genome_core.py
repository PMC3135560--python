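"""Sequence containers, FASTA I/O, circular coordinates and composition stats.

Coordinates are 1-based inclusive throughout (GenBank convention). Circular
sequences support modular index arithmetic and rotation to a canonical start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

#: IUPAC nucleotide one-letter codes (ambiguity codes map to N on input).
IUPAC_NT = frozenset("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed or degenerate sequence input."""


@dataclass(frozen=True)
class CircularSequence:
    """A nucleotide sequence with explicit topology.

    Parameters
    ----------
    id :
        Record label (FASTA header token before first whitespace).
    residues :
        Uppercase string over ``{A, C, G, T, N}``.
    topology :
        ``"circular"`` or ``"linear"``. Circular topology makes index
        arithmetic modular and enables rotation.
    metadata :
        Free-form provenance, e.g. the rotation offset applied by
        :func:`canonicalize`.
    """

    id: str
    residues: str
    topology: str = "circular"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise SequenceError(f"unknown topology {self.topology!r}")
        if not self.residues:
            raise SequenceError(f"record {self.id!r} has zero-length sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise SequenceError(
                f"record {self.id!r} contains illegal characters {sorted(bad)}; "
                "normalize with read_fasta or sanitize_residues"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def base_at(self, pos: int) -> str:
        """Residue at 1-based position ``pos`` (modular when circular)."""
        if self.is_circular:
            return self.residues[(pos - 1) % len(self.residues)]
        if not 1 <= pos <= len(self.residues):
            raise IndexError(f"position {pos} outside linear sequence of length {len(self)}")
        return self.residues[pos - 1]

    def slice(self, start: int, length: int) -> str:
        """``length`` residues starting at 1-based ``start``, wrapping if circular."""
        n = len(self.residues)
        if self.is_circular:
            if length > 2 * n:
                raise SequenceError("slice longer than twice the circle")
            doubled = self.residues + self.residues
            i = (start - 1) % n
            return doubled[i : i + length]
        if start < 1 or start - 1 + length > n:
            raise IndexError(f"slice [{start}, +{length}] outside linear sequence")
        return self.residues[start - 1 : start - 1 + length]

    def reverse_complement(self) -> "CircularSequence":
        return replace(self, residues=reverse_complement(self.residues))


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def sanitize_residues(raw: str, record_id: str = "?") -> str:
    """Normalize raw FASTA letters: upper-case, U->T, other IUPAC codes -> N."""
    s = raw.upper().replace("U", "T")
    if not s:
        raise SequenceError(f"record {record_id!r} has zero-length sequence")
    bad = set(s) - ALPHABET
    if bad:
        illegal = bad - IUPAC_NT
        if illegal:
            raise SequenceError(
                f"record {record_id!r} contains non-IUPAC characters {sorted(illegal)}"
            )
        logger.warning(
            "record %r: ambiguity codes %s mapped to N", record_id, sorted(bad)
        )
        s = "".join(c if c in ALPHABET else "N" for c in s)
    return s


def read_fasta(path, topology: str = "circular") -> list[CircularSequence]:
    """Read a (single- or multi-record) FASTA file into CircularSequences.

    The header token before the first whitespace becomes the id. Lower-case
    letters are upper-cased, U maps to T, and non-ACGTN IUPAC ambiguity
    codes map to N with a logged warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        out.append(
            CircularSequence(
                id=rec.id,
                residues=sanitize_residues(str(rec.seq), rec.id),
                topology=topology,
            )
        )
    return out


def write_fasta(seqs, path, width: int = 60) -> None:
    """Write sequences as FASTA with ``width``-column line wrapping."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass(frozen=True)
class CompositionStats:
    """Mononucleotide fractions over the non-N residues of one sequence."""

    frac_A: float
    frac_C: float
    frac_G: float
    frac_T: float
    gc_fraction: float
    n_count: int
    length: int

    def percent(self, which: str) -> float:
        """Percentage rounded to one decimal for display, e.g. ``percent("GC")``."""
        value = {
            "A": self.frac_A,
            "C": self.frac_C,
            "G": self.frac_G,
            "T": self.frac_T,
            "GC": self.gc_fraction,
        }[which]
        return round(100.0 * value, 1)


def composition(seq: CircularSequence) -> CompositionStats:
    """Mononucleotide composition with N residues excluded from denominators."""
    counts = {b: seq.residues.count(b) for b in "ACGTN"}
    n_acgt = len(seq.residues) - counts["N"]
    if n_acgt == 0:
        raise SequenceError(f"record {seq.id!r} is all-N; composition undefined")
    fa, fc, fg, ft = (counts[b] / n_acgt for b in "ACGT")
    return CompositionStats(
        frac_A=fa,
        frac_C=fc,
        frac_G=fg,
        frac_T=ft,
        gc_fraction=fc + fg,
        n_count=counts["N"],
        length=len(seq.residues),
    )


def rotate(seq: CircularSequence, anchor_start: int) -> CircularSequence:
    """Rotation of a circular sequence with ``anchor_start`` mapped to position 1."""
    if not seq.is_circular:
        raise SequenceError("rotation undefined for linear topology")
    n = len(seq.residues)
    if not 1 <= anchor_start <= n:
        raise SequenceError(f"anchor_start {anchor_start} outside [1, {n}]")
    k = anchor_start - 1
    meta = dict(seq.metadata)
    meta["rotation_offset"] = (meta.get("rotation_offset", 0) + k) % n
    return replace(seq, residues=seq.residues[k:] + seq.residues[:k], metadata=meta)


# rotate() is the primitive; canonicalize() is the documented name for
# anchoring position 1 at a chosen start (e.g. the start codon of the
# longest predicted ORF, mirroring GenBank-style numbering).
canonicalize = rotate
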