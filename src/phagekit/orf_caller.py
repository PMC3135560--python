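"""ORF prediction on circular (or linear) genomes with wraparound support.

An ORF is a first-start-codon-to-stop interval in one reading frame on one
strand: scanning backwards in frame from the start codon, a stop codon is
reached before any earlier start codon. ORFs may wrap across the origin of
a circular sequence but may not span more than one full circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from phagekit.genome_core import CircularSequence, reverse_complement

DEFAULT_MIN_NT = 100
DEFAULT_START_CODONS = frozenset({"ATG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class OrfError(ValueError):
    pass


@dataclass(frozen=True)
class OrfRecord:
    """One predicted ORF.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates of the
    first base of the start codon and the last base of the stop codon *in
    reading order*: for '+' ORFs start precedes end (modularly); for '-'
    ORFs the reading direction runs from the higher coordinate downwards,
    so ``start`` > ``end`` unless the ORF wraps. ``nt_length`` includes the
    stop codon; ``aa_length`` excludes it.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    nt_length: int
    aa_length: int
    aa_seq: str

    def __post_init__(self):
        if self.nt_length != 3 * (self.aa_length + 1):
            raise OrfError("nt_length must equal 3*(aa_length+1)")
        if "*" in self.aa_seq:
            raise OrfError("internal stop in translation")


@dataclass
class OrfSet:
    genome_id: str
    genome_length: int
    records: list[OrfRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def longest(self) -> OrfRecord | None:
        return max(self.records, key=lambda r: r.aa_length, default=None)


def translate_codons(nt: str, table: int = 11) -> str:
    """Translate a stop-terminated nt string; returns aa without the stop."""
    aa = str(Seq(nt).translate(table=table))
    if not aa.endswith("*"):
        raise OrfError("sequence does not end in a stop codon")
    return aa[:-1]


def _scan_strand(
    residues: str,
    circular: bool,
    min_nt: int,
    start_codons: frozenset,
):
    """Yield (start0, nt_length) of ORFs on the given forward string.

    ``start0`` is the 0-based position of the start codon's first base on
    this strand's own coordinates. For circular sequences each stop codon
    anchors a backward in-frame walk (explicit modular arithmetic, exactly
    rotation invariant): the ORF, if any, begins at the first start codon
    after the previous in-frame stop, and may not be longer than the circle.
    """
    n = len(residues)
    if circular:
        doubled = residues + residues
        codon_at = lambda q: doubled[q : q + 3]  # noqa: E731
        stops = {q for q in range(n) if codon_at(q) in STOP_CODONS}
        # orbit of -3 steps mod n: the full in-frame cycle through a position
        orbit = n // 3 if n % 3 == 0 else n
        for t in sorted(stops):
            first_start = None  # (position, span in nt incl. stop)
            q = (t - 3) % n
            for k in range(1, orbit):
                if q in stops:
                    break  # previous stop reached: interval fully scanned
                if codon_at(q) in start_codons:
                    first_start = (q, 3 * k + 3)  # keeps updating -> earliest wins
                q = (q - 3) % n
            # (if the loop completes, the cycle closed back onto t itself)
            if first_start is not None:
                pos, nt_len = first_start
                if min_nt <= nt_len <= n:
                    # ORFs longer than the circle would wrap onto themselves
                    yield pos, nt_len
    else:
        for frame in range(3):
            open_start = None
            for i in range(frame, n - 2, 3):
                codon = residues[i : i + 3]
                if codon in STOP_CODONS:
                    if open_start is not None:
                        nt_len = i + 3 - open_start
                        if nt_len >= min_nt:
                            yield open_start, nt_len
                    open_start = None
                elif codon in start_codons and open_start is None:
                    open_start = i


def find_orfs(
    seq: CircularSequence,
    min_nt: int = DEFAULT_MIN_NT,
    start_codons=DEFAULT_START_CODONS,
    translation_table: int = 11,
    forward_only: bool = False,
) -> OrfSet:
    """Predict ORFs >= ``min_nt`` (start through stop inclusive) on both strands.

    Each stop-to-stop interval in each frame contributes at most one ORF,
    anchored at its first in-frame start codon. Wraparound across the origin
    of a circular sequence is allowed; an ORF may not wrap onto itself.
    """
    if min_nt < 3:
        raise OrfError("min_nt must be >= 3")
    n = len(seq.residues)
    if n < min_nt:
        raise OrfError(f"sequence length {n} shorter than min_nt {min_nt}")
    start_codons = frozenset(c.upper() for c in start_codons)
    circular = seq.is_circular
    records = []
    strands = [("+", seq.residues)]
    if not forward_only:
        strands.append(("-", reverse_complement(seq.residues)))
    for strand, residues in strands:
        for start0, nt_len in _scan_strand(residues, circular, min_nt, start_codons):
            nt = (residues + residues)[start0 : start0 + nt_len] if circular else residues[
                start0 : start0 + nt_len
            ]
            aa = translate_codons(nt, translation_table)
            if strand == "+":
                start = start0 + 1
                end = (start0 + nt_len - 1) % n + 1 if circular else start0 + nt_len
            else:
                # map strand-local coordinates back to forward coordinates
                start = n - start0
                end = (n - (start0 + nt_len - 1) - 1) % n + 1 if circular else n - (
                    start0 + nt_len - 1
                )
            records.append(
                OrfRecord(
                    genome_id=seq.id,
                    start=start,
                    end=end,
                    strand=strand,
                    nt_length=nt_len,
                    aa_length=nt_len // 3 - 1,
                    aa_seq=aa,
                )
            )
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    return OrfSet(genome_id=seq.id, genome_length=n, records=records)


def coding_capacity(orfs: OrfSet, genome_length: int, mode: str = "union") -> float:
    """Percent of the genome that is coding.

    ``union`` counts genome positions covered by at least one ORF (never
    exceeds 100); ``sum`` is 100 * total ORF nt / genome length and may
    exceed 100 when ORFs overlap. Display values round to the nearest
    integer (round half up).
    """
    if genome_length <= 0:
        raise OrfError("genome_length must be positive")
    if mode == "sum":
        return 100.0 * sum(r.nt_length for r in orfs.records) / genome_length
    if mode != "union":
        raise OrfError(f"unknown mode {mode!r}")
    covered = bytearray(genome_length)
    for r in orfs.records:
        if r.nt_length > genome_length:
            raise OrfError("ORF longer than genome")
        if r.strand == "+":
            first0 = r.start - 1
        else:
            first0 = (r.start - r.nt_length) % genome_length
        for k in range(r.nt_length):
            covered[(first0 + k) % genome_length] = 1
    return 100.0 * sum(covered) / genome_length


def orf_nt_sequence(seq: CircularSequence, rec: OrfRecord) -> str:
    """Genome slice (in reading order) claimed by an ORF record."""
    if rec.strand == "+":
        return seq.slice(rec.start, rec.nt_length)
    # '-' strand: rec.end is the lowest forward coordinate of the span
    return reverse_complement(seq.slice(rec.end, rec.nt_length))


def to_gff3(orfs: OrfSet) -> str:
    """GFF3 rendering; wraparound ORFs become two-part CDS features."""
    lines = ["##gff-version 3"]
    n = orfs.genome_length
    for i, r in enumerate(orfs.records, start=1):
        fid = f"{orfs.genome_id}_orf{i:02d}"
        attrs = f"ID={fid}"
        if r.strand == "+":
            lo, hi = r.start, r.start + r.nt_length - 1
        else:
            lo, hi = r.end, r.end + r.nt_length - 1
        if hi <= n:
            parts = [(lo, hi)]
        else:
            parts = [(lo, n), (1, hi - n)]
            attrs += ";wrap=true"
        for a, b in parts:
            lines.append(
                "\t".join(
                    [
                        orfs.genome_id,
                        "orf_caller",
                        "CDS",
                        str(a),
                        str(b),
                        ".",
                        r.strand,
                        "0",
                        attrs,
                    ]
                )
            )
    return "\n".join(lines) + "\n"
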