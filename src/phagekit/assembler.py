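"""Greedy exact-overlap assembly of circular genomes from unoriented fragments.

Only 100%-identity suffix/prefix overlaps of at least ``min_overlap`` nt are
merged (longest first, lexicographic id tie-break), and a contig whose own
ends share such an overlap is circularized by trimming one copy of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from phagekit.genome_core import CircularSequence, reverse_complement

DEFAULT_MIN_OVERLAP = 250


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class Fragment:
    id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise AssemblyError(f"fragment {self.id!r} is empty")
        bad = set(self.residues.upper()) - set("ACGT")
        if bad:
            raise AssemblyError(f"fragment {self.id!r} has non-ACGT characters {sorted(bad)}")


@dataclass
class LayoutEntry:
    fragment_id: str
    contig_id: str
    offset: int  # 0-based position of the fragment's first base in the contig
    orientation: str  # '+' or '-'


@dataclass
class AssemblyResult:
    contigs: list[CircularSequence]
    layout: list[LayoutEntry]
    circularized: dict[str, bool] = field(default_factory=dict)
    coverage_fold: float = 0.0


@dataclass
class _Contig:
    """Working contig: sequence plus the fragment placements inside it."""

    key: str  # lexicographically smallest member fragment id (tie-break key)
    seq: str
    frags: list[tuple[str, int, str]]  # (fragment id, offset, orientation)

    def rc(self) -> "_Contig":
        n = len(self.seq)
        flipped = [
            (fid, n - off - self._frag_len(fid), "-" if ori == "+" else "+")
            for fid, off, ori in self.frags
        ]
        c = _Contig(self.key, reverse_complement(self.seq), flipped)
        c._lens = self._lens
        return c

    _lens: dict = None

    def _frag_len(self, fid: str) -> int:
        return self._lens[fid]


def _suffix_prefix_overlap(a: str, b: str, min_overlap: int, max_o: int | None = None) -> int:
    """Length of the longest exact overlap between a suffix of a and a prefix of b."""
    if max_o is None:
        max_o = min(len(a), len(b))
    for o in range(max_o, min_overlap - 1, -1):
        if a.endswith(b[:o]):
            return o
    return 0


def assemble_exact(
    fragments: list[Fragment], min_overlap: int = DEFAULT_MIN_OVERLAP
) -> AssemblyResult:
    """Assemble fragments by greedy merging of exact overlaps.

    Repeatedly merges the pair of contigs (in either relative orientation)
    with the longest exact suffix-prefix overlap >= ``min_overlap`` until no
    merge is possible; then circularizes any contig whose own ends overlap
    exactly by >= ``min_overlap``. Deterministic given the fragment set:
    ties are broken by the lexicographically smallest involved fragment ids.
    """
    if not fragments:
        raise AssemblyError("no fragments given")
    if min_overlap < 20:
        raise AssemblyError("min_overlap must be >= 20")
    ids = [f.id for f in fragments]
    if len(set(ids)) != len(ids):
        raise AssemblyError("duplicate fragment ids")
    if all(len(f.residues) < min_overlap for f in fragments):
        raise AssemblyError("min_overlap longer than every fragment")

    lens = {f.id: len(f.residues) for f in fragments}
    contigs: dict[str, _Contig] = {}
    for f in sorted(fragments, key=lambda x: x.id):
        c = _Contig(f.id, f.residues.upper(), [(f.id, 0, "+")])
        c._lens = lens
        contigs[f.id] = c

    while True:
        best = None  # (overlap, key_a, key_b, flip_b)
        keys = sorted(contigs)
        for ka in keys:
            for kb in keys:
                if ka == kb:
                    continue
                a, b = contigs[ka], contigs[kb]
                for flip, bseq in ((False, b.seq), (True, reverse_complement(b.seq))):
                    o = _suffix_prefix_overlap(a.seq, bseq, min_overlap)
                    if o >= min_overlap:
                        cand = (o, ka, kb, flip)
                        if best is None or (cand[0], ) > (best[0], ) or (
                            cand[0] == best[0] and (ka, kb) < (best[1], best[2])
                        ):
                            best = cand
        if best is None:
            break
        o, ka, kb, flip = best
        a = contigs.pop(ka)
        b = contigs.pop(kb)
        if flip:
            b = b.rc()
        shift = len(a.seq) - o
        merged = _Contig(
            min(a.key, b.key),
            a.seq + b.seq[o:],
            a.frags + [(fid, off + shift, ori) for fid, off, ori in b.frags],
        )
        merged._lens = lens
        contigs[merged.key] = merged

    out_contigs: list[CircularSequence] = []
    layout: list[LayoutEntry] = []
    circularized: dict[str, bool] = {}
    total_frag_nt = sum(lens.values())
    total_contig_nt = 0
    for i, key in enumerate(sorted(contigs), start=1):
        c = contigs[key]
        cid = f"contig_{i}"
        seq, frags = c.seq, c.frags
        circ = False
        o = _suffix_prefix_overlap(seq, seq, min_overlap, max_o=len(seq) - 1)
        if o >= min_overlap:
            seq = seq[: len(seq) - o]
            frags = [(fid, off % len(seq), ori) for fid, off, ori in frags]
            circ = True
        out_contigs.append(
            CircularSequence(id=cid, residues=seq, topology="circular" if circ else "linear")
        )
        circularized[cid] = circ
        total_contig_nt += len(seq)
        for fid, off, ori in sorted(frags, key=lambda t: (t[1], t[0])):
            layout.append(LayoutEntry(fid, cid, off, ori))
    coverage = total_frag_nt / total_contig_nt if total_contig_nt else 0.0
    return AssemblyResult(
        contigs=out_contigs,
        layout=layout,
        circularized=circularized,
        coverage_fold=coverage,
    )
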