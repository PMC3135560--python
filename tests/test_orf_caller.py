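"""ORF caller tests, including an independent per-position modular oracle."""

import pytest

from phagekit.genome_core import CircularSequence, reverse_complement, rotate
from phagekit.orf_caller import (
    OrfError,
    STOP_CODONS,
    coding_capacity,
    find_orfs,
    orf_nt_sequence,
    to_gff3,
)

START_CODONS = {"ATG"}


def oracle_orfs(residues: str, circular: bool, min_nt: int, forward_only=False):
    """Enumerate ORFs by explicit (position, strand) modular walks.

    For every start-codon position, walk forward codon-by-codon to the first
    stop; the candidate is an ORF iff walking backward in frame hits a stop
    before any other start codon, and its span does not exceed the circle.
    Returns a set of (strand, start0-on-strand, nt_len) tuples.
    """
    out = set()
    n = len(residues)
    strands = [("+", residues)] if forward_only else [
        ("+", residues),
        ("-", reverse_complement(residues)),
    ]
    for strand, r in strands:
        def codon(q):
            if circular:
                return r[q % n] + r[(q + 1) % n] + r[(q + 2) % n]
            return r[q : q + 3] if q + 3 <= n else ""

        positions = range(n) if circular else range(n - 2)
        for q in positions:
            if codon(q) not in START_CODONS:
                continue
            # forward walk to the first stop
            nt_len = None
            x, steps = q + 3, 1
            max_codons = n if circular else (n - q) // 3
            while steps <= max_codons:
                c = codon(x) if circular else codon(x)
                if not circular and x + 3 > n:
                    break
                if c in STOP_CODONS:
                    nt_len = 3 * steps + 3
                    break
                x += 3
                steps += 1
            if nt_len is None or nt_len < min_nt or nt_len > n:
                continue
            # backward walk: a stop must come before any other start
            ok = False
            x, back = q - 3, 1
            limit = n if circular else q // 3 + 1
            while back <= limit:
                if not circular and x < 0:
                    ok = True  # sequence edge acts as interval boundary
                    break
                c = codon(x % n if circular else x)
                if c in STOP_CODONS:
                    ok = True
                    break
                if c in START_CODONS:
                    ok = False
                    break
                x -= 3
                back += 1
            if ok:
                out.add((strand, q, nt_len))
    return out


def orfset_as_tuples(orfs, n):
    """Map OrfRecords to (strand, start0-on-strand, nt_len) for oracle comparison."""
    out = set()
    for r in orfs.records:
        if r.strand == "+":
            start0 = r.start - 1
        else:
            start0 = n - r.start
        out.add((r.strand, start0, r.nt_length))
    return out


class TestFindOrfsConstructed:
    def test_minimal_orf(self):
        # 9 nt coding + 93 nt of A padding: poly-A is stop-free, and the ORF
        # ATG AAA TAA is the only start-anchored interval on either strand
        seq = CircularSequence(id="t", residues="ATGAAATAA" + "A" * 93)
        orfs = find_orfs(seq, min_nt=9)
        matching = [r for r in orfs.records if r.aa_seq == "MK"]
        assert len(matching) == 1
        rec = matching[0]
        assert (rec.start, rec.end, rec.strand) == (1, 9, "+")
        assert rec.nt_length == 9 and rec.aa_length == 2

    def test_no_orfs_below_threshold(self):
        seq = CircularSequence(id="t", residues="ATGAAATAA" + "A" * 93)
        orfs = find_orfs(seq, min_nt=100)
        assert len([r for r in orfs.records if r.strand == "+"]) == 0

    def test_wraparound_orf(self):
        # place the ORF across the origin: last 6 nt are ATG AAA, first 3 are TAA
        core = "ATGAAATAA"
        seq = CircularSequence(id="t", residues=core + "A" * 93)
        rot = rotate(seq, 7)  # start codon now at position len-5
        orfs = find_orfs(rot, min_nt=9)
        matching = [r for r in orfs.records if r.aa_seq == "MK"]
        assert len(matching) == 1
        rec = matching[0]
        n = len(rot.residues)
        assert rec.start == n - 5
        assert rec.end == 3  # stop codon wraps the origin: occupies 1..3
        assert orf_nt_sequence(rot, rec) == "ATGAAATAA"

    def test_min_nt_validation(self):
        seq = CircularSequence(id="t", residues="ATGAAATAA" + "A" * 93)
        with pytest.raises(OrfError):
            find_orfs(seq, min_nt=2)

    def test_short_sequence_errors(self):
        with pytest.raises(OrfError):
            find_orfs(CircularSequence(id="t", residues="ATGAAATAA"), min_nt=100)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_circular_600(self, seed):
        import numpy as np

        from conftest import random_dna

        rng = np.random.default_rng(seed)
        residues = random_dna(rng, 600, gc=0.45)
        seq = CircularSequence(id=f"r{seed}", residues=residues)
        orfs = find_orfs(seq, min_nt=60)
        assert orfset_as_tuples(orfs, 600) == oracle_orfs(residues, True, 60)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_linear(self, seed):
        import numpy as np

        from conftest import random_dna

        rng = np.random.default_rng(100 + seed)
        residues = random_dna(rng, 500, gc=0.5)
        seq = CircularSequence(id=f"l{seed}", residues=residues, topology="linear")
        orfs = find_orfs(seq, min_nt=60)
        assert orfset_as_tuples(orfs, 500) == oracle_orfs(residues, False, 60)

    def test_length_not_multiple_of_three(self):
        import numpy as np

        from conftest import random_dna

        for n in (601, 602):
            rng = np.random.default_rng(n)
            residues = random_dna(rng, n, gc=0.4)
            seq = CircularSequence(id="x", residues=residues)
            orfs = find_orfs(seq, min_nt=60)
            assert orfset_as_tuples(orfs, n) == oracle_orfs(residues, True, 60)


class TestInvariants:
    def test_rotation_invariance(self, random_circular, rng):
        seq = random_circular(n=600, gc=0.45)
        base = {(r.strand, r.nt_length, r.aa_seq) for r in find_orfs(seq, min_nt=60)}
        for _ in range(5):
            k = int(rng.integers(2, 600))
            rot = rotate(seq, k)
            rotated = {(r.strand, r.nt_length, r.aa_seq) for r in find_orfs(rot, min_nt=60)}
            assert rotated == base

    def test_strand_symmetry(self, random_circular):
        seq = random_circular(n=600, gc=0.45)
        rc = seq.reverse_complement()
        fwd = {(r.strand, r.nt_length, r.aa_seq) for r in find_orfs(seq, min_nt=60)}
        flipped = {
            ("+" if s == "-" else "-", L, aa)
            for s, L, aa in ((r.strand, r.nt_length, r.aa_seq) for r in find_orfs(rc, min_nt=60))
        }
        assert fwd == flipped

    def test_retranslation_fixpoint(self, random_circular):
        seq = random_circular(n=900, gc=0.45)
        from phagekit.orf_caller import translate_codons

        for rec in find_orfs(seq, min_nt=60):
            nt = orf_nt_sequence(seq, rec)
            assert translate_codons(nt) == rec.aa_seq


class TestCodingCapacity:
    def test_paper_worked_example(self):
        # ten ORF aa lengths -> sum mode 91% on a 5,514 nt genome
        from phagekit.orf_caller import OrfRecord, OrfSet

        aa_lengths = [565, 234, 353, 71, 78, 39, 80, 80, 117, 52]
        records = []
        pos = 1
        for aa in aa_lengths:
            nt = (aa + 1) * 3
            records.append(
                OrfRecord(
                    genome_id="g",
                    start=pos,
                    end=pos + nt - 1,
                    strand="+",
                    nt_length=nt,
                    aa_length=aa,
                    aa_seq="M" * aa,
                )
            )
            pos += nt
        orfs = OrfSet(genome_id="g", genome_length=5514, records=records)
        assert sum(r.nt_length for r in records) == 5037
        pct = coding_capacity(orfs, 5514, mode="sum")
        assert round(pct) == 91

    def test_empty_is_zero(self):
        from phagekit.orf_caller import OrfSet

        assert coding_capacity(OrfSet("g", 100, []), 100) == 0.0

    def test_union_against_bitmap_oracle(self, random_circular):
        seq = random_circular(n=900, gc=0.45)
        orfs = find_orfs(seq, min_nt=60)
        n = len(seq.residues)
        # independent bitmap: mark positions via each record's own span walk
        marked = set()
        for r in orfs.records:
            first0 = (r.start - 1) if r.strand == "+" else (r.start - r.nt_length) % n
            for k in range(r.nt_length):
                marked.add((first0 + k) % n)
        assert coding_capacity(orfs, n, mode="union") == pytest.approx(
            100.0 * len(marked) / n
        )

    def test_union_monotone_and_bounded(self, random_circular):
        from phagekit.orf_caller import OrfSet

        seq = random_circular(n=900, gc=0.45)
        orfs = find_orfs(seq, min_nt=60)
        prev = 0.0
        for k in range(len(orfs.records) + 1):
            sub = OrfSet(seq.id, 900, orfs.records[:k])
            val = coding_capacity(sub, 900, mode="union")
            assert val >= prev
            assert val <= 100.0
            prev = val


def test_gff3_output_wraparound(random_circular):
    seq = CircularSequence(id="t", residues=rotate(
        CircularSequence(id="t", residues="ATGAAATAA" + "A" * 93), 7
    ).residues)
    orfs = find_orfs(seq, min_nt=9)
    gff = to_gff3(orfs)
    assert gff.startswith("##gff-version 3")
    assert "wrap=true" in gff
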