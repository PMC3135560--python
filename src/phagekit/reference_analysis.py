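"""Headline analyses of the reference genome set (requires fetched sequences).

These helpers reproduce the deposited-genome numbers: composition, longest
ORF, tetranucleotide R² against the nearest relative, and capsid/rep
protein identities. They raise :class:`FileNotFoundError` when the
reference FASTA files have not been fetched.
"""

from __future__ import annotations

from phagekit.genome_core import composition
from phagekit.orf_caller import OrfRecord, OrfSet, find_orfs
from phagekit.protein_align import AlignmentResult, local_align
from phagekit.reference import QUERY_ACCESSION, load_genome
from phagekit.tetra_similarity import pairwise_r2, tetra_zscores

SPV4_ACCESSION = "NC_003438"


def query_genome():
    return load_genome(QUERY_ACCESSION)


def query_orfs(min_nt: int = 100) -> OrfSet:
    return find_orfs(query_genome(), min_nt=min_nt)


def query_gc_percent() -> float:
    return composition(query_genome()).percent("GC")


def query_a_percent() -> float:
    return composition(query_genome()).percent("A")


def tetra_r2_vs(accession: str = SPV4_ACCESSION) -> float:
    """R² of tetranucleotide z-scores between the query genome and another."""
    profiles = [tetra_zscores(query_genome()), tetra_zscores(load_genome(accession))]
    return float(pairwise_r2(profiles).r2[0, 1])


def orf_with_aa_length(orfs: OrfSet, aa_length: int) -> OrfRecord:
    """The unique ORF of a given amino-acid length (errors if not unique)."""
    matches = [r for r in orfs.records if r.aa_length == aa_length]
    if len(matches) != 1:
        raise ValueError(
            f"expected exactly one ORF of {aa_length} aa, found {len(matches)}"
        )
    return matches[0]


def best_counterpart(protein: str, accession: str = SPV4_ACCESSION, min_nt: int = 100):
    """The subject genome's predicted protein with the best local hit to ``protein``."""
    subject_orfs = find_orfs(load_genome(accession), min_nt=min_nt)
    best = None
    for rec in subject_orfs.records:
        res = local_align(protein, rec.aa_seq)
        if best is None or res.score > best[0].score:
            best = (res, rec)
    if best is None:
        raise ValueError(f"no ORFs predicted for {accession}")
    return best


def capsid_identity_vs_spv4() -> AlignmentResult:
    """Local identity of the query's longest ORF vs its best SpV4 counterpart."""
    orf1 = query_orfs().longest()
    res, _ = best_counterpart(orf1.aa_seq)
    return res


def rep_identity_vs_spv4(rep_aa_length: int = 353) -> AlignmentResult:
    """Local identity of the query's replication-initiation ORF (selected by
    its published length) vs its best SpV4 counterpart."""
    rep = orf_with_aa_length(query_orfs(), rep_aa_length)
    res, _ = best_counterpart(rep.aa_seq)
    return res
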