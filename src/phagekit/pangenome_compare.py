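"""Pangenome construction and shared/unique gene determination for a query genome.

The pangenome is the plain pooled union of predicted genes across source
genomes. A query gene is *shared by clustering* when a joint greedy
clustering of query + pangenome at the threshold places it with at least
one pangenome gene, *shared by local alignment* when its best local hit
against the pooled pangenome reaches the E-value cutoff, and *unique* when
neither holds. The two routes are reported independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from phagekit.gene_clustering import ProteinRecord, greedy_cluster
from phagekit.protein_align import local_hit

DEFAULT_CLUSTER_THRESHOLD = 0.40
DEFAULT_EVALUE_CUTOFF = 0.01


class PangenomeError(ValueError):
    pass


@dataclass
class Pangenome:
    proteins: list[ProteinRecord]
    source_manifest: dict[str, int]

    @property
    def total_residues(self) -> int:
        return sum(len(p.aa_seq.rstrip("*")) for p in self.proteins)


@dataclass
class BestHit:
    gene: tuple[str, str]
    subject: tuple[str, str] | None
    identity_pct: float
    evalue: float
    score: float


@dataclass
class SharedUniqueReport:
    query_id: str
    n_query_genes: int
    shared_by_cluster: set = field(default_factory=set)
    shared_by_local: set = field(default_factory=set)
    unique: set = field(default_factory=set)
    best_hits: list[BestHit] = field(default_factory=list)


def build_pangenome(genome_protein_sets: dict[str, list[ProteinRecord]]) -> Pangenome:
    """Pooled union of per-genome gene sets with a per-source manifest."""
    if not genome_protein_sets:
        raise PangenomeError("no genomes given")
    proteins: list[ProteinRecord] = []
    manifest: dict[str, int] = {}
    seen = set()
    for genome_id in genome_protein_sets:
        genes = genome_protein_sets[genome_id]
        if not genes:
            raise PangenomeError(f"genome {genome_id!r} contributes no genes")
        for p in genes:
            if p.key in seen:
                raise PangenomeError(f"duplicate gene key {p.key}")
            seen.add(p.key)
            proteins.append(p)
        manifest[genome_id] = len(genes)
    return Pangenome(proteins=proteins, source_manifest=manifest)


def shared_unique(
    query: list[ProteinRecord],
    pan: Pangenome,
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    similarity_def: str = "shorter",
) -> SharedUniqueReport:
    """Classify each query gene as shared (by cluster and/or local hit) or unique."""
    if not query:
        raise PangenomeError("empty query gene set")
    if not pan.proteins:
        raise PangenomeError("empty pangenome")
    query_keys = {p.key for p in query}
    pan_keys = {p.key for p in pan.proteins}
    if query_keys & pan_keys:
        raise PangenomeError("query and pangenome share gene keys")

    # cluster route: joint clustering of query + pangenome
    joint = greedy_cluster(
        query + list(pan.proteins), threshold=cluster_threshold, similarity_def=similarity_def
    )
    shared_cluster = set()
    for c in joint.clusters:
        members = set(c.members)
        if members & pan_keys:
            shared_cluster |= members & query_keys

    # local route: best hit of each query gene against the pooled database
    db_len = pan.total_residues
    shared_local = set()
    best_hits = []
    for q in query:
        best = None
        for s in pan.proteins:
            hit = local_hit(
                q.aa_seq,
                s.aa_seq,
                db_len=db_len,
                query_id=f"{q.genome_id}|{q.gene_id}",
                subject_id=f"{s.genome_id}|{s.gene_id}",
            )
            if best is None or hit.result.score > best[0].result.score:
                best = (hit, s.key)
        hit, skey = best
        best_hits.append(
            BestHit(
                gene=q.key,
                subject=skey if hit.result.score > 0 else None,
                identity_pct=hit.result.identity_pct,
                evalue=hit.evalue,
                score=hit.result.score,
            )
        )
        if hit.evalue <= evalue_cutoff:
            shared_local.add(q.key)

    unique = query_keys - shared_cluster - shared_local
    return SharedUniqueReport(
        query_id=query[0].genome_id,
        n_query_genes=len(query),
        shared_by_cluster=shared_cluster,
        shared_by_local=shared_local,
        unique=unique,
        best_hits=best_hits,
    )
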