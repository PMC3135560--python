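"""Greedy incremental protein clustering at a similarity threshold.

Sequences are processed longest-first; each either joins the best-matching
existing representative whose similarity strictly exceeds the threshold, or
founds a new cluster. Similarity defaults to identical residues in the
optimal global alignment divided by the shorter sequence length (the CD-HIT
definition); ``similarity_def="columns"`` divides by alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from phagekit.protein_align import SubstitutionMatrix, global_align, load_matrix

DEFAULT_THRESHOLD = 0.40


class ClusterError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    genome_id: str
    gene_id: str
    aa_seq: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.genome_id, self.gene_id)


@dataclass
class Cluster:
    representative: tuple[str, str]
    members: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class Clustering:
    clusters: list[Cluster]
    threshold: float

    def cluster_of(self) -> dict[tuple[str, str], int]:
        out = {}
        for i, c in enumerate(self.clusters):
            for m in c.members:
                out[m] = i
        return out

    def __len__(self):
        return len(self.clusters)


def pair_similarity(
    a: str,
    b: str,
    similarity_def: str = "shorter",
    matrix: SubstitutionMatrix | None = None,
) -> float:
    """Global-alignment identity fraction under the chosen denominator."""
    res = global_align(a, b, matrix=matrix)
    if similarity_def == "shorter":
        denom = min(len(a.rstrip("*")), len(b.rstrip("*")))
    elif similarity_def == "columns":
        denom = res.aligned_cols
    else:
        raise ClusterError(f"unknown similarity_def {similarity_def!r}")
    return res.n_identical / denom if denom else 0.0


def greedy_cluster(
    proteins: list[ProteinRecord],
    threshold: float = DEFAULT_THRESHOLD,
    similarity_def: str = "shorter",
    matrix: SubstitutionMatrix | None = None,
) -> Clustering:
    """CD-HIT-style greedy clustering (accurate mode: best representative wins).

    Membership requires similarity strictly greater than ``threshold``
    (">40% similar" is strict; boundary equality founds a new cluster).
    """
    if not proteins:
        raise ClusterError("empty input")
    if not 0.0 < threshold <= 1.0:
        raise ClusterError("threshold must be in (0, 1]")
    keys = [p.key for p in proteins]
    if len(set(keys)) != len(keys):
        raise ClusterError("duplicate (genome_id, gene_id) keys")
    matrix = matrix or load_matrix()
    ordered = sorted(proteins, key=lambda p: (-len(p.aa_seq.rstrip("*")), p.key))
    clusters: list[Cluster] = []
    reps: list[ProteinRecord] = []
    for p in ordered:
        best_i, best_sim = None, threshold
        for i, rep in enumerate(reps):
            sim = pair_similarity(p.aa_seq, rep.aa_seq, similarity_def, matrix)
            # strict threshold; earliest (longest) representative wins exact ties
            if sim > best_sim:
                best_i, best_sim = i, sim
        if best_i is None:
            reps.append(p)
            clusters.append(Cluster(representative=p.key, members=[p.key]))
        else:
            clusters[best_i].members.append(p.key)
    return Clustering(clusters=clusters, threshold=threshold)


@dataclass
class MembershipMatrix:
    genome_ids: list[str]
    cluster_ids: list[str]
    counts: list[list[int]]

    def row(self, genome_id: str) -> list[int]:
        return self.counts[self.genome_ids.index(genome_id)]

    def binarized(self) -> "MembershipMatrix":
        return MembershipMatrix(
            genome_ids=list(self.genome_ids),
            cluster_ids=list(self.cluster_ids),
            counts=[[1 if c else 0 for c in row] for row in self.counts],
        )


def membership_matrix(clustering: Clustering, genomes: list[str]) -> MembershipMatrix:
    """Genome x cluster gene-count incidence matrix."""
    index = {g: i for i, g in enumerate(genomes)}
    counts = [[0] * len(clustering.clusters) for _ in genomes]
    for j, cluster in enumerate(clustering.clusters):
        for genome_id, _gene in cluster.members:
            if genome_id not in index:
                raise ClusterError(f"unknown genome id {genome_id!r}")
            counts[index[genome_id]][j] += 1
    cluster_ids = [f"cluster_{j}" for j in range(len(clustering.clusters))]
    return MembershipMatrix(genome_ids=list(genomes), cluster_ids=cluster_ids, counts=counts)


def write_clstr(clustering: Clustering, proteins: list[ProteinRecord], path) -> None:
    """CD-HIT ``.clstr``-style text output."""
    lens = {p.key: len(p.aa_seq.rstrip("*")) for p in proteins}
    with open(path, "w") as fh:
        for i, c in enumerate(clustering.clusters):
            fh.write(f">Cluster {i}\n")
            for j, m in enumerate(c.members):
                tag = "*" if m == c.representative else ""
                fh.write(f"{j}\t{lens[m]}aa, >{m[0]}|{m[1]}... {tag}\n")
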