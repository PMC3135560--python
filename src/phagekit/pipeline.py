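"""End-to-end analysis pipeline: stats -> ORFs -> tetra -> cluster -> pangenome -> trees.

Produces a machine-readable report in which every number is recomputable
from the inputs plus the configuration (no hidden state); reruns on the
same inputs yield identical report content apart from the timestamp.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from phagekit import __version__
from phagekit.gene_clustering import (
    ProteinRecord,
    greedy_cluster,
    membership_matrix,
)
from phagekit.genome_core import composition, read_fasta
from phagekit.orf_caller import coding_capacity, find_orfs
from phagekit.pangenome_compare import build_pangenome, shared_unique
from phagekit.profiles_trees import ProfileTable, profile_distance, upgma
from phagekit.tetra_similarity import pairwise_r2, tetra_zscores

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    genome_fastas: list[str]
    query_genome_id: str | None = None
    protein_fastas: list[str] = field(default_factory=list)  # else predicted from ORFs
    min_orf_nt: int = 100
    cluster_threshold: float = 0.40
    evalue_cutoff: float = 0.01
    tetra_circular: bool = True
    tree_metric: str = "jaccard"
    output_dir: str = "phagekit_out"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.cluster_threshold <= 1:
            raise PipelineError("cluster_threshold outside (0, 1]")
        if self.evalue_cutoff <= 0:
            raise PipelineError("evalue_cutoff must be positive")
        if self.min_orf_nt < 3:
            raise PipelineError("min_orf_nt must be >= 3")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        for path in list(self.genome_fastas) + list(self.protein_fastas):
            payload[f"digest:{path}"] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_proteins(config, genomes) -> dict[str, list[ProteinRecord]]:
    from Bio import SeqIO

    if config.protein_fastas:
        out: dict[str, list[ProteinRecord]] = {}
        for path in config.protein_fastas:
            genome_id = Path(path).stem
            out[genome_id] = [
                ProteinRecord(genome_id, rec.id, str(rec.seq).rstrip("*"))
                for rec in SeqIO.parse(path, "fasta")
            ]
        return out
    out = {}
    for g in genomes:
        orfs = find_orfs(g, min_nt=config.min_orf_nt)
        out[g.id] = [
            ProteinRecord(g.id, f"orf{i:02d}", r.aa_seq)
            for i, r in enumerate(sorted(orfs.records, key=lambda r: -r.aa_length), start=1)
        ]
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the analysis report as a plain dict."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": 1,
        "provenance": {
            "phagekit_version": __version__,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    }
    stage = "stats"
    try:
        genomes = []
        for path in config.genome_fastas:
            genomes.extend(read_fasta(path, topology="circular"))
        report["genomes"] = {}
        orf_sets = {}
        for g in genomes:
            stage = f"stats:{g.id}"
            comp = composition(g)
            stage = f"orfs:{g.id}"
            orfs = find_orfs(g, min_nt=config.min_orf_nt)
            orf_sets[g.id] = orfs
            report["genomes"][g.id] = {
                "length": len(g.residues),
                "A_pct": comp.percent("A"),
                "C_pct": comp.percent("C"),
                "G_pct": comp.percent("G"),
                "T_pct": comp.percent("T"),
                "GC_pct": comp.percent("GC"),
                "n_orfs": len(orfs),
                "longest_orf_aa": orfs.longest().aa_length if len(orfs) else 0,
                "coding_capacity_sum_pct": round(
                    coding_capacity(orfs, len(g.residues), mode="sum")
                ),
                "coding_capacity_union_pct": round(
                    coding_capacity(orfs, len(g.residues), mode="union")
                ),
            }
        if len(genomes) < 2:
            report["comparisons"] = "not-applicable (single genome)"
            report["runtime_s"] = round(time.time() - t0, 3)
            _write_report(report, outdir)
            return report

        stage = "tetra"
        profiles = [tetra_zscores(g) for g in genomes]
        sim = pairwise_r2(profiles)
        report["tetra"] = {
            "genome_ids": sim.genome_ids,
            "r2": [[round(v, 6) for v in row] for row in sim.r2.tolist()],
            "nearest": sim.nearest,
        }

        stage = "cluster"
        proteins_by_genome = _load_proteins(config, genomes)
        all_proteins = [p for ps in proteins_by_genome.values() for p in ps]
        clustering = greedy_cluster(all_proteins, threshold=config.cluster_threshold)
        genome_ids = [g.id for g in genomes]
        members = membership_matrix(clustering, genome_ids)
        report["clustering"] = {
            "n_proteins": len(all_proteins),
            "n_clusters": len(clustering),
            "threshold": config.cluster_threshold,
        }

        stage = "pangenome"
        if config.query_genome_id:
            qid = config.query_genome_id
            if qid not in proteins_by_genome:
                raise PipelineError(f"query genome {qid!r} not among inputs")
            pan = build_pangenome(
                {k: v for k, v in proteins_by_genome.items() if k != qid}
            )
            rep = shared_unique(
                proteins_by_genome[qid],
                pan,
                cluster_threshold=config.cluster_threshold,
                evalue_cutoff=config.evalue_cutoff,
            )
            report["pangenome"] = {
                "query": qid,
                "n_query_genes": rep.n_query_genes,
                "shared_by_cluster": len(rep.shared_by_cluster),
                "shared_by_local": len(rep.shared_by_local),
                "unique": len(rep.unique),
            }

        stage = "trees"
        table = ProfileTable(
            row_ids=members.genome_ids,
            column_ids=members.cluster_ids,
            values=members.counts,
        )
        dm = profile_distance(table, metric=config.tree_metric)
        tree = upgma(dm)
        newick = tree.newick()
        (outdir / "membership_upgma.nwk").write_text(newick + "\n")
        report["trees"] = {"membership_upgma_newick": newick}
        report["runtime_s"] = round(time.time() - t0, 3)
        _write_report(report, outdir)
        return report
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _write_report(report: dict, outdir: Path) -> None:
    path = outdir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("report written to %s", path)


def canonical_report_json(report: dict) -> str:
    """Report serialization with volatile fields removed (for byte-diff checks)."""
    pruned = json.loads(json.dumps(report))
    pruned.get("provenance", {}).pop("timestamp", None)
    pruned.get("provenance", {}).get("config", {}).pop("output_dir", None)
    pruned.pop("runtime_s", None)
    return json.dumps(pruned, indent=2, sort_keys=True)
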