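"""Seeded synthetic datasets with truth tables for every analysis stage.

Generates orthologous protein families evolved down a random ultrametric
tree (uniform amino-acid replacement model, so expected pairwise identity
has a closed form), back-translates them with a GC-biased codon choice,
assembles modular circular genomes with stop-guarded spacers, and shreds
genomes into overlapping fragments. All randomness flows from one integer
seed through per-stage spawned generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from phagekit.assembler import Fragment
from phagekit.genome_core import CircularSequence, reverse_complement
from phagekit.profiles_trees import TreeNode

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: table 11 codons per amino acid, sorted by (GC count, codon) ascending
CODONS = {
    "A": ["GCA", "GCT", "GCC", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGA", "GGT", "GGC", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATA", "ATT", "ATC"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "CTA", "CTT", "TTG", "CTC", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCA", "CCT", "CCC", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["AGA", "CGA", "AGG", "CGT", "CGC", "CGG"],
    "S": ["AGT", "TCA", "TCT", "AGC", "TCC", "TCG"],
    "T": ["ACA", "ACT", "ACC", "ACG"],
    "V": ["GTA", "GTT", "GTC", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
STOPS_BY_GC = ["TAA", "TAG", "TGA"]


def _gc(s: str) -> int:
    return s.count("G") + s.count("C")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_genomes: int = 15
    n_families: int = 8
    tree_height: float = 0.5
    aa_rate_per_branch: float | None = None
    gc_target: float = 0.40
    spacer_len_range: tuple[int, int] = (20, 80)
    genome_len_target: int = 5500
    fragment_len: int = 1000
    fragment_overlap: int = 250
    seed: int = 0
    family_len_range: tuple[int, int] = (40, 600)
    #: per-family evolutionary-rate multipliers drawn log-uniform in this range;
    #: a spread makes cluster memberships split at many tree depths
    family_rate_range: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        if self.n_genomes < 2 or self.n_families < 1:
            raise SimulationError("counts must be positive (>=2 genomes)")
        if not 0.25 <= self.gc_target <= 0.75:
            raise SimulationError("gc_target outside feasible range [0.25, 0.75]")
        if self.fragment_overlap >= self.fragment_len:
            raise SimulationError("fragment_overlap must be < fragment_len")


@dataclass
class GeneTruth:
    genome_id: str
    gene_id: str
    family: int
    start: int  # 1-based, start codon first base
    end: int  # 1-based, stop codon last base (modular)
    strand: str
    aa_seq: str


@dataclass
class TruthTables:
    generating_tree: TreeNode
    orthology: dict[tuple[str, str], int] = field(default_factory=dict)
    gene_coordinates: list[GeneTruth] = field(default_factory=list)
    fragment_layout: dict[str, tuple[str, int, str]] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genomes: list[CircularSequence]
    proteins: dict[str, list[tuple[str, str]]]  # genome -> [(gene_id, aa_seq)]
    truth: TruthTables


def random_ultrametric_tree(labels: list[str], height: float, rng) -> TreeNode:
    """Random rooted bifurcating ultrametric tree over ``labels``."""
    if len(labels) < 2:
        raise SimulationError("need >= 2 labels")
    nodes = [TreeNode(name=lab, height=0.0) for lab in labels]
    heights = np.sort(rng.uniform(0.05 * height, height, size=len(labels) - 1))
    heights[-1] = height
    for h in heights:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = TreeNode(height=float(h), children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def _branch_sub_prob(branch_len: float, fixed: float | None) -> float:
    if fixed is not None:
        return fixed
    return 1.0 - float(np.exp(-branch_len))


def expected_identity(path_length: float) -> float:
    """Closed-form expected identity between two leaves at total path length t."""
    return 1.0 / 20.0 + 19.0 / 20.0 * float(np.exp(-path_length))


def _draw_codon(aa: str, q: float, rng) -> str:
    opts = CODONS[aa]
    return opts[-1] if rng.random() < q else opts[0]


def _evolve(state: list[tuple[str, str]], p: float, q: float, rng) -> list[tuple[str, str]]:
    """Uniform replacement model on (aa, codon) pairs: each site substitutes
    w.p. ``p`` to a uniform amino acid with a freshly GC-biased codon; codons
    of conserved sites are inherited. The start methionine is never touched.
    """
    out = list(state)
    hits = np.nonzero(rng.random(len(state)) < p)[0]
    for i in hits:
        if i == 0:
            continue
        aa = AMINO_ACIDS[rng.integers(20)]
        out[i] = (aa, _draw_codon(aa, q, rng))
    return out


def _evolve_down(node: TreeNode, state, rate: float, fixed_p, q, rng, out: dict):
    for child in node.children:
        t = (node.height - child.height) * rate
        p = _branch_sub_prob(t, fixed_p)
        child_state = _evolve(state, p, q, rng)
        if child.is_leaf:
            out[child.name] = child_state
        else:
            _evolve_down(child, child_state, rate, fixed_p, q, rng, out)


def calibrate_gc_bias(aa_seq: str, gc_target: float) -> float:
    """Probability q of picking the max-GC (vs min-GC) synonymous codon per site
    so that the expected coding GC fraction hits gc_target, clamped to [0, 1]."""
    lo = sum(_gc(CODONS[a][0]) for a in aa_seq)
    hi = sum(_gc(CODONS[a][-1]) for a in aa_seq)
    want = gc_target * 3 * len(aa_seq)
    if hi == lo:
        return 0.5
    return min(1.0, max(0.0, (want - lo) / (hi - lo)))


def back_translate(aa_seq: str, gc_target: float, rng) -> str:
    """Codon choice biased toward the GC target; appends a stop codon."""
    q = calibrate_gc_bias(aa_seq, gc_target)
    codons = [_draw_codon(a, q, rng) for a in aa_seq]
    codons.append(_draw_stop(q, rng))
    return "".join(codons)


def _draw_stop(q: float, rng) -> str:
    if rng.random() >= q:
        return "TAA"
    return "TAG" if rng.random() < 0.5 else "TGA"


def _random_spacer(length: int, gc_target: float, rng) -> str:
    gc_choices = "GC"
    at_choices = "AT"
    out = []
    for _ in range(length):
        pool = gc_choices if rng.random() < gc_target else at_choices
        out.append(pool[rng.integers(2)])
    return "".join(out)


def simulate_dataset(
    config: SimulationConfig, tree: TreeNode | None = None
) -> SyntheticDataset:
    """Simulate genomes, proteins and truth tables (fully seed-reproducible).

    ``tree`` optionally fixes the generating tree (its leaf count must equal
    ``n_genomes``); by default a random ultrametric tree is drawn.
    """
    root_ss = np.random.SeedSequence(config.seed)
    tree_rng, fam_rng, evo_rng, bt_rng, genome_rng = (
        np.random.default_rng(s) for s in root_ss.spawn(5)
    )
    if tree is None:
        labels = [f"g{i:02d}" for i in range(1, config.n_genomes + 1)]
        tree = random_ultrametric_tree(labels, config.tree_height, tree_rng)
    else:
        labels = tree.leaves()
        if len(labels) != config.n_genomes:
            raise SimulationError("tree leaf count != n_genomes")

    # ancestral families and their evolved leaf copies: (aa, codon) states
    # evolve jointly so conserved sites inherit codons down the tree
    lo, hi = config.family_len_range
    r_lo, r_hi = config.family_rate_range
    families: list[dict[str, list[tuple[str, str]]]] = []
    family_stops: list[str] = []
    for f in range(config.n_families):
        length = int(fam_rng.integers(lo, hi + 1))
        aa_anc = "M" + "".join(AMINO_ACIDS[i] for i in fam_rng.integers(20, size=length - 1))
        q = calibrate_gc_bias(aa_anc, config.gc_target)
        anc_state = [(a, _draw_codon(a, q, bt_rng)) for a in aa_anc]
        family_stops.append(_draw_stop(q, bt_rng))
        rate = float(np.exp(fam_rng.uniform(np.log(r_lo), np.log(r_hi)))) if r_hi > r_lo else r_lo
        leaf_states: dict[str, list[tuple[str, str]]] = {}
        _evolve_down(tree, anc_state, rate, config.aa_rate_per_branch, q, evo_rng, leaf_states)
        families.append(leaf_states)

    genomes = []
    proteins: dict[str, list[tuple[str, str]]] = {}
    truth = TruthTables(generating_tree=tree)
    for lab in labels:
        parts = []
        pos = 0  # 0-based running position
        gene_truths = []
        proteins[lab] = []
        for f, fam in enumerate(families):
            state = fam[lab]
            aa = "".join(a for a, _ in state)
            nt = "".join(c for _, c in state) + family_stops[f]
            spacer_len = int(
                genome_rng.integers(config.spacer_len_range[0], config.spacer_len_range[1] + 1)
            )
            spacer = _random_spacer(spacer_len, config.gc_target, genome_rng)
            # guard: in-frame stop immediately upstream of the gene start so the
            # gene's own ATG is always the first start after a stop
            spacer = spacer[:-3] + "TAA" if spacer_len >= 3 else "TAA"
            parts.append(spacer)
            pos += len(spacer)
            gene_id = f"fam{f:02d}"
            gene_truths.append((gene_id, f, pos, pos + len(nt) - 1, aa))
            proteins[lab].append((gene_id, aa))
            truth.orthology[(lab, gene_id)] = f
            parts.append(nt)
            pos += len(nt)
        # pad to the target length with a trailing stop-guarded spacer
        if pos < config.genome_len_target:
            parts.append(
                _random_spacer(config.genome_len_target - pos, config.gc_target, genome_rng)
            )
        residues = "".join(parts)
        genomes.append(CircularSequence(id=lab, residues=residues, topology="circular"))
        for gene_id, f, s0, e0, aa in gene_truths:
            truth.gene_coordinates.append(
                GeneTruth(
                    genome_id=lab,
                    gene_id=gene_id,
                    family=f,
                    start=s0 + 1,
                    end=e0 % len(residues) + 1,
                    strand="+",
                    aa_seq=aa,
                )
            )
    return SyntheticDataset(config=config, genomes=genomes, proteins=proteins, truth=truth)


def shred(
    genome: CircularSequence, fragment_len: int, step: int, seed: int
) -> tuple[list[Fragment], dict[str, tuple[str, int, str]]]:
    """Tile a circular genome with overlapping fragments in random orientation.

    Fragments start every ``step`` nt (overlap = fragment_len - step between
    consecutive fragments) and wrap across the origin.
    """
    n = len(genome.residues)
    if fragment_len > n:
        raise SimulationError("fragment_len exceeds genome length")
    if step >= fragment_len:
        raise SimulationError("step must be < fragment_len so fragments overlap")
    rng = np.random.default_rng(seed)
    doubled = genome.residues + genome.residues
    count = int(np.ceil(n / step))
    fragments = []
    layout = {}
    for i in range(count):
        off = (i * step) % n
        piece = doubled[off : off + fragment_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            piece = reverse_complement(piece)
        fid = f"{genome.id}_frag{i:03d}"
        fragments.append(Fragment(id=fid, residues=piece))
        layout[fid] = (genome.id, off, strand)
    return fragments, layout
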