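# phagekit

A comparative-genomics toolkit for small circular ssDNA phage genomes. It
covers the full analysis chain needed to characterize an uncultured
microvirus against a panel of reference genomes:

- **genome_core** — FASTA I/O, circular-coordinate arithmetic (1-based,
  GenBank convention), rotation/canonicalization, nucleotide composition.
- **assembler** — greedy exact-overlap (100% identity) assembly of a
  circular genome from unoriented fragments, with layout tracking and
  self-overlap circularization.
- **orf_caller** — ORF prediction on circular genomes (wraparound across
  the origin, both strands, translation table 11) and coding-capacity
  statistics.
- **tetra_similarity** — z-score-normalized tetranucleotide signatures
  (maximal-order Markov expectations, both strands, circular counting) and
  pairwise regression R² with nearest-match reporting.
- **protein_align** — affine-gap global (Needleman–Wunsch) and local
  (Smith–Waterman) protein alignment with BLOSUM62, percent
  identity/similarity, and Karlin–Altschul E-values.
- **gene_clustering** — CD-HIT-style greedy incremental clustering at a
  similarity threshold plus genome×cluster membership matrices.
- **pangenome_compare** — pooled pangenome construction and shared/unique
  gene determination by clustering and by local-alignment screening.
- **profiles_trees** — Jaccard/Bray–Curtis profile distances, UPGMA
  dendrograms with Newick I/O, Robinson–Foulds distance.
- **synthetic_data** — seeded simulator: protein families evolved down a
  known ultrametric tree with codon inheritance and GC-targeted
  back-translation, modular circular genomes, fragment shredding — all
  with truth tables for recovery tests.
- **pipeline / cli** — end-to-end orchestration with a deterministic JSON
  report.

## CLI

All commands are under a single entry point:

```sh
phagekit stats genomes.fasta                 # length + composition TSV
phagekit assemble fragments.fasta --min-overlap 250
phagekit orfs genome.fasta --min-nt 100 --table 11 --out-prefix orfs
phagekit tetra a.fasta b.fasta               # z-score R² matrix + nearest matches
phagekit align --mode local query.faa subject.faa
phagekit cluster proteins.faa --threshold 0.40
phagekit pangenome --query q.faa --pan g1.faa --pan g2.faa
phagekit tree membership.tsv --metric jaccard
phagekit simulate --seed 17 --n-genomes 15
phagekit run --genomes genomes.fasta --query g01 --out outdir
```

Coordinates are 1-based inclusive everywhere; ORFs may wrap the origin of
circular sequences (`end < start` on the forward strand).

## Reference sequences and the acceptance report

The headline checks against the deposited genome sequences need ~75 kb of
public GenBank FASTA that is not redistributed here. With network access:

```sh
python scripts/fetch_reference_data.py
```

This populates `src/phagekit/data/reference/`, after which the
accession-gated tests in `tests/test_acceptance.py` un-skip.

The acceptance report recomputes every reachable target from scratch:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Targets whose reference sequences are absent are omitted with a note on
stderr; everything else (worked examples, oracle equivalences, round
trips, parameter recovery, determinism) is computed offline.
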