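"""Registry of the reference genome set used for the comparative analysis.

The query phage genome (GenBank HQ264138) plus the 14 Microviridae
comparison genomes. Sequences are not bundled; ``scripts/fetch_reference_data.py``
downloads them into :data:`REFERENCE_DIR` when network access is available,
and every consumer degrades gracefully when they are absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from phagekit.genome_core import CircularSequence, read_fasta

REFERENCE_DIR = Path(__file__).parent / "data" / "reference"

QUERY_ACCESSION = "HQ264138"


@dataclass(frozen=True)
class ReferenceGenome:
    abbreviation: str
    name: str
    accession: str
    expected_length: int  # published genome size (bp), used to sanity-check downloads
    gene_count: int


#: the 14 comparison genomes (published sizes and IMG gene counts)
COMPARISON_GENOMES = [
    ReferenceGenome("Chp1", "Chlamydia phage 1", "NC_001741", 4877, 12),
    ReferenceGenome("Chp2", "Chlamydia phage 2", "NC_002194", 4563, 8),
    ReferenceGenome("Chp3", "Chlamydia phage 3", "NC_008355", 4554, 8),
    ReferenceGenome("Chp4", "Chlamydia phage 4", "NC_007461", 4530, 8),
    ReferenceGenome("CPAR39", "Chlamydia pneumoniae phage CPAR39", "NC_002180", 4532, 7),
    ReferenceGenome("Col-ID18", "Coliphage ID18", "NC_007856", 5486, 11),
    ReferenceGenome("Col-WA13", "Coliphage WA13", "NC_007821", 6068, 10),
    ReferenceGenome("EntG4", "Enterobacteria phage G4", "NC_001420", 5577, 11),
    ReferenceGenome("Ent-St1", "Enterobacteria phage St-1", "NC_012868", 6094, 11),
    ReferenceGenome("Ent-alpha3", "Enterobacteria phage alpha3", "NC_001330", 6087, 10),
    ReferenceGenome("X174", "Enterobacteria phage phiX174", "NC_001422", 5386, 11),
    ReferenceGenome("CPG1", "Guinea pig Chlamydia phage", "NC_001998", 4529, 9),
    ReferenceGenome("MH2K", "Phage phiMH2K", "NC_002643", 4594, 11),
    ReferenceGenome("SpV4", "Spiroplasma phage 4", "NC_003438", 4421, 9),
]

ALL_ACCESSIONS = [QUERY_ACCESSION] + [g.accession for g in COMPARISON_GENOMES]


def genome_path(accession: str) -> Path:
    return REFERENCE_DIR / f"{accession}.fasta"


def have_genome(accession: str) -> bool:
    return genome_path(accession).exists()


def load_genome(accession: str) -> CircularSequence:
    """Load one reference genome as a circular sequence (raises if absent)."""
    path = genome_path(accession)
    if not path.exists():
        raise FileNotFoundError(
            f"reference genome {accession} not present at {path}; "
            "run scripts/fetch_reference_data.py with network access"
        )
    (seq,) = read_fasta(path, topology="circular")
    return CircularSequence(id=accession, residues=seq.residues, topology="circular")
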