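# Reference genome sequences

This directory holds the reference genome FASTA files used by the
accession-gated acceptance checks: `HQ264138.fasta` (the query phage) and
the 14 Microviridae comparison genomes (see `phagekit/reference.py` for the
full accession list).

The sequences are small public GenBank records (~75 kb total) but are not
redistributed with the package. To populate this directory, run (with
network access):

    python scripts/fetch_reference_data.py

Checks that need these files skip cleanly when they are absent, and
`scripts/acceptance.py` omits the corresponding targets.
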