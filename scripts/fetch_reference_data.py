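#!/usr/bin/env python
"""Download the reference genome FASTA files from NCBI into the package data dir.

Requires network access; verifies each downloaded sequence length against
the published genome size before writing.
"""

from __future__ import annotations

import sys
import time
import urllib.parse
import urllib.request

from phagekit.reference import (
    ALL_ACCESSIONS,
    COMPARISON_GENOMES,
    QUERY_ACCESSION,
    REFERENCE_DIR,
    genome_path,
)

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
EXPECTED = {g.accession: g.expected_length for g in COMPARISON_GENOMES}
EXPECTED[QUERY_ACCESSION] = 5514


def fetch(accession: str) -> str:
    params = urllib.parse.urlencode(
        {"db": "nuccore", "id": accession, "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EUTILS}?{params}", timeout=60) as resp:
        return resp.read().decode()


def main() -> int:
    REFERENCE_DIR.mkdir(parents=True, exist_ok=True)
    failures = 0
    for acc in ALL_ACCESSIONS:
        path = genome_path(acc)
        if path.exists():
            print(f"{acc}: already present")
            continue
        try:
            text = fetch(acc)
        except Exception as exc:  # noqa: BLE001
            print(f"{acc}: download failed ({exc})", file=sys.stderr)
            failures += 1
            continue
        seq_len = sum(len(line.strip()) for line in text.splitlines() if not line.startswith(">"))
        expected = EXPECTED[acc]
        if seq_len != expected:
            print(
                f"{acc}: length {seq_len} != published {expected}; not writing",
                file=sys.stderr,
            )
            failures += 1
            continue
        path.write_text(text)
        print(f"{acc}: {seq_len} nt written to {path}")
        time.sleep(0.4)  # NCBI rate courtesy
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
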