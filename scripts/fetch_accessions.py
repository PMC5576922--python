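#!/usr/bin/env python
"""Download the deposited phage genomes used by the optional accession-gated
tests (requires network access).

    python scripts/fetch_accessions.py

Writes FASTA files to scratch/accessions/.  The test suite picks them up
automatically; without them the optional tests are skipped.
"""

import urllib.request
from pathlib import Path

ACCESSIONS = {
    "KY626177": "phage CPG1g",
    "KY626176": "phage CPP1m",
    "MF481197": "phage CB5A",
}

EUTILS = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=fasta&retmode=text"
)


def main():
    outdir = Path(__file__).resolve().parent.parent / "scratch" / "accessions"
    outdir.mkdir(parents=True, exist_ok=True)
    for acc, label in ACCESSIONS.items():
        dest = outdir / f"{acc}.fasta"
        if dest.exists():
            print(f"{acc} ({label}): already present")
            continue
        print(f"fetching {acc} ({label}) ...")
        with urllib.request.urlopen(EUTILS.format(acc=acc), timeout=60) as r:
            dest.write_bytes(r.read())
        print(f"  -> {dest}")


if __name__ == "__main__":
    main()
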