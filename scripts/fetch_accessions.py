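#!/usr/bin/env python
"""Download the deposited reference records used by the accession-based
checks (requires network access to NCBI E-utilities).

Fetches into data/accessions/:
  AB036706.1.fasta   human ITLN1 mRNA CDS (FASTA of the coding sequence)
  AY065973.1.fasta   human ITLN2 mRNA CDS
  XM_017598901.fasta rat Itln1 predicted mRNA CDS
  HM370554.gb        129S7-derived ~603 kb contig (GenBank with gene
                     annotation; mouse Itln1..Itln6)
"""

from __future__ import annotations

import sys
import urllib.parse
import urllib.request
from pathlib import Path

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
OUT = Path(__file__).resolve().parent.parent / "data" / "accessions"

TARGETS = [
    ("AB036706.1", "fasta_cds_na", "AB036706.1.fasta"),
    ("AY065973.1", "fasta_cds_na", "AY065973.1.fasta"),
    ("XM_017598901", "fasta_cds_na", "XM_017598901.fasta"),
    ("HM370554", "gbwithparts", "HM370554.gb"),
]


def fetch(accession: str, rettype: str) -> bytes:
    params = urllib.parse.urlencode({
        "db": "nuccore", "id": accession, "rettype": rettype,
        "retmode": "text",
    })
    with urllib.request.urlopen(f"{EUTILS}?{params}", timeout=120) as resp:
        return resp.read()


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    status = 0
    for accession, rettype, filename in TARGETS:
        dest = OUT / filename
        if dest.exists():
            print(f"{filename}: already present")
            continue
        try:
            data = fetch(accession, rettype)
        except Exception as exc:  # pragma: no cover - network dependent
            print(f"{filename}: FAILED ({exc})", file=sys.stderr)
            status = 1
            continue
        dest.write_bytes(data)
        print(f"{filename}: {len(data)} bytes")
    return status


if __name__ == "__main__":
    raise SystemExit(main())
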