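#!/usr/bin/env python
"""Fetch the human Titin benchmark sequence (UniProtKB A0A0A0MTS7).

Downloads the 35 991-residue protein used for the peptide-count benchmark
into ``data/titin_A0A0A0MTS7.fasta``.  Requires network access; the rest
of the package works entirely offline.  Run from the repository root:

    python scripts/fetch_titin.py
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ACCESSION = "A0A0A0MTS7"
URL = f"https://rest.uniprot.org/uniprotkb/{ACCESSION}.fasta"
DEST = Path(__file__).resolve().parent.parent / "data" / f"titin_{ACCESSION}.fasta"
EXPECTED_LENGTH = 35_991


def main() -> int:
    DEST.parent.mkdir(parents=True, exist_ok=True)
    print(f"fetching {URL} ...")
    try:
        with urllib.request.urlopen(URL, timeout=60) as resp:
            text = resp.read().decode()
    except OSError as exc:
        print(f"download failed: {exc}", file=sys.stderr)
        return 1
    residues = sum(len(line.strip()) for line in text.splitlines() if not line.startswith(">"))
    if residues != EXPECTED_LENGTH:
        print(
            f"warning: fetched sequence has {residues} residues, expected "
            f"{EXPECTED_LENGTH}; the UniProt entry may have changed",
            file=sys.stderr,
        )
    DEST.write_text(text)
    print(f"wrote {DEST} ({residues} residues)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
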