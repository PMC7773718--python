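#!/usr/bin/env python
"""Download the two deposited Senna plastome records (network required).

Fetches MK817504 (S. obtusifolia) and MK817505 (S. occidentalis) as
GenBank flat files into scratch/accessions/, where the optional
deposited-genome verification job (tests and scripts/verify_accessions.py)
expects them.  Run once from the repository root:

    python scripts/fetch_accessions.py
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = ("MK817504", "MK817505")
EUTILS = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&rettype=gbwithparts&retmode=text&id={acc}"
)


def main() -> int:
    out_dir = Path(__file__).resolve().parents[1] / "scratch" / "accessions"
    out_dir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = out_dir / f"{acc}.gb"
        if dest.exists():
            print(f"{dest} already present")
            continue
        url = EUTILS.format(acc=acc)
        print(f"fetching {acc} ...")
        with urllib.request.urlopen(url, timeout=60) as resp:
            text = resp.read().decode()
        if "LOCUS" not in text[:200]:
            print(f"unexpected response for {acc}", file=sys.stderr)
            return 1
        dest.write_text(text)
        print(f"wrote {dest} ({len(text)} bytes)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
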