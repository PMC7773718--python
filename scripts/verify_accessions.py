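#!/usr/bin/env python
"""Verify the toolkit against the two deposited Senna plastome records.

An optional job (the records must first be fetched with
scripts/fetch_accessions.py; network required once).  Checks, against
the published values: plastome lengths (162,426 / 159,993 bp), GC
content (36.0 / 36.2 %), the nucleotide-diversity ranking of the shared
protein-coding genes (ycf1 > rpl23 > petL > matK, pi(ycf1)=0.04363,
pi(matK)=0.03206 up to alignment-dependent trailing decimals), the
in-silico PCR amplicon sizes of the two published matK primer pairs
(200 and 151 bp), and the seven insert variable sites of each.

    python scripts/verify_accessions.py
"""

from __future__ import annotations

import sys
from pathlib import Path

from minibarcode import datasets
from minibarcode.diversity import rank_gene_diversity
from minibarcode.genome_io import read_genome, shared_gene_table
from minibarcode.primers import count_variable_sites, in_silico_pcr


def main() -> int:
    acc_dir = Path(__file__).resolve().parents[1] / "scratch" / "accessions"
    paths = [acc_dir / "MK817504.gb", acc_dir / "MK817505.gb"]
    if not all(p.exists() for p in paths):
        print(
            "records missing; run scripts/fetch_accessions.py first",
            file=sys.stderr,
        )
        return 2
    obtusifolia = read_genome(paths[0], "genbank")
    occidentalis = read_genome(paths[1], "genbank")
    failures = 0

    def check(label, got, want, tol=0.0):
        nonlocal failures
        ok = abs(got - want) <= tol if tol else got == want
        failures += 0 if ok else 1
        print(f"{'PASS' if ok else 'FAIL'}  {label}: got {got}, expected {want}")

    check("S. obtusifolia plastome length (bp)", obtusifolia.length, 162_426)
    check("S. occidentalis plastome length (bp)", occidentalis.length, 159_993)
    check("S. obtusifolia GC (%)", round(obtusifolia.gc_percent(), 1), 36.0, 0.05)
    check("S. occidentalis GC (%)", round(occidentalis.gc_percent(), 1), 36.2, 0.05)

    table = shared_gene_table(obtusifolia, occidentalis)
    print(f"shared protein-coding genes: {len(table)}")
    records = rank_gene_diversity(table)
    top = [r.gene_name for r in records[:4]]
    print(f"top-4 by pi: {top}")
    failures += 0 if top == ["ycf1", "rpl23", "petL", "matK"] else 1
    by = {r.gene_name: r for r in records}
    check("pi(ycf1)", round(by["ycf1"].pi, 5), 0.04363, 5e-4)
    check("pi(matK)", round(by["matK"].pi, 5), 0.03206, 5e-4)

    for name, size, insert in (("647F-847R", 200, 164), ("478F-629R", 151, 111)):
        pair = datasets.senna_primer_pair(name)
        amps = {}
        for rec in (obtusifolia, occidentalis):
            hits = in_silico_pcr(pair, rec, 2)
            check(f"{name} unique on {rec.accession}", len(hits), 1)
            if len(hits) != 1:
                continue
            check(f"{name} amplicon size on {rec.accession}", len(hits[0].full_sequence), size)
            check(f"{name} insert size on {rec.accession}", len(hits[0].insert_sequence), insert)
            amps[rec.accession] = hits[0]
        if len(amps) == 2:
            check(f"{name} insert variable sites", count_variable_sites(amps), 7)

    print(f"\n{failures} check(s) failed" if failures else "\nall checks passed")
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
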