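"""Shared fixtures: toy annotated genomes and small simulation configs."""

from __future__ import annotations

import random

import pytest

from minibarcode._dna import revcomp
from minibarcode.genome_io import GeneFeature, GenomeRecord
from minibarcode.primers import PrimerCandidate, PrimerPair

# A tiny hand-written GenBank record: two CDS (one on the minus strand),
# one of them duplicated as in an inverted repeat, plus a tRNA.
TOY_GENBANK = """\
LOCUS       TOY00001                 120 bp    DNA     linear   PLN 01-JAN-2020
DEFINITION  Toy organelle fragment.
ACCESSION   TOY00001
VERSION     TOY00001.1
SOURCE      Toyus minimus
  ORGANISM  Toyus minimus
FEATURES             Location/Qualifiers
     source          1..120
                     /organism="Toyus minimus"
     CDS             7..24
                     /gene="aaaA"
     CDS             complement(31..48)
                     /gene="bbbB"
     tRNA            55..66
                     /gene="trnX"
     CDS             91..108
                     /gene="aaaA"
ORIGIN
        1 acgtacatgg ctaaaggtcc attagcatgc tcagttcgaa ctcgatcaag cctgacgtag
       61 ctaagcctga aatcgtacgt atcgatcgaa atggctaaag gtccattagc gtacgtacgt
//
"""


@pytest.fixture
def toy_genbank(tmp_path):
    path = tmp_path / "toy.gb"
    path.write_text(TOY_GENBANK)
    return path


def make_record(accession: str, genes: dict[str, tuple[str, str]], spacer: str = "TTTTTT") -> GenomeRecord:
    """Assemble a GenomeRecord from {gene: (sequence, strand)}, in order."""
    seq_parts = [spacer]
    features = []
    pos = len(spacer)
    for name, (gene_seq, strand) in genes.items():
        placed = gene_seq if strand == "+" else revcomp(gene_seq)
        seq_parts.append(placed)
        features.append(GeneFeature(name, "CDS", ((pos, pos + len(gene_seq), strand),)))
        pos += len(gene_seq)
        seq_parts.append(spacer)
        pos += len(spacer)
    return GenomeRecord(accession, "", "".join(seq_parts), features)


def random_dna(n: int, seed: int = 0) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_pair(fwd: str, rev: str, name: str = "pair") -> PrimerPair:
    mk = lambda s, o: PrimerCandidate(s, -1, o, 0.0, 0.0, False, 0)
    return PrimerPair(mk(fwd, "forward"), mk(rev, "reverse"), name)
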