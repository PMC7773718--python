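"""Reading organelle genome records and extracting protein-coding genes.

GenBank and FASTA parsing is delegated to Biopython; this module
normalizes the results into light-weight records with 0-based half-open
coordinates, extracts spliced coding sequences in coding orientation,
and intersects the gene complements of two genomes into an ortholog
table.  Genes duplicated in the inverted repeats are collapsed onto the
copy with the smaller start coordinate; trans-spliced annotations
(segments on both strands, e.g. *rps12*) are excluded because their
splicing is annotation-dependent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from ._dna import IUPAC_DNA, revcomp

FEATURE_KINDS = ("CDS", "tRNA", "rRNA")


@dataclass
class GeneFeature:
    """One annotated gene with ordered (start, end, strand) segments."""

    gene_name: str
    kind: str  # CDS | tRNA | rRNA
    segments: tuple[tuple[int, int, str], ...]  # 0-based half-open
    ir_duplicate: bool = False

    @property
    def start(self) -> int:
        return min(s for s, _, _ in self.segments)

    @property
    def strands(self) -> set[str]:
        return {st for _, _, st in self.segments}


@dataclass
class GenomeRecord:
    """An organelle genome: sequence plus typed gene features."""

    accession: str
    organism: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise ValueError(f"{self.accession}: non-IUPAC characters {sorted(bad)!r}")
        for f in self.features:
            for s, e, strand in f.segments:
                if not (0 <= s < e <= len(self.sequence)):
                    raise ValueError(
                        f"{self.accession}: feature {f.gene_name} segment ({s},{e}) "
                        f"outside [0,{len(self.sequence)})"
                    )
                if strand not in "+-":
                    raise ValueError(f"{self.accession}: bad strand {strand!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gc_percent(self) -> float:
        gc = self.sequence.count("G") + self.sequence.count("C")
        return 100.0 * gc / len(self.sequence)


@dataclass
class CodingGene:
    """A spliced protein-coding gene in coding (5'->3') orientation."""

    gene_name: str
    sequence: str
    source_accession: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 3:
            raise ValueError(f"{self.gene_name}: coding sequence shorter than 3 nt")
        if "-" in self.sequence:
            raise ValueError(f"{self.gene_name}: coding sequence contains gaps")


def normalize_gene_name(name: str) -> str:
    """Whitespace-stripped, case-insensitive comparison key for gene names."""
    return name.strip().casefold()


def _feature_name(feature) -> str | None:
    for key in ("gene", "locus_tag"):
        vals = feature.qualifiers.get(key)
        if vals:
            return vals[0].strip()
    return None


def read_genome(path: str | Path, format: str | None = None) -> GenomeRecord:
    """Parse a GenBank or FASTA file into a :class:`GenomeRecord`.

    ``format`` is ``"genbank"`` or ``"fasta"``; when omitted it is
    inferred from the file extension.  GenBank locations (1-based,
    inclusive, possibly ``join``/``complement``) are converted to 0-based
    half-open segments.  FASTA records carry no features.
    """
    path = Path(path)
    if format is None:
        ext = path.suffix.lower()
        format = "genbank" if ext in {".gb", ".gbk", ".gbff", ".genbank"} else "fasta"
    if format not in {"genbank", "fasta"}:
        raise ValueError(f"unknown format {format!r}")
    try:
        record = next(SeqIO.parse(str(path), format))
    except StopIteration:
        raise ValueError(f"{path}: no records found") from None
    except Exception as exc:  # malformed file
        raise ValueError(f"{path}: failed to parse as {format}: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq:
        raise ValueError(f"{path}: record {record.id} has an empty sequence")

    features: list[GeneFeature] = []
    if format == "genbank":
        for feat in record.features:
            if feat.type not in FEATURE_KINDS:
                continue
            name = _feature_name(feat)
            if name is None:
                warnings.warn(f"{record.id}: unnamed {feat.type} feature skipped")
                continue
            segments = tuple(
                (int(part.start), int(part.end), "+" if part.strand != -1 else "-")
                for part in feat.location.parts
            )
            segments = tuple(sorted(segments))
            features.append(GeneFeature(name, feat.type, segments))
        _flag_ir_duplicates(features)
    organism = record.annotations.get("organism", "") if format == "genbank" else ""
    accession = record.id
    return GenomeRecord(accession, organism, seq, features)


def _flag_ir_duplicates(features: list[GeneFeature]) -> None:
    by_name: dict[tuple[str, str], list[GeneFeature]] = {}
    for f in features:
        by_name.setdefault((f.kind, normalize_gene_name(f.gene_name)), []).append(f)
    for group in by_name.values():
        if len(group) > 1:
            for f in sorted(group, key=lambda g: g.start)[1:]:
                f.ir_duplicate = True


def _splice(record: GenomeRecord, feature: GeneFeature) -> str:
    parts = [record.sequence[s:e] for s, e, _ in feature.segments]
    seq = "".join(parts)
    if feature.strands == {"-"}:
        seq = revcomp(seq)
    return seq


def extract_coding_genes(record: GenomeRecord) -> list[CodingGene]:
    """One spliced :class:`CodingGene` per unique CDS gene name.

    Inverted-repeat duplicates keep only the lower-coordinate copy;
    trans-spliced and zero-length annotations are skipped with a warning.
    """
    genes: list[CodingGene] = []
    seen: set[str] = set()
    cds = sorted((f for f in record.features if f.kind == "CDS"), key=lambda f: f.start)
    for feat in cds:
        key = normalize_gene_name(feat.gene_name)
        if key in seen:
            continue
        if len(feat.strands) > 1:
            warnings.warn(f"{record.accession}: {feat.gene_name} is trans-spliced; skipped")
            seen.add(key)
            continue
        if any(e - s == 0 for s, e, _ in feat.segments):
            warnings.warn(f"{record.accession}: {feat.gene_name} has a zero-length segment; skipped")
            seen.add(key)
            continue
        seq = _splice(record, feat)
        if len(seq) < 3:
            warnings.warn(f"{record.accession}: {feat.gene_name} shorter than one codon; skipped")
            seen.add(key)
            continue
        genes.append(CodingGene(feat.gene_name, seq, record.accession))
        seen.add(key)
    return genes


def shared_gene_table(
    a: GenomeRecord, b: GenomeRecord
) -> list[tuple[str, CodingGene, CodingGene]]:
    """Orthologs present in both genomes, sorted by gene name.

    Names are compared case-insensitively after whitespace stripping;
    the spelling from genome *a* is reported.  Genes private to one
    genome are reported via a warning, not an error.
    """
    genes_a = {normalize_gene_name(g.gene_name): g for g in extract_coding_genes(a)}
    genes_b = {normalize_gene_name(g.gene_name): g for g in extract_coding_genes(b)}
    shared = sorted(set(genes_a) & set(genes_b))
    private = sorted((set(genes_a) ^ set(genes_b)))
    if private:
        warnings.warn(f"genes private to one genome excluded: {', '.join(private)}")
    if not shared:
        warnings.warn("no shared protein-coding genes between the two genomes")
    return [(genes_a[k].gene_name, genes_a[k], genes_b[k]) for k in shared]


def shared_gene_frame(table: Iterable[tuple[str, CodingGene, CodingGene]]) -> pd.DataFrame:
    """Shared-gene report with columns gene, length_a, length_b."""
    rows = [
        {"gene": name, "length_a": len(ga.sequence), "length_b": len(gb.sequence)}
        for name, ga, gb in table
    ]
    return pd.DataFrame(rows, columns=["gene", "length_a", "length_b"])


def write_fasta(records: GenomeRecord | Iterable[GenomeRecord], path: str | Path) -> None:
    if isinstance(records, GenomeRecord):
        records = [records]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession} {rec.organism}\n".rstrip() + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
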