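"""Seeded synthetic genomes and tagged amplicon mixtures with ground truth.

Two generators make every stage of the toolkit testable without any
external download: a pair of annotated "organelle" genomes whose genes
diverged by independent per-site substitutions (conserved flanks kept
identical so primers have somewhere to sit), and pools of dual-tagged,
primer-flanked paired-end reads drawn from reference amplicons at known
species proportions with a uniform per-base error rate.  Both are pure
functions of their configuration, including the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._dna import revcomp
from .genome_io import GeneFeature, GenomeRecord
from .quant import ReadPair, TagScheme, write_paired_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Conditions for the synthetic genome pair and read mixtures.

    ``divergence`` is the per-site substitution probability between the
    two genomes (plastid coding genes of congeners sit around a few
    percent); ``conserved_flank`` bases at each gene end stay identical.
    ``error_rate`` is the per-base sequencing error of simulated reads.
    """

    seed: int = 0
    gene_count: int = 8
    gene_length: int = 900
    divergence: float = 0.03
    conserved_flank: int = 30
    proportions: dict[str, float] = field(
        default_factory=lambda: {"taxon_a": 0.5, "taxon_b": 0.5}
    )
    n_reads: int = 20_000
    error_rate: float = 0.002
    read_len: int = 150
    spacer_length: int = 120
    per_gene_divergence: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must lie in [0, 1]")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must lie in [0, 1]")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


@dataclass
class GroundTruth:
    """What the generators planted, for closing the loop in tests."""

    true_proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    variable_sites: dict[str, list[int]] = field(default_factory=dict)
    primer_footprints: dict[str, tuple[int, int]] = field(default_factory=dict)
    read_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(
    rng: np.random.Generator, arr: np.ndarray, rate: float, protect: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Substitute each unprotected position independently with prob *rate*.

    Returns (mutated copy, positions changed).  Substitutions always
    change the base (a uniformly chosen different one).
    """
    out = arr.copy()
    hit = (rng.random(arr.size) < rate) & ~protect
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out, idx


def simulate_genome_pair(
    config: SimulationConfig,
) -> tuple[GenomeRecord, GenomeRecord, GroundTruth]:
    """Build two annotated genomes that differ by planted substitutions.

    Genome A concatenates ``gene_count`` random genes separated by
    random spacers; genome B carries independent substitutions at rate
    ``divergence`` (or ``per_gene_divergence[i]``) inside each gene,
    with ``conserved_flank`` bases at both gene ends kept identical.
    Spacers diverge at the same scalar rate.  Every third gene is placed
    on the minus strand.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    per_gene = config.per_gene_divergence or tuple(
        [config.divergence] * config.gene_count
    )
    if len(per_gene) != config.gene_count:
        raise ValueError("per_gene_divergence length must equal gene_count")
    parts_a: list[np.ndarray] = []
    parts_b: list[np.ndarray] = []
    features: list[GeneFeature] = []
    truth = GroundTruth()
    pos = 0
    for i in range(config.gene_count):
        spacer = _random_seq(rng, config.spacer_length)
        spacer_b, _ = _mutate(
            rng, spacer, config.divergence, np.zeros(spacer.size, dtype=bool)
        )
        parts_a.append(spacer)
        parts_b.append(spacer_b)
        pos += spacer.size

        gene = _random_seq(rng, config.gene_length)
        protect = np.zeros(gene.size, dtype=bool)
        flank = min(config.conserved_flank, gene.size // 2)
        protect[:flank] = True
        protect[gene.size - flank:] = True
        gene_b, changed = _mutate(rng, gene, per_gene[i], protect)
        parts_a.append(gene)
        parts_b.append(gene_b)
        name = f"gene{i + 1:03d}"
        strand = "-" if i % 3 == 2 else "+"
        features.append(GeneFeature(name, "CDS", ((pos, pos + gene.size, strand),)))
        # gene-local coordinates, on the plus strand
        truth.variable_sites[name] = [int(c) for c in changed]
        pos += gene.size
    tail = _random_seq(rng, config.spacer_length)
    tail_b, _ = _mutate(rng, tail, config.divergence, np.zeros(tail.size, dtype=bool))
    parts_a.append(tail)
    parts_b.append(tail_b)

    seq_a = np.concatenate(parts_a).tobytes().decode()
    seq_b = np.concatenate(parts_b).tobytes().decode()
    import copy

    rec_a = GenomeRecord("SIM_A", "Simulated taxon A", seq_a, features)
    rec_b = GenomeRecord("SIM_B", "Simulated taxon B", seq_b, copy.deepcopy(features))
    return rec_a, rec_b, truth


def simulate_mixture_reads(
    refs: Mapping[str, str],
    scheme: TagScheme,
    config: SimulationConfig,
    proportions_per_sample: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[list[ReadPair], GroundTruth]:
    """Draw tagged paired-end reads from reference amplicons.

    ``refs`` maps taxon -> full amplicon sequence (primer footprints
    included).  Each sample in the tag scheme receives ``n_reads``
    pairs; pair *i* comes from taxon *t* with the sample's proportion.
    Read 1 is forward tag + amplicon prefix, read 2 is reverse tag +
    reverse-complement amplicon suffix; every base (tags included) is
    flipped to a uniformly chosen different base with probability
    ``error_rate``.  Qualities are constant and consistent with the
    error rate.
    """
    rng = np.random.default_rng(config.seed + 1)
    if proportions_per_sample is None:
        proportions_per_sample = {s: config.proportions for s in scheme.tags}
    taxa = sorted(refs)
    L = scheme.tag_length
    bio_len = config.read_len - L
    for taxon, amp in refs.items():
        if len(amp) < 2 * 20:
            raise ValueError(f"amplicon for {taxon} too short to merge")
    q = 40 if config.error_rate <= 0 else min(
        40, max(2, round(-10.0 * math.log10(config.error_rate)))
    )
    qual = chr(q + 33) * config.read_len
    truth = GroundTruth()
    reads: list[ReadPair] = []
    for sample in scheme.tags:
        props = proportions_per_sample[sample]
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError(f"proportions for {sample} do not sum to 1")
        ftag, rtag = scheme.tags[sample]
        p = np.array([props.get(t, 0.0) for t in taxa])
        draws = rng.choice(len(taxa), size=config.n_reads, p=p)
        counts = {t: int((draws == k).sum()) for k, t in enumerate(taxa)}
        truth.true_proportions[sample] = dict(props)
        truth.read_counts[sample] = counts
        for i, k in enumerate(draws):
            amp = refs[taxa[k]]
            s1 = ftag + amp[:bio_len]
            s2 = rtag + revcomp(amp)[:bio_len]
            if config.error_rate > 0:
                s1 = _seq_errors(rng, s1, config.error_rate)
                s2 = _seq_errors(rng, s2, config.error_rate)
            reads.append(
                ReadPair(f"{sample}_read{i:06d}", s1, qual[: len(s1)], s2, qual[: len(s2)])
            )
    return reads, truth


def simulate_barcode_refs(
    config: SimulationConfig,
    forward_primer: str,
    reverse_primer: str,
    insert_length: int = 164,
    n_variable: int = 7,
    taxa: Sequence[str] = ("taxon_a", "taxon_b"),
) -> tuple[dict[str, str], GroundTruth]:
    """Two reference amplicons sharing primer footprints, diverged at
    ``n_variable`` planted insert positions (mini-barcode geometry)."""
    rng = np.random.default_rng(config.seed + 2)
    insert_a = _random_seq(rng, insert_length)
    sites = sorted(rng.choice(insert_length, size=n_variable, replace=False).tolist())
    insert_b = insert_a.copy()
    for i in sites:
        choices = _BASES[_BASES != insert_b[i]]
        insert_b[i] = rng.choice(choices)
    tail = revcomp(reverse_primer)
    refs = {
        taxa[0]: forward_primer + insert_a.tobytes().decode() + tail,
        taxa[1]: forward_primer + insert_b.tobytes().decode() + tail,
    }
    truth = GroundTruth(variable_sites={"barcode": [int(s) for s in sites]})
    lo = len(forward_primer)
    truth.primer_footprints = {
        t: (lo, lo + insert_length) for t in taxa
    }
    return refs, truth


def _seq_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def write_simulation(
    out_dir: str | Path,
    genomes: Sequence[GenomeRecord],
    reads: list[ReadPair] | None = None,
    truth: GroundTruth | None = None,
) -> None:
    """Write simulated genomes (FASTA + GenBank), reads and truth JSON."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .genome_io import write_fasta

    for rec in genomes:
        write_fasta(rec, out / f"{rec.accession}.fasta")
        sr = SeqRecord(
            Seq(rec.sequence),
            id=rec.accession,
            description=rec.organism,
            annotations={"molecule_type": "DNA", "organism": rec.organism},
        )
        for f in rec.features:
            for s, e, strand in f.segments:
                sr.features.append(
                    SeqFeature(
                        FeatureLocation(s, e, strand=1 if strand == "+" else -1),
                        type=f.kind,
                        qualifiers={"gene": [f.gene_name]},
                    )
                )
        SeqIO.write(sr, out / f"{rec.accession}.gb", "genbank")
    if reads is not None:
        write_paired_fastq(reads, out / "reads_R1.fastq", out / "reads_R2.fastq")
    if truth is not None:
        truth.to_json(out / "ground_truth.json")
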