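"""Published reference data for the *Senna* mini-barcode system.

Two mini-barcode primer pairs were developed from *matK* to distinguish
*Senna obtusifolia* (Juemingzi) from its common adulterant
*S. occidentalis*: 647F-847R (200 bp amplicon, 164 bp insert) and
478F-629R (151 bp amplicon, 111 bp insert), each spanning seven
variable sites.  This module packages the primer sequences, the printed
amplicon geometry, and the per-mixture ASV read counts reported for the
four experimental seed mixtures (JM1-JM4), so that the reporting path
can be exercised without any sequencing data.

The ASV *sequences* of the mixtures were not published; where a
sequence-shaped object is needed, synthetic stand-in sequences are
generated and clearly labelled as such.  The read counts are the
published values.
"""

from __future__ import annotations

from dataclasses import dataclass

from .primers import PrimerCandidate, PrimerPair, gc_content, melting_temperature, hairpin_check, dimer_check
from .quant import ASVTable, Assignment

MIXTURES = ("JM1", "JM2", "JM3", "JM4")

_PRIMER_SEQS: dict[str, tuple[str, str]] = {
    "647F-847R": ("GTGAATACGAATCTATCT", "GGATTTTCCTTGATATCT"),
    "478F-629R": ("GTTCAAACCCTTCGATACTG", "GGAACAGGAAAAATCTTGGA"),
}

AMPLICON_SIZES: dict[str, int] = {"647F-847R": 200, "478F-629R": 151}

# Reported per-mixture ASV read counts; each ASV was identified at 100%
# identity against the named species' barcode region.
_ASV_COUNTS: dict[str, dict[str, dict[str, int]]] = {
    "647F-847R": {
        "Senna occidentalis": {"JM1": 56_065, "JM2": 564_176, "JM3": 11_901, "JM4": 400_029},
        "Senna obtusifolia": {"JM1": 57_978, "JM2": 31_078, "JM3": 321_102, "JM4": 348_064},
    },
    "478F-629R": {
        "Senna occidentalis": {"JM1": 108_018, "JM2": 288_609, "JM3": 6_666, "JM4": 65_827},
        "Senna obtusifolia": {"JM1": 27_160, "JM2": 2_937, "JM3": 79_349, "JM4": 3_718},
    },
}


def _candidate(seq: str, orientation: str) -> PrimerCandidate:
    return PrimerCandidate(
        sequence=seq,
        template_start=-1,
        orientation=orientation,
        gc_percent=gc_content(seq),
        tm_celsius=melting_temperature(seq),
        hairpin=bool(hairpin_check(seq)),
        max_self_dimer_run=dimer_check(seq, seq).max_run,
    )


def senna_primer_pair(name: str) -> PrimerPair:
    """One of the two published *matK* primer pairs, physicochemistry recomputed."""
    fwd, rev = _PRIMER_SEQS[name]
    return PrimerPair(_candidate(fwd, "forward"), _candidate(rev, "reverse"), name)


def senna_primer_names() -> tuple[str, ...]:
    return tuple(_PRIMER_SEQS)


def insert_length(name: str) -> int:
    """Published amplicon size minus both primer footprints."""
    fwd, rev = _PRIMER_SEQS[name]
    return AMPLICON_SIZES[name] - len(fwd) - len(rev)


@dataclass
class SennaCounts:
    """Published mixture read counts wired into the reporting containers."""

    table: ASVTable
    assignments: list[Assignment]
    taxa: tuple[str, ...]


def _synthetic_stand_in(taxon: str, length: int) -> str:
    # Deterministic placeholder for an unpublished ASV sequence: not a
    # real Senna sequence, distinct per taxon, correct insert length.
    import random

    rng = random.Random(taxon)
    return "".join(rng.choice("ACGT") for _ in range(length))


def senna_count_table(primer_name: str) -> SennaCounts:
    """The published per-mixture read counts as an :class:`ASVTable`.

    ASV sequences are synthetic stand-ins (the originals were not
    deposited); counts and species identities are the published values,
    with every ASV assigned at 100% identity.
    """
    counts = _ASV_COUNTS[primer_name]
    length = insert_length(primer_name)
    table_counts: dict[str, dict[str, int]] = {}
    assignments = []
    for taxon, per_mix in counts.items():
        seq = _synthetic_stand_in(taxon, length)
        table_counts[seq] = dict(per_mix)
        assignments.append(Assignment(seq, taxon, 100.0, "species"))
    table = ASVTable(table_counts, list(MIXTURES))
    return SennaCounts(table, assignments, tuple(counts))
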