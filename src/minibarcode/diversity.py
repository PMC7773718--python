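"""Per-gene nucleotide diversity (pi) and variable-site window scans.

For two aligned sequences pi is the p-distance over compared sites:
columns holding a gap or an ambiguity code in any sequence are excluded
entirely ("complete deletion"), and pi = variable / compared.  For more
than two sequences pi is the mean pairwise p-distance over the same set
of fully unambiguous columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from ._dna import UNAMBIGUOUS
from .align import PairwiseAlignment, ScoringScheme, global_align
from .genome_io import CodingGene


@dataclass
class DiversityRecord:
    """Nucleotide diversity of one gene; ``pi`` is None when undefined."""

    gene_name: str
    pi: float | None
    compared_sites: int
    variable_sites: int


@dataclass
class WindowStat:
    """Variable-site and gap counts inside one alignment window."""

    start: int
    end: int
    variable_sites: int
    gap_columns: int


def nucleotide_diversity(
    alignment: PairwiseAlignment | Sequence[str],
) -> tuple[float, int, int]:
    """(pi, compared_sites, variable_sites) for an alignment.

    Accepts a :class:`PairwiseAlignment` or a list of >=2 equal-length
    aligned strings.  Raises when no column is comparable.
    """
    if isinstance(alignment, PairwiseAlignment):
        seqs: Sequence[str] = (alignment.aligned_a, alignment.aligned_b)
    else:
        seqs = list(alignment)
    if len(seqs) < 2:
        raise ValueError("nucleotide diversity needs at least two sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences differ in length")
    compared = 0
    variable = 0
    diff_sum = 0  # summed pairwise differences over compared columns
    n_pairs = len(seqs) * (len(seqs) - 1) // 2
    for col in zip(*seqs):
        if any(c not in UNAMBIGUOUS for c in col):
            continue
        compared += 1
        if len(set(col)) > 1:
            variable += 1
            diff_sum += sum(x != y for x, y in combinations(col, 2))
    if compared == 0:
        raise ValueError("pi undefined: no gap-free unambiguous columns to compare")
    pi = diff_sum / n_pairs / compared
    return pi, compared, variable


def rank_gene_diversity(
    table: Iterable[tuple[str, CodingGene, CodingGene]],
    scoring: ScoringScheme | None = None,
) -> list[DiversityRecord]:
    """Align each ortholog pair and rank genes by pi, descending.

    Ties break by gene name ascending; genes whose alignment has no
    comparable column are flagged (``pi=None``) and placed last.
    """
    records: list[DiversityRecord] = []
    for name, gene_a, gene_b in table:
        aln = global_align(gene_a.sequence, gene_b.sequence, scoring)
        try:
            pi, compared, variable = nucleotide_diversity(aln)
            records.append(DiversityRecord(name, pi, compared, variable))
        except ValueError:
            records.append(DiversityRecord(name, None, 0, aln.variable_sites))
    records.sort(key=lambda r: (r.pi is None, -(r.pi or 0.0), r.gene_name.casefold()))
    return records


def scan_windows(
    alignment: PairwiseAlignment, window: int, step: int
) -> list[WindowStat]:
    """Tile the alignment with windows and count variable/gap columns."""
    length = len(alignment)
    if not (1 <= step <= window):
        raise ValueError("require 1 <= step <= window")
    if window > length:
        raise ValueError(f"window {window} longer than alignment ({length})")
    is_gap = []
    is_var = []
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        is_gap.append(x == "-" or y == "-")
        is_var.append(x in UNAMBIGUOUS and y in UNAMBIGUOUS and x != y)
    out = []
    for start in range(0, length, step):
        end = min(start + window, length)
        out.append(
            WindowStat(start, end, sum(is_var[start:end]), sum(is_gap[start:end]))
        )
        if end == length:
            break
    return out


def diversity_frame(records: Iterable[DiversityRecord]) -> pd.DataFrame:
    """Diversity report with pi rounded to 5 decimals (NA when undefined)."""
    rows = [
        {
            "gene": r.gene_name,
            "pi": round(r.pi, 5) if r.pi is not None else pd.NA,
            "compared_sites": r.compared_sites,
            "variable_sites": r.variable_sites,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["gene", "pi", "compared_sites", "variable_sites"])
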