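"""Mini-barcode primer enumeration, physicochemical screens, in-silico PCR.

Primer pairs are enumerated exhaustively from conserved alignment blocks
flanking a hypervariable insert, filtered on length, GC, melting
temperature, hairpin and dimer heuristics, then validated by in-silico
PCR against whole genomes (a "specific" pair must amplify exactly one
product per genome).  Melting temperatures use the unified nearest-
neighbor thermodynamic parameters with an entropic salt correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from ._dna import UNAMBIGUOUS, WC_PAIR, encode, revcomp, validate_dna
from .align import PairwiseAlignment, ScoringScheme, global_align
from .diversity import rank_gene_diversity
from .genome_io import GenomeRecord, shared_gene_table

# ---------------------------------------------------------------------------
# constraints and record types


@dataclass(frozen=True)
class DesignConstraints:
    """Screening windows for mini-barcode primer pairs.

    Defaults: 150-300 bp products, 18-30 nt primers, Tm 40-70 C,
    GC 30-70 %, and up to 2 primer-template mismatches in PCR validation.
    """

    product_size: tuple[int, int] = (150, 300)
    primer_size: tuple[int, int] = (18, 30)
    tm: tuple[float, float] = (40.0, 70.0)
    gc: tuple[float, float] = (30.0, 70.0)
    max_pcr_mismatch: int = 2

    def __post_init__(self) -> None:
        for name in ("product_size", "primer_size", "tm", "gc"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name}: need 0 < min <= max, got ({lo}, {hi})")


@dataclass
class PrimerCandidate:
    sequence: str  # 5'->3'
    template_start: int  # on the reference template, 0-based
    orientation: str  # forward | reverse
    gc_percent: float
    tm_celsius: float
    hairpin: bool
    max_self_dimer_run: int


@dataclass
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    name: str = ""


@dataclass
class Amplicon:
    """A predicted PCR product; sequences read in the forward-primer direction."""

    template_accession: str
    start: int  # 0-based half-open on the template plus strand
    end: int
    strand: str
    full_sequence: str  # primer footprints included
    insert_sequence: str  # primer footprints excluded


@dataclass
class BarcodeCandidate:
    gene_name: str
    pair: PrimerPair
    amplicon_size_per_taxon: dict[str, int]
    insert_variable_sites: int
    rank: int = 0


@dataclass
class DesignResult:
    """Ranked candidates plus a per-gene account of why pairs were rejected."""

    candidates: list[BarcodeCandidate]
    rejections: dict[str, dict[str, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# primer physicochemistry


def gc_content(seq: str) -> float:
    """GC percentage of an unambiguous primer, to 1 decimal."""
    seq = validate_dna(seq, unambiguous=True, name="primer")
    return round(100.0 * (seq.count("G") + seq.count("C")) / len(seq), 1)


# Unified nearest-neighbor duplex parameters: dH in kcal/mol, dS in cal/(mol K),
# keyed by the top-strand dinucleotide read 5'->3'.
_NN_DH = {
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "TG": -8.5, "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
_NN_DS = {
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "TG": -22.7, "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}
_INIT_GC = (0.1, -2.8)  # terminal G.C initiation (dH, dS)
_INIT_AT = (2.3, 4.1)  # terminal A.T initiation
_R_GAS = 1.987  # cal/(mol K)


def melting_temperature(seq: str, salt_mM: float = 50.0, primer_nM: float = 250.0) -> float:
    """Nearest-neighbor Tm (Celsius) of a primer against its perfect complement.

    Uses the unified duplex parameter set with the entropic salt
    correction dS += 0.368 (N-1) ln[Na+] and Tm = 1000 dH / (dS + R
    ln(Ct/4)) - 273.15 for a non-self-complementary duplex at total
    strand concentration ``primer_nM``.
    """
    seq = validate_dna(seq, unambiguous=True, name="primer")
    if not (8 <= len(seq) <= 50):
        raise ValueError(f"primer length {len(seq)} outside [8, 50]")
    dh, ds = 0.0, 0.0
    for terminal in (seq[0], seq[-1]):
        ih, is_ = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += ih
        ds += is_
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        dh += _NN_DH[pair]
        ds += _NN_DS[pair]
    ds += 0.368 * (len(seq) - 1) * math.log(salt_mM / 1000.0)
    ct = primer_nM * 1e-9
    return dh * 1000.0 / (ds + _R_GAS * math.log(ct / 4.0)) - 273.15


@dataclass
class HairpinResult:
    has_hairpin: bool
    stem_length: int = 0
    stem_start: int = -1  # 5' arm start
    loop_length: int = 0

    def __bool__(self) -> bool:
        return self.has_hairpin


def hairpin_check(seq: str, min_stem: int = 4, min_loop: int = 3) -> HairpinResult:
    """Detect an intramolecular stem-loop by exhaustive enumeration.

    A hairpin requires >= ``min_stem`` contiguous Watson-Crick pairs
    between the two arms and a loop of >= ``min_loop`` unpaired bases.
    The longest stem found is reported even when below threshold.
    """
    seq = validate_dna(seq, unambiguous=True, name="primer")
    n = len(seq)
    best = HairpinResult(False)
    # (i, j) is the outermost base pair; the stem extends inward while
    # seq[i+k] pairs seq[j-k] and at least min_loop bases stay unpaired.
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if WC_PAIR[seq[i]] != seq[j]:
                continue
            s = 1
            while i + s < j - s and WC_PAIR[seq[i + s]] == seq[j - s]:
                s += 1
            s = min(s, (j - i + 1 - min_loop) // 2)  # keep the loop >= min_loop
            if s > best.stem_length:
                best = HairpinResult(False, s, i, j - i - 2 * s + 1)
    best.has_hairpin = best.stem_length >= min_stem
    return best


@dataclass
class DimerResult:
    passed: bool
    max_run: int
    max_three_prime_run: int

    def __bool__(self) -> bool:
        return self.passed


def dimer_check(
    a: str, b: str, max_run: int = 8, max_3prime_run: int = 4
) -> DimerResult:
    """Screen two primers for complementary runs at every ungapped offset.

    Fails when the longest contiguous complementary stretch reaches
    ``max_run`` anywhere, or ``max_3prime_run`` anchored at either
    primer's 3' terminus.  Self-dimers are ``dimer_check(p, p)``.
    """
    a = validate_dna(a, unambiguous=True, name="primer a")
    b = validate_dna(b, unambiguous=True, name="primer b")
    rc = revcomp(b)  # a[i] pairs with b[len(b)-1-k] iff a[i] == rc[k]
    max_run_seen, max_3p = _dimer_scan(encode(a), encode(rc))
    passed = max_run_seen < max_run and max_3p < max_3prime_run
    return DimerResult(passed, int(max_run_seen), int(max_3p))


@njit(cache=True)
def _dimer_scan(a, rc):  # pragma: no cover - jit
    la = a.size
    lb = rc.size
    max_run = 0
    max_3p = 0
    for offset in range(-(lb - 1), la):
        run = 0
        for k in range(lb):
            i = offset + k
            if 0 <= i < la and a[i] == rc[k]:
                run += 1
                # a run touching a's 3' end (i == la-1) or b's 3' end (rc[0])
                if i == la - 1 or k - run + 1 == 0:
                    if run > max_3p:
                        max_3p = run
            else:
                run = 0
            if run > max_run:
                max_run = run
    return max_run, max_3p


# ---------------------------------------------------------------------------
# enumeration over conserved blocks


def _degap_maps(alignment: PairwiseAlignment) -> tuple[list[int], list[int]]:
    """Per alignment column, the template coordinate in each sequence.

    For a gap column the coordinate of the next real base is reported,
    so footprint spans can be converted with [start, end) semantics.
    """
    maps = []
    for aligned in (alignment.aligned_a, alignment.aligned_b):
        pos = 0
        col_to_pos = []
        for ch in aligned:
            col_to_pos.append(pos)
            if ch != "-":
                pos += 1
        col_to_pos.append(pos)
        maps.append(col_to_pos)
    return maps[0], maps[1]


def _conserved_mask(alignment: PairwiseAlignment) -> list[bool]:
    return [
        x == y and x in UNAMBIGUOUS
        for x, y in zip(alignment.aligned_a, alignment.aligned_b)
    ]


def _screen_primer(
    seq: str,
    template_start: int,
    orientation: str,
    constraints: DesignConstraints,
    cache: dict,
    reject: dict[str, int] | None = None,
) -> PrimerCandidate | None:
    if seq in cache:
        cand = cache[seq]
    else:
        gc = gc_content(seq)
        tm = melting_temperature(seq)
        hp = hairpin_check(seq)
        sd = dimer_check(seq, seq)
        cand = PrimerCandidate(seq, -1, orientation, gc, tm, bool(hp), sd.max_run)
        ok = True
        if not (constraints.gc[0] <= gc <= constraints.gc[1]):
            ok = False
            _bump(reject, "gc_out_of_range")
        elif not (constraints.tm[0] <= tm <= constraints.tm[1]):
            ok = False
            _bump(reject, "tm_out_of_range")
        elif hp:
            ok = False
            _bump(reject, "hairpin")
        elif not sd.passed:
            ok = False
            _bump(reject, "self_dimer")
        cache[seq] = cand if ok else None
        if not ok:
            return None
    if cand is None:
        return None
    return replace(cand, template_start=template_start, orientation=orientation)


def _bump(reject: dict[str, int] | None, key: str) -> None:
    if reject is not None:
        reject[key] = reject.get(key, 0) + 1


def enumerate_primer_pairs(
    alignment: PairwiseAlignment,
    constraints: DesignConstraints | None = None,
    rejections: dict[str, int] | None = None,
) -> list[PrimerPair]:
    """Exhaustively enumerate screened primer pairs on conserved blocks.

    Primers are drawn only from alignment columns identical (and
    unambiguous) in both taxa.  Every returned pair satisfies the size,
    GC, Tm, hairpin and dimer constraints in both orientations, the
    product lies within ``product_size`` for each taxon, and the insert
    between the footprints carries at least one variable site.  Output
    is sorted by insert variable sites (desc), insert length (asc), then
    template coordinate.
    """
    constraints = constraints or DesignConstraints()
    cons = _conserved_mask(alignment)
    map_a, map_b = _degap_maps(alignment)
    variable = [
        x in UNAMBIGUOUS and y in UNAMBIGUOUS and x != y
        for x, y in zip(alignment.aligned_a, alignment.aligned_b)
    ]
    var_prefix = np.cumsum([0] + [int(v) for v in variable])

    pmin, pmax = constraints.primer_size
    # maximal conserved runs
    blocks: list[tuple[int, int]] = []
    i = 0
    n = len(cons)
    while i < n:
        if cons[i]:
            j = i
            while j < n and cons[j]:
                j += 1
            if j - i >= pmin:
                blocks.append((i, j))
            i = j
        else:
            i += 1
    if not blocks:
        warnings.warn("no conserved block long enough for a primer; nothing to enumerate")
        return []

    template = alignment.aligned_a.replace("-", "")
    cache_f: dict = {}
    cache_r: dict = {}
    fwd: list[tuple[int, int, PrimerCandidate]] = []  # (col_start, col_end, cand)
    rev: list[tuple[int, int, PrimerCandidate]] = []
    for bs, be in blocks:
        for start in range(bs, be - pmin + 1):
            for length in range(pmin, min(pmax, be - start) + 1):
                seq = template[map_a[start] : map_a[start] + length]
                cand = _screen_primer(
                    seq, map_a[start], "forward", constraints, cache_f, rejections
                )
                if cand is not None:
                    fwd.append((start, start + length, cand))
                rseq = revcomp(seq)
                rcand = _screen_primer(
                    rseq, map_a[start], "reverse", constraints, cache_r, rejections
                )
                if rcand is not None:
                    rev.append((start, start + length, rcand))

    fwd.sort(key=lambda t: t[0])
    rev.sort(key=lambda t: t[0])
    pairs: list[tuple[int, int, int, PrimerPair]] = []
    lo, hi = constraints.product_size
    for fs, fe, fcand in fwd:
        for rs, re_, rcand in rev:
            if rs < fe:
                continue
            # product size on each taxon's own coordinates
            size_a = map_a[re_] - map_a[fs]
            size_b = map_b[re_] - map_b[fs]
            if size_a > hi and size_b > hi:
                break  # rev sorted by start; later ones only longer
            if not (lo <= size_a <= hi and lo <= size_b <= hi):
                _bump(rejections, "product_size")
                continue
            ivs = int(var_prefix[rs] - var_prefix[fe])
            if ivs < 1:
                _bump(rejections, "no_insert_variable_site")
                continue
            if not dimer_check(fcand.sequence, rcand.sequence).passed:
                _bump(rejections, "cross_dimer")
                continue
            name = f"{map_a[fs] + 1}F-{map_a[re_]}R"
            pair = PrimerPair(fcand, rcand, name)
            insert_len = map_a[rs] - map_a[fe]
            pairs.append((ivs, insert_len, map_a[fs], pair))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [p for _, _, _, p in pairs]


# ---------------------------------------------------------------------------
# in-silico PCR


def _annealing_sites(template: np.ndarray, primer: str, max_mismatch: int) -> list[int]:
    """Start positions where *primer* (5'->3' along the array) anneals.

    Requires <= ``max_mismatch`` substitutions overall and an exact
    3'-terminal trinucleotide.
    """
    p = encode(primer)
    k = p.size
    if template.size < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(template, k)
    mism = (windows != p).sum(axis=1)
    hits = np.flatnonzero(mism <= max_mismatch)
    out = []
    for h in hits:
        if np.array_equal(windows[h, -3:], p[-3:]):
            out.append(int(h))
    return out


def in_silico_pcr(
    pair: PrimerPair,
    genome: GenomeRecord | str,
    max_mismatch: int = 2,
    max_product: int = 2000,
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on a template.

    Both primers are searched on both strands with <= ``max_mismatch``
    substitutions and an exact 3'-terminal trinucleotide; every
    plus/minus site combination with a non-negative insert and a product
    <= ``max_product`` bp is reported.  Zero amplicons is a valid result.
    """
    if isinstance(genome, GenomeRecord):
        accession, template = genome.accession, genome.sequence
    else:
        accession, template = "template", validate_dna(genome, name="template")
    arr = encode(template)
    rc_arr = encode(revcomp(template))
    L = len(template)

    primers = {
        "forward": validate_dna(pair.forward.sequence, unambiguous=True, name="forward primer"),
        "reverse": validate_dna(pair.reverse.sequence, unambiguous=True, name="reverse primer"),
    }
    plus: list[tuple[str, int, int]] = []  # (which, start, len) extending rightward
    minus: list[tuple[str, int, int]] = []  # start on plus coords, extending leftward
    for which, p in primers.items():
        for s in _annealing_sites(arr, p, max_mismatch):
            plus.append((which, s, len(p)))
        for s in _annealing_sites(rc_arr, p, max_mismatch):
            # position s on the reverse strand = plus-strand window [L-s-k, L-s)
            minus.append((which, L - s - len(p), len(p)))

    amplicons: list[Amplicon] = []
    for pw, ps, pk in plus:
        for mw, ms, mk in minus:
            if ms < ps + pk:  # footprints must not overlap (insert >= 0)
                continue
            end = ms + mk
            if end - ps > max_product:
                continue
            full = template[ps:end]
            insert = template[ps + pk : ms]
            strand = "+" if pw == "forward" else "-"
            if pw == "reverse":
                # read the product in the forward-primer direction
                full = revcomp(full)
                insert = revcomp(insert)
            amplicons.append(Amplicon(accession, ps, end, strand, full, insert))
    amplicons.sort(key=lambda a: (a.start, a.end))
    return amplicons


def count_variable_sites(
    amplicons: Mapping[str, Amplicon | None], scoring: ScoringScheme | None = None
) -> int:
    """Differing compared columns between globally aligned inserts.

    Primer footprints are excluded (the inserts are compared).  Exactly
    two taxa are supported; a missing amplicon raises naming the taxon.
    """
    missing = [t for t, a in amplicons.items() if a is None]
    if missing:
        raise ValueError(f"missing amplicon for taxon: {', '.join(sorted(missing))}")
    if len(amplicons) != 2:
        raise ValueError(f"expected amplicons for exactly 2 taxa, got {len(amplicons)}")
    (a, b) = (amp.insert_sequence for amp in amplicons.values())
    if a == b:
        return 0
    aln = global_align(a, b, scoring)
    return aln.variable_sites


# ---------------------------------------------------------------------------
# end-to-end design


def design_minibarcodes(
    genomes: Sequence[GenomeRecord],
    constraints: DesignConstraints | None = None,
    top_genes: int = 4,
    scoring: ScoringScheme | None = None,
    max_pairs_per_gene: int = 200,
) -> DesignResult:
    """Full mini-barcode design pipeline on two annotated genomes.

    Shared protein-coding genes are ranked by nucleotide diversity; for
    each of the ``top_genes`` most diverse genes, primer pairs are
    enumerated on conserved blocks, validated by in-silico PCR against
    every genome (keeping pairs that amplify exactly one product per
    genome), and ranked by insert variable sites.
    """
    if len(genomes) != 2:
        raise ValueError("mini-barcode design is defined for exactly two genomes")
    constraints = constraints or DesignConstraints()
    table = shared_gene_table(genomes[0], genomes[1])
    ranked = rank_gene_diversity(table, scoring)
    gene_seqs = {name: (ga, gb) for name, ga, gb in table}
    rejections: dict[str, dict[str, int]] = {}

    scored: list[tuple[int, int, BarcodeCandidate]] = []
    for rec in ranked[:top_genes]:
        if rec.pi is None or rec.pi == 0.0:
            rejections.setdefault(rec.gene_name, {})["no_variable_sites_in_gene"] = 1
            continue
        gene_a, gene_b = gene_seqs[rec.gene_name]
        aln = global_align(gene_a.sequence, gene_b.sequence, scoring)
        gene_rej: dict[str, int] = {}
        pairs = enumerate_primer_pairs(aln, constraints, gene_rej)
        for pair in pairs[:max_pairs_per_gene]:
            products = {
                g.accession: in_silico_pcr(pair, g, constraints.max_pcr_mismatch)
                for g in genomes
            }
            if any(len(v) != 1 for v in products.values()):
                _bump(gene_rej, "not_unique_amplicon")
                continue
            amps = {acc: v[0] for acc, v in products.items()}
            ivs = count_variable_sites(amps, scoring)
            if ivs < 1:
                _bump(gene_rej, "no_insert_variable_site")
                continue
            sizes = {acc: len(a.full_sequence) for acc, a in amps.items()}
            insert_len = min(len(a.insert_sequence) for a in amps.values())
            cand = BarcodeCandidate(rec.gene_name, pair, sizes, ivs)
            scored.append((ivs, insert_len, cand))
        rejections[rec.gene_name] = gene_rej
    scored.sort(key=lambda t: (-t[0], t[1], t[2].gene_name))
    candidates = []
    for rank, (_, _, cand) in enumerate(scored, start=1):
        cand.rank = rank
        candidates.append(cand)
    return DesignResult(candidates, rejections)


def candidate_frame(result: DesignResult) -> pd.DataFrame:
    """Candidate report: one row per primer pair with physicochemistry."""
    rows = []
    for c in result.candidates:
        f, r = c.pair.forward, c.pair.reverse
        row = {
            "rank": c.rank,
            "gene": c.gene_name,
            "pair": c.pair.name,
            "fwd_seq": f.sequence,
            "rev_seq": r.sequence,
            "tm_f": round(f.tm_celsius, 1),
            "tm_r": round(r.tm_celsius, 1),
            "gc_f": f.gc_percent,
            "gc_r": r.gc_percent,
            "insert_variable_sites": c.insert_variable_sites,
        }
        for taxon, size in c.amplicon_size_per_taxon.items():
            row[f"amplicon_{taxon}"] = size
        rows.append(row)
    return pd.DataFrame(rows)


def primers_to_fasta(pairs: Iterable[PrimerPair], path) -> None:
    with open(path, "w") as fh:
        for pair in pairs:
            fh.write(f">{pair.name}_F\n{pair.forward.sequence}\n")
            fh.write(f">{pair.name}_R\n{pair.reverse.sequence}\n")
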