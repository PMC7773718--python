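"""Tagged paired-end amplicon reads -> ASV tables -> species proportions.

The pipeline mirrors a dual-tagged amplicon metabarcoding experiment:
exact dual-tag demultiplexing (tag jumps go to the unassigned pool),
overlap merging of read pairs, substitution-tolerant primer trimming,
exact dereplication into amplicon sequence variants (ASVs), an
abundance-based denoising collapse, global-identity taxon assignment
against reference inserts, and read-proportion estimation with an
optional reads-vs-biomass regression.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from numba import njit
from scipy import stats

from ._dna import encode, revcomp
from .align import ScoringScheme, global_align
from .primers import PrimerPair

# ---------------------------------------------------------------------------
# input records


@dataclass(frozen=True)
class TagScheme:
    """Sample -> (forward_tag, reverse_tag); all tags one common length."""

    tags: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.tags:
            raise ValueError("empty tag scheme")
        lengths = {len(t) for pair in self.tags.values() for t in pair}
        if len(lengths) != 1:
            raise ValueError(f"tags have mixed lengths: {sorted(lengths)}")
        if lengths.pop() < 6:
            raise ValueError("tags must be at least 6 nt")
        pairs = list(self.tags.values())
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (forward_tag, reverse_tag) pair in scheme")
        object.__setattr__(self, "tags", dict(self.tags))

    @property
    def tag_length(self) -> int:
        return len(next(iter(self.tags.values()))[0])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TagScheme":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = [c.lower() for c in df.columns]
        df.columns = cols
        return cls(
            {r["sample"]: (r["fwd_tag"].upper(), r["rev_tag"].upper()) for _, r in df.iterrows()}
        )


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


def read_paired_fastq(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Stream mate pairs from two FASTQ files (.gz accepted), Phred+33."""

    def _open(p):
        p = Path(p)
        return gzip.open(p, "rt") if p.suffix == ".gz" else open(p)

    with _open(path1) as fh1, _open(path2) as fh2:
        for (id1, s1, q1), (id2, s2, q2) in zip(
            FastqGeneralIterator(fh1), FastqGeneralIterator(fh2), strict=True
        ):
            yield ReadPair(id1.split()[0], s1.upper(), q1, s2.upper(), q2)


def write_paired_fastq(
    reads: Iterable[ReadPair], path1: str | Path, path2: str | Path
) -> None:
    with open(path1, "w") as fh1, open(path2, "w") as fh2:
        for r in reads:
            fh1.write(f"@{r.read_id}/1\n{r.seq1}\n+\n{r.qual1}\n")
            fh2.write(f"@{r.read_id}/2\n{r.seq2}\n+\n{r.qual2}\n")


# ---------------------------------------------------------------------------
# demultiplexing


@dataclass
class DemuxResult:
    per_sample: dict[str, list[ReadPair]]
    unassigned: list[ReadPair]

    @property
    def assigned_count(self) -> int:
        return sum(len(v) for v in self.per_sample.values())


def demultiplex(reads: Iterable[ReadPair], scheme: TagScheme) -> DemuxResult:
    """Assign read pairs to samples by exact dual-tag match, 0 mismatches.

    A pair belongs to sample *s* iff read 1 starts with s's forward tag
    and read 2 with s's reverse tag; any other combination -- including
    a tag jump mixing two samples' tags -- is unassigned.  Tags are
    stripped from assigned reads.
    """
    L = scheme.tag_length
    lookup = {pair: sample for sample, pair in scheme.tags.items()}
    out = DemuxResult({s: [] for s in scheme.tags}, [])
    for r in reads:
        sample = lookup.get((r.seq1[:L], r.seq2[:L]))
        if sample is None:
            out.unassigned.append(r)
        else:
            out.per_sample[sample].append(
                ReadPair(r.read_id, r.seq1[L:], r.qual1[L:], r.seq2[L:], r.qual2[L:])
            )
    return out


# ---------------------------------------------------------------------------
# pair merging


@njit(cache=True)
def _best_overlap(r1, r2rc, min_overlap, max_mismatch_frac):  # pragma: no cover - jit
    n1 = r1.size
    n2 = r2rc.size
    best_ov = -1
    best_matches = -1
    top = n1 if n1 < n2 else n2
    for ov in range(min_overlap, top + 1):
        matches = 0
        off = n1 - ov
        for k in range(ov):
            if r1[off + k] == r2rc[k]:
                matches += 1
        if (ov - matches) / ov <= max_mismatch_frac and matches >= best_matches:
            best_matches = matches
            best_ov = ov
    return best_ov, best_matches


@dataclass
class MergeResult:
    ok: bool
    sequence: str = ""
    quality: str = ""
    overlap: int = 0
    reason: str = ""

    def __bool__(self) -> bool:
        return self.ok


def merge_pairs(
    pair: ReadPair, min_overlap: int = 20, max_mismatch_frac: float = 0.1
) -> MergeResult:
    """Overlap-merge a read pair into one amplicon-spanning sequence.

    Mate 2 is reverse-complemented, the admissible overlap (length >=
    ``min_overlap``, mismatch fraction <= ``max_mismatch_frac``)
    maximizing the number of matching bases is chosen (ties prefer the
    longer overlap), and disagreeing positions take the higher-quality
    base (mate 1 wins quality ties).
    """
    s2 = revcomp(pair.seq2)
    q2 = pair.qual2[::-1]
    ov, _ = _best_overlap(
        encode(pair.seq1), encode(s2), min_overlap, max_mismatch_frac
    )
    if ov < 0:
        return MergeResult(False, reason="no admissible overlap")
    off = len(pair.seq1) - ov
    head_s, head_q = pair.seq1[:off], pair.qual1[:off]
    cons = []
    consq = []
    for k in range(ov):
        b1, b2 = pair.seq1[off + k], s2[k]
        c1, c2 = pair.qual1[off + k], q2[k]
        if b1 == b2:
            cons.append(b1)
            consq.append(max(c1, c2))
        elif c2 > c1:
            cons.append(b2)
            consq.append(c2)
        else:
            cons.append(b1)
            consq.append(c1)
    return MergeResult(
        True,
        head_s + "".join(cons) + s2[ov:],
        head_q + "".join(consq) + q2[ov:],
        ov,
    )


# ---------------------------------------------------------------------------
# primer trimming


@dataclass
class TrimResult:
    ok: bool
    insert: str = ""
    reason: str = ""

    def __bool__(self) -> bool:
        return self.ok


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_primers(merged: str, pair: PrimerPair, max_mismatch: int = 2) -> TrimResult:
    """Strip primer footprints from a merged amplicon sequence.

    The forward primer must match at the 5' end and the
    reverse-complemented reverse primer at the 3' end, each with at most
    ``max_mismatch`` substitutions and no indels.
    """
    fwd = pair.forward.sequence.upper()
    rev_rc = revcomp(pair.reverse.sequence.upper())
    if len(merged) <= len(fwd) + len(rev_rc):
        return TrimResult(False, reason="shorter than combined primers")
    if _mismatches(merged[: len(fwd)], fwd) > max_mismatch:
        return TrimResult(False, reason="forward primer unmatched")
    if _mismatches(merged[-len(rev_rc):], rev_rc) > max_mismatch:
        return TrimResult(False, reason="reverse primer unmatched")
    return TrimResult(True, merged[len(fwd): -len(rev_rc)])


# ---------------------------------------------------------------------------
# dereplication into ASVs


@dataclass
class ASVTable:
    """Unique insert sequences x per-sample read counts.

    Rows iterate in decreasing total abundance (ties lexicographic).
    ``n_discarded`` counts inserts dropped for containing N.
    """

    counts: dict[str, dict[str, int]]
    samples: list[str]
    n_discarded: dict[str, int] = field(default_factory=dict)

    @property
    def sequences(self) -> list[str]:
        return sorted(self.counts, key=lambda s: (-self.total(s), s))

    def total(self, seq: str | None = None) -> int:
        if seq is not None:
            return sum(self.counts[seq].values())
        return sum(sum(c.values()) for c in self.counts.values())

    def sample_count(self, seq: str, sample: str) -> int:
        return self.counts.get(seq, {}).get(sample, 0)

    def to_frame(self) -> pd.DataFrame:
        seqs = self.sequences
        df = pd.DataFrame(
            {
                "asv_id": [f"ASV{i + 1}" for i in range(len(seqs))],
                "sequence": seqs,
            }
        )
        for s in self.samples:
            df[s] = [self.counts[q].get(s, 0) for q in seqs]
        return df


def dereplicate(inserts: Mapping[str, Iterable[str]]) -> ASVTable:
    """Pool identical insert sequences per sample (100% identity ASVs).

    Sequences are uppercased; any insert containing a base outside
    A/C/G/T (e.g. N) is discarded and counted in ``n_discarded``.
    """
    counts: dict[str, dict[str, int]] = {}
    discarded: dict[str, int] = {}
    samples = list(inserts)
    for sample, seqs in inserts.items():
        for seq in seqs:
            seq = seq.upper()
            if set(seq) - {"A", "C", "G", "T"}:
                discarded[sample] = discarded.get(sample, 0) + 1
                continue
            col = counts.setdefault(seq, {})
            col[sample] = col.get(sample, 0) + 1
    return ASVTable(counts, samples, discarded)


# ---------------------------------------------------------------------------
# denoising


def _hamming1_adjacency(seqs: Sequence[str]) -> dict[str, set[str]]:
    """Pairs of sequences at Hamming distance exactly 1 (equal lengths)."""
    adj: dict[str, set[str]] = {s: set() for s in seqs}
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)
    for group in by_len.values():
        if len(group) < 2:
            continue
        mat = np.vstack([encode(s) for s in group])
        # chunked pairwise Hamming distances
        chunk = max(1, int(2e7 // (mat.shape[1] * len(group)) or 1))
        for lo in range(0, len(group), chunk):
            hi = min(lo + chunk, len(group))
            d = (mat[lo:hi, None, :] != mat[None, :, :]).sum(axis=2)
            ii, jj = np.nonzero(d == 1)
            for i, j in zip(ii, jj):
                adj[group[lo + i]].add(group[j])
    return adj


def denoise(table: ASVTable, min_count: int = 2, skew: float = 0.05) -> ASVTable:
    """Abundance-based collapse of likely sequencing-error ASVs.

    Per sample: ASVs with count < ``min_count`` are removed; then, in
    descending abundance order, an ASV joins an existing cluster when it
    lies within Hamming distance 1 of *any* sequence already merged into
    that cluster and its count is <= ``skew`` times the cluster's
    current total (most abundant eligible cluster wins, ties by centroid
    sequence).  Chaining through previously merged error sequences lets
    multi-error variants collapse onto the true sequence while distinct
    biological ASVs, protected by the abundance-skew test, never merge.
    """
    survivors: dict[str, dict[str, int]] = {}
    per_sample_survivors: dict[str, dict[str, int]] = {s: {} for s in table.samples}
    for seq, cc in table.counts.items():
        for sample, c in cc.items():
            if c >= min_count:
                per_sample_survivors[sample][seq] = c
    all_seqs = sorted({s for col in per_sample_survivors.values() for s in col})
    adj = _hamming1_adjacency(all_seqs)

    out: dict[str, dict[str, int]] = {}
    for sample, col in per_sample_survivors.items():
        order = sorted(col, key=lambda s: (-col[s], s))
        clusters: list[dict] = []  # {"centroid", "count", "members": set}
        for seq in order:
            c = col[seq]
            best = None
            for cl in clusters:
                if c <= skew * cl["count"] and adj[seq] & cl["members"]:
                    if (
                        best is None
                        or cl["count"] > best["count"]
                        or (cl["count"] == best["count"] and cl["centroid"] < best["centroid"])
                    ):
                        best = cl
            if best is None:
                clusters.append({"centroid": seq, "count": c, "members": {seq}})
            else:
                best["count"] += c
                best["members"].add(seq)
        # an error variant can be reached only through a member that joins
        # later; keep folding whole clusters together until nothing moves
        merged_any = True
        while merged_any and len(clusters) > 1:
            merged_any = False
            clusters.sort(key=lambda cl: (-cl["count"], cl["centroid"]))
            for small in sorted(clusters, key=lambda cl: (cl["count"], cl["centroid"])):
                best = None
                for big in clusters:
                    if big is small:
                        continue
                    if small["count"] <= skew * big["count"] and any(
                        adj[m] & big["members"] for m in small["members"]
                    ):
                        best = big
                        break  # clusters pre-sorted: first hit is the best
                if best is not None:
                    best["count"] += small["count"]
                    best["members"] |= small["members"]
                    clusters.remove(small)
                    merged_any = True
                    break
        for cl in clusters:
            out.setdefault(cl["centroid"], {})[sample] = cl["count"]
    return ASVTable(out, table.samples, dict(table.n_discarded))


# ---------------------------------------------------------------------------
# taxon assignment and proportions


@dataclass
class Assignment:
    asv_sequence: str
    taxon: str
    identity: float  # percent
    status: str  # species | near | unassigned
    tie: bool = False


def assign_taxa(
    table: ASVTable,
    refs: Mapping[str, str],
    scoring: ScoringScheme | None = None,
    near_threshold: float = 97.0,
) -> list[Assignment]:
    """Assign each ASV to the best reference insert by global identity.

    Identity is 100 x matching columns / alignment columns of a global
    alignment.  100% -> ``species``; >= ``near_threshold`` -> ``near``;
    otherwise ``unassigned``.  An ASV equally close to several
    references below 100% is unassigned with the tie flag set.
    """
    if not refs:
        raise ValueError("empty reference set")
    ref_items = sorted((t, r.upper()) for t, r in refs.items())
    if len({r for _, r in ref_items}) != len(ref_items):
        raise ValueError("reference inserts are not unique per taxon")
    out = []
    for seq in table.sequences:
        scores = []
        for taxon, ref in ref_items:
            if seq == ref:
                ident = 100.0
            else:
                aln = global_align(seq, ref, scoring)
                matches = sum(
                    x == y and x != "-" for x, y in zip(aln.aligned_a, aln.aligned_b)
                )
                ident = 100.0 * matches / len(aln)
            scores.append((ident, taxon))
        scores.sort(key=lambda t: (-t[0], t[1]))
        best_ident, best_taxon = scores[0]
        tie = len(scores) > 1 and scores[1][0] == best_ident
        if best_ident == 100.0 and not tie:
            out.append(Assignment(seq, best_taxon, best_ident, "species"))
        elif tie:
            out.append(Assignment(seq, best_taxon, best_ident, "unassigned", tie=True))
        elif best_ident >= near_threshold:
            out.append(Assignment(seq, best_taxon, best_ident, "near"))
        else:
            out.append(Assignment(seq, best_taxon, best_ident, "unassigned"))
    return out


def species_proportions(
    table: ASVTable, assignments: Sequence[Assignment]
) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample taxon read proportions over species-level assignments.

    Returns a (samples x taxa) frame whose rows sum to 1, plus the list
    of samples with zero species-assigned reads (rows of NaN).
    """
    by_seq = {a.asv_sequence: a for a in assignments}
    missing = [s for s in table.counts if s not in by_seq]
    if missing:
        raise ValueError(f"{len(missing)} ASVs lack an assignment")
    taxa = sorted({a.taxon for a in assignments if a.status == "species"})
    rows = {}
    flagged = []
    for sample in table.samples:
        totals = dict.fromkeys(taxa, 0)
        for seq, cc in table.counts.items():
            a = by_seq[seq]
            if a.status == "species":
                totals[a.taxon] += cc.get(sample, 0)
        grand = sum(totals.values())
        if grand == 0:
            flagged.append(sample)
            rows[sample] = {t: math.nan for t in taxa}
        else:
            rows[sample] = {t: totals[t] / grand for t in taxa}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=taxa)
    df.index.name = "sample"
    return df, flagged


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def proportion_regression(
    points: Sequence[tuple[float, float]]
) -> RegressionResult:
    """OLS of reads proportion on biomass proportion, pooled over taxa.

    ``r_squared`` is the squared Pearson correlation.  A constant-y
    input yields slope 0 and R^2 = 0 with a degenerate-fit warning.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in biomass proportions")
    if np.ptp(y) == 0:
        warnings.warn("reads proportions are constant; degenerate fit")
        return RegressionResult(0.0, float(y[0]), 0.0, len(points))
    fit = stats.linregress(x, y)
    return RegressionResult(
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2), len(points)
    )


# ---------------------------------------------------------------------------
# pipeline driver


@dataclass
class QuantResult:
    """End-to-end quantification output with per-stage read accounting."""

    asv_table: ASVTable
    denoised: ASVTable
    assignments: list[Assignment]
    proportions: pd.DataFrame
    unassigned_samples: list[str]
    stage_counts: dict[str, int]
    regression: RegressionResult | None = None


def run_quantification(
    reads: Iterable[ReadPair],
    scheme: TagScheme,
    pair: PrimerPair,
    refs: Mapping[str, str],
    biomass: pd.DataFrame | None = None,
    min_count: int = 2,
    skew: float = 0.05,
    max_primer_mismatch: int = 2,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> QuantResult:
    """Run demultiplex -> merge -> trim -> dereplicate -> denoise ->
    assign -> proportions, with read conservation tracked per stage.

    ``biomass``, if given, is a frame with columns sample, taxon,
    proportion; a pooled reads-vs-biomass OLS is then fitted over all
    (sample, taxon) points.
    """
    demux = demultiplex(reads, scheme)
    n_in = demux.assigned_count + len(demux.unassigned)
    inserts: dict[str, list[str]] = {}
    n_merged = n_trimmed = 0
    for sample, rs in demux.per_sample.items():
        kept = []
        for r in rs:
            m = merge_pairs(r, min_overlap, max_mismatch_frac)
            if not m:
                continue
            n_merged += 1
            t = trim_primers(m.sequence, pair, max_primer_mismatch)
            if not t:
                continue
            n_trimmed += 1
            kept.append(t.insert)
        inserts[sample] = kept
    table = dereplicate(inserts)
    den = denoise(table, min_count=min_count, skew=skew)
    assignments = assign_taxa(den, refs)
    props, flagged = species_proportions(den, assignments)
    stage_counts = {
        "input_pairs": n_in,
        "demux_assigned": demux.assigned_count,
        "demux_unassigned": len(demux.unassigned),
        "merged": n_merged,
        "trimmed": n_trimmed,
        "dereplicated_reads": table.total(),
        "denoised_reads": den.total(),
    }
    regression = None
    if biomass is not None:
        pts = []
        for _, row in biomass.iterrows():
            sample, taxon = row["sample"], row["taxon"]
            if sample in props.index and taxon in props.columns:
                val = props.loc[sample, taxon]
                if not math.isnan(val):
                    pts.append((float(row["proportion"]), float(val)))
        regression = proportion_regression(pts)
    return QuantResult(table, den, assignments, props, flagged, stage_counts, regression)
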