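"""Demultiplexing, merging, trimming, ASVs, denoising, proportions."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_pair, random_dna
from minibarcode._dna import revcomp
from minibarcode.quant import (
    ASVTable,
    Assignment,
    ReadPair,
    TagScheme,
    assign_taxa,
    demultiplex,
    denoise,
    dereplicate,
    merge_pairs,
    proportion_regression,
    species_proportions,
    trim_primers,
)

SCHEME = TagScheme(
    {
        "s1": ("ACGTAC", "TGCATG"),
        "s2": ("CAGTCA", "GTCAGT"),
    }
)


def _pair(seq1, seq2, q1=None, q2=None, rid="r0"):
    return ReadPair(rid, seq1, q1 or "I" * len(seq1), seq2, q2 or "I" * len(seq2))


# ---------------------------------------------------------------- demultiplex


def test_demultiplex_assigns_on_matching_dual_tags_and_strips_them():
    body1, body2 = random_dna(40, 1), random_dna(40, 2)
    res = demultiplex([_pair("ACGTAC" + body1, "TGCATG" + body2)], SCHEME)
    assert len(res.per_sample["s1"]) == 1
    out = res.per_sample["s1"][0]
    assert out.seq1 == body1 and out.seq2 == body2
    assert len(out.qual1) == len(out.seq1)


def test_tag_jump_goes_to_unassigned():
    body = random_dna(40, 3)
    # forward tag of s1 with reverse tag of s2: a tag jump
    res = demultiplex([_pair("ACGTAC" + body, "GTCAGT" + body)], SCHEME)
    assert res.assigned_count == 0
    assert len(res.unassigned) == 1


def test_demultiplex_conserves_reads():
    rng = random.Random(4)
    reads = []
    for i in range(50):
        f = rng.choice(["ACGTAC", "CAGTCA", "GGGGGG"])
        r = rng.choice(["TGCATG", "GTCAGT", "CCCCCC"])
        reads.append(_pair(f + random_dna(30, i), r + random_dna(30, 100 + i), rid=f"r{i}"))
    res = demultiplex(reads, SCHEME)
    assert res.assigned_count + len(res.unassigned) == 50


def test_duplicate_tag_pair_is_a_configuration_error():
    with pytest.raises(ValueError):
        TagScheme({"a": ("ACGTAC", "TGCATG"), "b": ("ACGTAC", "TGCATG")})


# ---------------------------------------------------------------- merge_pairs


def test_merge_reconstructs_amplicon_from_paired_reads():
    amplicon = random_dna(200, seed=5)
    pair = _pair(amplicon[:150], revcomp(amplicon[-150:]))
    m = merge_pairs(pair)
    assert m.ok
    assert m.sequence == amplicon
    assert m.overlap == 100
    assert len(m.quality) == 200


def test_merge_rejects_short_overlap():
    # disjoint halves: best overlap would be ~10 nt, below the minimum
    a, b = random_dna(80, 6), random_dna(80, 7)
    m = merge_pairs(_pair(a, revcomp(b)), min_overlap=20)
    assert not m.ok and m.reason


def test_merge_takes_higher_quality_base_at_disagreement():
    amplicon = random_dna(120, seed=8)
    read1 = list(amplicon[:100])
    read1[60] = "ACGT"["ACGT".index(read1[60]) - 1]  # error in mate 1
    q1 = chr(10 + 33) * 100  # Q10
    read2 = revcomp(amplicon[-100:])
    q2 = chr(40 + 33) * 100  # Q40
    m = merge_pairs(_pair("".join(read1), read2, q1, q2))
    assert m.ok
    assert m.sequence == amplicon  # mate 2's Q40 base wins


# --------------------------------------------------------------- trim_primers


FWD, REV = "GTGAATACGAATCTATCT", "GGATTTTCCTTGATATCT"
PAIR = make_pair(FWD, REV)


def test_trim_recovers_insert_from_exact_amplicon():
    insert = random_dna(164, seed=9)
    t = trim_primers(FWD + insert + revcomp(REV), PAIR)
    assert t.ok and t.insert == insert
    assert len(t.insert) == 200 - len(FWD) - len(REV) == 164


def test_trim_rejects_excess_mismatches_and_missing_primers():
    insert = random_dna(100, seed=10)
    fwd3 = "CCC" + FWD[3:]  # 3 mismatches in the forward footprint
    assert not trim_primers(fwd3 + insert + revcomp(REV), PAIR, max_mismatch=2).ok
    assert not trim_primers(random_dna(150, seed=11), PAIR).ok


# ---------------------------------------------------------------- dereplicate


def test_dereplicate_pools_identical_sequences():
    s1, s2 = random_dna(50, 12), random_dna(50, 13)
    table = dereplicate({"m1": [s1] * 10 + [s2] * 5})
    assert table.sequences == sorted([s1, s2], key=lambda s: (-table.total(s), s))
    assert table.sample_count(s1, "m1") == 10
    assert table.sample_count(s2, "m1") == 5
    assert table.total() == 15


def test_dereplicate_normalizes_case_and_discards_n():
    s = random_dna(30, 14)
    table = dereplicate({"m1": [s, s.lower(), s[:-1] + "N"]})
    assert len(table.counts) == 1
    assert table.total() == 2
    assert table.n_discarded == {"m1": 1}


# -------------------------------------------------------------------- denoise


def test_denoise_merges_one_off_child_into_parent():
    parent = random_dna(60, 15)
    child = "ACGT".replace(parent[0], "") [0] + parent[1:]
    table = ASVTable({parent: {"m": 100}, child: {"m": 2}}, ["m"])
    out = denoise(table, min_count=2, skew=0.05)
    assert out.sample_count(parent, "m") == 102
    assert child not in out.counts


def test_denoise_retains_distant_abundant_asvs():
    a = random_dna(60, 16)
    b = list(a)
    b[0] = "ACGT".replace(a[0], "")[0]
    b[30] = "ACGT".replace(a[30], "")[0]
    b = "".join(b)  # Hamming distance 2, comparable abundance
    table = ASVTable({a: {"m": 100}, b: {"m": 90}}, ["m"])
    out = denoise(table)
    assert out.sample_count(a, "m") == 100
    assert out.sample_count(b, "m") == 90


def test_denoise_removes_singletons():
    a, b = random_dna(60, 17), random_dna(60, 18)
    table = ASVTable({a: {"m": 50}, b: {"m": 1}}, ["m"])
    out = denoise(table, min_count=2)
    assert b not in out.counts
    assert out.total() == 50


def test_denoise_collapses_error_chains_onto_true_sequence():
    # a double-error variant has no abundant Hamming-1 parent but chains
    # through an absorbed single-error variant
    true = random_dna(60, 19)
    single = "ACGT".replace(true[0], "")[0] + true[1:]
    double = single[:30] + "ACGT".replace(single[30], "")[0] + single[31:]
    table = ASVTable({true: {"m": 1000}, single: {"m": 12}, double: {"m": 2}}, ["m"])
    out = denoise(table)
    assert list(out.counts) == [true]
    assert out.sample_count(true, "m") == 1014


def test_denoise_never_increases_totals_and_is_identity_when_no_rule_fires():
    a, b = random_dna(40, 20), random_dna(40, 21)
    table = ASVTable({a: {"m": 30}, b: {"m": 25}}, ["m"])
    out = denoise(table)
    assert out.counts == table.counts


# ------------------------------------------------------------------ assign


def test_assignment_statuses():
    ref_a, ref_b = random_dna(164, 22), random_dna(164, 23)
    one_off = "ACGT".replace(ref_a[0], "")[0] + ref_a[1:]
    table = ASVTable({ref_a: {"m": 5}, one_off: {"m": 5}}, ["m"])
    res = assign_taxa(table, {"A": ref_a, "B": ref_b})
    by_seq = {a.asv_sequence: a for a in res}
    assert by_seq[ref_a].status == "species" and by_seq[ref_a].identity == 100.0
    near = by_seq[one_off]
    assert near.status == "near" and near.taxon == "A"
    assert near.identity == pytest.approx(100 * 163 / 164)


def test_equidistant_asv_is_unassigned_with_tie_flag():
    ref_a = "ACGTACGTACGTACGTACGT"
    ref_b = ref_a[:-1] + "C"
    # one substitution from each reference
    mid = ref_a[:-1] + "A"
    table = ASVTable({mid: {"m": 3}}, ["m"])
    (res,) = assign_taxa(table, {"A": ref_a, "B": ref_b})
    assert res.status == "unassigned" and res.tie


def test_empty_reference_set_is_an_error():
    with pytest.raises(ValueError):
        assign_taxa(ASVTable({}, ["m"]), {})


# -------------------------------------------------------------- proportions


def test_reported_mixture_counts_give_printed_proportions():
    # JM1 counts for the 647F-847R barcode: 56,065 and 57,978 reads
    a, b = random_dna(164, 24), random_dna(164, 25)
    table = ASVTable({a: {"JM1": 56_065}, b: {"JM1": 57_978}}, ["JM1"])
    assignments = [
        Assignment(a, "S. occidentalis", 100.0, "species"),
        Assignment(b, "S. obtusifolia", 100.0, "species"),
    ]
    props, flagged = species_proportions(table, assignments)
    assert flagged == []
    assert props.loc["JM1", "S. occidentalis"] == pytest.approx(0.4916, abs=5e-5)
    assert props.loc["JM1", "S. obtusifolia"] == pytest.approx(0.5084, abs=5e-5)
    assert props.loc["JM1"].sum() == pytest.approx(1.0)


def test_single_species_sample_and_unassigned_sample():
    a = random_dna(50, 26)
    b = random_dna(50, 27)
    table = ASVTable({a: {"m1": 10, "m2": 0}, b: {"m2": 4}}, ["m1", "m2"])
    assignments = [
        Assignment(a, "A", 100.0, "species"),
        Assignment(b, "B", 98.0, "near"),  # not species -> excluded
    ]
    props, flagged = species_proportions(table, assignments)
    assert props.loc["m1", "A"] == 1.0
    assert flagged == ["m2"]
    assert math.isnan(props.loc["m2", "A"])


def test_regression_on_perfect_line_and_degenerate_inputs():
    pts = [(0.1, 0.1), (0.4, 0.4), (0.9, 0.9)]
    fit = proportion_regression(pts)
    assert fit.slope == pytest.approx(1.0)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.n_points == 3

    with pytest.warns(UserWarning):
        flat = proportion_regression([(0.1, 0.5), (0.9, 0.5)])
    assert flat.r_squared == 0.0 and flat.slope == 0.0

    with pytest.raises(ValueError):
        proportion_regression([(0.5, 0.1), (0.5, 0.9)])  # zero x variance
    with pytest.raises(ValueError):
        proportion_regression([(0.1, 0.2)])


# -------------------------------------------------------- end-to-end


def _simulated_run(seed: int, n_reads: int, error_rate: float):
    from minibarcode.datasets import senna_primer_pair
    from minibarcode.quant import run_quantification
    from minibarcode.simulate import (
        SimulationConfig,
        simulate_barcode_refs,
        simulate_mixture_reads,
    )

    pair = senna_primer_pair("647F-847R")
    cfg = SimulationConfig(
        seed=seed,
        n_reads=n_reads,
        error_rate=error_rate,
        proportions={"taxon_a": 0.2, "taxon_b": 0.8},
    )
    refs, _ = simulate_barcode_refs(cfg, pair.forward.sequence, pair.reverse.sequence)
    scheme = TagScheme({"mix": ("ACGTACGT", "TGCATGCA")})
    reads, _ = simulate_mixture_reads(refs, scheme, cfg)
    insert_refs = {t: a[18:-18] for t, a in refs.items()}
    return run_quantification(reads, scheme, pair, insert_refs), cfg


def test_parameter_recovery_from_deep_simulated_mixture():
    """50,000 read pairs at error rate 0.001: each estimated proportion
    within 0.02 of truth and exactly one ASV per species after denoising."""
    result, cfg = _simulated_run(seed=77, n_reads=50_000, error_rate=0.001)
    assert len(result.denoised.counts) == 2
    species = [a for a in result.assignments if a.status == "species"]
    assert len(species) == 2
    for taxon, p in cfg.proportions.items():
        assert abs(result.proportions.loc["mix", taxon] - p) <= 0.02


def test_pipeline_is_deterministic():
    frames = []
    for _ in range(2):
        result, _ = _simulated_run(seed=55, n_reads=1_000, error_rate=0.002)
        frames.append(
            result.denoised.to_frame().to_csv(index=False)
            + result.proportions.to_csv()
        )
    assert frames[0] == frames[1]


# ------------------------------------------------- conservation (fuzzed)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.sampled_from(["ACGTAC", "CAGTCA", "GGGGGG"]), min_size=0, max_size=20),
       st.randoms(use_true_random=False))
def test_read_conservation_through_demux_and_derep(tags, rnd):
    reads = []
    for i, f in enumerate(tags):
        r = rnd.choice(["TGCATG", "GTCAGT", "AAAAAA"])
        body = "".join(rnd.choice("ACGTN") for _ in range(30))
        reads.append(_pair(f + body, r + body, rid=f"r{i}"))
    res = demultiplex(reads, SCHEME)
    assert res.assigned_count + len(res.unassigned) == len(reads)
    inserts = {s: [r.seq1 for r in rs] for s, rs in res.per_sample.items()}
    table = dereplicate(inserts)
    retained = sum(len(v) for v in inserts.values()) - sum(table.n_discarded.values())
    assert table.total() == retained
    den = denoise(table)
    assert den.total() <= table.total()
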