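"""Primer physicochemistry, enumeration, and in-silico PCR."""

import random

import pytest

from conftest import make_pair, make_record, random_dna
from minibarcode._dna import revcomp
from minibarcode.align import global_align
from minibarcode.primers import (
    DesignConstraints,
    count_variable_sites,
    design_minibarcodes,
    dimer_check,
    enumerate_primer_pairs,
    gc_content,
    hairpin_check,
    in_silico_pcr,
    melting_temperature,
)

# frozen values from an independently hand-summed nearest-neighbor table
TM_ORACLE = {
    "GTGAATACGAATCTATCT": 42.1045,
    "GGATTTTCCTTGATATCT": 42.2703,
    "GTTCAAACCCTTCGATACTG": 50.5594,
}


@pytest.mark.parametrize(
    "seq,expected",
    [("ATAT", 0.0), ("GCGC", 100.0), ("GTTCAAACCCTTCGATACTG", 45.0)],
)
def test_gc_content(seq, expected):
    assert gc_content(seq) == expected


def test_gc_content_rejects_ambiguity_codes():
    with pytest.raises(ValueError):
        gc_content("ACGTN")


@pytest.mark.parametrize("seq,expected", sorted(TM_ORACLE.items()))
def test_tm_matches_hand_summed_nearest_neighbor_oracle(seq, expected):
    assert melting_temperature(seq) == pytest.approx(expected, abs=1e-3)


def test_tm_cross_checked_against_independent_implementation():
    from Bio.SeqUtils import MeltingTemp as mt

    for seq in TM_ORACLE:
        ref = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, saltcorr=5, dnac1=125, dnac2=125)
        assert melting_temperature(seq) == pytest.approx(float(ref), abs=0.05)


def test_tm_invariant_under_reverse_complement():
    for seq in ("GTGAATACGAATCTATCT", "ACGTGGCCAATTCGCGAT"):
        assert melting_temperature(seq) == pytest.approx(
            melting_temperature(revcomp(seq)), abs=1e-9
        )


def test_gc_rich_duplex_melts_higher_than_at_rich():
    assert melting_temperature("GCGCGCGCGCGCGCGCGC") > melting_temperature(
        "ATATATATATATATATAT"
    )


def test_tm_length_bounds():
    with pytest.raises(ValueError):
        melting_temperature("ACGTACG")  # 7 nt


def test_hairpin_detection():
    hit = hairpin_check("GGGGAAAACCCC")
    assert hit.has_hairpin and hit.stem_length == 4 and hit.loop_length == 4
    assert not hairpin_check("AAAAAAAAAA").has_hairpin
    # complementary ends but loop below the minimum
    assert not hairpin_check("AAAATTTT").has_hairpin


def test_dimer_screen():
    a = "ACGTACGTACGT"
    assert not dimer_check(a, revcomp(a)).passed  # full-length run
    full = dimer_check("AAAAAAAA", "TTTTTTTT")
    assert not full.passed and full.max_run == 8
    clean = dimer_check("AAAAAAAA", "CCCCCCCC")
    assert clean.passed and clean.max_run == 0


def _planted_alignment(n_subs: int = 7, seed: int = 17):
    """20 nt conserved + 160 nt variable block + 20 nt conserved."""
    rng = random.Random(seed)
    left = "GTGGACTACGAATCTATCTG"
    right = "CAGGATCTTCCTTGATATCG"
    middle = random_dna(160, seed=seed + 1)
    pos = rng.sample(range(160), n_subs)
    other = list(middle)
    for p in pos:
        other[p] = "ACGT"["ACGT".index(other[p]) - 1]
    a = left + middle + right
    b = left + "".join(other) + right
    return global_align(a, b), sorted(pos)


def test_enumeration_recovers_pair_spanning_planted_variable_sites():
    aln, _ = _planted_alignment()
    constraints = DesignConstraints(product_size=(150, 300))
    pairs = enumerate_primer_pairs(aln, constraints)
    assert pairs, "no primer pair found on the planted fixture"
    best = pairs[0]
    amp = in_silico_pcr(best, aln.aligned_a.replace("-", ""), 0)
    assert len(amp) == 1
    # the top-ranked pair spans all 7 planted substitutions
    amp_b = in_silico_pcr(best, aln.aligned_b.replace("-", ""), 0)
    assert count_variable_sites({"a": amp[0], "b": amp_b[0]}) == 7


def test_enumeration_on_identical_sequences_is_empty():
    seq = random_dna(200, seed=3)
    aln = global_align(seq, seq)
    assert enumerate_primer_pairs(aln, DesignConstraints()) == []


def test_enumeration_infeasible_product_range_is_empty():
    aln, _ = _planted_alignment()
    constraints = DesignConstraints(product_size=(10, 20), primer_size=(18, 18))
    assert enumerate_primer_pairs(aln, constraints) == []


def test_every_enumerated_pair_satisfies_all_constraints():
    aln, _ = _planted_alignment()
    constraints = DesignConstraints()
    for pair in enumerate_primer_pairs(aln, constraints)[:25]:
        for cand in (pair.forward, pair.reverse):
            assert constraints.primer_size[0] <= len(cand.sequence) <= constraints.primer_size[1]
            assert constraints.gc[0] <= cand.gc_percent <= constraints.gc[1]
            assert constraints.tm[0] <= cand.tm_celsius <= constraints.tm[1]
            assert not cand.hairpin
        assert dimer_check(pair.forward.sequence, pair.reverse.sequence).passed


def test_enumeration_invariant_under_taxon_order():
    aln, _ = _planted_alignment()
    swapped = global_align(aln.aligned_b.replace("-", ""), aln.aligned_a.replace("-", ""))
    seqs = {(p.forward.sequence, p.reverse.sequence) for p in enumerate_primer_pairs(aln)}
    seqs_swapped = {
        (p.forward.sequence, p.reverse.sequence) for p in enumerate_primer_pairs(swapped)
    }
    assert seqs == seqs_swapped


def test_in_silico_pcr_on_constructed_template():
    fwd = "GTGAATACGAATCTATCT"
    rev = "GGATTTTCCTTGATATCT"
    insert = random_dna(164, seed=8)
    template = "AAAC" + fwd + insert + revcomp(rev) + "GGTT"
    amps = in_silico_pcr(make_pair(fwd, rev), template, 0)
    assert len(amps) == 1
    amp = amps[0]
    assert (amp.start, amp.end, amp.strand) == (4, 204, "+")
    assert len(amp.full_sequence) == 18 + 164 + 18 == 200
    assert amp.insert_sequence == insert
    assert len(amp.insert_sequence) == len(amp.full_sequence) - len(fwd) - len(rev)


def test_in_silico_pcr_finds_reverse_strand_products():
    fwd = "GTGAATACGAATCTATCT"
    rev = "GGATTTTCCTTGATATCT"
    insert = random_dna(100, seed=9)
    template = revcomp("AAAC" + fwd + insert + revcomp(rev) + "GGTT")
    amps = in_silico_pcr(make_pair(fwd, rev), template, 0)
    assert len(amps) == 1
    assert amps[0].strand == "-"
    assert amps[0].insert_sequence == insert


def test_in_silico_pcr_empty_when_sites_absent():
    assert in_silico_pcr(make_pair("GTGAATACGAATCTATCT", "GGATTTTCCTTGATATCT"),
                         random_dna(500, seed=10), 0) == []


def test_in_silico_pcr_tolerates_internal_but_not_3prime_mismatches():
    fwd = "GTGAATACGAATCTATCT"
    rev = "GGATTTTCCTTGATATCT"
    insert = random_dna(80, seed=12)
    mutated_fwd = "GTGAATACGAATCTATCT"
    mutated_fwd = "C" + mutated_fwd[1:]  # internal (5') mismatch
    template = mutated_fwd + insert + revcomp(rev)
    assert len(in_silico_pcr(make_pair(fwd, rev), template, 1)) == 1
    assert in_silico_pcr(make_pair(fwd, rev), template, 0) == []
    # mismatch in the 3'-terminal trinucleotide kills annealing at any tolerance
    bad3 = fwd[:-1] + ("A" if fwd[-1] != "A" else "C")
    template3 = bad3 + insert + revcomp(rev)
    assert in_silico_pcr(make_pair(fwd, rev), template3, 2) == []


def test_count_variable_sites_examples():
    fwd, rev = "GTGAATACGAATCTATCT", "GGATTTTCCTTGATATCT"
    insert = random_dna(60, seed=13)
    other = list(insert)
    for p in (5, 20, 40):
        other[p] = "ACGT"["ACGT".index(other[p]) - 1]
    t1 = fwd + insert + revcomp(rev)
    t2 = fwd + "".join(other) + revcomp(rev)
    a1 = in_silico_pcr(make_pair(fwd, rev), t1, 0)[0]
    a2 = in_silico_pcr(make_pair(fwd, rev), t2, 0)[0]
    assert count_variable_sites({"x": a1, "y": a1}) == 0
    assert count_variable_sites({"x": a1, "y": a2}) == 3
    with pytest.raises(ValueError, match="y"):
        count_variable_sites({"x": a1, "y": None})


def test_design_on_identical_genomes_is_empty():
    rec = make_record("A", {"g1": (random_dna(300, 14), "+")}, spacer="T" * 40)
    result = design_minibarcodes([rec, rec])
    assert result.candidates == []
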