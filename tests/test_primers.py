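"""Primer statistics, the 3'-discriminating-base rule, and pair screening.

The two published oligos of the common-pandora NAD2 assay serve as exact
worked examples: their printed length, GC% and base counts must be
reproduced to the digit.
"""

import pytest

from mitomarker.align import Alignment
from mitomarker.genomes import reverse_complement
from mitomarker.primers import (DesignConstraints, Primer,
                                check_pair_interactions, design_pairs,
                                discriminating_positions,
                                enumerate_candidates, primer_stats,
                                published_pair)
from mitomarker.simulate import (FW303, FW_ANCHOR, REV593, REV_ANCHOR)


@pytest.mark.parametrize("seq, length, gc, a, t, c, g", [
    (FW303, 22, 45.5, 6, 6, 6, 4),
    (REV593, 26, 46.2, 11, 3, 2, 10),
])
def test_published_primer_table_reproduced_exactly(seq, length, gc, a, t, c, g):
    st = primer_stats(seq)
    assert st.length == length
    assert round(st.gc_percent, 1) == gc
    assert (st.count_a, st.count_t, st.count_c, st.count_g) == (a, t, c, g)


def test_wallace_rule_arithmetic():
    st = primer_stats("AAAA")
    assert st.gc_percent == 0.0
    assert st.tm_wallace == 8.0


def test_stats_reject_ambiguity_codes():
    with pytest.raises(ValueError):
        primer_stats("ACGN")


def test_reverse_complement_preserves_gc_and_tm():
    for seq in (FW303, REV593, "ACGTACGTTTGCA"):
        st, rc = primer_stats(seq), primer_stats(reverse_complement(seq))
        assert st.gc_percent == rc.gc_percent
        assert st.tm_wallace == rc.tm_wallace
        assert st.tm_nn == pytest.approx(rc.tm_nn, abs=1e-9)


def test_counts_sum_to_length():
    st = primer_stats(FW303)
    assert st.count_a + st.count_t + st.count_c + st.count_g == st.length


# -- discriminating positions ------------------------------------------------

def test_all_identical_alignment_has_no_discriminating_positions():
    aln = Alignment({"t": "ACGT", "u": "ACGT", "v": "ACGT"})
    assert discriminating_positions(aln, "t") == []


def test_single_engineered_site_found():
    aln = Alignment({"t": "ACGTA", "u": "ACCTA", "v": "ACCTA"})
    assert discriminating_positions(aln, "t") == [3]


def test_positions_in_ungapped_target_coordinates():
    # target row has a leading gap; discriminating column 4 is target base 3
    aln = Alignment({"t": "-ACGA", "u": "TACTA", "v": "GACTA"})
    assert discriminating_positions(aln, "t") == [3]


def test_gap_in_others_counts_as_difference():
    aln = Alignment({"t": "ACGT", "u": "AC-T", "v": "ACAT"})
    assert discriminating_positions(aln, "t") == [3]


def test_quorum_relaxation():
    aln = Alignment({"t": "ACGT", "u": "ACAT", "v": "ACGT"})
    assert discriminating_positions(aln, "t") == []
    assert discriminating_positions(aln, "t", quorum=0.5) == [3]


def test_missing_target_rejected():
    with pytest.raises(ValueError):
        discriminating_positions(Alignment({"u": "ACGT", "v": "ACGT"}), "t")


# -- candidate enumeration ---------------------------------------------------

def _engineered_alignment(site: int = 60, length: int = 120, seed: int = 2):
    """Gap-free panel identical everywhere except one target-unique site."""
    import random
    rng = random.Random(seed)
    base = "".join(rng.choice("ACGT") for _ in range(length))
    target = base[:site - 1] + "A" + base[site:]
    other = base[:site - 1] + "G" + base[site:]
    return Alignment({"t": target, "u": other, "v": other})


def relaxed_constraints(**kw):
    defaults = dict(length_range=(20, 20), tm_range=(0.0, 100.0),
                    gc_range=(1.0, 99.0), max_homopolymer=20,
                    max_any_run=20, max_three_prime_run=20)
    defaults.update(kw)
    return DesignConstraints(**defaults)


def test_no_discriminating_positions_yields_no_candidates():
    aln = Alignment({"t": "ACGTACGTACGTACGTACGTACGT" * 2,
                     "u": "ACGTACGTACGTACGTACGTACGT" * 2})
    assert enumerate_candidates(aln, "t", relaxed_constraints()) == []


def test_engineered_site_yields_one_candidate_per_orientation():
    aln = _engineered_alignment()
    cands = enumerate_candidates(aln, "t", relaxed_constraints())
    assert len(cands) == 2
    fw = next(c for c in cands if c.orientation == "forward")
    rev = next(c for c in cands if c.orientation == "reverse")
    tseq = aln.rows["t"]
    # brute-force oracle: the only admissible 20-mers end on the site
    assert fw.sequence == tseq[40:60]
    assert fw.anchor == 41
    assert rev.sequence == reverse_complement(tseq[59:79])
    assert rev.anchor == 79


def test_every_candidate_ends_on_a_discriminating_position():
    aln = _engineered_alignment()
    sites = set(discriminating_positions(aln, "t"))
    for c in enumerate_candidates(
            aln, "t", relaxed_constraints(length_range=(18, 24))):
        assert c.three_prime_position in sites


def test_enumeration_equals_bruteforce_window_scan():
    aln = _engineered_alignment(site=50, length=100)
    c = relaxed_constraints(length_range=(18, 22))
    got = {(p.orientation, p.anchor, p.sequence)
           for p in enumerate_candidates(aln, "t", c)}
    tseq = aln.rows["t"]
    sites = set(discriminating_positions(aln, "t"))
    expected = set()
    for L in range(18, 23):
        for start in range(1, len(tseq) - L + 2):
            window = tseq[start - 1:start + L - 1]
            if start + L - 1 in sites:
                expected.add(("forward", start, window))
            if start in sites:
                expected.add(("reverse", start + L - 1,
                              reverse_complement(window)))
    assert got == expected


def test_primer_alphabet_enforced():
    with pytest.raises(ValueError):
        Primer("x", "ACGN", "forward", 1)


# -- pair interactions -------------------------------------------------------

def _primer(seq, orientation="forward", anchor=1):
    return Primer("p", seq, orientation, anchor)


def test_poly_a_does_not_self_anneal():
    rep = check_pair_interactions(_primer("AAAAAA"), _primer("AAAAAA"))
    assert rep.cross_run == 0
    assert rep.passed


def test_full_complement_cross_run():
    rep = check_pair_interactions(_primer("AAAAAA"), _primer("TTTTTT"))
    assert rep.cross_run == 6


def test_published_pair_passes_default_screen():
    pair = published_pair(FW303, REV593, FW_ANCHOR, REV_ANCHOR)
    assert pair.interactions.passed
    assert pair.product_size == 291
    assert pair.delta_tm < 3.0


# -- pair design -------------------------------------------------------------

def test_design_pairs_empty_candidates():
    assert design_pairs([]) == []


def test_two_site_panel_pair_brackets_both_sites():
    import random
    rng = random.Random(9)
    L = 400
    base = "".join(rng.choice("ACGT") for _ in range(L))
    s1, s2 = 80, 350  # 271 bp apart -> product within [250, 350]
    target = list(base)
    other = list(base)
    target[s1 - 1], other[s1 - 1] = "A", "G"
    target[s2 - 1], other[s2 - 1] = "C", "T"
    aln = Alignment({"t": "".join(target), "u": "".join(other),
                     "v": "".join(other)})
    c = relaxed_constraints(length_range=(18, 24), product_range=(250, 350),
                            max_pair_tm_diff=50.0)
    sites = discriminating_positions(aln, "t")
    assert sites == [s1, s2]
    pairs = design_pairs(enumerate_candidates(aln, "t", c), c, sites)
    assert pairs
    top = pairs[0]
    assert top.forward.three_prime_position == s1
    assert top.reverse.three_prime_position == s2
    # deterministic order
    again = design_pairs(enumerate_candidates(aln, "t", c), c, sites)
    assert pairs == again
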