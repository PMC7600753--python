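"""Pairwise and progressive alignment against independent oracles."""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitomarker.align import (Alignment, AlignmentParams, guide_tree,
                              kmer_cosine_distance, pairwise_global,
                              progressive_msa)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=12)
P = AlignmentParams()


# -- independent scoring + exhaustive-enumeration oracle --------------------

def score_alignment(ra: str, rb: str, p: AlignmentParams) -> float:
    """Column-by-column score; gap run of length L costs open+(L-1)*extend."""
    s = 0.0
    prev = None
    for x, y in zip(ra, rb):
        if x == "-":
            s -= p.gap_extend if prev == "a" else p.gap_open
            prev = "a"
        elif y == "-":
            s -= p.gap_extend if prev == "b" else p.gap_open
            prev = "b"
        else:
            s += p.match if x == y else p.mismatch
            prev = None
    return s


def best_score_bruteforce(a: str, b: str, p: AlignmentParams) -> float:
    """Enumerate every global alignment of two short strings."""
    best = [-float("inf")]

    def rec(i, j, ra, rb):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score_alignment(ra, rb, p))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ra + a[i], rb + b[j])
        if i < len(a):
            rec(i + 1, j, ra + a[i], rb + "-")
        if j < len(b):
            rec(i, j + 1, ra + "-", rb + b[j])

    rec(0, 0, "", "")
    return best[0]


def test_identity_alignment_has_no_gaps():
    aln = pairwise_global("ACGT", "ACGT")
    assert aln.rows == {"a": "ACGT", "b": "ACGT"}


def test_single_deletion():
    aln = pairwise_global("ACGT", "ACT")
    assert aln.rows["a"] == "ACGT"
    assert aln.rows["b"].count("-") == 1
    assert score_alignment(aln.rows["a"], aln.rows["b"], P) == \
        best_score_bruteforce("ACGT", "ACT", P)


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        pairwise_global("ACGT", "")


def test_pairwise_matches_enumeration_oracle_on_short_strings():
    rng = random.Random(7)
    for _ in range(60):
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
        aln = pairwise_global(a, b)
        got = score_alignment(aln.rows["a"], aln.rows["b"], P)
        assert got == pytest.approx(best_score_bruteforce(a, b, P)), (a, b)


@given(a=DNA, b=DNA)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_degapped_rows_reproduce_inputs(a, b):
    aln = pairwise_global(a, b)
    assert aln.degapped("a") == a
    assert aln.degapped("b") == b
    assert aln.length >= max(len(a), len(b))


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        AlignmentParams(gap_open=1, gap_extend=2)
    with pytest.raises(ValueError):
        AlignmentParams(match=1, mismatch=2)


# -- progressive MSA --------------------------------------------------------

def test_msa_of_two_reduces_to_pairwise():
    a, b = "ACGTTGCAACGT", "ACGTGCACGT"
    pw = pairwise_global(a, b, labels=("x", "y"))
    msa = progressive_msa({"x": a, "y": b})
    assert score_alignment(msa.rows["x"], msa.rows["y"], P) == \
        score_alignment(pw.rows["x"], pw.rows["y"], P)


def test_msa_identical_sequences_gap_free():
    seqs = {f"s{i}": "ACGTACGTAA" for i in range(3)}
    msa = progressive_msa(seqs)
    assert msa.length == 10
    assert all("-" not in r for r in msa.rows.values())


def test_msa_degap_and_no_all_gap_columns():
    seqs = {"a": "ACGTACGTAC", "b": "ACGACGTAC", "c": "ACGTACTAC",
            "d": "TCGTACGTAC"}
    msa = progressive_msa(seqs)
    for lab, s in seqs.items():
        assert msa.degapped(lab) == s
    for col in range(msa.length):
        assert any(r[col] != "-" for r in msa.rows.values())


def test_msa_invariant_to_relabeling():
    seqs = {"a": "ACGTACGTACGTTT", "b": "ACGACGTACGTT", "c": "ACGTACGTAGG"}
    swapped = {"c": seqs["c"], "b": seqs["b"], "a": seqs["a"]}
    s1 = progressive_msa(seqs).score(P)
    s2 = progressive_msa(swapped).score(P)
    assert s1 == pytest.approx(s2)


def test_msa_rejects_duplicate_content_under_one_label():
    with pytest.raises(ValueError):
        progressive_msa({"a": "ACGT"})


def test_msa_recovers_simulated_divergence():
    """Sequences at ~5% divergence from one ancestor align to a mean
    pairwise p-distance within 3 binomial SE of the expectation."""
    rng = np.random.default_rng(11)
    L, d = 600, 0.05
    anc = "".join(rng.choice(list("ACGT"), size=L))
    seqs = {}
    for i in range(5):
        arr = list(anc)
        for pos in np.flatnonzero(rng.random(L) < d):
            arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
        seqs[f"s{i}"] = "".join(arr)
    msa = progressive_msa(seqs)
    ps = []
    for x, y in itertools.combinations(msa.rows.values(), 2):
        diff = sum(1 for u, v in zip(x, y) if u != v and "-" not in (u, v))
        n = sum(1 for u, v in zip(x, y) if "-" not in (u, v))
        ps.append(diff / n)
    expected = 2 * d - (4 / 3) * d * d
    se = np.sqrt(expected * (1 - expected) / L)
    assert abs(np.mean(ps) - expected) < 3 * se


# -- guide tree --------------------------------------------------------------

def test_guide_tree_two_sequences():
    assert guide_tree({"a": "ACGTACGT", "b": "ACGTATGT"}) == [(0, 1)]


def test_guide_tree_joins_identical_pair_first():
    seqs = {"a": "ACGTACGTACGTAA", "b": "TTTTGGGGCCCCAA",
            "c": "ACGTACGTACGTAA"}
    order = guide_tree(seqs)
    assert set(order[0]) == {0, 2}


def brute_force_upgma(dm: np.ndarray) -> list[tuple[int, int]]:
    """Quadratic-per-step reference UPGMA on an exact distance table."""
    n = dm.shape[0]
    active = {i: [i] for i in range(n)}
    dist = {frozenset((i, j)): dm[i, j]
            for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(active) > 1:
        pair = min(dist, key=lambda k: (dist[k], sorted(k)))
        i, j = sorted(pair)
        merges.append((i, j))
        members = active[i] + active[j]
        del active[i], active[j]
        for k in list(active):
            d = np.mean([dm[a, b] for a in members for b in active[k]])
            dist[frozenset((nxt, k))] = d
        dist = {key: v for key, v in dist.items()
                if i not in key and j not in key}
        active[nxt] = members
        nxt += 1
    return merges


def test_guide_tree_matches_bruteforce_upgma():
    rng = random.Random(3)
    seqs = {}
    anc = "".join(rng.choice("ACGT") for _ in range(200))
    for i in range(6):
        s = list(anc)
        for _ in range(rng.randint(5, 60)):
            p = rng.randrange(200)
            s[p] = rng.choice("ACGT")
        seqs[f"t{i}"] = "".join(s)
    labels = list(seqs)
    n = len(labels)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = kmer_cosine_distance(
                seqs[labels[i]], seqs[labels[j]])
    assert guide_tree(seqs) == brute_force_upgma(dm)
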