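"""Global pairwise and progressive multiple sequence alignment.

The divergence statistics downstream are all computed on alignment rows, so
this module provides the alignments: optimal global Needleman–Wunsch with
affine gaps (Gotoh's three-state recurrence) for pairs, and a guide-tree
ordered progressive profile–profile alignment for panels.

Scoring convention: a gap run of length L costs ``gap_open + (L-1) *
gap_extend`` (the first gap column carries the opening penalty). Traceback
ties break diagonal, then up, then left, so outputs are reproducible.

The inner DP is vectorized row-wise with numpy; the horizontal-gap state is
resolved exactly with a prefix-max scan, so the alignment is optimal, not
banded or heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

NEG = -1e30  # effectively -infinity for the DP

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
GAP = 5  # index of the gap symbol in profile frequency vectors


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("require gap_open >= gap_extend >= 0")
        if not self.match > self.mismatch:
            raise ValueError("require match > mismatch")

    def score_matrix(self) -> np.ndarray:
        """6x6 symbol score matrix: A C G T, ambiguous, gap.

        Ambiguity codes score as mismatch against everything (including
        themselves); any comparison involving a gap symbol scores 0 — gap
        placement is priced solely by the affine penalties.
        """
        s = np.full((6, 6), self.mismatch)
        np.fill_diagonal(s, self.match)
        s[4, 4] = self.mismatch
        s[5, :] = 0.0
        s[:, 5] = 0.0
        return s


@dataclass
class Alignment:
    """Equal-length gapped rows keyed by species label."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lens = {len(r) for r in self.rows.values()}
        if len(lens) != 1:
            raise ValueError("alignment rows must be equal length")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def degapped(self, label: str) -> str:
        return self.rows[label].replace("-", "")

    def score(self, params: AlignmentParams) -> float:
        """Sum-of-pairs score of the alignment under ``params``."""
        total = 0.0
        labels = list(self.rows)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                total += _pair_score(self.rows[a], self.rows[b], params)
        return total


def _pair_score(ra: str, rb: str, p: AlignmentParams) -> float:
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(ra, rb):
        if x == "-" and y == "-":
            continue
        if x == "-":
            score -= p.gap_extend if in_gap_a else p.gap_open
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score -= p.gap_extend if in_gap_b else p.gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += p.match if (x == y and x in _CODE) else p.mismatch
            in_gap_a = in_gap_b = False
    return score


def encode(seq: str) -> np.ndarray:
    """Encode DNA to integer codes: ACGT -> 0..3, anything else -> 4."""
    return np.array([_CODE.get(c, 4) for c in seq.upper()], dtype=np.int8)


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 6) column frequency profile of gapped rows (gap index 5)."""
    arr = np.stack([
        np.array([_CODE.get(c, 4) if c != "-" else GAP for c in r],
                 dtype=np.int8)
        for r in rows
    ])
    freq = np.zeros((arr.shape[1], 6))
    for sym in range(6):
        freq[:, sym] = (arr == sym).mean(axis=0)
    return freq


def _gotoh(sim: np.ndarray, p: AlignmentParams):
    """Fill Gotoh matrices for a precomputed (n, m) column-pair similarity.

    Returns (M, X, Y): M aligns column i to column j, X puts a gap in the
    second profile (vertical move), Y in the first (horizontal move).
    """
    n, m = sim.shape
    go, ge = p.gap_open, p.gap_extend
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    j = np.arange(1, m + 1)
    Y[0, 1:] = -go - (j - 1) * ge
    i = np.arange(1, n + 1)
    X[1:, 0] = -go - (i - 1) * ge

    jj = np.arange(1, m + 1)
    for r in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[r - 1], X[r - 1]), Y[r - 1])
        M[r, 1:] = prev_best[:-1] + sim[r - 1]
        X[r, 1:] = np.maximum(
            np.maximum(M[r - 1, 1:], Y[r - 1, 1:]) - go,
            X[r - 1, 1:] - ge,
        )
        # Y[r, j] = max_{1<=k<=j} Z[r, k-1] - go - (j-k)*ge, Z = max(M, X):
        # exact prefix-max scan of the same-row horizontal-gap recurrence.
        Z = np.maximum(M[r, :-1], X[r, :-1])
        Y[r, 1:] = np.maximum.accumulate(Z + jj * ge) - go - jj * ge
    return M, X, Y


def _traceback(M, X, Y, sim, p: AlignmentParams):
    """Optimal path as a list of moves: 'D' (diag), 'U' (up), 'L' (left).

    Ties prefer D, then U, then L, at every decision point.
    """
    go, ge = p.gap_open, p.gap_extend
    n, m = sim.shape
    i, j = n, m
    scores = (M[n, m], X[n, m], Y[n, m])
    state = "MXY"[int(np.argmax(scores))]  # argmax is first-max: M wins ties
    moves: list[str] = []
    tol = 1e-6
    while i > 0 or j > 0:
        if state == "M":
            moves.append("D")
            prev = M[i, j] - sim[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for s, val in (("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])):
                if abs(val - prev) < tol:
                    state = s
                    break
        elif state == "X":
            moves.append("U")
            here = X[i, j]
            i -= 1
            if abs(M[i, j] - go - here) < tol:
                state = "M"
            elif abs(X[i, j] - ge - here) < tol:
                state = "X"
            else:
                state = "Y"
        else:
            moves.append("L")
            here = Y[i, j]
            j -= 1
            if abs(M[i, j] - go - here) < tol:
                state = "M"
            elif abs(X[i, j] - go - here) < tol:
                state = "X"
            else:
                state = "Y"
    moves.reverse()
    return moves


def _align_profiles(rows_a: dict[str, str], rows_b: dict[str, str],
                    p: AlignmentParams) -> dict[str, str]:
    fa = _profile(list(rows_a.values()))
    fb = _profile(list(rows_b.values()))
    S = p.score_matrix()
    sim = fa @ S @ fb.T
    M, X, Y = _gotoh(sim, p)
    moves = _traceback(M, X, Y, sim, p)

    def expand(row: str, gap_move: str) -> str:
        out = []
        it = iter(row)
        for mv in moves:
            out.append("-" if mv == gap_move else next(it))
        return "".join(out)

    merged = {lab: expand(r, "L") for lab, r in rows_a.items()}
    merged.update({lab: expand(r, "U") for lab, r in rows_b.items()})
    return merged


def pairwise_global(a: str, b: str,
                    params: AlignmentParams | None = None,
                    labels: tuple[str, str] = ("a", "b")) -> Alignment:
    """Optimal global alignment of two sequences with affine gap costs."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    p = params or AlignmentParams()
    rows = _align_profiles({labels[0]: a}, {labels[1]: b}, p)
    return Alignment(rows)


def alignment_score(a: str, b: str, params: AlignmentParams | None = None) -> float:
    p = params or AlignmentParams()
    aln = pairwise_global(a, b, p)
    return _pair_score(aln.rows["a"], aln.rows["b"], p)


def _kmer_vector(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        counts[w] = counts.get(w, 0) + 1
    return counts


def kmer_cosine_distance(a: str, b: str, k: int = 6) -> float:
    """1 - cosine similarity of k-mer count vectors (quick tree distance)."""
    k = max(1, min(k, len(a), len(b)))
    va, vb = _kmer_vector(a, k), _kmer_vector(b, k)
    dot = sum(va[w] * vb.get(w, 0) for w in va)
    na = np.sqrt(sum(v * v for v in va.values()))
    nb = np.sqrt(sum(v * v for v in vb.values()))
    if na == 0 or nb == 0:
        return 1.0
    return float(1.0 - dot / (na * nb))


def guide_tree(seqs: dict[str, str], k: int = 6) -> list[tuple[int, int]]:
    """UPGMA joining order over k-mer cosine distances.

    Returns merge pairs in scipy linkage convention: leaves are 0..n-1 in
    input order, merge t creates cluster n+t. Deterministic given input
    order.
    """
    labels = list(seqs)
    n = len(labels)
    if n < 2:
        raise ValueError("guide tree needs >= 2 sequences")
    if n == 2:
        return [(0, 1)]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = kmer_cosine_distance(
                seqs[labels[i]], seqs[labels[j]], k)
    Z = linkage(squareform(dm, checks=False), method="average")
    return [(int(a), int(b)) for a, b, _, _ in Z]


def progressive_msa(seqs: dict[str, str],
                    params: AlignmentParams | None = None) -> Alignment:
    """Progressive multiple alignment along a UPGMA guide tree.

    Profiles are merged with the same affine-gap global aligner used for
    pairs (column scores are profile-frequency weighted), so two sequences
    reduce exactly to :func:`pairwise_global`.
    """
    if len(seqs) < 2:
        raise ValueError("MSA needs >= 2 sequences")
    if len(seqs) != len(set(seqs)):
        raise ValueError("duplicate labels")
    for lab, s in seqs.items():
        if not s:
            raise ValueError(f"empty sequence for {lab!r}")
    p = params or AlignmentParams()
    labels = list(seqs)
    clusters: dict[int, dict[str, str]] = {
        i: {lab: seqs[lab]} for i, lab in enumerate(labels)}
    nxt = len(labels)
    for a, b in guide_tree(seqs):
        clusters[nxt] = _align_profiles(clusters.pop(a), clusters.pop(b), p)
        nxt += 1
    (merged,) = clusters.values()
    # restore input row order
    return Alignment({lab: merged[lab] for lab in labels})
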