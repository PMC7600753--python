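"""Species-specific primer enumeration and screening.

The design rule at the heart of the assay: a primer's 3'-terminal base must
sit on an alignment column where the target species differs from every other
species in the panel, so that polymerase extension fails on all non-target
templates. Candidates are enumerated as target-sequence windows whose 3'
terminus lands on such a discriminating position, then screened on length,
GC content, melting temperature, homopolymers and complementarity runs
(self-annealing, hairpin, cross-annealing), and finally combined into
convergent pairs with a bounded product size.

Two melting-temperature models are carried: the Wallace rule 2(A+T)+4(G+C)
for a quick sanity figure, and the SantaLucia 1998 unified nearest-neighbor
model (50 mM monovalent cation, 500 nM oligo) as the screening Tm.
"""

from __future__ import annotations

import functools
import itertools
import logging
from dataclasses import dataclass, field, replace

from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp

from .align import Alignment
from .genomes import reverse_complement

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class Primer:
    """An oriented oligo in 1-based target-gene coordinates.

    ``anchor`` is the 5' end's plus-strand position: for a forward primer the
    leftmost template base it covers; for a reverse primer the rightmost
    (its sequence is the reverse complement of the covered window), which is
    also the last base of any amplicon it closes.
    """

    name: str
    sequence: str
    orientation: str
    anchor: int

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(
                f"designed primers must be unambiguous ACGT: {self.sequence}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def three_prime_position(self) -> int:
        """Plus-strand template position paired with the 3'-terminal base."""
        if self.orientation == "forward":
            return self.anchor + len(self) - 1
        return self.anchor - len(self) + 1


@dataclass(frozen=True)
class PrimerStats:
    length: int
    count_a: int
    count_t: int
    count_c: int
    count_g: int
    gc_percent: float
    tm_wallace: float
    tm_nn: float


@dataclass(frozen=True)
class DesignConstraints:
    """Physical screening thresholds; conventional PCR-design defaults."""

    length_range: tuple[int, int] = (18, 30)
    tm_range: tuple[float, float] = (50.0, 65.0)
    max_pair_tm_diff: float = 3.0
    gc_range: tuple[float, float] = (40.0, 60.0)
    product_range: tuple[int, int] = (100, 600)
    max_homopolymer: int = 5
    max_any_run: int = 7       # complementarity run of >= this+1 fails
    max_three_prime_run: int = 4

    def __post_init__(self) -> None:
        for lo, hi in (self.length_range, self.tm_range, self.gc_range,
                       self.product_range):
            if not lo <= hi:
                raise ValueError("constraint ranges must be ordered")


def primer_stats(seq: str) -> PrimerStats:
    """Exact base counts, GC%, and both oligo Tm models."""
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguity codes not allowed in primers: {seq}")
    a, t, c, g = (seq.count(x) for x in "ATCG")
    return PrimerStats(
        length=len(seq),
        count_a=a, count_t=t, count_c=c, count_g=g,
        gc_percent=100.0 * (g + c) / len(seq),
        tm_wallace=2.0 * (a + t) + 4.0 * (g + c),
        tm_nn=float(MeltingTemp.Tm_NN(Seq(seq), Na=50, dnac1=500, dnac2=0)),
    )


def _max_homopolymer(seq: str) -> int:
    return max(len(list(g)) for _, g in itertools.groupby(seq))


@functools.lru_cache(maxsize=65536)
def _complementary_runs(a: str, b: str) -> tuple[int, int, int]:
    """Longest antiparallel Watson–Crick run between two oligos.

    Returns ``(anywhere, at_a_3prime, at_b_3prime)`` where the 3' variants
    are the longest runs whose paired stretch includes the respective
    oligo's 3'-terminal base. Antiparallel pairing of a against b equals a
    parallel match of a against reverse_complement(b).
    """
    r = reverse_complement(b)
    n, m = len(a), len(r)
    best = a3 = b3 = 0
    for i in range(n):
        for j in range(m):
            if a[i] != r[j]:
                continue
            if i > 0 and j > 0 and a[i - 1] == r[j - 1]:
                continue  # not a run start
            k = 0
            while i + k < n and j + k < m and a[i + k] == r[j + k]:
                k += 1
            best = max(best, k)
            if i + k == n:
                a3 = max(a3, k)
            if j == 0:
                b3 = max(b3, k)
    return best, a3, b3


@functools.lru_cache(maxsize=65536)
def _hairpin_stem(seq: str, min_loop: int = 3) -> int:
    """Longest self-complementary stem closable with a loop >= min_loop."""
    n = len(seq)
    best = 0
    for i in range(n):
        for j in range(n - 1, i, -1):
            k = 0
            while (i + k < j - k - min_loop
                   and seq[i + k] == _COMPLEMENT.get(seq[j - k], "?")):
                k += 1
            best = max(best, k)
    return best


@dataclass(frozen=True)
class InteractionReport:
    self_run_fw: int
    self_run_rev: int
    hairpin_fw: int
    hairpin_rev: int
    cross_run: int
    cross_run_fw3: int
    cross_run_rev3: int
    passed: bool


def check_pair_interactions(
    fw: Primer, rev: Primer,
    constraints: DesignConstraints | None = None,
) -> InteractionReport:
    """Self-annealing, hairpin and cross-annealing screen for a pair."""
    c = constraints or DesignConstraints()
    sf, sf3, _ = _complementary_runs(fw.sequence, fw.sequence)
    sr, sr3, _ = _complementary_runs(rev.sequence, rev.sequence)
    x, xf3, xr3 = _complementary_runs(fw.sequence, rev.sequence)
    hf = _hairpin_stem(fw.sequence)
    hr = _hairpin_stem(rev.sequence)
    passed = (
        max(sf, sr, x, hf, hr) <= c.max_any_run
        and max(sf3, sr3, xf3, xr3) <= c.max_three_prime_run
    )
    return InteractionReport(
        self_run_fw=sf, self_run_rev=sr, hairpin_fw=hf, hairpin_rev=hr,
        cross_run=x, cross_run_fw3=xf3, cross_run_rev3=xr3, passed=passed)


def discriminating_positions(
    aln: Alignment, target: str, quorum: float = 1.0,
) -> list[int]:
    """Ungapped target-gene positions unique to the target species.

    A column qualifies when the target carries a non-gap base there and at
    least a ``quorum`` fraction of the other rows carry a different symbol
    (a gap counts as different — no non-target template can pair there).
    The strict default ``quorum=1.0`` requires difference from ALL others.
    """
    if target not in aln.rows:
        raise ValueError(f"target {target!r} not in alignment")
    if not 0 < quorum <= 1:
        raise ValueError("quorum must be in (0, 1]")
    trow = aln.rows[target]
    others = [r for lab, r in aln.rows.items() if lab != target]
    if not others:
        raise ValueError("alignment must contain non-target rows")
    positions = []
    upos = 0
    for col in range(aln.length):
        tb = trow[col]
        if tb == "-":
            continue
        upos += 1
        differing = sum(1 for r in others if r[col] != tb)
        if differing / len(others) >= quorum:
            positions.append(upos)
    return positions


def enumerate_candidates(
    aln: Alignment, target: str,
    constraints: DesignConstraints | None = None,
    quorum: float = 1.0,
) -> list[Primer]:
    """All screened primer candidates with a discriminating 3' terminus.

    For each discriminating position and admissible length, the forward
    window ends on the position and the reverse window starts on it (its
    reverse complement becomes the primer). Windows failing any physical
    constraint are dropped with a logged reason; an empty list is a valid
    outcome.
    """
    c = constraints or DesignConstraints()
    tseq = aln.degapped(target)
    out: list[Primer] = []
    for pos in discriminating_positions(aln, target, quorum):
        for length in range(c.length_range[0], c.length_range[1] + 1):
            # forward: 5' anchor pos-length+1, 3' terminus on pos
            if pos - length + 1 >= 1:
                window = tseq[pos - length:pos]
                p = _screen(window, "forward", pos - length + 1, pos, c)
                if p:
                    out.append(p)
            # reverse: covers [pos, pos+length-1], 5' anchor at the right end
            if pos + length - 1 <= len(tseq):
                window = tseq[pos - 1:pos + length - 1]
                p = _screen(reverse_complement(window), "reverse",
                            pos + length - 1, pos, c)
                if p:
                    out.append(p)
    out.sort(key=lambda p: (p.three_prime_position, p.orientation,
                            len(p.sequence)))
    return out


def _screen(seq: str, orientation: str, anchor: int, pos: int,
            c: DesignConstraints) -> Primer | None:
    tag = f"{orientation[:3].upper()}{anchor}"
    if set(seq) - set("ACGT"):
        logger.debug("%s: ambiguous bases, dropped", tag)
        return None
    st = primer_stats(seq)
    if not c.gc_range[0] <= st.gc_percent <= c.gc_range[1]:
        logger.debug("%s: GC %.1f outside %s", tag, st.gc_percent, c.gc_range)
        return None
    if not c.tm_range[0] <= st.tm_nn <= c.tm_range[1]:
        logger.debug("%s: Tm_NN %.1f outside %s", tag, st.tm_nn, c.tm_range)
        return None
    if _max_homopolymer(seq) > c.max_homopolymer:
        logger.debug("%s: homopolymer > %d", tag, c.max_homopolymer)
        return None
    primer = Primer(name=tag, sequence=seq, orientation=orientation,
                    anchor=anchor)
    self_run, self3, _ = _complementary_runs(seq, seq)
    if self_run > c.max_any_run or self3 > c.max_three_prime_run:
        logger.debug("%s: self-annealing run %d/%d", tag, self_run, self3)
        return None
    if _hairpin_stem(seq) > c.max_any_run:
        logger.debug("%s: hairpin stem too long", tag)
        return None
    return primer


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    product_size: int
    delta_tm: float
    covered_sites: int = 0
    interactions: InteractionReport | None = field(default=None, compare=False)


def design_pairs(
    candidates: list[Primer],
    constraints: DesignConstraints | None = None,
    discriminating: list[int] | None = None,
) -> list[PrimerPair]:
    """Screened, ranked convergent primer pairs.

    Ranking: more additional discriminating positions inside the amplicon
    (both 3' termini already sit on one each), then smaller |dTm|, then
    product size nearer the midpoint of the allowed range; final tie-break
    on coordinates keeps the order deterministic.
    """
    c = constraints or DesignConstraints()
    sites = discriminating or []
    lo, hi = c.product_range
    mid = (lo + hi) / 2
    tm_nn = {p.sequence: primer_stats(p.sequence).tm_nn for p in candidates}
    pairs: list[PrimerPair] = []
    for fw in candidates:
        if fw.orientation != "forward":
            continue
        for rev in candidates:
            if rev.orientation != "reverse":
                continue
            product = rev.anchor - fw.anchor + 1
            if not lo <= product <= hi:
                continue
            if rev.three_prime_position <= fw.three_prime_position:
                continue  # 3' ends must face each other with a gap between
            dtm = abs(tm_nn[fw.sequence] - tm_nn[rev.sequence])
            if dtm > c.max_pair_tm_diff:
                continue
            inter = check_pair_interactions(fw, rev, c)
            if not inter.passed:
                continue
            covered = sum(
                1 for s in sites
                if fw.three_prime_position < s < rev.three_prime_position)
            pairs.append(PrimerPair(fw, rev, product, dtm, covered, inter))
    pairs.sort(key=lambda pr: (-pr.covered_sites, pr.delta_tm,
                               abs(pr.product_size - mid),
                               pr.forward.anchor, pr.reverse.anchor))
    return pairs


def published_pair(fw_seq: str, rev_seq: str, fw_anchor: int,
                   rev_anchor: int) -> PrimerPair:
    """Wrap an externally designed pair (e.g. from a printed table)."""
    fw = Primer("FW%d" % fw_anchor, fw_seq, "forward", fw_anchor)
    rev = Primer("REV%d" % rev_anchor, rev_seq, "reverse", rev_anchor)
    dtm = abs(primer_stats(fw_seq).tm_nn - primer_stats(rev_seq).tm_nn)
    return PrimerPair(fw, rev, rev_anchor - fw_anchor + 1, dtm, 0,
                      check_pair_interactions(fw, rev))
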