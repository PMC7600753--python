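"""In-silico PCR: primer binding-site search, amplicon prediction, and the
panel specificity matrix.

Binding is modelled as ungapped annealing with a mismatch budget and a
strict 3' clamp: a window is a site when total mismatches stay within
``max_mismatches`` AND the terminal ``clamp`` bases match perfectly —
polymerase extension from a mismatched 3' end is taken as failed, which is
exactly the property the single discriminating 3' base exploits. IUPAC
ambiguity codes in the template count as a match when the primer base is
among the code's expansion.

Amplicon melting temperature uses the salt-adjusted GC formula
``Tm = 81.5 + 16.6 log10([Na+]) + 0.41 GC% - 675/N`` (valid for products of
at least 14 bp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomes import MitoGenome, reverse_complement
from .primers import Primer, PrimerPair

_IUPAC_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}


@dataclass(frozen=True)
class Tolerance:
    """Annealing model knobs: mismatch budget outside a perfect 3' clamp."""

    max_mismatches: int = 2
    clamp: int = 3

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.clamp < 0:
            raise ValueError("tolerance fields must be non-negative")


@dataclass(frozen=True)
class BindingSite:
    genome: str
    strand: str
    start: int   # 1-based inclusive, plus strand
    end: int
    mismatches: int
    three_prime_mismatches: int


@dataclass(frozen=True)
class Amplicon:
    genome: str
    start: int
    end: int
    length: int
    gc_percent: float
    tm_salt_adjusted: float


def _mask(seq: str) -> np.ndarray:
    return np.array([_IUPAC_MASK.get(c, 0) for c in seq.upper()],
                    dtype=np.uint8)


def _scan(primer_mask: np.ndarray, template_mask: np.ndarray) -> np.ndarray:
    """Mismatch count of the primer against every template window.

    Returns an (n_windows, L) boolean mismatch matrix; a primer base
    mismatches when its bit is absent from the template position's mask.
    """
    L = len(primer_mask)
    n = len(template_mask) - L + 1
    if n <= 0:
        return np.zeros((0, L), dtype=bool)
    mm = np.empty((n, L), dtype=bool)
    for k in range(L):
        mm[:, k] = (template_mask[k:k + n] & primer_mask[k]) == 0
    return mm


def find_binding_sites(
    primer: Primer | str,
    seq: str,
    tolerance: Tolerance | None = None,
    circular: bool = False,
    genome_label: str = "",
) -> list[BindingSite]:
    """All annealing sites of a primer on both strands of a template.

    Plus-strand sites are windows equal (within tolerance) to the primer
    read 5'->3' (the primer anneals to the minus strand and extends
    rightward); minus-strand sites are windows equal to its reverse
    complement (extension leftward). For circular templates the window scan
    wraps the origin; wrapped sites report their start position on the
    original coordinates.
    """
    pseq = primer.sequence if isinstance(primer, Primer) else primer.upper()
    tol = tolerance or Tolerance()
    n = len(seq)
    if n < len(pseq):
        return []
    ext = seq + seq[:len(pseq) - 1] if circular else seq
    tmask = _mask(ext)
    L = len(pseq)
    sites: list[BindingSite] = []
    for strand, oriented in (("+", pseq), ("-", reverse_complement(pseq))):
        mm = _scan(_mask(oriented), tmask)
        if strand == "+":
            clamp_cols = slice(L - tol.clamp, L) if tol.clamp else slice(0, 0)
        else:
            clamp_cols = slice(0, tol.clamp) if tol.clamp else slice(0, 0)
        total = mm.sum(axis=1)
        clamp_mm = mm[:, clamp_cols].sum(axis=1)
        ok = np.flatnonzero((clamp_mm == 0) & (total <= tol.max_mismatches))
        for i in ok:
            start = int(i) + 1  # wrapped sites keep end > n by design
            sites.append(BindingSite(
                genome=genome_label, strand=strand,
                start=start, end=start + L - 1,
                mismatches=int(total[i]),
                three_prime_mismatches=int(clamp_mm[i]),
            ))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(
    fw: Primer | str,
    rev: Primer | str,
    seq: str,
    product_range: tuple[int, int] = (100, 600),
    tolerance: Tolerance | None = None,
    circular: bool = False,
    genome_label: str = "",
    na_mM: float = 50.0,
) -> list[Amplicon]:
    """Amplicons from every convergent (forward +, reverse -) site pair."""
    fsites = [s for s in find_binding_sites(fw, seq, tolerance, circular,
                                            genome_label)
              if s.strand == "+"]
    rsites = [s for s in find_binding_sites(rev, seq, tolerance, circular,
                                            genome_label)
              if s.strand == "-"]
    lo, hi = product_range
    out = []
    for fs in fsites:
        for rs in rsites:
            length = rs.end - fs.start + 1
            if not lo <= length <= hi:
                continue
            if rs.start <= fs.end:
                continue  # primers overlap: not a clean convergent pair
            sub = seq[fs.start - 1:rs.end]
            out.append(Amplicon(
                genome=genome_label, start=fs.start, end=rs.end,
                length=length,
                gc_percent=_gc_percent(sub),
                tm_salt_adjusted=amplicon_tm(sub, na_mM),
            ))
    out.sort(key=lambda a: (a.start, a.end))
    return out


def _gc_percent(seq: str) -> float:
    s = seq.upper()
    gc = sum(s.count(b) for b in "GCS")
    return 100.0 * gc / len(s) if s else 0.0


def amplicon_tm(seq: str, na_mM: float = 50.0) -> float:
    """Salt-adjusted GC melting temperature of a long product (>= 14 bp)."""
    if len(seq) < 14:
        raise ValueError("salt-adjusted formula needs length >= 14")
    if na_mM <= 0:
        raise ValueError("Na+ concentration must be positive")
    gc = _gc_percent(seq)
    return (81.5 + 16.6 * math.log10(na_mM / 1000.0)
            + 0.41 * gc - 675.0 / len(seq))


@dataclass
class SpecificityMatrix:
    """Per-genome predicted amplification for one primer pair."""

    table: pd.DataFrame
    target_species: str

    @property
    def amplified(self) -> list[str]:
        return list(self.table.index[self.table["amplified"]])

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df.insert(0, "species", df.index)
        df.to_csv(path, sep="\t", index=False, float_format="%.2f")


def specificity_matrix(
    pair: PrimerPair,
    genomes: list[MitoGenome],
    tolerance: Tolerance | None = None,
    product_range: tuple[int, int] = (100, 600),
    target_species: str = "",
) -> SpecificityMatrix:
    """Predicted amplification of a pair against every genome of a panel."""
    if not genomes:
        raise ValueError("empty genome panel")
    rows = {}
    for g in genomes:
        amps = predict_amplicons(
            pair.forward, pair.reverse, g.sequence, product_range,
            tolerance, circular=g.circular, genome_label=g.species_label)
        first = amps[0] if amps else None
        rows[g.species_label] = {
            "amplified": bool(amps),
            "n_amplicons": len(amps),
            "amplicon_length": first.length if first else 0,
            "amplicon_tm": round(first.tm_salt_adjusted, 2) if first else float("nan"),
            "amplicon_start": first.start if first else 0,
            "amplicon_end": first.end if first else 0,
            "is_target": g.species_label == target_species,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return SpecificityMatrix(table=table, target_species=target_species)
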