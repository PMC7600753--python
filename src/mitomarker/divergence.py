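"""Per-gene divergence statistics and barcoding-marker ranking.

Three statistics are computed on alignment rows:

* Hamming percent — 100 x mismatching columns / compared columns between two
  rows, after a gap policy. Reported per gene as the mean of the target
  species against every other panel member (the marker-discovery view).
* Mean p-distance — the same proportion averaged over all unordered species
  pairs (the panel-wide view).
* Column variability — percent of alignment columns holding more than one
  distinct non-gap symbol, at nucleotide or amino-acid level.

Gap policy default is pairwise deletion: a column where either row is a gap
is excluded from numerator and denominator for that pair. Complete deletion
(drop any column containing a gap in any row) is available. Note p-distance
after gap exclusion is not guaranteed to satisfy the triangle inequality.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .align import Alignment, AlignmentParams, progressive_msa
from .genomes import GenePanel, PROTEIN_CODING_GENES, translate_mt

REPORT_COLUMNS = ("gene", "hamming_vs_target_pct", "mean_p_distance",
                  "nt_variability_pct", "aa_variability_pct")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _compared_columns(a: str, b: str, gap_policy: str):
    if len(a) != len(b):
        raise ValueError("rows must be aligned to equal length")
    if gap_policy not in ("pairwise", "complete"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    return [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]


def hamming_percent(row_a: str, row_b: str, gap_policy: str = "pairwise") -> float:
    """Percent mismatching columns between two aligned rows.

    Under pairwise deletion, columns where either row is a gap are excluded
    from both counts. Returns 0.0 for two all-gap rows (no compared sites).
    """
    pairs = _compared_columns(row_a, row_b, gap_policy)
    if not pairs:
        return 0.0
    mism = sum(1 for x, y in pairs if x != y)
    return 100.0 * mism / len(pairs)


def p_distance(row_a: str, row_b: str, gap_policy: str = "pairwise") -> float:
    """Uncorrected proportion of differing sites (Hamming percent / 100)."""
    return hamming_percent(row_a, row_b, gap_policy) / 100.0


def mean_pairwise_p_distance(aln: Alignment, gap_policy: str = "pairwise") -> float:
    """Mean p-distance over all unordered row pairs of an alignment."""
    rows = list(aln.rows.values())
    if len(rows) < 2:
        raise ValueError("need >= 2 rows")
    dists = [p_distance(a, b, gap_policy)
             for a, b in itertools.combinations(rows, 2)]
    return sum(dists) / len(dists)


def _complete_deletion(rows: list[str]) -> list[str]:
    keep = [i for i in range(len(rows[0]))
            if all(r[i] != "-" for r in rows)]
    return ["".join(r[i] for i in keep) for r in rows]


def column_variability(aln: Alignment, level: str = "nucleotide") -> float:
    """Percent of columns with >= 2 distinct non-gap symbols.

    Denominator: columns holding >= 2 non-gap symbols (a column seen in only
    one row cannot witness variation). ``level='aminoacid'`` expects rows
    that are already aligned translations.
    """
    if level not in ("nucleotide", "aminoacid"):
        raise ValueError(f"unknown level {level!r}")
    rows = list(aln.rows.values())
    if len(rows) < 2:
        raise ValueError("variability needs >= 2 rows")
    comparable = variable = 0
    for i in range(aln.length):
        col = [r[i] for r in rows if r[i] != "-"]
        if len(col) < 2:
            continue
        comparable += 1
        if len(set(col)) > 1:
            variable += 1
    if comparable == 0:
        return 0.0
    return 100.0 * variable / comparable


@dataclass
class DivergenceReport:
    """Per-gene statistics plus the panel-wide distance table."""

    per_gene: pd.DataFrame
    whole_genome: pd.DataFrame
    target_species: str

    def to_tsv(self, path) -> None:
        df = self.per_gene.copy()
        df["hamming_vs_target_pct"] = df["hamming_vs_target_pct"].map(
            lambda v: round_half_up(v, 1))
        df["mean_p_distance"] = df["mean_p_distance"].map(
            lambda v: round_half_up(v, 4))
        df["nt_variability_pct"] = df["nt_variability_pct"].map(
            lambda v: round_half_up(v, 1))
        df["aa_variability_pct"] = df["aa_variability_pct"].map(
            lambda v: "" if pd.isna(v) else round_half_up(v, 1))
        df.to_csv(path, sep="\t", index=False)


def align_panel(panel: GenePanel,
                params: AlignmentParams | None = None) -> Alignment:
    """Multiple-align one gene panel (no-op gap-free if already aligned)."""
    if panel.aligned:
        return Alignment(dict(panel.members))
    return progressive_msa(panel.members, params)


def aa_alignment(panel: GenePanel,
                 params: AlignmentParams | None = None) -> Alignment:
    """Translate panel members (table 2) and align the proteins.

    Protein rows are aligned with the nucleotide scorer applied to residue
    identity (match/mismatch only) — sufficient for the variability count,
    which only asks whether residues differ.
    """
    prots = {lab: translate_mt(seq) for lab, seq in panel.members.items()}
    lens = {len(p) for p in prots.values()}
    if len(lens) == 1:
        return Alignment(prots)
    return progressive_msa(prots, params)


def gene_divergence_report(
    panels: dict[str, GenePanel],
    target: str,
    params: AlignmentParams | None = None,
    gap_policy: str = "pairwise",
    summary: str = "mean",
) -> DivergenceReport:
    """Compute all three statistics for every gene panel.

    ``hamming_vs_target_pct`` summarizes target-vs-others distances with the
    mean (or median via ``summary='median'``). Amino-acid variability is
    computed for protein-coding genes only; rRNA genes get NaN there.
    """
    if summary not in ("mean", "median"):
        raise ValueError(f"unknown summary {summary!r}")
    records = []
    species: list[str] = []
    per_gene_dist: dict[str, dict[tuple[str, str], float]] = {}
    for gene, panel in panels.items():
        if target not in panel.members:
            raise ValueError(f"target {target!r} absent from {gene} panel")
        aln = align_panel(panel, params)
        labels = list(aln.rows)
        species = labels
        dists = {}
        for a, b in itertools.combinations(labels, 2):
            dists[(a, b)] = p_distance(aln.rows[a], aln.rows[b], gap_policy)
        per_gene_dist[gene] = dists

        vs_target = [100.0 * d for (a, b), d in dists.items()
                     if target in (a, b)]
        if summary == "mean":
            ham = sum(vs_target) / len(vs_target)
        else:
            vs = sorted(vs_target)
            mid = len(vs) // 2
            ham = vs[mid] if len(vs) % 2 else (vs[mid - 1] + vs[mid]) / 2
        mean_p = sum(dists.values()) / len(dists)
        nt_var = column_variability(aln, "nucleotide")
        if gene in PROTEIN_CODING_GENES:
            aa_var = column_variability(aa_alignment(panel, params),
                                        "aminoacid")
        else:
            aa_var = float("nan")
        records.append((gene, ham, mean_p, nt_var, aa_var))

    per_gene = pd.DataFrame.from_records(records, columns=REPORT_COLUMNS)

    # Whole-genome distance: length-weighted over the concatenated per-gene
    # alignments (avoids one quadratic 16.5 kb alignment and the
    # hypervariable control region).
    wg = pd.DataFrame(0.0, index=species, columns=species)
    total_len = {pair: 0 for pair in itertools.combinations(species, 2)}
    mism = {pair: 0.0 for pair in total_len}
    for gene, panel in panels.items():
        glen = max(len(s) for s in panel.members.values())
        for pair, d in per_gene_dist[gene].items():
            mism[pair] += d * glen
            total_len[pair] += glen
    for (a, b), m in mism.items():
        val = 100.0 * m / total_len[(a, b)] if total_len[(a, b)] else 0.0
        wg.loc[a, b] = wg.loc[b, a] = val
    return DivergenceReport(per_gene=per_gene, whole_genome=wg,
                            target_species=target)


def rank_genes(report: DivergenceReport, by: str = "hamming_vs_target_pct") -> list[str]:
    """Genes in descending order of a report column; ties alphabetical."""
    if by not in REPORT_COLUMNS[1:]:
        raise ValueError(f"unknown column {by!r}")
    df = report.per_gene
    ordered = df.sort_values(by=[by, "gene"], ascending=[False, True],
                             kind="mergesort")
    return list(ordered["gene"])
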