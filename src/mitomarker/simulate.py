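"""Synthetic mitogenome panels with known divergence truth.

The generator emulates a panel of same-length orthologous mitochondrial
genes under a star phylogeny: one ancestral genome drawn uniformly over
ACGT, each species derived by independent per-site substitution (the
substituted base uniform over the three alternatives). Two refinements make
the synthetic panel behave like real interspecific data:

* a per-gene *target branch rate* distinct from the background rate, so the
  target-vs-rest distance summary and the all-pairs mean can rank genes
  differently (as they do in real panels);
* a per-gene *variable-site fraction* (rate hotspots): substitutions are
  confined to a random subset of sites, with the conditional rate scaled up
  to preserve pairwise distances. Without it, independent mutation at
  realistic interspecific rates would make ~90% of columns variable across
  16 taxa, far above what shared phylogeny produces in real alignments.

Engineered species-unique sites provide ground truth for the
3'-discriminating-base design rule, and :func:`study_panel` builds the
16-species sparid-like panel (real teleost gene lengths, per-gene rates
solved from the published summary statistics, the published primer
footprints carried on the target's NAD2) on which the whole workflow is
exercised without any sequence download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genomes import GeneFeature, MitoGenome, reverse_complement

_BASES = np.array(list("ACGT"))

#: Canonical vertebrate mitochondrial gene order (NAD6 on the minus strand).
GENE_ORDER = ("12S", "16S", "NAD1", "NAD2", "COI", "COII", "ATP8", "ATP6",
              "COIII", "NAD3", "NAD4L", "NAD4", "NAD5", "NAD6", "Cytb")
MINUS_STRAND_GENES = frozenset({"NAD6"})

#: Typical teleost mitochondrial gene lengths (bp); protein-coding lengths
#: are multiples of three.
TELEOST_GENE_LENGTHS = {
    "12S": 954, "16S": 1686, "NAD1": 975, "NAD2": 1047, "COI": 1551,
    "COII": 690, "ATP8": 168, "ATP6": 684, "COIII": 786, "NAD3": 351,
    "NAD4L": 297, "NAD4": 1383, "NAD5": 1839, "NAD6": 522, "Cytb": 1140,
}

SPACER = 30  # conserved inter-genic spacer, bp


@dataclass(frozen=True)
class GeneRates:
    """Per-gene substitution model: background and target branch rates are
    unconditional per-site probabilities; mutations are confined to a
    ``variable_fraction`` of sites (conditional rate = rate / fraction)."""

    background: float
    target: float
    variable_fraction: float = 1.0

    def __post_init__(self) -> None:
        for r in (self.background / self.variable_fraction,
                  self.target / self.variable_fraction):
            if not 0 <= r <= 0.75:
                raise ValueError(
                    "conditional substitution rate outside [0, 0.75]")
        if not 0 < self.variable_fraction <= 1:
            raise ValueError("variable_fraction must be in (0, 1]")


@dataclass
class SimulationSpec:
    n_species: int
    gene_lengths: dict[str, int]
    rates: dict[str, GeneRates]
    target_species: str
    seed: int
    species_labels: list[str] | None = None
    engineered_sites: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for gene, length in self.gene_lengths.items():
            if gene not in ("12S", "16S") and length % 3:
                raise ValueError(f"{gene} length must be a multiple of 3")
            if gene not in self.rates:
                raise ValueError(f"no rates for gene {gene}")
        if self.species_labels is not None:
            if len(self.species_labels) != self.n_species:
                raise ValueError("species_labels length != n_species")
            if len(set(self.species_labels)) != self.n_species:
                raise ValueError("duplicate species labels")

    @property
    def labels(self) -> list[str]:
        if self.species_labels:
            return list(self.species_labels)
        pad = len(str(self.n_species))
        return [f"species_{i + 1:0{pad}d}" for i in range(self.n_species)]


@dataclass
class PanelTruth:
    """Replayable ground truth of a simulated panel."""

    ancestral_genes: dict[str, str]
    mutated_positions: dict[str, dict[str, list[int]]]  # gene -> label -> 1-based
    variable_sites: dict[str, list[int]]
    engineered: list[tuple[str, int]] = field(default_factory=list)
    rates: dict[str, GeneRates] = field(default_factory=dict)

    def expected_pairwise_p(self, gene: str) -> float:
        """Expected p-distance between two non-target species."""
        r = self.rates[gene]
        d, v = r.background, r.variable_fraction
        return 2 * d - (4.0 / 3.0) * d * d / v

    def expected_target_p(self, gene: str) -> float:
        """Expected p-distance between the target and a non-target."""
        r = self.rates[gene]
        return (r.target + r.background
                - (4.0 / 3.0) * r.target * r.background / r.variable_fraction)


def solve_rates(target_vs_rest: float, mean_pairwise: float,
                variable_fraction: float, n_species: int) -> GeneRates:
    """Invert the two published distance summaries into branch rates.

    Under the star phylogeny, the expected p-distance between species with
    branch rates a and b, hotspot fraction v, is ``a + b - (4/3)ab/v``
    (both mutated at a shared hot site agree with probability 1/3). Given a
    gene's expected target-vs-rest distance h and all-pairs mean p, with
    n-1 target pairs among n(n-1)/2 total, the background rate d solves
    ``2d - (4/3)d^2/v = q`` where q is the implied non-target pair mean,
    and the target rate follows. Raises when the pair of summaries is not
    attainable under the model.
    """
    n = n_species
    npairs = n * (n - 1) // 2
    q = (npairs * mean_pairwise - (n - 1) * target_vs_rest) / (npairs - (n - 1))
    v = variable_fraction
    disc = 4 - 16 * q / (3 * v)
    if disc < 0:
        raise ValueError(
            f"summaries unattainable: non-target mean {q:.3f} exceeds "
            f"saturation {3 * v / 4:.3f} for variable fraction {v}")
    d = (3 * v / 8) * (2 - math.sqrt(disc))
    t = (target_vs_rest - d) / (1 - (4.0 / 3.0) * d / v)
    if t < 0:
        raise ValueError("summaries imply a negative target branch rate")
    return GeneRates(background=d, target=t, variable_fraction=v)


def _mutate(gene_arr: np.ndarray, hot: np.ndarray, rate_conditional: float,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Substitute hot sites i.i.d.; returns (mutated copy, hit positions)."""
    out = gene_arr.copy()
    hits = hot[rng.random(hot.size) < rate_conditional]
    for pos in hits:
        alternatives = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return out, hits


def simulate_panel(spec: SimulationSpec) -> tuple[list[MitoGenome], PanelTruth]:
    """Draw a full annotated panel plus its replayable truth.

    Genes are laid out in the canonical vertebrate order (those present in
    the spec), separated by conserved spacers; NAD6 is written on the minus
    strand. Identical specs give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    order = [g for g in GENE_ORDER if g in spec.gene_lengths]
    order += [g for g in spec.gene_lengths if g not in GENE_ORDER]

    ancestral: dict[str, str] = {}
    hot_sites: dict[str, np.ndarray] = {}
    for gene in order:
        L = spec.gene_lengths[gene]
        ancestral[gene] = "".join(rng.choice(_BASES, size=L))
        v = spec.rates[gene].variable_fraction
        n_hot = max(1, round(v * L))
        hot_sites[gene] = np.sort(
            rng.choice(L, size=n_hot, replace=False))

    labels = spec.labels
    per_species_genes: dict[str, dict[str, np.ndarray]] = {}
    mutated: dict[str, dict[str, list[int]]] = {g: {} for g in order}
    for label in labels:
        is_target = label == spec.target_species
        genes: dict[str, np.ndarray] = {}
        for gene in order:
            r = spec.rates[gene]
            rate = (r.target if is_target else r.background)
            cond = rate / r.variable_fraction
            arr = np.array(list(ancestral[gene]))
            arr, hits = _mutate(arr, hot_sites[gene], cond, rng)
            genes[gene] = arr
            mutated[gene][label] = [int(p) + 1 for p in sorted(hits)]
        per_species_genes[label] = genes

    truth = PanelTruth(
        ancestral_genes=ancestral,
        mutated_positions=mutated,
        variable_sites={g: [int(p) + 1 for p in hot_sites[g]] for g in order},
        rates=dict(spec.rates),
    )
    genomes = _assemble(spec, order, per_species_genes, rng)
    for gene, pos in spec.engineered_sites:
        implant_discriminating_site(genomes, gene, pos, spec.target_species,
                                    truth)
    return genomes, truth


def _assemble(spec, order, per_species_genes, rng) -> list[MitoGenome]:
    spacer = "".join(rng.choice(_BASES, size=SPACER))
    genomes = []
    for i, label in enumerate(spec.labels):
        parts: list[str] = []
        features: list[GeneFeature] = []
        pos = 1
        for gene in order:
            parts.append(spacer)
            pos += SPACER
            seq = "".join(per_species_genes[label][gene])
            strand = "-" if gene in MINUS_STRAND_GENES else "+"
            if strand == "-":
                seq = reverse_complement(seq)
            parts.append(seq)
            features.append(GeneFeature(gene, pos, pos + len(seq) - 1, strand))
            pos += len(seq)
        genomes.append(MitoGenome(
            species_label=label,
            accession=f"SYN_{spec.seed}_{i + 1:02d}",
            sequence="".join(parts),
            features=features,
            circular=True,
        ))
    return genomes


def _gene_site(genome: MitoGenome, gene: str, position: int) -> tuple[int, bool]:
    """Genome coordinate (0-based) of a 1-based gene-oriented position."""
    f = genome.feature(gene)
    length = f.end - f.start + 1
    if not 1 <= position <= length:
        raise ValueError(f"position {position} outside {gene} (1..{length})")
    if f.strand == "+":
        return f.start - 1 + position - 1, False
    return f.end - 1 - (position - 1), True


def implant_discriminating_site(
    genomes: list[MitoGenome], gene: str, position: int, target: str,
    truth: PanelTruth | None = None,
) -> list[MitoGenome]:
    """Force one gene position to be unique to the target species.

    The target keeps its current base; every other species is set to a
    common base different from the target's (the next base in ACGT order),
    so the strict all-species discriminating rule holds by construction.
    Idempotent: re-implanting an already discriminating site changes
    nothing but the truth registry de-duplicates it anyway.
    """
    target_genome = next(g for g in genomes if g.species_label == target)
    idx, flipped = _gene_site(target_genome, gene, position)
    tbase = target_genome.sequence[idx]
    gene_base = reverse_complement(tbase) if flipped else tbase
    alt = "ACGT"[("ACGT".index(gene_base) + 1) % 4]
    for g in genomes:
        if g.species_label == target:
            continue
        i, flip = _gene_site(g, gene, position)
        base = reverse_complement(alt) if flip else alt
        g.sequence = g.sequence[:i] + base + g.sequence[i + 1:]
    if truth is not None and (gene, position) not in truth.engineered:
        truth.engineered.append((gene, position))
    return genomes


def overwrite_gene_segment(genome: MitoGenome, gene: str, start: int,
                           segment: str) -> None:
    """Write ``segment`` into a gene at 1-based gene-oriented ``start``."""
    f = genome.feature(gene)
    if f.strand == "-":
        idx, _ = _gene_site(genome, gene, start + len(segment) - 1)
        piece = reverse_complement(segment)
    else:
        idx, _ = _gene_site(genome, gene, start)
        piece = segment
    genome.sequence = (genome.sequence[:idx] + piece
                       + genome.sequence[idx + len(piece):])


# ---------------------------------------------------------------------------
# Ready-made panels

FIXTURE_SEED = 20200917

#: Published sparid panel: species of the 16 analyzed mitogenomes.
SPARID_SPECIES = (
    "Acanthopagrus latus", "Acanthopagrus schlegelii", "Dentex angolensis",
    "Dentex dentex", "Dentex gibbosus", "Dentex tumifrons",
    "Diplodus puntazzo", "Pagellus acarne", "Pagellus bogaraveo",
    "Pagellus erythrinus", "Pagrus auriga", "Pagrus caeruleostictus",
    "Pagrus major", "Parargyrops edita", "Rhabdosargus sarba",
    "Sparus aurata",
)
TARGET_SPECIES = "Pagellus erythrinus"

#: Published per-gene summaries: (target-vs-rest Hamming proportion,
#: all-pairs mean p-distance, variable-column fraction). The five NAD/ATP6
#: values and the COI/Cytb means are the printed figures; the remaining
#: entries are plausible interpolations consistent with the printed
#: rankings (COI lowest on variability, rRNAs most conserved on distance).
STUDY_GENE_SUMMARIES: dict[str, tuple[float, float, float]] = {
    "NAD1": (0.20, 0.205, 0.39),
    "NAD2": (0.24, 0.25, 0.50),
    "NAD3": (0.19, 0.20, 0.39),
    "NAD4L": (0.20, 0.20, 0.39),
    "NAD4": (0.24, 0.23, 0.43),
    "NAD5": (0.23, 0.24, 0.41),
    "NAD6": (0.24, 0.21, 0.44),
    "ATP6": (0.25, 0.22, 0.38),
    "ATP8": (0.22, 0.20, 0.36),
    "COI": (0.13, 0.16, 0.24),
    "COII": (0.15, 0.17, 0.28),
    "COIII": (0.15, 0.17, 0.28),
    "Cytb": (0.16, 0.19, 0.30),
    "12S": (0.10, 0.11, 0.27),
    "16S": (0.12, 0.13, 0.28),
}

#: Published NAD2 assay geometry: forward window 303-324, reverse 568-593.
FW303 = "CCTGGCCCTAAAAATTGGTCTA"
REV593 = "GAGGGAGAGAATTGTAGAACAAGGAC"
FW_ANCHOR, REV_ANCHOR = 303, 593
FW_3PRIME_SITE, REV_3PRIME_SITE = 324, 568


def study_spec(seed: int = FIXTURE_SEED) -> SimulationSpec:
    """The 16-species sparid-like study panel specification."""
    rates = {
        gene: solve_rates(h, p, v, n_species=16)
        for gene, (h, p, v) in STUDY_GENE_SUMMARIES.items()
    }
    return SimulationSpec(
        n_species=16,
        gene_lengths=dict(TELEOST_GENE_LENGTHS),
        rates=rates,
        target_species=TARGET_SPECIES,
        seed=seed,
        species_labels=list(SPARID_SPECIES),
        engineered_sites=[("NAD2", FW_3PRIME_SITE), ("NAD2", REV_3PRIME_SITE)],
    )


def study_panel(seed: int = FIXTURE_SEED) -> tuple[list[MitoGenome], PanelTruth]:
    """Simulate the study panel and carry the published assay geometry.

    The ancestral NAD2 carries the published primer footprints at their
    printed coordinates; the target species keeps them unmutated (so the
    designed windows equal the published oligos exactly) while non-target
    species diverge from them at the gene's background rate. The two
    3'-terminal positions are engineered species-unique after the
    overwrite, preserving the target's printed bases.
    """
    spec = study_spec(seed)
    spec.engineered_sites = []  # implant after footprints are in place
    genomes, truth = simulate_panel(spec)

    fw_anc = FW303
    rev_anc_plus = reverse_complement(REV593)
    # write footprints into the ancestor-derived sequences: non-targets get
    # the footprint with their own realized NAD2 substitutions re-applied
    for g in genomes:
        overwrite_gene_segment(g, "NAD2", FW_ANCHOR, fw_anc)
        overwrite_gene_segment(g, "NAD2", REV_3PRIME_SITE, rev_anc_plus)
    rng = np.random.default_rng(spec.seed + 1)
    # within the footprint the target is pinned to the printed oligos, so a
    # non-target site differs from the target iff its own copy mutated: use
    # the combined target-vs-rest rate to keep the footprint as diverged as
    # the rest of the gene
    cond = (truth.expected_target_p("NAD2")
            / truth.rates["NAD2"].variable_fraction)
    hot = set(truth.variable_sites["NAD2"])
    for g in genomes:
        if g.species_label == spec.target_species:
            continue
        for gene_pos in list(range(FW_ANCHOR, FW_3PRIME_SITE + 1)) + list(
                range(REV_3PRIME_SITE, REV_ANCHOR + 1)):
            if gene_pos in hot and rng.random() < cond:
                idx, flip = _gene_site(g, "NAD2", gene_pos)
                cur = g.sequence[idx]
                alt = rng.choice([b for b in "ACGT" if b != cur])
                g.sequence = g.sequence[:idx] + alt + g.sequence[idx + 1:]
    for site in (FW_3PRIME_SITE, REV_3PRIME_SITE):
        implant_discriminating_site(genomes, "NAD2", site,
                                    spec.target_species, truth)
    truth.ancestral_genes["NAD2"] = (
        truth.ancestral_genes["NAD2"][:FW_ANCHOR - 1] + fw_anc
        + truth.ancestral_genes["NAD2"][FW_3PRIME_SITE:REV_3PRIME_SITE - 1]
        + rev_anc_plus + truth.ancestral_genes["NAD2"][REV_ANCHOR:])
    return genomes, truth


def fixture_genomes() -> tuple[list[MitoGenome], PanelTruth]:
    """Small deterministic 4-species, 3-gene (~2 kb) panel for fast tests
    and documentation examples."""
    spec = SimulationSpec(
        n_species=4,
        gene_lengths={"NAD2": 522, "COI": 600, "12S": 402},
        rates={
            "NAD2": GeneRates(0.10, 0.12, 0.5),
            "COI": GeneRates(0.05, 0.05, 0.4),
            "12S": GeneRates(0.03, 0.03, 0.4),
        },
        target_species="species_2",
        seed=FIXTURE_SEED,
        engineered_sites=[("NAD2", 120), ("NAD2", 400)],
    )
    return simulate_panel(spec)
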