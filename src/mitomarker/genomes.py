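"""Annotated mitochondrial genome I/O and gene extraction.

Reads GenBank flat files or FASTA, normalizes the notoriously inconsistent
gene nomenclature of mitochondrial annotations (ND2/NAD2/nad2, COX1/CO1/COI,
COB/CYTB, ...), extracts strand-resolved orthologous gene sequences, and
translates protein-coding genes under the vertebrate mitochondrial code
(NCBI translation table 2).

Coordinates are 1-based inclusive throughout the public surface; features on
the minus strand are reverse-complemented on extraction, and features may
wrap the origin of a circular molecule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 13 vertebrate mitochondrial protein-coding genes.
PROTEIN_CODING_GENES = (
    "NAD1", "NAD2", "NAD3", "NAD4", "NAD4L", "NAD5", "NAD6",
    "COI", "COII", "COIII", "ATP6", "ATP8", "Cytb",
)
#: Genes entering gene-by-gene divergence analyses: 13 PCGs + the two rRNAs.
ANALYSIS_GENES = PROTEIN_CODING_GENES + ("12S", "16S")

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

# Synonym table for annotation labels -> canonical names. Keys lowercase,
# punctuation stripped. Covers the spellings seen across GenBank submissions.
_SYNONYMS: dict[str, str] = {}
for canonical, raws in {
    "NAD1": ["nad1", "nd1", "nadh1", "nadhdehydrogenasesubunit1"],
    "NAD2": ["nad2", "nd2", "nadh2", "nadhdehydrogenasesubunit2"],
    "NAD3": ["nad3", "nd3", "nadh3", "nadhdehydrogenasesubunit3"],
    "NAD4": ["nad4", "nd4", "nadh4", "nadhdehydrogenasesubunit4"],
    "NAD4L": ["nad4l", "nd4l", "nadh4l", "nadhdehydrogenasesubunit4l"],
    "NAD5": ["nad5", "nd5", "nadh5", "nadhdehydrogenasesubunit5"],
    "NAD6": ["nad6", "nd6", "nadh6", "nadhdehydrogenasesubunit6"],
    "COI": ["coi", "co1", "cox1", "coxi", "cytochromecoxidasesubunit1",
            "cytochromecoxidasesubuniti"],
    "COII": ["coii", "co2", "cox2", "coxii", "cytochromecoxidasesubunit2",
             "cytochromecoxidasesubunitii"],
    "COIII": ["coiii", "co3", "cox3", "coxiii", "cytochromecoxidasesubunit3",
              "cytochromecoxidasesubunitiii"],
    "ATP6": ["atp6", "atpase6", "atpsynthasef0subunit6", "atpsynthase6"],
    "ATP8": ["atp8", "atpase8", "atpsynthasef0subunit8", "atpsynthase8"],
    "Cytb": ["cytb", "cob", "cytochromeb", "cytochromebapoenzyme"],
    "12S": ["12s", "rrns", "12srrna", "12sribosomalrna", "srrna",
            "smallsubunitribosomalrna"],
    "16S": ["16s", "rrnl", "16srrna", "16sribosomalrna", "lrrna",
            "largesubunitribosomalrna"],
}.items():
    for raw in raws:
        _SYNONYMS[raw] = canonical


def normalize_gene_name(raw: str) -> tuple[str, bool]:
    """Map an annotation label to its canonical gene name.

    Returns ``(canonical_name, known)``. Unknown labels are returned
    unchanged with ``known=False`` — never an error, because a panel may
    carry features outside the analysis set.
    """
    if not raw:
        raise ValueError("empty gene label")
    key = "".join(ch for ch in raw.lower() if ch.isalnum())
    if key in _SYNONYMS:
        return _SYNONYMS[key], True
    logger.debug("unknown gene label %r left unchanged", raw)
    return raw, False


@dataclass(frozen=True)
class GeneFeature:
    """A located gene on a mitogenome. 1-based inclusive coordinates;
    ``start > end`` only for features wrapping the origin of a circular
    molecule."""

    name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError("coordinates are 1-based and positive")


@dataclass
class MitoGenome:
    """An annotated (possibly circular) mitochondrial genome."""

    species_label: str
    accession: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession}")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"non-IUPAC characters {sorted(bad)} in {self.accession}")
        n = len(self.sequence)
        for f in self.features:
            if f.start > n or f.end > n:
                raise ValueError(
                    f"feature {f.name} [{f.start},{f.end}] outside 1..{n}")
            if f.start > f.end and not self.circular:
                raise ValueError(
                    f"feature {f.name} wraps origin of a linear genome")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(
            f"genome {self.accession} ({self.species_label}) has no "
            f"feature named {name!r}")


@dataclass
class GenePanel:
    """One orthologous gene across a species panel, raw or aligned."""

    gene: str
    members: dict[str, str]
    aligned: bool = False

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a panel needs at least 2 members")
        if self.aligned:
            lens = {len(s) for s in self.members.values()}
            if len(lens) != 1:
                raise ValueError("aligned panel rows must be equal length")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_gene(genome: MitoGenome, name: str) -> str:
    """Plus-strand-oriented sequence of a named gene.

    Minus-strand features are reverse-complemented; features wrapping the
    origin of a circular genome are stitched tail+head.
    """
    f = genome.feature(name)
    if f.start <= f.end:
        sub = genome.sequence[f.start - 1:f.end]
    else:  # origin wrap
        sub = genome.sequence[f.start - 1:] + genome.sequence[:f.end]
    return reverse_complement(sub) if f.strand == "-" else sub


def translate_mt(nt: str) -> str:
    """Translate under the vertebrate mitochondrial code (table 2).

    A trailing partial codon is truncated (and logged); internal stops
    render as ``*``.
    """
    nt = nt.upper()
    bad = set(nt) - IUPAC_DNA
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    if len(nt) % 3:
        logger.info("truncating %d trailing bases before translation",
                    len(nt) % 3)
        nt = nt[:len(nt) - len(nt) % 3]
    return str(Seq(nt).translate(table=2))


def read_genbank(path: str | Path) -> MitoGenome:
    """Read one GenBank record into a :class:`MitoGenome`.

    Gene names are taken from gene/CDS/rRNA features (gene qualifier first,
    then product) and normalized; a record without gene features yields an
    empty feature list with a warning, not an error.
    """
    path = Path(path)
    try:
        record = SeqIO.read(path, "genbank")
    except Exception as exc:  # noqa: BLE001 - rewrap with path context
        raise ValueError(f"cannot read GenBank file {path}: {exc}") from exc
    if not record.seq:
        raise ValueError(f"empty sequence in GenBank file {path}")

    features: list[GeneFeature] = []
    seen: set[tuple[str, int, int]] = set()
    for feat in record.features:
        if feat.type not in ("gene", "CDS", "rRNA"):
            continue
        labels = feat.qualifiers.get("gene") or feat.qualifiers.get("product")
        if not labels:
            continue
        name, _known = normalize_gene_name(labels[0])
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        key = (name, start, end)
        if key in seen:  # gene + CDS pair for the same locus
            continue
        seen.add(key)
        strand = "-" if feat.location.strand == -1 else "+"
        features.append(GeneFeature(name, start, end, strand))
    if not features:
        logger.warning("no gene features found in %s", path)

    topology = record.annotations.get("topology", "circular")
    return MitoGenome(
        species_label=record.annotations.get("organism", record.id),
        accession=record.id,
        sequence=str(record.seq),
        features=features,
        circular=topology == "circular",
    )


def write_genbank(genome: MitoGenome, path: str | Path) -> None:
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession,
        name=genome.accession.replace(".", "_")[:16],
        description=f"{genome.species_label} mitochondrion",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "organism": genome.species_label,
        },
    )
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        loc = FeatureLocation(f.start - 1, f.end, strand=strand)
        record.features.append(
            SeqFeature(loc, type="gene", qualifiers={"gene": [f.name]}))
    SeqIO.write([record], str(path), "genbank")


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    """Write labelled sequences as FASTA, 70-column wrapped."""
    with open(path, "w") as fh:
        for label, seq in seqs.items():
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def gene_panels(
    genomes: list[MitoGenome],
    genes: tuple[str, ...] = ANALYSIS_GENES,
) -> dict[str, GenePanel]:
    """Per-gene orthologous sequence panels over a genome set.

    Genes absent from one or more genomes are skipped with a warning so a
    ragged panel never silently biases downstream statistics.
    """
    labels = [g.species_label for g in genomes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species labels in panel")
    panels: dict[str, GenePanel] = {}
    for gene in genes:
        members: dict[str, str] = {}
        for g in genomes:
            try:
                members[g.species_label] = extract_gene(g, gene)
            except KeyError:
                logger.warning("%s missing from %s; gene skipped from panel",
                               gene, g.accession)
                members = {}
                break
        if members:
            panels[gene] = GenePanel(gene=gene, members=members)
    return panels
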