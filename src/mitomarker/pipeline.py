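"""End-to-end workflow: extract -> align -> divergence -> design -> in-silico
PCR -> report, as one reproducible function over a run configuration.

Every output is a pure function of (inputs, config, seed): tabular outputs
are TSV with one header line, a JSON mirror and a run manifest (config copy
and file checksums) are written next to them, so a rerun with the same
config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .align import AlignmentParams
from .divergence import gene_divergence_report, rank_genes, align_panel
from .genomes import MitoGenome, gene_panels, read_genbank, write_fasta
from .ispcr import Tolerance, specificity_matrix
from .primers import (DesignConstraints, design_pairs,
                      discriminating_positions, enumerate_candidates,
                      primer_stats)
from .reporting import virtual_gel, write_json

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_paths: list[str]
    output_dir: str
    target_species: str
    marker_gene: str | None = None  # None: take the top-ranked gene
    genes: tuple[str, ...] | None = None
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    constraints: DesignConstraints = field(default_factory=DesignConstraints)
    tolerance: Tolerance = field(default_factory=Tolerance)
    gap_policy: str = "pairwise"
    rank_by: str = "mean_p_distance"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig,
                 genomes: list[MitoGenome] | None = None) -> dict:
    """Run the whole workflow; returns a manifest of produced artifacts.

    ``genomes`` may be passed directly (e.g. a simulated panel); otherwise
    ``config.input_paths`` are read as GenBank files. Any stage failure
    raises with the stage named in the log.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if genomes is None:
        logger.info("stage=ingest reading %d files", len(config.input_paths))
        if not config.input_paths:
            raise ValueError("config.input_paths is empty and no genomes given")
        genomes = [read_genbank(p) for p in config.input_paths]

    logger.info("stage=extract building gene panels")
    panels = (gene_panels(genomes, config.genes) if config.genes
              else gene_panels(genomes))
    for gene, panel in panels.items():
        write_fasta(panel.members, out / f"gene_{gene}.fasta")

    logger.info("stage=divergence computing per-gene statistics")
    report = gene_divergence_report(panels, config.target_species,
                                    config.alignment, config.gap_policy)
    report.to_tsv(out / "divergence.tsv")
    ranking = rank_genes(report, by=config.rank_by)
    (out / "ranked_markers.tsv").write_text(
        "rank\tgene\n" + "".join(f"{i}\t{g}\n"
                                 for i, g in enumerate(ranking, 1)))

    marker = config.marker_gene or ranking[0]
    logger.info("stage=design marker gene %s", marker)
    aln = align_panel(panels[marker], config.alignment)
    sites = discriminating_positions(aln, config.target_species)
    candidates = enumerate_candidates(aln, config.target_species,
                                      config.constraints)
    pairs = design_pairs(candidates, config.constraints, sites)
    with open(out / "primers.tsv", "w") as fh:
        fh.write("pair\trole\tname\tsequence\tanchor\tlength\tgc_percent"
                 "\ttm_wallace\ttm_nn\tproduct_bp\n")
        for i, pr in enumerate(pairs, 1):
            for role, p in (("forward", pr.forward), ("reverse", pr.reverse)):
                st = primer_stats(p.sequence)
                fh.write(f"{i}\t{role}\t{p.name}\t{p.sequence}\t{p.anchor}"
                         f"\t{st.length}\t{st.gc_percent:.1f}"
                         f"\t{st.tm_wallace:.1f}\t{st.tm_nn:.1f}"
                         f"\t{pr.product_size}\n")
    write_fasta(
        {f"pair{i}_{p.name}": p.sequence
         for i, pr in enumerate(pairs, 1)
         for p in (pr.forward, pr.reverse)},
        out / "primers.fasta",
    )

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "marker_gene": marker,
        "n_discriminating_positions": len(sites),
        "n_candidate_primers": len(candidates),
        "n_pairs": len(pairs),
    }

    if pairs:
        logger.info("stage=ispcr screening best pair against the panel")
        best = pairs[0]
        matrix = specificity_matrix(
            best, genomes, config.tolerance,
            config.constraints.product_range, config.target_species)
        matrix.to_tsv(out / "specificity.tsv")
        (out / "virtual_gel.txt").write_text(virtual_gel(matrix))
        manifest["amplified_species"] = matrix.amplified
    else:
        logger.warning("stage=ispcr skipped: no admissible pairs")

    manifest["checksums"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir())
        if p.suffix in (".tsv", ".fasta", ".txt")
    }
    write_json(manifest, out / "run_manifest.json")
    logger.info("stage=done artifacts in %s", out)
    return manifest
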