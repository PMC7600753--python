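# Methods

## Problem setting

Given a panel of complete, annotated mitochondrial genomes — one per
species, one designated the *target* — the package (1) ranks the 13
protein-coding genes plus the two rRNAs by interspecific divergence to
nominate a barcoding marker, (2) designs primer pairs on that marker whose
3′-terminal bases fall on positions unique to the target species, and (3)
predicts, by in-silico PCR, which panel species the pair would amplify. The
control region is excluded from gene-by-gene analyses (hypervariable,
alignment-hostile, and not a practical assay substrate); tRNAs are ignored.

## Divergence statistics

All distances are computed on rows of a multiple alignment, never on
unaligned sequences of unequal length (on raw sequences "Hamming distance"
is ill-defined). Default gap policy is **pairwise deletion**: a column where
either row of the compared pair carries a gap is excluded from both
numerator and denominator; complete deletion is available as an option.

- *Hamming percent* between two rows: `100 · mismatches / compared sites`.
- *p-distance*: the same quantity as a proportion. The per-gene panel
  statistic is the mean over all unordered pairs; the target-vs-rest
  summary is the mean over the n−1 pairs involving the target (median
  optional).
- *Column variability*: `100 · (columns with ≥ 2 distinct non-gap symbols)
  / (columns with ≥ 2 non-gap symbols)`. Amino-acid variability applies the
  same count to translated rows (NCBI table 2 — the panel species are
  teleost fish; a trailing partial codon is truncated, internal stops
  render `*`).
- Whole-genome distances are length-weighted means over the per-gene
  alignments (concatenation), not one ~16.5 kb global alignment: quadratic
  cost and control-region hypervariability argue against the literal
  variant, and per-gene concatenation is the standard practice.

p-distance under pairwise deletion is not guaranteed metric (the triangle
inequality may fail across different deletion masks); nothing downstream
relies on metricity. Reported percentages are rounded half-up at
presentation (1 decimal in TSVs); internal values stay unrounded.

## Alignment

Pairwise: optimal global Needleman–Wunsch with affine gaps (Gotoh's
three-state recurrence). A gap run of length L costs
`gap_open + (L−1)·gap_extend`. Defaults, EDNAFULL-like: match +5,
mismatch −4, gap_open 10, gap_extend 0.5. The horizontal-gap state is
solved exactly with a prefix-max scan so rows vectorize in numpy; traceback
ties break diagonal → up → left, making outputs reproducible. Ambiguity
codes score as mismatch against everything.

Multiple: progressive profile–profile alignment along a UPGMA guide tree
built on 6-mer cosine distances (scipy average linkage). Profile columns
are frequency vectors over {A,C,G,T,other,gap}; the column score is the
frequency-weighted mean pair score, gap symbols scoring 0 so gap placement
is priced only by the affine penalties. Two sequences reduce exactly to the
pairwise aligner. No iterative refinement and no codon-aware mode.

A consequence worth knowing: at ~25% nucleotide divergence the optimal
alignment occasionally absorbs clusters of mismatches into short gap
columns, which pairwise deletion then excludes — reported Hamming
percentages can sit up to about one percentage point below the divergence
the sequences were generated at. Alignment-parameter sensitivity of this
order is inherent to distance-from-alignment pipelines.

## Primer design

A position is **discriminating** when the target's (non-gap) base differs
from the symbol of every other row in that column — a gap in another row
counts as different, since no template base can pair there. Positions are
reported in ungapped target-gene coordinates, 1-based. A quorum option
(`quorum < 1`) relaxes "every" to a fraction, for large panels.

For each discriminating position and each admissible length, the forward
candidate is the target window ending on the position and the reverse
candidate the reverse complement of the window starting on it. Screens, in
order: ACGT-only alphabet, GC 40–60%, nearest-neighbor Tm 50–65 °C
(SantaLucia 1998 unified parameters, 50 mM Na⁺, 500 nM oligo; the Wallace
rule 2(A+T)+4(G+C) is reported alongside as a legacy quick figure),
homopolymer ≤ 5, self-annealing/hairpin complementarity runs. Pairs
additionally require product size in range (default 100–600 bp,
convergent, non-overlapping), |ΔTm| ≤ 3 °C, and a cross-annealing screen.
Complementarity is measured as the longest contiguous antiparallel
Watson–Crick run (equivalently, longest common substring with the other
oligo's reverse complement): fail at ≥ 8 anywhere or ≥ 5 in a run that
includes a 3′-terminal base; hairpins require a ≥ 3-base loop. The 3′-run
threshold admits runs of 4 deliberately — cross-annealing runs of 4 at a
3′ end are common in perfectly serviceable published pairs.

Pairs are ranked by (more additional discriminating positions inside the
amplicon, smaller |ΔTm|, product size nearer the range midpoint), with
coordinate tie-breaks for determinism. The ranking is a heuristic; a pair
designed by eye (like the published one) is expected to appear in the
admissible list but not necessarily at rank 1.

## In-silico PCR

Annealing is ungapped: a primer binds a window when total mismatches ≤ 2
(default) **and** the 3′-terminal 3 bases match perfectly. The hard clamp
models polymerase extension failure from a mismatched 3′ end — the very
mechanism the single discriminating base exploits — so one engineered
3′ mismatch suffices to veto a non-target template regardless of the
mismatch budget. IUPAC ambiguity in the template matches iff the primer
base is in the code's expansion. Circular genomes are scanned across the
origin. Every convergent (forward-on-plus, reverse-on-minus) site pair
whose span lies in the product range yields an amplicon; amplicon Tm uses
the salt-adjusted GC formula (valid ≥ 14 bp, default 50 mM Na⁺). The
specificity matrix is one row per genome (amplified, count, size, Tm,
coordinates) with a deterministic TSV rendering and a text virtual gel
whose band positions are log-interpolated against a 100 bp ladder.

Note the two oligo-Tm models and the amplicon formula answer different
questions and different salt regimes; the amplicon formula at 50 mM Na⁺
predicts ≈ 79–80 °C for a 291 bp fragment of ~47% GC, consistent with
SYBR-melt observations on instruments, while web calculators at higher
ionic strength print values in the high 80s for the same fragment.

## Synthetic study panel

Real accessions are deliberately not bundled or fetched; the generator
produces panels with known truth so every stage is testable offline.

Model: star phylogeny. One ancestral genome uniform over ACGT; each
species substitutes sites independently (substituted base uniform over the
three alternatives); genes are laid out in the canonical vertebrate
mitochondrial order with 30 bp conserved spacers, NAD6 on the minus
strand. Two refinements:

- **Target branch rate.** Each gene carries a background rate *d* (all
  non-target species) and a target rate *t*. Expected p-distance between
  branches with rates *a*, *b* is `a + b − (4/3)ab/v` (shared hot site,
  both mutated, agree with probability 1/3).
- **Hotspot fraction** *v*: substitutions are confined to a random
  fraction *v* of sites, conditional rates scaled by 1/v. This preserves
  pairwise distances while capping column variability near *v·100%*.
  Without it, independent mutation at interspecific rates (~0.25) across
  16 taxa makes ~90% of columns variable — far above what shared phylogeny
  produces in real alignments, where variation concentrates at recurrent
  sites.

Calibration: for each gene the pair (target-vs-rest Hamming, all-pairs
mean p-distance) is inverted analytically into (t, d) given *v* and the
panel size (`solve_rates`). The study panel uses the published per-gene
summaries where printed (the ATP6/NAD2/NAD4/NAD5/NAD6 Hamming values, the
COI and Cytb mean p-distances, the seven NAD-group nucleotide
variabilities) and plausible interpolations consistent with the printed
orderings elsewhere; gene lengths are typical teleost values (NAD2
1047 bp). The target's NAD2 carries the two published primer footprints
verbatim at gene positions 303–324 and 568–593; non-target copies of the
footprint diverge at the gene's calibrated target-vs-rest rate, and the
two 3′-terminal positions are engineered species-unique (non-targets
forced to one common alternative base) so the strict discriminating rule
holds by construction while the target keeps its printed bases.

What the panel does **not** emulate, hence what passing tests do not show
about real data: tree-structured covariance between species (distances to
the target concentrate instead of spreading over the real 10–19% range);
purifying selection (synonymous/nonsynonymous structure — amino-acid
variability comes out higher than in real coding genes); indels
(alignment stress uses hand-built gapped fixtures instead); and
compositional bias. Estimates from very short genes (ATP8, 168 bp) are
intrinsically noisy, so rank order among genes separated by a single
percentage point can swap between seeds — the same caveat applies to the
real panel.

Determinism: a spec (including its mandatory seed) maps to byte-identical
FASTA/GenBank output; the truth object records ancestral sequences,
per-species mutated positions, hot-site registry and engineered sites.

## Numerical and interface choices

- Coordinates 1-based inclusive everywhere on the public surface; reverse
  primers are anchored at their plus-strand 5′ end, so an amplicon runs
  from the forward anchor to the reverse anchor and
  `length = end − start + 1` (291 = 593 − 303 + 1).
- Gene panels drop a gene missing from any genome (with a warning) rather
  than analyze ragged orthology.
- Unknown annotation labels survive normalization unchanged and flagged;
  ingestion never fails on nomenclature.
- All tabular outputs are single-header TSV; pipeline reruns with the same
  config and seed are byte-identical, and the run manifest records config
  and artifact checksums.
- Problem sizes in tests and the acceptance script (16 genomes × ~14.5 kb,
  full 15-gene divergence, 200-pair alignment oracle, 50-template binding
  oracle) were chosen to keep a full run in the tens of seconds while
  leaving every statistical check at 3-standard-error resolution.
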