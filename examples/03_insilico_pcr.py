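"""In-silico PCR of the published NAD2 pair against all 16 genomes.

The specificity matrix is the computational twin of an end-point PCR gel:
one row per species, amplified yes/no, product size and melting
temperature. Only the target species should light up.
"""

from mitomarker import Tolerance, published_pair, specificity_matrix
from mitomarker.reporting import virtual_gel
from mitomarker.simulate import (FW303, FW_ANCHOR, REV593, REV_ANCHOR,
                                 TARGET_SPECIES, study_panel)

genomes, _ = study_panel(seed=1)
pair = published_pair(FW303, REV593, FW_ANCHOR, REV_ANCHOR)

matrix = specificity_matrix(pair, genomes, Tolerance(max_mismatches=2, clamp=3),
                            product_range=(100, 600),
                            target_species=TARGET_SPECIES)
print(matrix.table.to_string())
print()
print(virtual_gel(matrix))
# With a 2-mismatch budget and a strict 3-base 3' clamp, the pair anneals
# productively only on the target species: a presence/absence assay.
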