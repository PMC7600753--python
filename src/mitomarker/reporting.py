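"""Text renderings and run artifacts: the virtual gel and TSV/JSON writers."""

from __future__ import annotations

import json
import math
from pathlib import Path

from .ispcr import SpecificityMatrix

LADDER = (100, 200, 300, 400, 500, 600, 800, 1000)
GEL_HEIGHT = 24


def _band_row(length: int, lo: int, hi: int) -> int:
    """Gel row of a fragment: migration distance ~ -log(length)."""
    frac = (math.log(hi) - math.log(length)) / (math.log(hi) - math.log(lo))
    frac = min(max(frac, 0.0), 1.0)
    return int(round(frac * (GEL_HEIGHT - 1)))


def virtual_gel(matrix: SpecificityMatrix, lane_width: int = 4) -> str:
    """Fixed-width text gel: a ladder lane then one lane per genome.

    Band vertical position is proportional to log(length) between the
    ladder extremes; lanes without amplification stay empty, mirroring a
    presence/absence readout.
    """
    if matrix.table.empty:
        raise ValueError("empty specificity matrix")
    lo, hi = LADDER[0], LADDER[-1]
    lanes = list(matrix.table.index)
    grid = [[" " * lane_width for _ in range(len(lanes) + 1)]
            for _ in range(GEL_HEIGHT)]
    for mark in LADDER:
        grid[_band_row(mark, lo, hi)][0] = f"{mark:>{lane_width}}"
    for li, label in enumerate(lanes, start=1):
        row = matrix.table.loc[label]
        if row["amplified"] and row["amplicon_length"] > 0:
            r = _band_row(int(row["amplicon_length"]), lo, hi)
            grid[r][li] = "=" * lane_width
    header = " " * lane_width + "".join(
        f"{i:>{lane_width + 1}}" for i in range(1, len(lanes) + 1))
    body = "\n".join("|".join(cells) for cells in grid)
    legend = "\n".join(f"{i:>3}: {lab}" + ("  <- target" if row_is_target else "")
                       for i, (lab, row_is_target)
                       in enumerate(zip(lanes, matrix.table["is_target"]), 1))
    return f"{header}\n{body}\n\nM: bp ladder\n{legend}\n"


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
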