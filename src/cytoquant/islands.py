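"""Island-level aggregation of manual epithelial/mesenchymal scoring.

The classification of peripheral cells as "epithelial" (dense
concentric microtubules, smooth edge) or "mesenchymal" (spread,
migratory, outward-pointing microtubules) is a manual, morphology-based
call and stays an input here; this module implements only the exclusion
rule (islands below a minimum cell count are dropped) and the
aggregation into per-island percentages with a mean ± SEM summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imgio import IslandAnnotation
from .stats import summarize

MIN_CELLS_DEFAULT = 5  # islands smaller than this are not scored


@dataclass
class FractionSummary:
    per_island: pd.DataFrame  # island_id, n_cells, percent
    mean: float  # percent
    sem: float
    n_islands: int
    n_excluded: int


def mesenchymal_fraction(annotations: list[IslandAnnotation],
                         min_cells: int = MIN_CELLS_DEFAULT) -> FractionSummary:
    """Percent mesenchymal cells per island, summarized over islands.

    Islands with fewer than ``min_cells`` scored cells are excluded;
    each remaining island contributes 100 * mesenchymal / total cells,
    and the summary is mean ± SEM over islands.
    """
    if not annotations:
        raise ValueError("no annotations")
    rows = []
    excluded = 0
    for a in annotations:
        if a.n_cells < min_cells:
            excluded += 1
            continue
        rows.append({
            "island_id": a.island_id,
            "n_cells": a.n_cells,
            "percent": 100.0 * a.n_mesenchymal / a.n_cells,
        })
    if not rows:
        raise ValueError(f"all {len(annotations)} islands below min_cells={min_cells}")
    df = pd.DataFrame(rows)
    mean, sem, n = summarize(df["percent"])
    return FractionSummary(df, mean, sem, n, excluded)


def perimeter_fraction(annotations: list[IslandAnnotation]) -> FractionSummary:
    """Percent of the island perimeter length bordered by mesenchymal
    cells, summarized over islands.  Requires perimeter segments."""
    if not annotations:
        raise ValueError("no annotations")
    rows = []
    for a in annotations:
        if not a.perimeter_segments:
            raise ValueError(f"island {a.island_id!r} has no perimeter segments")
        total = sum(length for length, _ in a.perimeter_segments)
        mes = sum(length for length, cls in a.perimeter_segments
                  if cls == "mesenchymal")
        rows.append({
            "island_id": a.island_id,
            "n_cells": a.n_cells,
            "percent": 100.0 * mes / total,
        })
    df = pd.DataFrame(rows)
    mean, sem, n = summarize(df["percent"])
    return FractionSummary(df, mean, sem, n, 0)
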