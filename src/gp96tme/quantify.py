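"""Per-core quantification of multiplexed-IF cell tables.

A tissue-microarray core is reduced to the measurements the downstream
survival analyses consume: marker *staining extent* (fraction of all
nucleated cells positive for a marker) and *phenotype densities*
(cells per mm² of core area), plus high/low dichotomization of
patient-level measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

MARKERS = ("GFAP", "gp96", "CD4", "CD8", "PD1")

CELL_COLUMNS = ("x_um", "y_um") + MARKERS


class EmptyCoreError(ValueError):
    """Raised when an operation is undefined on a core with no cells."""


@dataclass
class CoreCellTable:
    """One TMA core: cell centroids (µm) with binary marker phenotypes.

    ``cells`` columns: x_um, y_um and one 0/1 column per marker in
    :data:`MARKERS`. ``area_mm2`` is the tissue area used as the density
    denominator.
    """

    core_id: str
    area_mm2: float
    cells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.area_mm2) or self.area_mm2 <= 0:
            raise ValueError(f"core {self.core_id}: area_mm2 must be > 0, got {self.area_mm2}")
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"core {self.core_id}: cell table missing columns {missing}")
        xy = self.cells[["x_um", "y_um"]].to_numpy(float)
        if xy.size and not np.all(np.isfinite(xy)):
            raise ValueError(f"core {self.core_id}: non-finite cell coordinates")
        flags = self.cells[list(MARKERS)].to_numpy()
        if flags.size and not np.isin(flags, (0, 1)).all():
            raise ValueError(f"core {self.core_id}: marker flags must be 0/1")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class CoreQuantification:
    """The per-core measurements entering the cohort-level analyses."""

    core_id: str
    gp96_extent: float
    gfap_extent: float
    cd4_density: float
    cd8_density: float
    pd1_density: float
    cd4_pd1_density: float


def phenotype_mask(
    cells: pd.DataFrame,
    positive: Sequence[str] = (),
    negative: Sequence[str] = (),
) -> np.ndarray:
    """Boolean mask of cells positive for all ``positive`` markers and
    negative for all ``negative`` markers (e.g. CD4+PD1− T cells)."""
    for m in tuple(positive) + tuple(negative):
        if m not in MARKERS:
            raise ValueError(f"unknown marker {m!r}; known: {MARKERS}")
    mask = np.ones(len(cells), dtype=bool)
    for m in positive:
        mask &= cells[m].to_numpy() == 1
    for m in negative:
        mask &= cells[m].to_numpy() == 0
    return mask


def staining_extent(core: CoreCellTable, marker: str) -> float:
    """Fraction of all nucleated cells in the core positive for ``marker``."""
    if core.n_cells == 0:
        raise EmptyCoreError(f"core {core.core_id}: staining extent undefined on an empty core")
    return float(phenotype_mask(core.cells, positive=[marker]).sum()) / core.n_cells


def phenotype_density(
    core: CoreCellTable,
    positive: Sequence[str],
    negative: Sequence[str] = (),
) -> float:
    """Cells per mm² matching the phenotype predicate."""
    n = int(phenotype_mask(core.cells, positive, negative).sum())
    return n / core.area_mm2


def quantify_core(core: CoreCellTable) -> CoreQuantification:
    """Reduce one core to extents and densities.

    PD-1 density counts every PD-1+ cell regardless of CD4/CD8
    co-positivity; the CD4+PD-1+ conjunction is a separate measurement.
    """
    return CoreQuantification(
        core_id=core.core_id,
        gp96_extent=staining_extent(core, "gp96"),
        gfap_extent=staining_extent(core, "GFAP"),
        cd4_density=phenotype_density(core, ["CD4"]),
        cd8_density=phenotype_density(core, ["CD8"]),
        pd1_density=phenotype_density(core, ["PD1"]),
        cd4_pd1_density=phenotype_density(core, ["CD4", "PD1"]),
    )


def quantification_table(cores: Sequence[CoreCellTable]) -> pd.DataFrame:
    """One row per core, indexed by core_id."""
    rows = [vars(quantify_core(c)) for c in cores]
    return pd.DataFrame(rows).set_index("core_id")


def dichotomize(
    values: pd.Series | np.ndarray,
    rule: Literal["median", "maxstat"] | float = "median",
    *,
    times: np.ndarray | None = None,
    events: np.ndarray | None = None,
    epsilon: float = 0.1,
) -> tuple[np.ndarray, float]:
    """Split a per-patient measurement into high/low.

    Returns ``(high, cutoff)`` where ``high[i]`` is True iff
    ``values[i] > cutoff``; ties go to the low group (the ≤-median
    convention). ``rule`` may be ``"median"``, a fixed numeric cutoff,
    or ``"maxstat"``, which derives the survival-optimal cutpoint via
    maximally selected rank statistics (``times``/``events`` required).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("dichotomize requires at least 2 values")
    if np.unique(vals).size < 2:
        raise ValueError("all values identical: no valid cutoff exists")
    if rule == "median":
        cutoff = float(np.median(vals))
    elif rule == "maxstat":
        if times is None or events is None:
            raise ValueError("maxstat rule requires survival times and events")
        from .cutpoint import max_selected_rank

        cutoff = max_selected_rank(vals, np.asarray(times, float),
                                   np.asarray(events, int), epsilon=epsilon).cutpoint
    else:
        cutoff = float(rule)
    return vals > cutoff, cutoff
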