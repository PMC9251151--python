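"""Distance-annulus profiling of T-cell phenotypes around tumor cells.

Each non-reference cell is assigned the Euclidean distance to its
nearest reference cell (by default gp96+GFAP+ tumor cells); profiles
histogram those distances into fixed-width annuli (5 µm bands out to
100 µm), and the attraction test compares the full distance
distributions of two query phenotypes with a Mann–Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .group_stats import GroupComparisonResult, mann_whitney
from .quantify import CoreCellTable, phenotype_mask

REFERENCE_PHENOTYPE = {"positive": ("gp96", "GFAP")}
QUERY_PHENOTYPES = {
    "CD4+PD1+": {"positive": ("CD4", "PD1")},
    "CD4+PD1-": {"positive": ("CD4",), "negative": ("PD1",)},
}


def nearest_reference_distance(core: CoreCellTable,
                               reference: dict = REFERENCE_PHENOTYPE) -> pd.Series:
    """Distance (µm) from every non-reference cell to the nearest
    reference cell, indexed like ``core.cells``."""
    ref_mask = phenotype_mask(core.cells, **reference)
    if not ref_mask.any():
        raise ValueError(f"core {core.core_id}: no reference cells match {reference}")
    xy = core.cells[["x_um", "y_um"]].to_numpy(float)
    tree = cKDTree(xy[ref_mask])
    query = xy[~ref_mask]
    d = tree.query(query)[0] if len(query) else np.empty(0)
    return pd.Series(d, index=core.cells.index[~ref_mask], name="nearest_um")


@dataclass
class SpatialProfile:
    """Per-annulus counts/proportions of query phenotypes around
    reference cells. Proportions are normalized within phenotype over
    the cells falling inside ``max_distance``; cells beyond it are
    tallied in ``n_beyond``."""

    core_id: str
    bin_edges: np.ndarray
    counts: pd.DataFrame       # bins × phenotypes
    proportions: pd.DataFrame  # NaN column when a phenotype has no in-range cell
    n_reference: int
    n_beyond: dict[str, int]
    n_total: dict[str, int]

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for k, phen in enumerate(self.counts.columns):
            for i in range(len(self.bin_edges) - 1):
                rows.append({
                    "core_id": self.core_id,
                    "bin_low": self.bin_edges[i],
                    "bin_high": self.bin_edges[i + 1],
                    "phenotype": phen,
                    "count": int(self.counts.iloc[i, k]),
                    "proportion": float(self.proportions.iloc[i, k]),
                })
        return pd.DataFrame(rows)


def annulus_profile(
    core: CoreCellTable,
    reference: dict = REFERENCE_PHENOTYPE,
    queries: dict = QUERY_PHENOTYPES,
    bin_width: float = 5.0,
    max_distance: float = 100.0,
) -> SpatialProfile:
    """Histogram nearest-reference distances of each query phenotype into
    [0, bin_width), ..., [max_distance - bin_width, max_distance)."""
    n_bins = max_distance / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide max_distance")
    edges = np.arange(0.0, max_distance + bin_width / 2, bin_width)
    dist = nearest_reference_distance(core, reference)
    ref_mask = phenotype_mask(core.cells, **reference)
    counts, props, beyond, totals = {}, {}, {}, {}
    for name, phen in queries.items():
        mask = phenotype_mask(core.cells, **phen) & ~ref_mask
        d = dist.loc[core.cells.index[mask]].to_numpy()
        c, _ = np.histogram(d[d < max_distance], bins=edges)  # bins right-open
        counts[name] = c
        totals[name] = int(d.size)
        beyond[name] = int((d >= max_distance).sum())
        in_range = c.sum()
        props[name] = c / in_range if in_range else np.full(c.size, np.nan)
    ref_n = int(phenotype_mask(core.cells, **reference).sum())
    return SpatialProfile(
        core_id=core.core_id, bin_edges=edges,
        counts=pd.DataFrame(counts), proportions=pd.DataFrame(props),
        n_reference=ref_n, n_beyond=beyond, n_total=totals,
    )


def pool_profiles(profiles: list[SpatialProfile]) -> pd.DataFrame:
    """Pool per-core profiles as the mean of per-core proportions
    (each specimen weighted equally), tidy format."""
    if not profiles:
        raise ValueError("no profiles to pool")
    tidy = pd.concat([p.to_tidy() for p in profiles], ignore_index=True)
    pooled = (tidy.groupby(["bin_low", "bin_high", "phenotype"], as_index=False)
              .agg(count=("count", "sum"), proportion=("proportion", "mean")))
    return pooled.sort_values(["phenotype", "bin_low"]).reset_index(drop=True)


def attraction_test(
    core: CoreCellTable,
    reference: dict = REFERENCE_PHENOTYPE,
    phenotype_a: dict = QUERY_PHENOTYPES["CD4+PD1+"],
    phenotype_b: dict = QUERY_PHENOTYPES["CD4+PD1-"],
) -> GroupComparisonResult:
    """Mann–Whitney U test comparing nearest-reference distances of two
    query phenotypes (uncapped distances; attraction of phenotype A shows
    as stochastically smaller distances)."""
    dist = nearest_reference_distance(core, reference)
    ref = phenotype_mask(core.cells, **reference)
    d = {}
    for label, phen in (("a", phenotype_a), ("b", phenotype_b)):
        mask = phenotype_mask(core.cells, **phen) & ~ref
        d[label] = dist.loc[core.cells.index[mask]].to_numpy()
        if d[label].size < 3:
            raise ValueError(
                f"phenotype {phen} has {d[label].size} cells; need >= 3")
    return mann_whitney(d["a"], d["b"])
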