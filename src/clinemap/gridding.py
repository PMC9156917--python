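"""Grid-cell aggregation and Hardy-Weinberg allele-frequency estimation.

Records are pooled into fixed latitude/longitude cells (half-open, anchored
at (-180, -90)). Within each cell and locus the frequency of the
homozygous-recessive genotype class f = n_rec / n_scored is converted to a
recessive allele frequency under Hardy-Weinberg equilibrium, q_hat = sqrt(f).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .records import LOCI, ClassCall, Dataset, Source


@dataclass(frozen=True)
class GridSpec:
    """Cell size in degrees; cells are half-open [lo, lo+size) in both axes."""

    cell_size: float = 4.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not math.isclose(360.0 / self.cell_size, round(360.0 / self.cell_size)):
            raise ValueError("cell_size must divide 360 evenly")


def assign_cell(lat: float, lon: float, spec: GridSpec) -> tuple[int, int]:
    """Cell index (lon_idx, lat_idx) anchored at (-180, -90), half-open.

    Boundary points belong to the higher cell; lat = 90 is folded into the
    top row so the pole does not create a one-point cell.
    """
    if not -90.0 <= lat <= 90.0 or not -180.0 <= lon < 180.0:
        raise ValueError(f"coordinate out of bounds: ({lat}, {lon})")
    size = spec.cell_size
    lon_idx = int(math.floor((lon + 180.0) / size))
    lat_idx = int(math.floor((lat + 90.0) / size))
    lat_idx = min(lat_idx, int(round(180.0 / size)) - 1)
    return (lon_idx, lat_idx)


def cell_centre(index: tuple[int, int], spec: GridSpec) -> tuple[float, float]:
    """(lat, lon) of the geometric centre of a cell."""
    lon_idx, lat_idx = index
    size = spec.cell_size
    return (-90.0 + (lat_idx + 0.5) * size, -180.0 + (lon_idx + 0.5) * size)


@dataclass
class CellSummary:
    cell_index: tuple[int, int]
    centre: tuple[float, float]  # (lat, lon)
    n_records_total: int = 0
    n_by_source: dict = field(default_factory=dict)
    n_scored: dict = field(default_factory=dict)        # locus -> count
    n_recessive_hom: dict = field(default_factory=dict)  # locus -> count

    def f_rec_genotype(self, locus: str) -> float:
        """Frequency of the homozygous-recessive class; NaN when unscored."""
        n = self.n_scored.get(locus, 0)
        if n == 0:
            return float("nan")
        return self.n_recessive_hom.get(locus, 0) / n

    def q_hat(self, locus: str) -> float:
        """HWE recessive allele frequency, sqrt(f_rec); NaN when unscored."""
        return math.sqrt(self.f_rec_genotype(locus))


@dataclass
class FrequencyGrid:
    spec: GridSpec
    cells: dict  # cell_index -> CellSummary

    def __len__(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        """One row per occupied cell in the grid-CSV dialect."""
        rows = []
        for idx, c in sorted(self.cells.items()):
            row = {
                "lon_idx": idx[0],
                "lat_idx": idx[1],
                "centre_lon": c.centre[1],
                "centre_lat": c.centre[0],
                "n_total": c.n_records_total,
                "n_research": c.n_by_source.get("research", 0),
                "n_citizen": c.n_by_source.get("citizen", 0),
            }
            for loc in LOCI:
                row[f"{loc}_n"] = c.n_scored.get(loc, 0)
                row[f"{loc}_nrec"] = c.n_recessive_hom.get(loc, 0)
                row[f"{loc}_frec"] = c.f_rec_genotype(loc)
                row[f"{loc}_qhat"] = c.q_hat(loc)
            rows.append(row)
        return pd.DataFrame(rows)


def build_grid(ds: Dataset, spec: GridSpec) -> FrequencyGrid:
    """Aggregate a dataset into per-cell genotype counts.

    Records with all three loci missing still count toward occupancy
    (``n_records_total``) but contribute to no frequency.
    """
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    cells: dict[tuple[int, int], CellSummary] = {}
    for r in ds:
        idx = assign_cell(r.latitude, r.longitude, spec)
        cell = cells.get(idx)
        if cell is None:
            cell = CellSummary(
                cell_index=idx,
                centre=cell_centre(idx, spec),
                n_by_source={s.value: 0 for s in Source},
                n_scored={loc: 0 for loc in LOCI},
                n_recessive_hom={loc: 0 for loc in LOCI},
            )
            cells[idx] = cell
        cell.n_records_total += 1
        cell.n_by_source[r.source.value] += 1
        for loc in LOCI:
            call = r.calls[loc]
            if call is ClassCall.MISSING:
                continue
            cell.n_scored[loc] += 1
            if call is ClassCall.RECESSIVE_HOM:
                cell.n_recessive_hom[loc] += 1
    return FrequencyGrid(spec=spec, cells=cells)


class FixationClass(str, enum.Enum):
    NEAR_FIXED = "near_fixed"
    POLYMORPHIC = "polymorphic"
    NEAR_ABSENT = "near_absent"


def classify_fixation(freq: float, lo: float = 0.05, hi: float = 0.95) -> FixationClass:
    """Classify a frequency: > hi near-fixed, [lo, hi] polymorphic, < lo near-absent."""
    if not 0.0 < lo < hi < 1.0:
        raise ValueError("thresholds must satisfy 0 < lo < hi < 1")
    if freq is None or math.isnan(freq):
        raise ValueError("frequency undefined")
    if freq > hi:
        return FixationClass.NEAR_FIXED
    if freq >= lo:
        return FixationClass.POLYMORPHIC
    return FixationClass.NEAR_ABSENT


def fixation_summary(
    grid: FrequencyGrid,
    locus: str,
    min_n: int = 1,
    *,
    frequency: str = "genotype",
    lo: float = 0.05,
    hi: float = 0.95,
) -> dict:
    """Percentages of eligible cells in each fixation class at one locus.

    ``frequency`` selects the classified quantity: the recessive
    genotype-class frequency (``"genotype"``), the dominant-class frequency
    (``"genotype_dominant"``, e.g. for *B-* or *C-* summaries), or the HWE
    recessive/dominant allele frequency (``"allele"`` / ``"allele_dominant"``).
    Cells with fewer than ``min_n`` scored records are excluded from the
    denominator.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    getters = {
        "genotype": lambda c: c.f_rec_genotype(locus),
        "genotype_dominant": lambda c: 1.0 - c.f_rec_genotype(locus),
        "allele": lambda c: c.q_hat(locus),
        "allele_dominant": lambda c: 1.0 - c.q_hat(locus),
    }
    if frequency not in getters:
        raise ValueError(f"frequency must be one of {sorted(getters)}")
    eligible = [c for c in grid.cells.values() if c.n_scored.get(locus, 0) >= min_n]
    if not eligible:
        raise ValueError(f"no cell with >= {min_n} scored records at locus {locus}")
    counts = {k: 0 for k in FixationClass}
    for c in eligible:
        counts[classify_fixation(getters[frequency](c), lo, hi)] += 1
    n = len(eligible)
    return {
        "locus": locus,
        "n_cells": n,
        "percent": {k.value: 100.0 * v / n for k, v in counts.items()},
    }


def source_concordance(
    grid_research: FrequencyGrid, grid_citizen: FrequencyGrid, locus: str
) -> dict:
    """OLS regression of citizen genotype-class frequency on research frequency.

    Computed over cells scorable at the locus in both grids; quantifies how
    predictive conventional research records are of citizen-science records.
    """
    shared = [
        idx
        for idx in grid_research.cells
        if idx in grid_citizen.cells
        and grid_research.cells[idx].n_scored.get(locus, 0) > 0
        and grid_citizen.cells[idx].n_scored.get(locus, 0) > 0
    ]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared scorable cells at locus {locus}")
    x = np.array([grid_research.cells[i].f_rec_genotype(locus) for i in shared])
    y = np.array([grid_citizen.cells[i].f_rec_genotype(locus) for i in shared])
    res = stats.linregress(x, y)
    return {
        "locus": locus,
        "n_cells": len(shared),
        "slope": res.slope,
        "intercept": res.intercept,
        "r_squared": res.rvalue**2,
        "p_value": res.pvalue,
    }
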