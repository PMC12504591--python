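"""Land-use / land-cover (LULC) accounting.

The regional landscape is described by nine CORINE-style categories. Three
kinds of objects move through this module:

* :class:`AreaTable` — hectares allocated to each category in one epoch
  (e.g. the 1929 cadastral survey, or the 2024 remote-sensing product);
* :class:`CategoricalGrid` — a rasterised landscape: a 2-D integer array of
  category codes with a nodata code and a constant per-cell area;
* :class:`TransitionTable` — area flows between categories across two
  dates, obtained by cell-wise cross-tabulation of a pair of aligned grids.

Cells count toward a category or zone by their integer value only; there is
no partial-cell area weighting, which keeps all counts integer-exact and
makes marginal conservation an exact (not approximate) invariant.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    FormatError,
    UndefinedBaselineError,
    ValidationError,
)

#: The nine canonical categories, in reporting order. Codes are the raster
#: values used for gridded epochs (0 is reserved for nodata by convention).
CANONICAL_CATEGORIES: tuple[str, ...] = (
    "Agroforestry",
    "Fruit tree plantations",
    "Managed Forest",
    "Mixed Forest",
    "Grassland",
    "Unproductive area",
    "Non-irrigated arable land",
    "Uncultivated productive area",
    "Water body",
)

NAME_TO_CODE: dict[str, int] = {n: i + 1 for i, n in enumerate(CANONICAL_CATEGORIES)}
CODE_TO_NAME: dict[int, str] = {c: n for n, c in NAME_TO_CODE.items()}

#: Category name of the arable-monoculture class targeted by the management
#: scenarios, and of the classes it converts into.
ARABLE = "Non-irrigated arable land"
AGROFORESTRY = "Agroforestry"
MIXED_FOREST = "Mixed Forest"
WATER_BODY = "Water body"


@dataclass(frozen=True)
class LULCCategory:
    """One LULC class: a small-integer raster code and its canonical name."""

    code: int
    name: str


def canonical_categories() -> list[LULCCategory]:
    return [LULCCategory(code=c, name=n) for n, c in NAME_TO_CODE.items()]


@dataclass
class AreaTable:
    """Hectares per LULC category for one epoch.

    All nine canonical categories are always present (zero-area allowed);
    areas are non-negative. ``entries`` preserves the canonical order.
    """

    epoch: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.entries) - set(CANONICAL_CATEGORIES)
        if unknown:
            raise ValidationError(f"unknown LULC categories: {sorted(unknown)}")
        for name, area in self.entries.items():
            if not np.isfinite(area) or area < 0:
                raise ValidationError(f"negative or non-finite area for {name!r}: {area}")
        # fill absent categories with zero, in canonical order
        self.entries = {n: float(self.entries.get(n, 0.0)) for n in CANONICAL_CATEGORIES}

    @property
    def total(self) -> float:
        return float(sum(self.entries.values()))

    def __getitem__(self, category: str) -> float:
        return self.entries[category]

    def areas(self) -> np.ndarray:
        """Areas as a vector in canonical category order."""
        return np.array([self.entries[n] for n in CANONICAL_CATEGORIES])

    def replace(self, epoch: str | None = None, **updates: float) -> "AreaTable":
        new = dict(self.entries)
        new.update(updates)
        return AreaTable(epoch=epoch or self.epoch, entries=new)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": list(self.entries), "area_ha": list(self.entries.values())}
        )


def read_area_table(path: str | Path, epoch: str) -> AreaTable:
    """Read a ``category,area_ha`` CSV into a validated :class:`AreaTable`.

    Unknown category names and negative areas are rejected.
    """
    df = pd.read_csv(path)
    missing = {"category", "area_ha"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if df["category"].duplicated().any():
        dupes = df["category"][df["category"].duplicated()].tolist()
        raise FormatError(f"{path}: duplicated categories {dupes}")
    entries = dict(zip(df["category"].astype(str), df["area_ha"].astype(float)))
    return AreaTable(epoch=epoch, entries=entries)


def load_epoch_table(epoch: str) -> AreaTable:
    """Load a packaged regional area table ('1929', '1954' or '2024')."""
    if epoch not in ("1929", "1954", "2024"):
        raise ValidationError(f"no packaged area table for epoch {epoch!r}")
    ref = resources.files("silvocarbon.data") / f"area_{epoch}.csv"
    with resources.as_file(ref) as path:
        return read_area_table(path, epoch)


def percent_change(before: float, after: float) -> float:
    """Relative change 100 × (after − before) / before, in percent."""
    if before <= 0:
        raise UndefinedBaselineError(f"baseline must be positive, got {before}")
    return 100.0 * (after - before) / before


@dataclass
class CategoricalGrid:
    """A rasterised categorical landscape.

    ``cells`` holds integer category codes; ``nodata`` marks cells outside
    the analysed footprint; ``cell_area`` is hectares per cell.
    """

    cells: np.ndarray
    nodata: int = 0
    cell_area: float = 1.0

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 2:
            raise ValidationError("grid cells must be a 2-D array")
        if not np.issubdtype(self.cells.dtype, np.integer):
            raise ValidationError("grid cells must be integer category codes")
        if self.cell_area <= 0:
            raise ValidationError(f"cell_area must be positive, got {self.cell_area}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape  # type: ignore[return-value]

    def valid_mask(self) -> np.ndarray:
        return self.cells != self.nodata


@dataclass
class TransitionTable:
    """Area flows between categories across two dates, keyed by code pairs."""

    flows: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, area in self.flows.items():
            if area < 0:
                raise ValidationError(f"negative flow {key}: {area}")

    @property
    def total(self) -> float:
        return float(sum(self.flows.values()))

    def row_marginals(self) -> dict[int, float]:
        """Total outgoing area per source category (the from-epoch areas)."""
        out: dict[int, float] = {}
        for (i, _j), a in self.flows.items():
            out[i] = out.get(i, 0.0) + a
        return out

    def column_marginals(self) -> dict[int, float]:
        """Total incoming area per target category (the to-epoch areas)."""
        out: dict[int, float] = {}
        for (_i, j), a in self.flows.items():
            out[j] = out.get(j, 0.0) + a
        return out

    def nonzero(self) -> dict[tuple[int, int], float]:
        return {k: v for k, v in self.flows.items() if v > 0}


def _check_aligned(a: CategoricalGrid, b: CategoricalGrid) -> None:
    if a.shape != b.shape:
        raise AlignmentError(f"grid shapes differ: {a.shape} vs {b.shape}")
    if a.nodata != b.nodata:
        raise AlignmentError(f"nodata codes differ: {a.nodata} vs {b.nodata}")
    if a.cell_area != b.cell_area:
        raise AlignmentError(f"cell areas differ: {a.cell_area} vs {b.cell_area}")


def cross_tabulate(grid_a: CategoricalGrid, grid_b: CategoricalGrid) -> TransitionTable:
    """Cell-wise cross-tabulation of two aligned grids into area flows.

    ``flow(i, j) = cell_area × #{cells with code i in a and code j in b}``.
    Cells that are nodata in *either* grid are excluded, which keeps the
    from- and to-totals identical by construction.
    """
    _check_aligned(grid_a, grid_b)
    mask = grid_a.valid_mask() & grid_b.valid_mask()
    pairs = np.stack([grid_a.cells[mask], grid_b.cells[mask]])
    if pairs.size == 0:
        return TransitionTable(flows={})
    uniq, counts = np.unique(pairs, axis=1, return_counts=True)
    flows = {
        (int(i), int(j)): float(c) * grid_a.cell_area
        for (i, j), c in zip(uniq.T, counts)
    }
    return TransitionTable(flows=flows)


def zonal_areas(
    grid: CategoricalGrid,
    zones: CategoricalGrid,
    code_names: Mapping[int, str] | None = None,
) -> dict[int, AreaTable]:
    """Per-zone area tables from an aligned (grid, zone-grid) pair.

    Zones are integer labels; cells nodata in either raster are skipped.
    ``code_names`` maps raster codes to canonical category names (defaults
    to the packaged code table); unknown codes raise rather than pool.
    """
    _check_aligned(grid, zones)
    names = dict(code_names) if code_names is not None else dict(CODE_TO_NAME)
    mask = grid.valid_mask() & zones.valid_mask()
    out: dict[int, AreaTable] = {}
    codes_seen = np.unique(grid.cells[mask])
    unknown = [int(c) for c in codes_seen if int(c) not in names]
    if unknown:
        raise ValidationError(f"grid holds unknown category codes: {unknown}")
    for zone in np.unique(zones.cells[mask]):
        zmask = mask & (zones.cells == zone)
        codes, counts = np.unique(grid.cells[zmask], return_counts=True)
        entries = {
            names[int(c)]: float(n) * grid.cell_area for c, n in zip(codes, counts)
        }
        out[int(zone)] = AreaTable(epoch=f"zone {int(zone)}", entries=entries)
    return out


def grid_area_table(
    grid: CategoricalGrid,
    epoch: str,
    code_names: Mapping[int, str] | None = None,
) -> AreaTable:
    """Whole-grid category areas (a one-zone special case of zonal_areas)."""
    marker = grid.nodata + 1
    ones = CategoricalGrid(
        cells=np.where(grid.valid_mask(), marker, grid.nodata).astype(grid.cells.dtype),
        nodata=grid.nodata,
        cell_area=grid.cell_area,
    )
    zoned = zonal_areas(grid, ones, code_names)
    if not zoned:
        return AreaTable(epoch=epoch, entries={})
    (table,) = zoned.values()
    table.epoch = epoch
    return table


def sankey_export(
    table: TransitionTable,
    path: str | Path,
    code_names: Mapping[int, str] | None = None,
) -> None:
    """Write a ``source,target,value`` CSV of non-zero flows (hectares).

    The flow file is the plotting-ready form of a transition diagram: each
    row is one band whose width is the transitioned area.
    """
    names = dict(code_names) if code_names is not None else dict(CODE_TO_NAME)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "value"])
        for (i, j), area in sorted(table.nonzero().items()):
            writer.writerow([names.get(i, i), names.get(j, j), repr(area)])


def read_sankey(path: str | Path) -> TransitionTable:
    """Read a flow CSV written by :func:`sankey_export` back into a table."""
    df = pd.read_csv(path)
    missing = {"source", "target", "value"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")

    def as_code(x: object) -> int:
        if isinstance(x, str) and not x.lstrip("-").isdigit():
            return NAME_TO_CODE[x]
        return int(x)  # type: ignore[arg-type]

    flows = {
        (as_code(r.source), as_code(r.target)): float(r.value)
        for r in df.itertuples()
    }
    return TransitionTable(flows=flows)


def transition_frame(
    table: TransitionTable, code_names: Mapping[int, str] | None = None
) -> pd.DataFrame:
    """Long-format DataFrame view of the non-zero flows."""
    names = dict(code_names) if code_names is not None else dict(CODE_TO_NAME)
    rows = [
        {"source": names.get(i, i), "target": names.get(j, j), "area_ha": a}
        for (i, j), a in sorted(table.nonzero().items())
    ]
    return pd.DataFrame(rows, columns=["source", "target", "area_ha"])
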