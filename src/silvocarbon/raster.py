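"""Categorical raster I/O.

Grids travel as single-band integer TIFFs. The nodata value is stored in the
GDAL_NODATA TIFF tag (code 42113), the convention GIS toolchains use for
GeoTIFF, so files written here open with the correct mask elsewhere and
GDAL-produced categorical rasters read back with their mask honoured.
Georeferencing tags are ignored: accounting needs only codes and a constant
per-cell area, which the caller supplies.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError
from .lulc import CategoricalGrid

GDAL_NODATA_TAG = 42113


def write_categorical_tiff(grid: CategoricalGrid, path: str | Path) -> None:
    """Write a grid as a single-band integer TIFF with a GDAL nodata tag."""
    tifffile.imwrite(
        path,
        grid.cells,
        extratags=[(GDAL_NODATA_TAG, "s", 0, str(grid.nodata), True)],
    )


def read_categorical_tiff(
    path: str | Path,
    cell_area: float = 1.0,
    nodata: int | None = None,
) -> CategoricalGrid:
    """Read a single-band integer TIFF into a :class:`CategoricalGrid`.

    The nodata code is taken from the GDAL_NODATA tag when present;
    ``nodata`` overrides it (and is required if the tag is absent).
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        cells = page.asarray()
        if nodata is None:
            tag = page.tags.get(GDAL_NODATA_TAG)
            if tag is None:
                raise FormatError(
                    f"{path}: no GDAL_NODATA tag; pass nodata= explicitly"
                )
            nodata = int(float(tag.value))
    if cells.ndim == 3 and cells.shape[2] == 1:
        cells = cells[:, :, 0]
    if cells.ndim != 2:
        raise FormatError(f"{path}: expected a single-band raster, got {cells.shape}")
    if not np.issubdtype(cells.dtype, np.integer):
        raise FormatError(f"{path}: expected integer codes, got dtype {cells.dtype}")
    return CategoricalGrid(cells=cells, nodata=nodata, cell_area=cell_area)
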