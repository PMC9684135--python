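"""TIFF I/O for density rasters.

Rasters are written as single-band float32 TIFFs with the grid coordinates,
units and kind tag serialised as JSON in the ImageDescription tag, so a
round trip preserves the georeference and metadata the exposure stage needs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import xarray as xr


def write_tiff(raster: xr.DataArray, path: str | Path) -> None:
    meta = {
        "dims": list(raster.dims),
        "coords": {str(d): np.asarray(raster.coords[d]).tolist() for d in raster.dims},
        "attrs": {k: v for k, v in raster.attrs.items() if isinstance(v, (str, int, float))},
        "name": raster.name,
    }
    tifffile.imwrite(
        str(path), raster.values.astype(np.float32), description=json.dumps(meta)
    )


def read_tiff(path: str | Path) -> xr.DataArray:
    with tifffile.TiffFile(str(path)) as tif:
        values = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    dims = meta.get("dims", ["y", "x"])
    coords = {d: np.asarray(v) for d, v in meta.get("coords", {}).items()}
    return xr.DataArray(
        values.astype(float),
        dims=dims,
        coords=coords,
        name=meta.get("name"),
        attrs=meta.get("attrs", {}),
    )
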