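"""Standard-format I/O: feature-table CSV and per-cell TIFF image sets.

The feature table is an RFC-4180 CSV with header
``donor,cell_id,C,HW,L,MW,VA,AA,DFI`` (lengths in um, areas in um^2, C and
DFI dimensionless); unit metadata travels in ``#`` comment lines above the
header.  Image sets are one 16-bit grayscale TIFF per channel plus a JSON
sidecar with the pixel size and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import SchemaError, ValidationError
from .morphometry import CellImageSet

REQUIRED_COLUMNS = ("donor", "cell_id", "C", "HW", "L", "MW", "VA", "AA", "DFI")

UNITS_COMMENT = (
    "# spermdfi feature table\n"
    "# units: C dimensionless; HW, L, MW um; VA, AA um^2; DFI dimensionless in [0, 1]\n"
)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write the feature table with its unit header comments."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"table is missing required column(s): {missing}")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(UNITS_COMMENT)
        table.to_csv(fh, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read and validate a feature table CSV.

    Raises :class:`SchemaError` naming missing/renamed columns and
    :class:`ValidationError` naming the first row whose DFI falls outside
    [0, 1].  Extra columns are preserved untouched.
    """
    table = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    dfi = table["DFI"].to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(dfi) | (dfi < 0) | (dfi > 1))
    if bad.size:
        row = int(bad[0])
        raise ValidationError(
            f"{path}: DFI outside [0, 1] at row {row} "
            f"(cell_id={table['cell_id'].iloc[row]!r}, DFI={dfi[row]!r})"
        )
    return table


def write_image_set(images: CellImageSet, basepath, seed: int | None = None) -> None:
    """Write one cell's channels as TIFFs plus a JSON sidecar."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    for name, arr in (("brightfield", images.brightfield),
                      ("green", images.green), ("red", images.red)):
        tifffile.imwrite(f"{base}_{name}.tif", arr)
    meta = {
        "pixel_size_um": images.pixel_size_um,
        "cell_id": images.cell_id,
        "donor": images.donor,
        "seed": seed,
    }
    with open(f"{base}.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_image_set(basepath) -> CellImageSet:
    """Read a cell's image set written by :func:`write_image_set`."""
    base = Path(basepath)
    with open(f"{base}.json") as fh:
        meta = json.load(fh)
    channels = {name: tifffile.imread(f"{base}_{name}.tif")
                for name in ("brightfield", "green", "red")}
    return CellImageSet(
        brightfield=channels["brightfield"], green=channels["green"],
        red=channels["red"], pixel_size_um=float(meta["pixel_size_um"]),
        cell_id=meta.get("cell_id"), donor=meta.get("donor"),
    )
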