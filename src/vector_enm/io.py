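"""File formats: ESRI ASCII grids, stack directories and occurrence CSVs.

ESRI ASCII (.asc) is the interchange raster format: a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by
rows printed top-down. Categorical metadata (kind and code -> label map)
lives in a ``<name>.json`` sidecar next to each grid. Occurrences are a
CSV with columns ``species,x,y[,life_stage]``.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import EnvStack, RasterLayer

logger = logging.getLogger("vector_enm")

NODATA = -9999.0

__all__ = [
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "write_stack",
    "read_occurrences",
]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_grid(path, name: str | None = None) -> RasterLayer:
    """Read an ESRI ASCII grid (with its optional JSON sidecar).

    The file's top row is the northernmost; rows are flipped into the
    package's lower-left-origin convention. Malformed headers raise with
    the offending line number.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for i, key in enumerate(_HEADER_KEYS):
        if i >= len(lines):
            raise ValueError(f"{path}: truncated header at line {i + 1}")
        parts = lines[i].split()
        if len(parts) != 2 or parts[0].lower() != key:
            raise ValueError(
                f"{path}: line {i + 1}: expected '{key} <value>', got {lines[i].strip()!r}"
            )
        try:
            header[key] = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 1}: non-numeric value") from exc
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    body = np.loadtxt(lines[len(_HEADER_KEYS):], dtype=float)
    body = np.atleast_2d(body)
    if body.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data shape {body.shape} does not match header ({nrows}, {ncols})"
        )
    values = body[::-1]  # file is top-down; storage is bottom-up
    mask = values == header["nodata_value"]
    kind = "continuous"
    labels = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kind = meta.get("kind", "continuous")
        if meta.get("labels"):
            labels = {int(k): v for k, v in meta["labels"].items()}
    if kind == "categorical":
        values = np.where(mask, 0, values).astype(int)
    return RasterLayer(
        name=name or path.stem,
        kind=kind,
        values=values,
        nodata_mask=mask,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        category_labels=labels,
    )


def write_ascii_grid(layer: RasterLayer, path) -> Path:
    """Write a layer as an ESRI ASCII grid plus JSON sidecar when categorical."""
    path = Path(path)
    nr, nc = layer.shape
    x0, y0 = layer.origin
    vals = np.where(layer.nodata_mask, NODATA, layer.values.astype(float))
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\n")
        fh.write(f"nrows {nr}\n")
        fh.write(f"xllcorner {x0:.10g}\n")
        fh.write(f"yllcorner {y0:.10g}\n")
        fh.write(f"cellsize {layer.cell_size:.10g}\n")
        fh.write(f"NODATA_value {NODATA:.10g}\n")
        for row in vals[::-1]:  # northernmost row first
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    if layer.kind == "categorical":
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "kind": "categorical",
                    "labels": {str(k): v for k, v in (layer.category_labels or {}).items()},
                },
                indent=2,
            )
        )
    return path


def write_stack(stack: EnvStack, out_dir) -> list[Path]:
    """Write every layer of a stack into a directory of .asc files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return [write_ascii_grid(lyr, out / f"{lyr.name}.asc") for lyr in stack.layers]


def read_stack(stack_dir) -> EnvStack:
    """Read every .asc grid in a directory into an aligned stack."""
    stack_dir = Path(stack_dir)
    paths = sorted(stack_dir.glob("*.asc"))
    if not paths:
        raise ValueError(f"no .asc grids found in {stack_dir}")
    return EnvStack([read_ascii_grid(p) for p in paths])


def read_occurrences(path) -> pd.DataFrame:
    """Read an occurrence CSV (species,x,y[,life_stage]).

    Malformed rows (missing species or non-numeric coordinates) are
    dropped with a logged count; species names are whitespace-normalised.
    An empty file or a missing mandatory column raises.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty occurrence file") from exc
    missing = {"species", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no occurrence records")
    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    species = df["species"].astype(str).str.strip()
    ok = x.notna() & y.notna() & (species != "") & (species.str.lower() != "nan")
    n_bad = int((~ok).sum())
    if n_bad:
        bad_rows = (df.index[~ok] + 2).tolist()  # +2: header + 1-based
        logger.warning("%s: dropped %d malformed row(s) at line(s) %s", path, n_bad, bad_rows)
        warnings.warn(f"{path}: dropped {n_bad} malformed occurrence row(s)")
    out = pd.DataFrame({"species": species[ok], "x": x[ok], "y": y[ok]})
    if "life_stage" in df.columns:
        out["life_stage"] = df["life_stage"][ok]
    if len(out) == 0:
        raise ValueError(f"{path}: no valid occurrence records")
    return out.reset_index(drop=True)
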