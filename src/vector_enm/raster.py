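"""Raster data model and spatial pre-processing.

A :class:`RasterLayer` is a regular grid of environmental values (continuous
or categorical) with an explicit nodata mask; an :class:`EnvStack` is an
ordered, geometrically aligned collection of layers.  Grids use a lower-left
origin: ``values[row, col]`` covers the half-open box
``[x0 + col*s, x0 + (col+1)*s) x [y0 + row*s, y0 + (row+1)*s)`` and points
are assigned to cells by floor division.  All distances are planar Euclidean
in map units between cell centres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RasterLayer",
    "EnvStack",
    "resample_layer",
    "one_hot_encode",
    "distance_to",
    "pearson_correlation_matrix",
    "extract_values",
]


@dataclass
class RasterLayer:
    """A single environmental grid.

    Parameters
    ----------
    name : str
        Unique layer name.
    kind : {"continuous", "categorical"}
        Categorical layers hold integer codes; continuous layers hold floats.
    values : (nrows, ncols) ndarray
        Cell values, row 0 at the *bottom* (lower-left origin).
    nodata_mask : (nrows, ncols) bool ndarray
        True where the cell carries no data.
    cell_size : float
        Cell edge length in map units.
    origin : (float, float)
        (x0, y0) of the lower-left corner of the grid.
    category_labels : dict[int, str] | None
        Code -> label mapping, categorical layers only.
    """

    name: str
    kind: str
    values: np.ndarray
    nodata_mask: np.ndarray
    cell_size: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    category_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.nodata_mask.shape}"
            )
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.kind == "categorical":
            valid = self.values[~self.nodata_mask]
            if valid.size and not np.all(np.equal(np.mod(valid, 1), 0)):
                raise ValueError(f"categorical layer {self.name!r} has non-integer codes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def codes(self) -> np.ndarray:
        """Sorted unique category codes present on valid cells."""
        if self.kind != "categorical":
            raise ValueError(f"layer {self.name!r} is not categorical")
        return np.unique(self.values[~self.nodata_mask].astype(int))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate grids of the cell centres."""
        nr, nc = self.shape
        x0, y0 = self.origin
        x = x0 + (np.arange(nc) + 0.5) * self.cell_size
        y = y0 + (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(x, y)


@dataclass
class EnvStack:
    """An ordered stack of geometrically aligned layers.

    The effective nodata mask is the union of the member masks; layer names
    must be unique.
    """

    layers: list[RasterLayer] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [lyr.name for lyr in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        if self.layers:
            ref = self.layers[0]
            for lyr in self.layers[1:]:
                if (
                    lyr.shape != ref.shape
                    or lyr.cell_size != ref.cell_size
                    or lyr.origin != ref.origin
                ):
                    raise ValueError(
                        f"layer {lyr.name!r} does not share the stack geometry"
                    )

    def __getitem__(self, name: str) -> RasterLayer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(lyr.name == name for lyr in self.layers)

    @property
    def names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0].shape

    @property
    def cell_size(self) -> float:
        return self.layers[0].cell_size

    @property
    def origin(self) -> tuple[float, float]:
        return self.layers[0].origin

    @property
    def nodata_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for lyr in self.layers:
            mask |= lyr.nodata_mask
        return mask

    def add(self, layer: RasterLayer) -> None:
        self.layers.append(layer)
        self.__post_init__()

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        nr, nc = self.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nc * self.cell_size, y0 + nr * self.cell_size)

    def point_to_cell(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) by the half-open floor convention."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - y0) / self.cell_size).astype(int)
        return row, col

    def cell_to_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 + (np.asarray(row) + 0.5) * self.cell_size
        return x, y


def resample_layer(layer: RasterLayer, target_cell_size: float) -> RasterLayer:
    """Aggregate a layer to a coarser resolution.

    Continuous layers are aggregated by the mean over each target cell,
    categorical layers by the majority code (ties broken by the smallest
    code). A target cell is nodata only when every source cell under it is
    nodata. The target cell size must be an integer multiple of the source
    cell size and the grid dimensions must be divisible by the ratio.
    """
    ratio = target_cell_size / layer.cell_size
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"target cell size {target_cell_size} is not an integer multiple of "
            f"source cell size {layer.cell_size}"
        )
    if factor == 1:
        return replace(layer)
    nr, nc = layer.shape
    if nr % factor or nc % factor:
        raise ValueError(
            f"grid shape {layer.shape} not divisible by aggregation factor {factor}"
        )
    tr, tc = nr // factor, nc // factor
    # blocks[i, j] is the (factor, factor) source window under target cell (i, j)
    blocks = layer.values.reshape(tr, factor, tc, factor).swapaxes(1, 2)
    mask_blocks = layer.nodata_mask.reshape(tr, factor, tc, factor).swapaxes(1, 2)
    out_mask = mask_blocks.all(axis=(2, 3))
    if layer.kind == "continuous":
        vals = np.where(mask_blocks, np.nan, blocks.astype(float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
            out = np.nanmean(vals, axis=(2, 3))
        out = np.where(out_mask, 0.0, out)
    else:
        out = np.zeros((tr, tc), dtype=layer.values.dtype)
        for i in range(tr):
            for j in range(tc):
                cells = blocks[i, j][~mask_blocks[i, j]]
                if cells.size == 0:
                    continue
                codes, counts = np.unique(cells, return_counts=True)
                out[i, j] = codes[np.argmax(counts)]  # first max -> smallest code
    return RasterLayer(
        name=layer.name,
        kind=layer.kind,
        values=out,
        nodata_mask=out_mask,
        cell_size=target_cell_size,
        origin=layer.origin,
        category_labels=layer.category_labels,
    )


def one_hot_encode(layer: RasterLayer) -> list[RasterLayer]:
    """Expand a categorical layer into binary indicator layers.

    One 0/1 layer per category code, named ``<layer>__<label>``; at every
    valid cell exactly one indicator equals 1.
    """
    if layer.kind != "categorical":
        raise ValueError(f"one_hot_encode requires a categorical layer, got {layer.name!r}")
    out = []
    for code in layer.codes():
        label = (layer.category_labels or {}).get(int(code), str(int(code)))
        out.append(
            RasterLayer(
                name=f"{layer.name}__{label}",
                kind="continuous",
                values=(layer.values == code).astype(float),
                nodata_mask=layer.nodata_mask.copy(),
                cell_size=layer.cell_size,
                origin=layer.origin,
            )
        )
    return out


def distance_to(layer: RasterLayer, category: int) -> RasterLayer:
    """Euclidean distance to the nearest cell of a category.

    Each valid cell holds the planar distance (map units, cell centre to
    cell centre) to the nearest valid cell carrying ``category``; category
    cells hold 0. Nodata cells are never distance targets and stay nodata
    in the output.
    """
    target = (layer.values == category) & ~layer.nodata_mask
    if not target.any():
        raise ValueError(f"category {category} absent from layer {layer.name!r}")
    # exact EDT; recover integer squared offsets so the value is bit-identical
    # to a brute-force sqrt of the minimal integer squared distance
    _, (ri, ci) = ndimage.distance_transform_edt(~target, return_indices=True)
    rows, cols = np.indices(layer.shape)
    d2 = (rows - ri) ** 2 + (cols - ci) ** 2
    dist = np.sqrt(d2.astype(float)) * layer.cell_size
    dist[layer.nodata_mask] = 0.0
    label = (layer.category_labels or {}).get(int(category), str(int(category)))
    return RasterLayer(
        name=f"dist_to__{label}",
        kind="continuous",
        values=dist,
        nodata_mask=layer.nodata_mask.copy(),
        cell_size=layer.cell_size,
        origin=layer.origin,
    )


def pearson_correlation_matrix(
    stack: EnvStack, sample_points: pd.DataFrame, layer_names: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson r between continuous layers over sampled cells.

    ``sample_points`` needs ``x``/``y`` columns; rows falling on nodata are
    dropped. Zero-variance layers get r = 0 against every other layer (with
    a warning) so they can never survive a correlation screen on |r|.
    """
    if layer_names is None:
        layer_names = [l.name for l in stack.layers if l.kind == "continuous"]
    for name in layer_names:
        if stack[name].kind != "continuous":
            raise ValueError(f"layer {name!r} is not continuous")
    table = extract_values(stack, sample_points)
    table = table[table["valid"]]
    if len(table) < 3:
        raise ValueError(f"need >=3 valid sample points, got {len(table)}")
    data = table[layer_names].to_numpy(float)
    sd = data.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    corr = np.atleast_2d(corr)
    if degenerate.any():
        bad = [n for n, d in zip(layer_names, degenerate) if d]
        warnings.warn(f"zero-variance layers over the sample: {bad}; r set to 0")
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=layer_names, columns=layer_names)


def extract_values(stack: EnvStack, points: pd.DataFrame) -> pd.DataFrame:
    """Sample every layer of the stack at point locations.

    Returns one row per point with a column per layer plus a boolean
    ``valid`` column (False where the point falls on nodata).  Points
    outside the stack bounding box raise; if every point lands on nodata
    the extraction also raises, since nothing can be fitted from it.
    """
    x = points["x"].to_numpy(float)
    y = points["y"].to_numpy(float)
    xmin, ymin, xmax, ymax = stack.bounds()
    outside = (x < xmin) | (x >= xmax) | (y < ymin) | (y >= ymax)
    if outside.any():
        raise ValueError(f"{int(outside.sum())} point(s) outside the stack bounding box")
    row, col = stack.point_to_cell(x, y)
    out = {}
    for lyr in stack.layers:
        out[lyr.name] = lyr.values[row, col]
    valid = ~stack.nodata_mask[row, col]
    if not valid.any():
        raise ValueError("all points fall on nodata cells")
    df = pd.DataFrame(out, index=points.index)
    df["valid"] = valid
    return df
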