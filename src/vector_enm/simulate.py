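"""Synthetic island landscapes, virtual species and survey effort.

The generator emulates the data a small-island vector survey produces:
a ~10 m resolution raster stack with categorical land use (urban,
mangrove, forest/high scrub, scrub, salt plain, water, temporary
waterbodies), elevation, a protected-area mask and distance-to surfaces
for every category; virtual species whose true habitat suitability is a
known logistic function of one or two layers; and a multi-species survey
with spatially clustered, habitat-stratified effort. Everything is
deterministic given the seeds in the specs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .raster import EnvStack, RasterLayer, distance_to

__all__ = [
    "LandscapeSpec",
    "VirtualSpeciesSpec",
    "VirtualSpecies",
    "generate_landscape",
    "generate_virtual_species",
    "generate_survey",
    "preset_species_specs",
    "PRESET_NAMES",
]

LANDUSE_CODES = {
    1: "urban",
    2: "mangrove",
    3: "forest_high_scrub",
    4: "scrub",
    5: "salt_plain",
    6: "water",
    7: "temporary_water",
}
CODE_OF = {v: k for k, v in LANDUSE_CODES.items()}

# fixed response-transform shapes (scaled covariate u in [0, 1])
NEG_EXP_RATE = 5.0
GAUSS_CENTER = 0.5
GAUSS_WIDTH = 0.15

PRESET_NAMES = (
    "urban_dweller",
    "mangrove_dweller",
    "forest_dweller",
    "ephemeral_water_dweller",
)


@dataclass
class LandscapeSpec:
    """Parameters of a synthetic island raster stack."""

    nrows: int = 200
    ncols: int = 200
    cell_size: float = 10.0
    seed: int = 0
    elevation_range: tuple[float, float] = (0.0, 120.0)
    roughness: float = 8.0  # smoothing sigma in cells
    fractions: dict = field(
        default_factory=lambda: {
            "urban": 0.06,
            "mangrove": 0.08,
            "forest_high_scrub": 0.12,
            "salt_plain": 0.06,
            "water": 0.08,
            "temporary_water": 0.04,
        }
    )
    protected_fraction: float = 0.18

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if any(f < 0 or f > 1 for f in self.fractions.values()) or total > 1:
            raise ValueError("category fractions must lie in [0,1] and sum to <= 1")
        if min(self.nrows, self.ncols) < 50:
            raise ValueError("landscape presets need a grid of at least 50x50")


@dataclass(frozen=True)
class VirtualSpeciesSpec:
    """A virtual species: known response terms on named stack layers."""

    name: str
    terms: tuple  # of (variable, transform, coefficient)
    intercept: float = -3.5
    n_presences: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_presences < 4:
            raise ValueError("n_presences must be >= 4")


@dataclass
class VirtualSpecies:
    """Ground truth for parameter-recovery tests."""

    spec: VirtualSpeciesSpec
    truth: RasterLayer  # suitability in (0, 1) on valid cells
    occurrences: pd.DataFrame  # columns x, y, row, col
    generating_variables: list[str]

    @property
    def name(self) -> str:
        return self.spec.name

    def occurrence_cells(self) -> set[tuple[int, int]]:
        return set(zip(self.occurrences["row"], self.occurrences["col"]))


def _disks(shape, centers, radius) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = np.indices(shape)
    for (r, c) in centers:
        mask |= (rr - r) ** 2 + (cc - c) ** 2 <= radius ** 2
    return mask


def generate_landscape(spec: LandscapeSpec) -> EnvStack:
    """Build the synthetic island stack.

    Elevation is a smoothed seeded random field on a radially tapered
    island; land use follows elevation bands (water lowest, then mangrove
    and salt plain split by a second noise field, forest on the highest
    ground, scrub elsewhere) with urban as 1-3 compact patches and
    temporary waterbodies as low-elevation patches carved from scrub.
    Cells falling outside the island taper are nodata (open sea). The
    stack also carries a protected-area mask and a distance-to layer for
    every land-use category and for the protected area.
    """
    rng = np.random.default_rng(spec.seed)
    nr, nc = spec.nrows, spec.ncols
    rr, cc = np.indices((nr, nc))
    ry = (rr - (nr - 1) / 2.0) / (0.52 * nr)
    rx = (cc - (nc - 1) / 2.0) / (0.52 * nc)
    taper = 1.0 - (rx ** 2 + ry ** 2)
    noise = ndimage.gaussian_filter(rng.standard_normal((nr, nc)), spec.roughness)
    noise = noise / max(noise.std(), 1e-12)
    elev_field = taper + 0.45 * noise
    nodata = elev_field < 0.0
    valid = ~nodata
    n_valid = int(valid.sum())
    if n_valid < 100:
        raise ValueError("degenerate landscape: almost no land cells")

    # rank-quantile of the elevation field over valid cells
    q = np.zeros((nr, nc))
    order = np.argsort(elev_field[valid], kind="mergesort")
    ranks = np.empty(n_valid)
    ranks[order] = np.arange(n_valid)
    q[valid] = ranks / max(n_valid - 1, 1)

    f = spec.fractions
    landuse = np.full((nr, nc), CODE_OF["scrub"], dtype=int)
    landuse[valid & (q < f["water"])] = CODE_OF["water"]
    low_band = valid & (q >= f["water"]) & (q < f["water"] + f["mangrove"] + f["salt_plain"])
    noise2 = ndimage.gaussian_filter(rng.standard_normal((nr, nc)), spec.roughness)
    if low_band.any():
        frac_m = f["mangrove"] / max(f["mangrove"] + f["salt_plain"], 1e-12)
        cut = np.quantile(noise2[low_band], frac_m)
        landuse[low_band & (noise2 <= cut)] = CODE_OF["mangrove"]
        landuse[low_band & (noise2 > cut)] = CODE_OF["salt_plain"]
    landuse[valid & (q >= 1.0 - f["forest_high_scrub"])] = CODE_OF["forest_high_scrub"]

    def patchify(code: str, target_frac: float, host_q: tuple, n_patch_range: tuple):
        target_cells = target_frac * n_valid
        host = valid & (q >= host_q[0]) & (q < host_q[1]) & (landuse == CODE_OF["scrub"])
        hr, hc = np.nonzero(host)
        if hr.size == 0:
            hr, hc = np.nonzero(valid & (landuse == CODE_OF["scrub"]))
        n_patches = int(rng.integers(n_patch_range[0], n_patch_range[1] + 1))
        idx = rng.choice(hr.size, size=min(n_patches, hr.size), replace=False)
        radius = np.sqrt(target_cells / (np.pi * max(n_patches, 1)))
        disk = _disks((nr, nc), list(zip(hr[idx], hc[idx])), radius)
        sel = disk & valid & (landuse != CODE_OF["water"])
        landuse[sel] = CODE_OF[code]

    patchify("urban", f["urban"], (0.30, 0.85), (1, 3))
    patchify("temporary_water", f["temporary_water"], (f["water"], 0.45), (2, 5))

    # guarantee every category with a positive target exists somewhere
    for name, frac in f.items():
        if frac > 0 and not np.any(landuse[valid] == CODE_OF[name]):
            scr, scc = np.nonzero(valid & (landuse == CODE_OF["scrub"]))
            pick = rng.choice(scr.size, size=min(5, scr.size), replace=False)
            landuse[scr[pick], scc[pick]] = CODE_OF[name]

    pr, pc = np.nonzero(valid)
    n_blobs = int(rng.integers(1, 3))
    centers = rng.choice(pr.size, size=n_blobs, replace=False)
    radius = np.sqrt(spec.protected_fraction * n_valid / (np.pi * n_blobs))
    protected = (_disks((nr, nc), list(zip(pr[centers], pc[centers])), radius) & valid)

    emin, emax = spec.elevation_range
    ev = elev_field.copy()
    ev[valid] = emin + (emax - emin) * (ev[valid] - ev[valid].min()) / (
        ev[valid].max() - ev[valid].min()
    )
    ev[nodata] = 0.0

    geom = dict(cell_size=spec.cell_size, origin=(0.0, 0.0))
    elevation = RasterLayer("elevation", "continuous", ev, nodata.copy(), **geom)
    landuse_layer = RasterLayer(
        "landuse", "categorical", landuse, nodata.copy(),
        category_labels=dict(LANDUSE_CODES), **geom
    )
    protected_layer = RasterLayer(
        "protected", "categorical", protected.astype(int), nodata.copy(),
        category_labels={0: "unprotected", 1: "protected"}, **geom
    )
    stack = EnvStack([elevation, landuse_layer, protected_layer])
    for code in sorted(LANDUSE_CODES):
        stack.add(distance_to(landuse_layer, code))
    dprot = distance_to(protected_layer, 1)
    dprot.name = "dist_to__protected"
    stack.add(dprot)
    return stack


def _transform(u: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return u
    if kind == "negative_exponential":
        return np.exp(-NEG_EXP_RATE * u)
    if kind == "gaussian":
        return np.exp(-((u - GAUSS_CENTER) ** 2) / (2 * GAUSS_WIDTH ** 2))
    raise ValueError(f"unknown transform {kind!r}")


def generate_virtual_species(stack: EnvStack, spec: VirtualSpeciesSpec) -> VirtualSpecies:
    """Create a virtual species with a known suitability surface.

    True suitability is ``logistic(intercept + sum coef * transform(u))``
    where u is the named layer min-max scaled over valid cells; occurrence
    cells are drawn without replacement with probability proportional to
    suitability.
    """
    valid = ~stack.nodata_mask
    n_valid = int(valid.sum())
    if n_valid < spec.n_presences:
        raise ValueError("fewer valid cells than requested presences")
    eta = np.full(stack.shape, spec.intercept, dtype=float)
    for var, kind, coef in spec.terms:
        layer = stack[var]
        v = layer.values.astype(float)
        vmin, vmax = v[valid].min(), v[valid].max()
        if vmin == vmax:
            raise ValueError(f"layer {var!r} is constant; cannot define a response")
        u = np.clip((v - vmin) / (vmax - vmin), 0.0, 1.0)
        eta += coef * _transform(u, kind)
    s = expit(eta)
    if s[valid].max() - s[valid].min() < 1e-9:
        raise ValueError("degenerate virtual species: constant suitability surface")
    rng = np.random.default_rng(spec.seed)
    vr, vc = np.nonzero(valid)
    p = s[valid] / s[valid].sum()
    pick = rng.choice(n_valid, size=spec.n_presences, replace=False, p=p)
    rows, cols = vr[pick], vc[pick]
    x0, y0 = stack.origin
    occ = pd.DataFrame(
        {
            "x": x0 + (cols + 0.5) * stack.cell_size,
            "y": y0 + (rows + 0.5) * stack.cell_size,
            "row": rows,
            "col": cols,
        }
    )
    truth_vals = np.where(valid, s, 0.0)
    truth = RasterLayer(
        f"truth_{spec.name}", "continuous", truth_vals, stack.nodata_mask,
        cell_size=stack.cell_size, origin=stack.origin,
    )
    return VirtualSpecies(
        spec=spec,
        truth=truth,
        occurrences=occ,
        generating_variables=[t[0] for t in spec.terms],
    )


def preset_species_specs(n_presences: int = 40, seed: int = 0) -> dict[str, VirtualSpeciesSpec]:
    """The four shipped virtual-species presets, one per habitat group."""
    mk = lambda i, name, var: VirtualSpeciesSpec(
        name=name,
        terms=((var, "negative_exponential", 6.0),),
        intercept=-3.5,
        n_presences=n_presences,
        seed=seed + i,
    )
    return {
        "urban_dweller": mk(1, "urban_dweller", "dist_to__urban"),
        "mangrove_dweller": mk(2, "mangrove_dweller", "dist_to__mangrove"),
        "forest_dweller": mk(3, "forest_dweller", "dist_to__forest_high_scrub"),
        "ephemeral_water_dweller": mk(
            4, "ephemeral_water_dweller", "dist_to__temporary_water"
        ),
    }


def generate_survey(
    stack: EnvStack,
    species_list: list[VirtualSpecies],
    n_sites: int = 300,
    cluster_sd: float = 6.0,
    sites_per_cluster: int = 10,
    detection_rate: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a habitat-stratified, spatially clustered survey.

    Site quotas are allocated to land-use strata proportional to their
    area (minimum one site per non-empty stratum) and drawn around seeded
    cluster centres within each stratum. Every species' occurrence cells
    are also visited. At each site a species is recorded when the site is
    one of its occurrence cells, or otherwise detected with probability
    ``detection_rate`` times its true suitability — so well-surveyed,
    broadly suitable cells accumulate multi-species records.
    """
    if len(species_list) < 2:
        raise ValueError("survey generation needs at least 2 species")
    rng = np.random.default_rng(seed)
    landuse = stack["landuse"]
    valid = ~stack.nodata_mask
    site_cells: set[tuple[int, int]] = set()
    codes = landuse.codes()
    areas = {c: int(np.sum((landuse.values == c) & valid)) for c in codes}
    total_area = sum(areas.values())
    for code in codes:
        if areas[code] == 0:
            warnings.warn(f"empty land-use stratum {code}; skipped")
            continue
        quota = max(1, int(round(n_sites * areas[code] / total_area)))
        sr, sc = np.nonzero((landuse.values == code) & valid)
        n_centers = max(1, int(np.ceil(quota / sites_per_cluster)))
        centers = rng.choice(sr.size, size=min(n_centers, sr.size), replace=False)
        for ci, center in enumerate(centers):
            n_here = quota // len(centers) + (1 if ci < quota % len(centers) else 0)
            d2 = (sr - sr[center]) ** 2 + (sc - sc[center]) ** 2
            w = np.exp(-d2 / (2.0 * cluster_sd ** 2))
            w /= w.sum()
            n_here = min(n_here, sr.size)
            pick = rng.choice(sr.size, size=n_here, replace=False, p=w)
            site_cells.update(zip(sr[pick].tolist(), sc[pick].tolist()))
    for sp in species_list:
        site_cells.update(sp.occurrence_cells())

    records = []
    x0, y0 = stack.origin
    s = stack.cell_size
    occ_sets = {sp.name: sp.occurrence_cells() for sp in species_list}
    for (r, c) in sorted(site_cells):
        for sp in species_list:
            hit = (r, c) in occ_sets[sp.name]
            if not hit:
                hit = rng.random() < detection_rate * sp.truth.values[r, c]
            if hit:
                records.append(
                    {
                        "species": sp.name,
                        "x": x0 + (c + 0.5) * s,
                        "y": y0 + (r + 0.5) * s,
                        "life_stage": str(rng.choice(["larva", "adult"])),
                    }
                )
    return pd.DataFrame.from_records(records, columns=["species", "x", "y", "life_stage"])
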