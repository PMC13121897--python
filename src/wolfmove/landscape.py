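"""Per-track landscape covariates inside 1-km influence areas.

A daily track's "influence area" is the 1-km buffer around the polyline
through its fixes.  Within it we measure proxies of anthropogenic disturbance
(kernel density of population-weighted settlements, road-class length
densities), terrain ruggedness, and five refuge-cover pattern metrics
(percent cover, patch density, mean patch size, patch cohesion, fractal
dimension).  All geometry is planar, in km.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from skimage.measure import label as _cc_label

from .raster import Raster

# quad segments for circle approximation in buffers; high enough that a unit
# disk's area error is ~1e-4 relative
_BUFFER_QUAD_SEGS = 64


@dataclass
class InfluenceArea:
    """1-km buffer polygon around one daily track."""

    track_id: str
    polygon: Polygon
    radius_km: float

    @property
    def area_km2(self) -> float:
        return self.polygon.area


@dataclass
class RefugePatch:
    patch_id: int
    cell_count: int
    perimeter_edges: int  # exterior cell edges, in edge units
    cell_area_km2: float

    @property
    def area_km2(self) -> float:
        return self.cell_count * self.cell_area_km2

    @property
    def perimeter_km(self) -> float:
        return self.perimeter_edges * np.sqrt(self.cell_area_km2)

    @property
    def fractal_dimension(self) -> float:
        """Perimeter-area fractal dimension, 2*ln(0.25 P)/ln(A) in cell units.

        A square of any size gives exactly 1; a maximally ragged
        (diagonal-chain) patch gives 2.  Single-cell patches are assigned 1
        by convention (the formula is 0/0 there).
        """
        if self.cell_count <= 1:
            return 1.0
        return 2.0 * np.log(0.25 * self.perimeter_edges) / np.log(self.cell_count)


@dataclass
class RefugeMetrics:
    refuge_cover_pct: float
    patch_density_per_km2: float
    mean_patch_size_km2: float
    mean_cohesion: float
    mean_fdi: float
    n_patches: int
    n_fdi_clipped: int = 0


def buffer_track(xs, ys, radius_km: float = 1.0, track_id: str = "") -> InfluenceArea:
    """Buffer the polyline through the fixes; a single fix buffers to a disk."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0:
        raise ValueError("cannot buffer a track with no fixes")
    if xs.size == 1:
        geom = Point(xs[0], ys[0])
    else:
        geom = LineString(np.column_stack([xs, ys]))
    poly = geom.buffer(radius_km, quad_segs=_BUFFER_QUAD_SEGS)
    return InfluenceArea(track_id=track_id, polygon=poly, radius_km=radius_km)


def make_grid(extent_km: tuple[float, float], res_km: float) -> Raster:
    """All-zero raster template covering [0, width] x [0, height]."""
    nx = int(round(extent_km[0] / res_km))
    ny = int(round(extent_km[1] / res_km))
    return Raster(np.zeros((ny, nx)), 0.0, 0.0, res_km)


def settlement_kernel_density(
    points: np.ndarray,
    weights: np.ndarray | None,
    bandwidth_km: float,
    template: Raster,
) -> Raster:
    """Quartic (biweight) kernel density surface of weighted settlement points.

    K(d) = 3/(pi h^2) (1 - d^2/h^2)^2 for d < h, so the surface integrates to
    the total weight and has units weight per km^2.  With weights = population
    this is the human population density proxy; with unit weights it is the
    settlement density surface.
    """
    if bandwidth_km <= 0:
        raise ValueError("bandwidth must be positive")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.zeros_like(template.values, dtype=float)
    if points.size == 0:
        return Raster(out, template.x0, template.y0, template.res_km)
    if weights is None:
        weights = np.ones(len(points))
    weights = np.asarray(weights, dtype=float)
    res = template.res_km
    ny, nx = out.shape
    h2 = bandwidth_km**2
    norm = 3.0 / (np.pi * h2)
    r_cells = int(np.ceil(bandwidth_km / res)) + 1
    xs, ys = template.cell_centers()
    for (px, py), w in zip(points, weights):
        j0 = max(0, int((px - template.x0) / res) - r_cells)
        j1 = min(nx, int((px - template.x0) / res) + r_cells + 1)
        i0 = max(0, int((py - template.y0) / res) - r_cells)
        i1 = min(ny, int((py - template.y0) / res) + r_cells + 1)
        if j0 >= j1 or i0 >= i1:
            continue
        dx = xs[j0:j1] - px
        dy = ys[i0:i1] - py
        d2 = dy[:, None] ** 2 + dx[None, :] ** 2
        u = 1.0 - d2 / h2
        np.clip(u, 0.0, None, out=u)
        out[i0:i1, j0:j1] += w * norm * u**2
    return Raster(out, template.x0, template.y0, template.res_km)


def road_density(roads: dict[str, list[LineString]], area: InfluenceArea, road_class: str) -> float:
    """Clipped length (km) of one road class inside the polygon, per km^2."""
    if road_class not in roads:
        raise KeyError(f"unknown road class {road_class!r}; have {sorted(roads)}")
    total = 0.0
    for line in roads[road_class]:
        total += line.intersection(area.polygon).length
    return total / area.area_km2


def terrain_ruggedness(elevation: Raster) -> Raster:
    """Riley terrain ruggedness index: sqrt of the summed squared elevation
    differences to the 8 neighbours; edge cells use the neighbours they have."""
    z = np.asarray(elevation.values, dtype=float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("elevation raster must be at least 3x3")
    padded = np.pad(z, 1, mode="constant", constant_values=np.nan)
    ssq = np.zeros_like(z)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            nb = padded[1 + di : 1 + di + z.shape[0], 1 + dj : 1 + dj + z.shape[1]]
            diff = z - nb
            ssq += np.where(np.isnan(nb), 0.0, diff**2)
    return Raster(np.sqrt(ssq), elevation.x0, elevation.y0, elevation.res_km)


def polygon_cell_mask(raster: Raster, polygon: Polygon) -> tuple[np.ndarray, tuple[int, int]]:
    """Boolean mask of window cells whose centers fall inside the polygon.

    Returns the mask over the bounding-box window plus the window's (row, col)
    offset in the full raster.
    """
    xmin, ymin, xmax, ymax = polygon.bounds
    win, (i0, j0) = raster.window(xmin, ymin, xmax, ymax)
    if win.values.size == 0:
        return np.zeros((0, 0), dtype=bool), (i0, j0)
    xs, ys = win.cell_centers()
    xg, yg = np.meshgrid(xs, ys)
    mask = shapely.contains_xy(polygon, xg.ravel(), yg.ravel()).reshape(xg.shape)
    return mask, (i0, j0)


def raster_mean_over_area(raster: Raster, area: InfluenceArea) -> float:
    """Area-weighted mean of a raster surface over the influence area
    (approximated by the mean over cells whose centers fall inside)."""
    mask, (i0, j0) = polygon_cell_mask(raster, area.polygon)
    if mask.any():
        win = raster.values[i0 : i0 + mask.shape[0], j0 : j0 + mask.shape[1]]
        return float(win[mask].mean())
    c = area.polygon.centroid
    return float(raster.sample(np.array([c.x]), np.array([c.y]))[0])


def label_patches(
    refuge: Raster, area: InfluenceArea, connectivity: int = 2
) -> tuple[list[RefugePatch], int]:
    """Connected refuge patches clipped to the influence area.

    Patches are connected components (8-connectivity by default) of refuge
    cells whose centers lie inside the polygon; the perimeter counts exterior
    cell edges of the clipped patch.  Returns (patches, n_cells_in_area).
    """
    mask, (i0, j0) = polygon_cell_mask(refuge, area.polygon)
    if mask.size == 0:
        return [], 0
    win = refuge.values[i0 : i0 + mask.shape[0], j0 : j0 + mask.shape[1]]
    clipped = (np.asarray(win) > 0) & mask
    n_area_cells = int(mask.sum())
    if not clipped.any():
        return [], n_area_cells
    labels = _cc_label(clipped, connectivity=connectivity)
    cell_area = refuge.cell_area_km2
    # internal 4-adjacencies per label, to get perimeter = 4*n - 2*adj
    patches = []
    counts = np.bincount(labels.ravel())
    horiz = labels[:, :-1]
    horiz_match = (horiz == labels[:, 1:]) & (horiz > 0)
    vert = labels[:-1, :]
    vert_match = (vert == labels[1:, :]) & (vert > 0)
    adj = np.bincount(horiz[horiz_match].ravel(), minlength=counts.size) + np.bincount(
        vert[vert_match].ravel(), minlength=counts.size
    )
    for lab in range(1, counts.size):
        n = int(counts[lab])
        if n == 0:
            continue
        perim = 4 * n - 2 * int(adj[lab])
        patches.append(RefugePatch(patch_id=lab, cell_count=n, perimeter_edges=perim, cell_area_km2=cell_area))
    return patches, n_area_cells


def refuge_metrics(patches: list[RefugePatch], area: InfluenceArea, n_area_cells: int) -> RefugeMetrics:
    """The five refuge-cover metrics over one influence area.

    Cohesion follows the FRAGSTATS patch-cohesion formula with perimeters in
    cell-edge counts and areas in cell counts, reported on [0, 1] (the
    conventional value divided by 100).  A single isolated one-cell patch
    gives exactly 0.  Zero patches yield cover 0, density 0 and NaN for the
    per-patch means (flagged via n_patches).
    """
    area_km2 = area.area_km2
    if not patches:
        return RefugeMetrics(0.0, 0.0, float("nan"), float("nan"), float("nan"), 0)
    cell_area = patches[0].cell_area_km2
    refuge_cells = sum(p.cell_count for p in patches)
    cover_pct = 100.0 * refuge_cells / n_area_cells if n_area_cells else 0.0
    patch_density = len(patches) / area_km2
    mean_size = float(np.mean([p.area_km2 for p in patches]))
    fdis = np.array([p.fractal_dimension for p in patches])
    n_clipped = int(np.sum((fdis < 1.0) | (fdis > 2.0)))
    mean_fdi = float(np.clip(fdis, 1.0, 2.0).mean())
    p_edges = np.array([p.perimeter_edges for p in patches], dtype=float)
    a_cells = np.array([p.cell_count for p in patches], dtype=float)
    z = max(n_area_cells, 2)
    ratio = p_edges.sum() / (p_edges * np.sqrt(a_cells)).sum()
    cohesion = (1.0 - ratio) / (1.0 - 1.0 / np.sqrt(z))
    return RefugeMetrics(
        refuge_cover_pct=float(cover_pct),
        patch_density_per_km2=float(patch_density),
        mean_patch_size_km2=mean_size,
        mean_cohesion=float(np.clip(cohesion, 0.0, 1.0)),
        mean_fdi=mean_fdi,
        n_patches=len(patches),
        n_fdi_clipped=n_clipped,
    )


@dataclass
class LandscapeLayers:
    """The input layers covariate extraction needs, in one bundle."""

    refuge: Raster
    elevation: Raster
    settlements: np.ndarray  # (n, 2) in km
    settlement_weights: np.ndarray  # population per settlement
    roads: dict[str, list[LineString]]
    tri: Raster | None = None
    pop_kd: Raster | None = None
    settle_kd: Raster | None = None
    kd_grid_res_km: float = 0.1
    kernel_bandwidth_km: float = 1.0

    def prepare(self) -> "LandscapeLayers":
        """Precompute the kernel-density and TRI surfaces once."""
        if self.tri is None:
            self.tri = terrain_ruggedness(self.elevation)
        if self.pop_kd is None or self.settle_kd is None:
            xmin, ymin, xmax, ymax = self.refuge.extent
            template = Raster(
                np.zeros(
                    (
                        int(round((ymax - ymin) / self.kd_grid_res_km)),
                        int(round((xmax - xmin) / self.kd_grid_res_km)),
                    )
                ),
                xmin,
                ymin,
                self.kd_grid_res_km,
            )
            self.pop_kd = settlement_kernel_density(
                self.settlements, self.settlement_weights, self.kernel_bandwidth_km, template
            )
            self.settle_kd = settlement_kernel_density(
                self.settlements, None, self.kernel_bandwidth_km, template
            )
        return self


def load_layers(directory, kernel_bandwidth_km: float = 1.0) -> LandscapeLayers:
    """Read landscape layers from disk: refuge.tif / elevation.tif with JSON
    sidecars, settlements.geojson (Point features with a ``population``
    property) and roads.geojson (LineString features with ``road_class``).
    All coordinates must already be in the same planar km CRS."""
    import json
    from pathlib import Path

    directory = Path(directory)
    refuge = Raster.read(directory / "refuge.tif")
    elevation = Raster.read(directory / "elevation.tif")
    sj = json.loads((directory / "settlements.geojson").read_text())
    pts, weights = [], []
    for feat in sj["features"]:
        pts.append(feat["geometry"]["coordinates"])
        weights.append(feat["properties"].get("population", 1))
    rj = json.loads((directory / "roads.geojson").read_text())
    roads: dict[str, list[LineString]] = {}
    for feat in rj["features"]:
        cls = feat["properties"]["road_class"]
        roads.setdefault(cls, []).append(LineString(feat["geometry"]["coordinates"]))
    return LandscapeLayers(
        refuge=refuge,
        elevation=elevation,
        settlements=np.asarray(pts, dtype=float).reshape(-1, 2),
        settlement_weights=np.asarray(weights, dtype=float),
        roads=roads,
        kernel_bandwidth_km=kernel_bandwidth_km,
    )


def extract_covariates_for_track(
    track_id: str,
    xs: np.ndarray,
    ys: np.ndarray,
    layers: LandscapeLayers,
    buffer_radius_km: float = 1.0,
) -> dict:
    """All continuous covariates for one daily track (see CovariateRecord)."""
    layers.prepare()
    area = buffer_track(xs, ys, radius_km=buffer_radius_km, track_id=track_id)
    rec: dict = {"track_id": track_id, "influence_area_km2": area.area_km2}
    rec["pop_density"] = raster_mean_over_area(layers.pop_kd, area)
    rec["settlement_density"] = raster_mean_over_area(layers.settle_kd, area)
    # raw point count per buffer area, the alternative settlement measure
    pts = layers.settlements
    if len(pts):
        inside = shapely.contains_xy(area.polygon, pts[:, 0], pts[:, 1])
        rec["settlement_count_density"] = float(inside.sum()) / area.area_km2
    else:
        rec["settlement_count_density"] = 0.0
    rec["primary_road"] = road_density(layers.roads, area, "primary")
    rec["secondary_road"] = road_density(layers.roads, area, "secondary")
    rec["tri"] = raster_mean_over_area(layers.tri, area)
    patches, n_cells = label_patches(layers.refuge, area)
    rm = refuge_metrics(patches, area, n_cells)
    rec.update(
        refuge_cover_pct=rm.refuge_cover_pct,
        patch_density=rm.patch_density_per_km2,
        mean_patch_size=rm.mean_patch_size_km2,
        mean_cohesion=rm.mean_cohesion,
        mean_fdi=rm.mean_fdi,
        n_patches=rm.n_patches,
    )
    return rec
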