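"""Minimal planar raster container and text-friendly I/O.

All coordinates are kilometres in an arbitrary planar (projected) CRS; rasters
are row-major arrays whose [0, 0] element is the lower-left cell.  Real-data
users must pre-project their layers — no geodesy happens anywhere in this
package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

try:  # tifffile is the raster backend; sidecar JSON carries georeferencing
    import tifffile
except ImportError:  # pragma: no cover
    tifffile = None


@dataclass
class Raster:
    """A 2-D grid of values anchored at (x0, y0) with square cells.

    Attributes
    ----------
    values : ndarray, shape (ny, nx)
        Cell values, row 0 at the bottom (south) edge.
    x0, y0 : float
        Lower-left corner of the grid in km.
    res_km : float
        Cell edge length in km.
    """

    values: np.ndarray
    x0: float
    y0: float
    res_km: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_km2(self) -> float:
        return self.res_km**2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        ny, nx = self.values.shape
        return (self.x0, self.y0, self.x0 + nx * self.res_km, self.y0 + ny * self.res_km)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.res_km
        ys = self.y0 + (np.arange(ny) + 0.5) * self.res_km
        return xs, ys

    def window(self, xmin: float, ymin: float, xmax: float, ymax: float) -> tuple["Raster", tuple[int, int]]:
        """Sub-raster covering the bounding box (clipped to the grid).

        Returns the window and the (row, col) offset of its origin.
        """
        ny, nx = self.values.shape
        i0 = max(0, int(np.floor((ymin - self.y0) / self.res_km)))
        j0 = max(0, int(np.floor((xmin - self.x0) / self.res_km)))
        i1 = min(ny, int(np.ceil((ymax - self.y0) / self.res_km)))
        j1 = min(nx, int(np.ceil((xmax - self.x0) / self.res_km)))
        sub = Raster(self.values[i0:i1, j0:j1], self.x0 + j0 * self.res_km, self.y0 + i0 * self.res_km, self.res_km)
        return sub, (i0, j0)

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell lookup; points outside the grid are clamped to the edge."""
        ny, nx = self.values.shape
        j = np.clip(((np.asarray(x) - self.x0) / self.res_km).astype(int), 0, nx - 1)
        i = np.clip(((np.asarray(y) - self.y0) / self.res_km).astype(int), 0, ny - 1)
        return self.values[i, j]

    def write(self, path: str | Path) -> None:
        """Write as TIFF with a JSON sidecar holding origin and resolution."""
        if tifffile is None:  # pragma: no cover
            raise RuntimeError("tifffile is required for raster I/O")
        path = Path(path)
        tifffile.imwrite(path, np.asarray(self.values, dtype=np.float32))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"x0": self.x0, "y0": self.y0, "res_km": self.res_km}))

    @classmethod
    def read(cls, path: str | Path) -> "Raster":
        if tifffile is None:  # pragma: no cover
            raise RuntimeError("tifffile is required for raster I/O")
        path = Path(path)
        values = np.asarray(tifffile.imread(path), dtype=float)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(values, meta["x0"], meta["y0"], meta["res_km"])


def disk_mean(raster: Raster, radius_km: float) -> Raster:
    """Smooth a raster by averaging over a disk of the given radius.

    Used to turn point-supported surfaces into local-neighbourhood means,
    e.g. road length per unit area within 1 km of each cell.
    """
    from scipy.signal import fftconvolve

    r_cells = max(1, int(round(radius_km / raster.res_km)))
    yy, xx = np.mgrid[-r_cells : r_cells + 1, -r_cells : r_cells + 1]
    kernel = ((xx**2 + yy**2) <= r_cells**2).astype(float)
    kernel /= kernel.sum()
    sm = fftconvolve(raster.values, kernel, mode="same")
    return Raster(sm, raster.x0, raster.y0, raster.res_km)
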