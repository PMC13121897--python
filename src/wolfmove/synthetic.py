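"""Synthetic landscapes and GPS tracks with known ground truth.

The study's raw telemetry is legally protected, so every downstream stage is
exercised on simulated data.  The generator emulates the study system: a
densely settled Atlantic landscape (~3 settlements/km^2, ~3.5 km of road per
km^2, patchy refuge vegetation) and 2-h GPS fixes over tens to hundreds of
days per individual, with mean step lengths of ~0.8 km and mean daily travel
of ~9 km.

Ground truth enters at the *day* level: for each simulated day the expected
square root of the daily distance equals

    intercept + sum_k beta_k * z_k(day's area) + a_individual + b_grid_cell

where z_k are standardized local covariate surfaces.  The whole day's
step-length distribution is scaled to hit a draw from that model, which makes
the truth exactly recoverable by the daily pipeline (the generator also
writes the realized covariates and linear predictor per day, so recovery
tests need no re-extraction).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely import box as shapely_box
from shapely.geometry import LineString, mapping
from shapely.ops import substring
from skimage.measure import block_reduce

from .landscape import LandscapeLayers, settlement_kernel_density, terrain_ruggedness
from .raster import Raster, disk_mean

CONTINUOUS_SURFACES = (
    "pop_density",
    "settlement_density",
    "primary_road",
    "secondary_road",
    "tri",
    "refuge_dim1",
    "refuge_dim2",
)
CATEGORICAL_ATTRS = {
    "sex": ("female", "male"),
    "age": ("subadult", "adult"),
    "status": ("pack", "nonpack"),
    "diet": ("wild", "livestock", "horses"),
    "period": ("mating", "breeding", "nonreproductive"),
}


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    Defaults mirror the study region: 3 settlements/km^2, 3.5 km/km^2 of
    paved road split into sparse primary and dense secondary networks,
    heavy-tailed settlement populations, and ~50% patchy refuge cover
    rasterized at 10 m.
    """

    extent_km: tuple[float, float] = (10.0, 10.0)
    raster_resolution_m: float = 10.0
    n_settlements: int | None = None  # default: 3 per km^2
    population_lognormal: tuple[float, float] = (3.0, 1.2)  # heavy-tailed sizes
    road_km_per_km2: dict = field(default_factory=lambda: {"primary": 0.5, "secondary": 3.0})
    refuge_target_cover: float = 0.5
    refuge_patchiness_m: float = 200.0
    elevation_relief_m: float = 400.0
    seed: int = 0

    def __post_init__(self):
        w, h = self.extent_km
        if w <= 0 or h <= 0:
            raise ValueError("extent must be positive")
        if not 0.0 <= self.refuge_target_cover <= 1.0:
            raise ValueError("refuge_target_cover must be in [0, 1]")
        res_km = self.raster_resolution_m / 1000.0
        for e in (w, h):
            if abs(round(e / res_km) - e / res_km) > 1e-9:
                raise ValueError("raster resolution must divide the extent")
        for cls, dens in self.road_km_per_km2.items():
            if dens < 0:
                raise ValueError(f"negative road density for class {cls!r}")
            if dens > 100:
                raise ValueError(f"road density {dens} km/km^2 for {cls!r} exceeds geometric capacity")
        if self.n_settlements is None:
            self.n_settlements = int(round(3.0 * w * h))

    @property
    def area_km2(self) -> float:
        return self.extent_km[0] * self.extent_km[1]


@dataclass
class TruthTable:
    """Ground-truth coefficients on the sqrt(daily distance) scale.

    ``beta`` keys are model term names: continuous surfaces
    (e.g. ``settlement_density``), categorical indicators (``diet:livestock``),
    or interactions joined with ``x`` as in
    ``pop_density x settlement_density`` (spaces optional).
    """

    beta: dict[str, float] = field(default_factory=dict)
    intercept: float = 3.0  # sqrt-km; gives ~9 km mean daily distance
    sigma_individual: float = 0.4
    sigma_cell: float = 0.5
    sigma_resid: float = 0.8
    zero_inflation_pi: float = 0.0

    def __post_init__(self):
        for name, sd in (
            ("sigma_individual", self.sigma_individual),
            ("sigma_cell", self.sigma_cell),
            ("sigma_resid", self.sigma_resid),
        ):
            if sd < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.zero_inflation_pi <= 1.0:
            raise ValueError("zero_inflation_pi must be in [0, 1]")
        for key in self.beta:
            for part in _split_interaction(key):
                _validate_term(part)

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta": self.beta,
                "intercept": self.intercept,
                "sigma_individual": self.sigma_individual,
                "sigma_cell": self.sigma_cell,
                "sigma_resid": self.sigma_resid,
                "zero_inflation_pi": self.zero_inflation_pi,
            },
            indent=2,
        )


def _split_interaction(key: str) -> list[str]:
    return [p.strip() for p in key.split(" x ")] if " x " in key else [key.strip()]


def _validate_term(term: str) -> None:
    if term in CONTINUOUS_SURFACES:
        return
    if ":" in term:
        attr, level = term.split(":", 1)
        if attr in CATEGORICAL_ATTRS and level in CATEGORICAL_ATTRS[attr]:
            return
    raise ValueError(f"truth table references unknown predictor {term!r}")


@dataclass
class SimConfig:
    """GPS sampling design: 2-h fixes, 16:00->14:00 daily windows."""

    n_individuals: int = 26
    days_per_individual: int | tuple[int, int] = (52, 397)
    fix_interval_h: int = 2
    missingness_rate: float = 0.02
    start_date: date = date(2010, 1, 1)
    seed: int = 0

    def __post_init__(self):
        if 24 % self.fix_interval_h != 0:
            raise ValueError("fix interval must divide 24 h")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValueError("missingness_rate must be in [0, 1)")


@dataclass
class Landscape:
    """A generated landscape plus (lazily built) simulator covariate surfaces."""

    config: LandscapeConfig
    refuge: Raster
    elevation: Raster
    settlements: np.ndarray
    settlement_weights: np.ndarray
    roads: dict[str, list[LineString]]
    realized_cover: float
    _surfaces: dict | None = None

    def to_layers(self, kernel_bandwidth_km: float = 1.0) -> LandscapeLayers:
        return LandscapeLayers(
            refuge=self.refuge,
            elevation=self.elevation,
            settlements=self.settlements,
            settlement_weights=self.settlement_weights,
            roads=self.roads,
            kernel_bandwidth_km=kernel_bandwidth_km,
        )

    def covariate_surfaces(self, coarse_res_km: float = 0.1, radius_km: float = 1.0) -> dict[str, Raster]:
        """Standardized (z-scored over cells) 1-km-disk-mean covariate surfaces.

        These define the generative covariates z_k: kernel densities of
        population and settlements, road length densities per class, mean
        terrain ruggedness, and two refuge axes — dim1 = local refuge cover
        (extent/cohesion axis) and dim2 = local refuge edge density (shape
        complexity axis).
        """
        if self._surfaces is not None:
            return self._surfaces
        w, h = self.config.extent_km
        template = Raster(
            np.zeros((int(round(h / coarse_res_km)), int(round(w / coarse_res_km)))), 0.0, 0.0, coarse_res_km
        )
        surfaces: dict[str, Raster] = {}
        pop = settlement_kernel_density(self.settlements, self.settlement_weights, radius_km, template)
        sett = settlement_kernel_density(self.settlements, None, radius_km, template)
        surfaces["pop_density"] = disk_mean(pop, radius_km)
        surfaces["settlement_density"] = disk_mean(sett, radius_km)
        for cls in ("primary", "secondary"):
            surfaces[cls + "_road"] = disk_mean(_road_length_raster(self.roads.get(cls, []), template), radius_km)
        factor = max(1, int(round(coarse_res_km / self.elevation.res_km)))
        tri_fine = terrain_ruggedness(self.elevation)
        tri_coarse = Raster(
            block_reduce(tri_fine.values, (factor, factor), np.mean), 0.0, 0.0, coarse_res_km
        )
        surfaces["tri"] = disk_mean(tri_coarse, radius_km)
        ref_coarse = Raster(
            block_reduce(self.refuge.values.astype(float), (factor, factor), np.mean), 0.0, 0.0, coarse_res_km
        )
        surfaces["refuge_dim1"] = disk_mean(ref_coarse, radius_km)
        gy, gx = np.gradient(self.refuge.values.astype(float))
        edge = Raster(
            block_reduce(np.hypot(gx, gy), (factor, factor), np.mean), 0.0, 0.0, coarse_res_km
        )
        surfaces["refuge_dim2"] = disk_mean(edge, radius_km)
        # z-score each surface over its cells so truth coefficients are on the
        # standardized scale the models use
        for name, r in surfaces.items():
            v = r.values
            sd = v.std()
            surfaces[name] = Raster((v - v.mean()) / (sd if sd > 0 else 1.0), r.x0, r.y0, r.res_km)
        self._surfaces = surfaces
        return surfaces


def _road_length_raster(lines: list[LineString], template: Raster) -> Raster:
    """Road length per unit area (km/km^2) accumulated on the template grid."""
    out = np.zeros_like(template.values)
    res = template.res_km
    spacing = res / 4.0
    ny, nx = out.shape
    for line in lines:
        n = max(2, int(np.ceil(line.length / spacing)) + 1)
        d = np.linspace(0.0, line.length, n)
        pts = [line.interpolate(t) for t in d]
        seg = line.length / (n - 1)
        for p in pts:
            j = min(nx - 1, max(0, int((p.x - template.x0) / res)))
            i = min(ny - 1, max(0, int((p.y - template.y0) / res)))
            out[i, j] += seg
    return Raster(out / template.cell_area_km2, template.x0, template.y0, template.res_km)


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate refuge, elevation, settlements and roads for one seed.

    The refuge raster is smoothed Gaussian noise thresholded at the quantile
    that yields the target cover, which produces patches whose size scales
    with ``refuge_patchiness_m``.  Roads are random straight segments clipped
    to the extent, accumulated until each class hits its target length
    density exactly (the final segment is trimmed).
    """
    rng = np.random.default_rng(config.seed)
    res_km = config.raster_resolution_m / 1000.0
    w, h = config.extent_km
    nx, ny = int(round(w / res_km)), int(round(h / res_km))

    # refuge: thresholded smoothed noise
    if config.refuge_target_cover <= 0.0:
        refuge_vals = np.zeros((ny, nx), dtype=np.uint8)
    elif config.refuge_target_cover >= 1.0:
        refuge_vals = np.ones((ny, nx), dtype=np.uint8)
    else:
        noise = rng.standard_normal((ny, nx))
        sigma_cells = config.refuge_patchiness_m / config.raster_resolution_m
        field_ = gaussian_filter(noise, sigma=sigma_cells)
        thr = np.quantile(field_, 1.0 - config.refuge_target_cover)
        refuge_vals = (field_ > thr).astype(np.uint8)
    realized_cover = float(refuge_vals.mean())
    if abs(realized_cover - config.refuge_target_cover) > 0.03:
        raise RuntimeError(
            f"realized refuge cover {realized_cover:.3f} misses target {config.refuge_target_cover:.3f}"
        )
    refuge = Raster(refuge_vals, 0.0, 0.0, res_km)

    # elevation: broad-scale smoothed noise scaled to the relief
    elev_noise = gaussian_filter(rng.standard_normal((ny, nx)), sigma=500.0 / config.raster_resolution_m)
    rngspan = elev_noise.max() - elev_noise.min()
    elev_vals = (elev_noise - elev_noise.min()) / (rngspan if rngspan > 0 else 1.0) * config.elevation_relief_m
    elevation = Raster(elev_vals, 0.0, 0.0, res_km)

    # settlements: uniform locations, heavy-tailed (lognormal) populations
    pts = rng.uniform([0, 0], [w, h], size=(config.n_settlements, 2))
    mu, sig = config.population_lognormal
    weights = np.maximum(1, np.round(rng.lognormal(mu, sig, size=config.n_settlements))).astype(int)

    # roads: random clipped segments until the target density is met exactly
    bbox = shapely_box(0.0, 0.0, w, h)
    roads: dict[str, list[LineString]] = {}
    for cls, dens in config.road_km_per_km2.items():
        target = dens * config.area_km2
        segs: list[LineString] = []
        total = 0.0
        attempts = 0
        while total < target - 1e-9:
            attempts += 1
            if attempts > 100_000:
                raise RuntimeError(f"cannot reach road density {dens} km/km^2 for class {cls!r}")
            cx, cy = rng.uniform([0, 0], [w, h])
            ang = rng.uniform(0, np.pi)
            half = rng.uniform(1.0, 3.0)
            line = LineString(
                [
                    (cx - half * math.cos(ang), cy - half * math.sin(ang)),
                    (cx + half * math.cos(ang), cy + half * math.sin(ang)),
                ]
            ).intersection(bbox)
            if line.is_empty or line.length <= 0 or line.geom_type != "LineString":
                continue
            remaining = target - total
            if line.length > remaining:
                line = substring(line, 0.0, remaining)
            segs.append(line)
            total += line.length
        realized = total / config.area_km2
        if dens > 0 and abs(realized - dens) / dens > 0.10:
            raise RuntimeError(f"realized road density {realized:.3f} misses target {dens:.3f} for {cls!r}")
        roads[cls] = segs

    return Landscape(
        config=config,
        refuge=refuge,
        elevation=elevation,
        settlements=pts,
        settlement_weights=weights,
        roads=roads,
        realized_cover=realized_cover,
    )


def default_attribute_sampler(rng: np.random.Generator) -> dict:
    """Per-individual attributes with the study's approximate class balance
    (14M/12F; 16 subadult/10 adult; 19 pack/7 nonpack; mixed prey regions)."""
    return {
        "sex": rng.choice(["female", "male"], p=[12 / 26, 14 / 26]),
        "age": rng.choice(["subadult", "adult"], p=[16 / 26, 10 / 26]),
        "status": rng.choice(["pack", "nonpack"], p=[19 / 26, 7 / 26]),
        "diet": rng.choice(["wild", "livestock", "horses"], p=[0.5, 0.3, 0.2]),
    }


def _period_of_month(month: int) -> str:
    if month in (2, 3, 4):
        return "mating"
    if month in (5, 6, 7, 8, 9, 10):
        return "breeding"
    return "nonreproductive"


@dataclass
class SimulatedTracks:
    fixes: pd.DataFrame  # individual_id, timestamp, x_km, y_km
    attributes: pd.DataFrame  # individual_id, sex, age, status, diet
    day_truth: pd.DataFrame  # realized covariates, eta, targets per day
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fx = self.fixes.copy()
        fx["timestamp"] = pd.to_datetime(fx["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        fx.to_csv(outdir / "fixes.csv", index=False)
        self.attributes.to_csv(outdir / "attributes.csv", index=False)
        self.day_truth.to_csv(outdir / "day_truth.csv", index=False)
        (outdir / "truth.json").write_text(self.truth.to_json())


def simulate_tracks(
    landscape: Landscape,
    sim: SimConfig,
    truth: TruthTable,
    attribute_sampler=default_attribute_sampler,
) -> SimulatedTracks:
    """Simulate 2-h GPS fixes whose daily distances follow the known model.

    Each day: look up the standardized covariates of the day's local area
    (1-km-disk surface values at the day's start position), form the linear
    predictor eta with the individual and 1x1-km grid-cell intercepts, draw
    sqrt(D) ~ Normal(eta, sigma_resid), and scale a correlated-random-walk
    day of 11 steps so the realized daily distance is exactly D.  With
    probability ``zero_inflation_pi`` the day is closed into a loop (net
    displacement 0), producing exact zeros of the straightness index.  Fixes
    are then dropped independently at ``missingness_rate``.
    """
    rng = np.random.default_rng(sim.seed)
    surfaces = landscape.covariate_surfaces()
    w, h = landscape.config.extent_km
    n_steps = 24 // sim.fix_interval_h  # fixes per day window
    margin = 0.05

    cell_effects: dict[tuple[int, int], float] = {}
    rng_cells = np.random.default_rng(sim.seed + 1)

    fixes_rows = []
    attr_rows = []
    truth_rows = []
    for i in range(sim.n_individuals):
        ind = f"W{i + 1:02d}"
        attrs = attribute_sampler(rng)
        attr_rows.append({"individual_id": ind, **attrs})
        a_ind = rng.normal(0.0, truth.sigma_individual) if truth.sigma_individual > 0 else 0.0
        if isinstance(sim.days_per_individual, tuple):
            lo, hi = sim.days_per_individual
            n_days = int(rng.integers(lo, hi + 1))
        else:
            n_days = int(sim.days_per_individual)
        home = rng.uniform([0.15 * w, 0.15 * h], [0.85 * w, 0.85 * h])
        pos = home.copy()
        heading = rng.uniform(0, 2 * np.pi)
        start = sim.start_date + timedelta(days=int(rng.integers(0, 365)))
        for d in range(n_days):
            day = start + timedelta(days=d)
            cell = (int(pos[0]), int(pos[1]))
            if cell not in cell_effects:
                cell_effects[cell] = (
                    rng_cells.normal(0.0, truth.sigma_cell) if truth.sigma_cell > 0 else 0.0
                )
            b_cell = cell_effects[cell]
            covs = {name: float(surf.sample(pos[0], pos[1])) for name, surf in surfaces.items()}
            row_ctx = {**covs}
            for attr, levels in CATEGORICAL_ATTRS.items():
                val = attrs.get(attr) if attr != "period" else _period_of_month(day.month)
                for lev in levels:
                    row_ctx[f"{attr}:{lev}"] = 1.0 if val == lev else 0.0
            eta = truth.intercept + a_ind + b_cell
            for key, b in truth.beta.items():
                parts = _split_interaction(key)
                val = 1.0
                for p in parts:
                    val *= row_ctx[p]
                eta += b * val
            sqrt_d = eta + (rng.normal(0.0, truth.sigma_resid) if truth.sigma_resid > 0 else 0.0)
            sqrt_d = max(sqrt_d, 0.15)
            d_target = sqrt_d**2
            close_loop = rng.random() < truth.zero_inflation_pi

            # correlated random walk with home attraction; step lengths scaled
            # so they sum exactly to d_target
            wts = rng.gamma(0.45, 1.0, size=n_steps - 1)
            wts = np.maximum(wts, 1e-6)
            lengths = d_target * wts / wts.sum()
            # cap any single step so it always fits inside the extent, pushing
            # the excess onto the other steps (keeps the daily sum exact)
            l_max = 0.45 * min(w, h)
            for _ in range(20):
                over = lengths > l_max
                if not over.any():
                    break
                excess = float(np.sum(lengths[over] - l_max))
                lengths[over] = l_max
                under = ~over
                if not under.any() or lengths[under].sum() <= 0:
                    break
                lengths[under] += excess * lengths[under] / lengths[under].sum()
            day_pos = [pos.copy()]
            p = pos.copy()
            for s, L in enumerate(lengths):
                accepted = False
                for attempt in range(60):
                    if attempt == 0:
                        dist_home = np.hypot(home[0] - p[0], home[1] - p[1])
                        attract = min(0.7, 0.1 + 0.12 * dist_home)
                        home_dir = math.atan2(home[1] - p[1], home[0] - p[0])
                        turn = rng.normal(0.0, 0.9)
                        vx = (1 - attract) * math.cos(heading + turn) + attract * math.cos(home_dir)
                        vy = (1 - attract) * math.sin(heading + turn) + attract * math.sin(home_dir)
                        cand = math.atan2(vy, vx)
                    else:
                        cand = rng.uniform(0, 2 * np.pi)
                    newp = p + L * np.array([math.cos(cand), math.sin(cand)])
                    if margin <= newp[0] <= w - margin and margin <= newp[1] <= h - margin:
                        accepted = True
                        break
                if not accepted:  # pragma: no cover - pathological geometry
                    newp = np.clip(newp, margin, [w - margin, h - margin])
                heading = cand
                p = newp
                day_pos.append(p.copy())
            if close_loop:
                day_pos[-1] = day_pos[0].copy()
                p = day_pos[0].copy()

            t0 = pd.Timestamp(day) + pd.Timedelta(hours=16)
            realized_d = float(
                sum(
                    np.hypot(day_pos[k + 1][0] - day_pos[k][0], day_pos[k + 1][1] - day_pos[k][1])
                    for k in range(len(day_pos) - 1)
                )
            )
            for k, q in enumerate(day_pos):
                if rng.random() < sim.missingness_rate:
                    continue
                fixes_rows.append(
                    {
                        "individual_id": ind,
                        "timestamp": t0 + pd.Timedelta(hours=sim.fix_interval_h * k),
                        "x_km": q[0],
                        "y_km": q[1],
                    }
                )
            truth_rows.append(
                {
                    "individual_id": ind,
                    "track_date": day,
                    "cell_id": f"c{cell[0]}_{cell[1]}",
                    **covs,
                    "period": _period_of_month(day.month),
                    "eta": eta,
                    "sqrt_d_target": sqrt_d,
                    "d_target": d_target,
                    "d_realized": realized_d,
                    "a_individual": a_ind,
                    "b_cell": b_cell,
                    "closed_loop": close_loop,
                }
            )
            pos = p
    return SimulatedTracks(
        fixes=pd.DataFrame(fixes_rows),
        attributes=pd.DataFrame(attr_rows),
        day_truth=pd.DataFrame(truth_rows),
        truth=truth,
    )


def simulate_zib_data(
    n: int,
    pi: float = 0.10,
    beta0: float = -0.3,
    beta1: float = 0.8,
    phi: float = 8.0,
    seed: int = 0,
    n_individuals: int = 20,
    sigma_individual: float = 0.0,
) -> pd.DataFrame:
    """Zero-inflated Beta draws with a logit-linear mean, for recovery tests.

    y = 0 with probability ``pi``; otherwise y ~ Beta(mu*phi, (1-mu)*phi)
    with logit(mu) = beta0 + beta1*x (+ individual intercept).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    ind = rng.integers(0, n_individuals, size=n)
    a = rng.normal(0.0, sigma_individual, size=n_individuals) if sigma_individual > 0 else np.zeros(n_individuals)
    eta = beta0 + beta1 * x + a[ind]
    mu = 1.0 / (1.0 + np.exp(-eta))
    y = rng.beta(mu * phi, (1.0 - mu) * phi)
    y = np.clip(y, 1e-9, 1.0 - 1e-9)
    zero = rng.random(n) < pi
    y[zero] = 0.0
    return pd.DataFrame({"y": y, "x": x, "individual_id": [f"W{k:02d}" for k in ind]})


def write_landscape(landscape: Landscape, outdir: str | Path) -> None:
    """Write rasters (TIFF + JSON sidecar) and vector layers (GeoJSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    landscape.refuge.write(outdir / "refuge.tif")
    landscape.elevation.write(outdir / "elevation.tif")
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {"population": int(wt)},
        }
        for (x, y), wt in zip(landscape.settlements, landscape.settlement_weights)
    ]
    (outdir / "settlements.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )
    road_feats = [
        {"type": "Feature", "geometry": mapping(line), "properties": {"road_class": cls}}
        for cls, lines in landscape.roads.items()
        for line in lines
    ]
    (outdir / "roads.geojson").write_text(
        json.dumps({"type": "FeatureCollection", "features": road_feats})
    )
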