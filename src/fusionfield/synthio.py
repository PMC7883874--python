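"""Synthetic legume-grass field experiments.

Generates everything the downstream analysis consumes — per-plot TLS-style
point clouds plus a bare-ground scan, four co-registered reflectance bands,
plot polygons and a ground-truth table — with the statistical structure the
method assumes:

* a randomized block design of six treatments (clover-grass mixture CG,
  lucerne-grass mixture LG, their pure legume stands L_CG / L_LG and pure
  grass companions G_CG / G_LG) in four replicate blocks, mowed three times
  per year over two years;
* a drought first year that suppresses legume growth while grass matures
  tall with little biomass, and a second year in which the unfertilized
  grass declines;
* canopy point heights drawn from a right-skewed (scaled Beta(2, 5))
  profile modulated by a spatially autocorrelated patchiness field whose
  variance is larger in mixtures than in pure stands;
* band reflectances that saturate monotonically with dry matter (NIR up,
  red down) and carry Gaussian-random-field noise with treatment-specific
  correlation length, so texture features hold real signal;
* fresh matter linked to canopy height and cover,
  FM = a * height * (1 + b * cover) * (1 + eps), with treatment baselines
  calibrated so that annual treatment means fall inside realistic envelopes
  (FM roughly 10-104 t/ha/yr, DM 3-15, N_Fix 60-369 kg/ha/yr).

Everything is deterministic for a fixed seed: all randomness flows from a
single ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon, box

from .core import GridSpec, PointCloud, RasterGrid

TREATMENT_LABELS = ("CG", "LG", "L_CG", "L_LG", "G_CG", "G_LG")
BAND_NAMES = ("green", "red", "red_edge", "nir")
_HARVEST_WEIGHTS = (0.40, 0.33, 0.27)  # within-year yield split H1..H3


@dataclass
class TreatmentSpec:
    """Agronomic baseline of one treatment.

    ``base_fm_annual`` and ``base_height`` describe the *potential* (no
    climate multiplier) annual fresh matter and the per-harvest mean canopy
    height; ``legume_proportion`` is the sown legume fraction.
    """

    label: str
    legume_proportion: float
    base_height: tuple[float, ...]        # m, per harvest
    base_fm_annual: float                 # t/ha potential annual FM
    dm_content: float                     # DM / FM fraction
    n_conc_grass: float = 1.6             # % of DM
    n_conc_legume: float = 2.9            # % of DM
    cover_mean: float = 0.85              # canopy cover fraction
    heterogeneity: float = 0.30           # relative sd of the height patch field
    texture_correlation_length_m: float = 0.25

    def validate(self, harvests_per_year: int) -> None:
        if not 0.0 <= self.legume_proportion <= 1.0:
            raise ValueError(f"{self.label}: legume_proportion outside [0,1]")
        if self.label.startswith("G_") and self.legume_proportion != 0.0:
            raise ValueError(f"{self.label}: pure grass must have legume_proportion 0")
        if self.label.startswith("L_") and self.legume_proportion != 1.0:
            raise ValueError(f"{self.label}: pure legume must have legume_proportion 1")
        if len(self.base_height) < harvests_per_year:
            raise ValueError(f"{self.label}: base_height needs one entry per harvest")
        if not 0 < self.dm_content < 1:
            raise ValueError(f"{self.label}: dm_content must be in (0,1)")


@dataclass
class YearSpec:
    """Per-year climate multipliers (drought year: legume growth < 1)."""

    year: int
    legume_growth: float = 1.0
    grass_growth: float = 1.0
    legume_height: float = 1.0
    grass_height: float = 1.0

    def fm_mult(self, legume_prop: float) -> float:
        return (legume_prop * self.legume_growth
                + (1 - legume_prop) * self.grass_growth)

    def height_mult(self, legume_prop: float) -> float:
        return (legume_prop * self.legume_height
                + (1 - legume_prop) * self.grass_height)

    def realized_legume_fraction(self, legume_prop: float) -> float:
        m = self.fm_mult(legume_prop)
        return legume_prop * self.legume_growth / m if m > 0 else 0.0


def default_treatments() -> list[TreatmentSpec]:
    return [
        TreatmentSpec("CG", 0.50, (0.50, 0.42, 0.32), 64.0, 0.20,
                      cover_mean=0.88, heterogeneity=0.40,
                      texture_correlation_length_m=0.20),
        TreatmentSpec("LG", 0.45, (0.45, 0.38, 0.30), 46.0, 0.20,
                      cover_mean=0.85, heterogeneity=0.40,
                      texture_correlation_length_m=0.25),
        TreatmentSpec("L_CG", 1.00, (0.55, 0.45, 0.35), 95.0, 0.15,
                      cover_mean=0.92, heterogeneity=0.25,
                      texture_correlation_length_m=0.12),
        TreatmentSpec("L_LG", 1.00, (0.45, 0.40, 0.30), 55.0, 0.15,
                      cover_mean=0.90, heterogeneity=0.25,
                      texture_correlation_length_m=0.15),
        TreatmentSpec("G_CG", 0.00, (0.40, 0.30, 0.25), 26.0, 0.28,
                      cover_mean=0.75, heterogeneity=0.28,
                      texture_correlation_length_m=0.35),
        TreatmentSpec("G_LG", 0.00, (0.35, 0.28, 0.22), 16.0, 0.28,
                      cover_mean=0.70, heterogeneity=0.28,
                      texture_correlation_length_m=0.45),
    ]


def default_years() -> list[YearSpec]:
    # year 1: drought (legumes suppressed, mature grass tall with low
    # biomass); year 2: unfertilized grass declines.
    return [
        YearSpec(1, legume_growth=0.60, grass_growth=1.00,
                 legume_height=0.65, grass_height=1.30),
        YearSpec(2, legume_growth=1.00, grass_growth=0.75,
                 legume_height=1.00, grass_height=0.85),
    ]


def default_exclusions() -> list[tuple[str, int, int, int]]:
    """(treatment, block, year, harvest) of plots excluded from analysis.

    Four plots at the last harvest of year 2, exactly two of them
    legume-containing, so the fixation response set has 94 of 96 rows."""
    return [("CG", 1, 2, 3), ("L_LG", 2, 2, 3), ("G_CG", 3, 2, 3),
            ("G_LG", 4, 2, 3)]


@dataclass
class SimConfig:
    seed: int = 0
    n_replicates: int = 4
    treatments: list[TreatmentSpec] = field(default_factory=default_treatments)
    years: list[YearSpec] = field(default_factory=default_years)
    harvests_per_year: int = 3
    plot_length_m: float = 12.0
    plot_width_m: float = 1.5
    excluded_strip_m: float = 1.5
    pathway_m: float = 0.5
    margin_m: float = 1.0
    point_density: float = 1200.0          # canopy points / m^2
    ground_point_density: float = 600.0    # bare-ground scan points / m^2
    csh_cell_m: float = 0.05
    ms_cell_m: float = 0.045
    height_noise_sd: float = 0.01          # m, per-point measurement noise
    height_cv: float = 0.08                # plot-level height variability
    reflectance_sd: float = 0.05           # within-plot band noise
    plot_reflectance_sd: float = 0.015     # per-plot illumination/calibration bias
    biomass_cv: float = 0.05
    n_conc_sd: float = 0.08                # % of DM, absolute
    cover_sd: float = 0.05
    exclusions: list[tuple[str, int, int, int]] = field(
        default_factory=default_exclusions)
    max_cells: int = 4_000_000
    crs: str = "local"

    def validate(self) -> None:
        for name in ("plot_length_m", "plot_width_m", "pathway_m",
                     "point_density", "ground_point_density",
                     "csh_cell_m", "ms_cell_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.harvests_per_year < 1:
            raise ValueError("harvests_per_year must be >= 1")
        if self.csh_cell_m >= min(self.plot_length_m, self.plot_width_m) \
                or self.ms_cell_m >= min(self.plot_length_m, self.plot_width_m):
            raise ValueError("cell sizes must be smaller than the plot")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate block")
        labels = [t.label for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate treatment labels")
        for t in self.treatments:
            t.validate(self.harvests_per_year)
        w, h = self.site_size()
        for cell in (self.csh_cell_m, self.ms_cell_m):
            n = int(np.ceil(w / cell)) * int(np.ceil(h / cell))
            if n > self.max_cells:
                raise ValueError(
                    f"grid of {n} cells at {cell} m exceeds the cell budget "
                    f"of {self.max_cells}")

    # --- layout ----------------------------------------------------------

    def site_size(self) -> tuple[float, float]:
        n_t = len(self.treatments)
        block_w = n_t * self.plot_width_m + (n_t - 1) * self.pathway_m
        bx = min(2, self.n_replicates)
        by = int(np.ceil(self.n_replicates / 2)) if self.n_replicates > 1 else 1
        width = 2 * self.margin_m + bx * block_w + (bx - 1) * self.pathway_m
        height = (2 * self.margin_m + by * self.plot_length_m
                  + (by - 1) * self.pathway_m)
        return width, height

    def layout(self) -> tuple[dict[str, Polygon], dict[str, dict]]:
        """Plot polygons and properties; plots run north-south (length on y)."""
        n_t = len(self.treatments)
        block_w = n_t * self.plot_width_m + (n_t - 1) * self.pathway_m
        polygons: dict[str, Polygon] = {}
        props: dict[str, dict] = {}
        for rep in range(self.n_replicates):
            bx, by = rep % 2, rep // 2
            ox = self.margin_m + bx * (block_w + self.pathway_m)
            oy = self.margin_m + by * (self.plot_length_m + self.pathway_m)
            # fixed rotation of treatment order per block (randomized design
            # stand-in that stays layout-stable across seeds)
            order = [(k + rep) % n_t for k in range(n_t)]
            for pos, k in enumerate(order):
                t = self.treatments[k]
                x0 = ox + pos * (self.plot_width_m + self.pathway_m)
                plot_id = f"{t.label}_B{rep + 1}"
                polygons[plot_id] = box(x0, oy, x0 + self.plot_width_m,
                                        oy + self.plot_length_m)
                props[plot_id] = {"treatment": t.label, "block": rep + 1}
        return polygons, props

    def csh_gridspec(self) -> GridSpec:
        w, h = self.site_size()
        return GridSpec.from_bounds(0, 0, w, h, self.csh_cell_m, self.crs)

    def ms_gridspec(self) -> GridSpec:
        w, h = self.site_size()
        return GridSpec.from_bounds(0, 0, w, h, self.ms_cell_m, self.crs)


# --- random-field and terrain helpers ------------------------------------

def gaussian_random_field(shape: tuple[int, int], cell_size: float,
                          correlation_length: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian field with the given correlation length.

    White noise smoothed with a Gaussian kernel (sigma = correlation length
    in cells) and re-standardized; correlation length 0 returns white noise.
    """
    noise = rng.standard_normal(shape)
    sigma = correlation_length / cell_size
    if sigma < 1e-6:
        return noise
    f = ndimage.gaussian_filter(noise, sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def dem_elevation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Analytic bare-ground surface: a gentle tilted plane with undulation."""
    return (100.0 + 0.012 * np.asarray(x) + 0.008 * np.asarray(y)
            + 0.02 * np.sin(np.asarray(x) / 7.0) * np.cos(np.asarray(y) / 9.0))


# --- point clouds ----------------------------------------------------------

def simulate_plot_cloud(spec: TreatmentSpec, footprint: Polygon,
                        climate_mult: float, density: float,
                        seed: int | np.random.SeedSequence, *,
                        harvest: int = 1, mean_height: float | None = None,
                        cover: float | None = None,
                        height_noise_sd: float = 0.01,
                        cell_size: float = 0.05) -> PointCloud:
    """TLS-style cloud of one plot at one harvest.

    Ground returns lie on the DEM; canopy returns add a right-skewed height
    (scaled Beta(2, 5), support [0, 3.5 x target] so the sample mean equals
    ``mean_height`` — by default ``base_height[harvest-1] * climate_mult``)
    modulated by a patchiness field whose variance grows with the
    treatment's heterogeneity (mixtures > pure stands).
    """
    if density <= 0:
        raise ValueError("point density must be positive")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = footprint.bounds
    area = (xmax - xmin) * (ymax - ymin)
    n = rng.poisson(density * area)
    n = max(n, 1)
    x = rng.uniform(xmin, xmax, n)
    y = rng.uniform(ymin, ymax, n)
    target = (spec.base_height[harvest - 1] * climate_mult
              if mean_height is None else mean_height)
    cov = spec.cover_mean if cover is None else cover
    canopy = rng.random(n) < cov

    z = dem_elevation(x, y) + rng.normal(0.0, 0.003, n)
    if target > 0 and canopy.any():
        nxc = max(2, int(np.ceil((xmax - xmin) / cell_size)))
        nyc = max(2, int(np.ceil((ymax - ymin) / cell_size)))
        patch = gaussian_random_field((nyc, nxc), cell_size,
                                      spec.texture_correlation_length_m, rng)
        sig = spec.heterogeneity
        mult = np.exp(sig * patch)
        mult /= mult.mean()  # mean-1 per realization: patchiness stays
        # within-plot; between-plot height variability is injected upstream
        jj = np.clip(((x - xmin) / cell_size).astype(int), 0, nxc - 1)
        ii = np.clip(((y - ymin) / cell_size).astype(int), 0, nyc - 1)
        h = 3.5 * target * rng.beta(2.0, 5.0, n) * mult[ii, jj]
        h += rng.normal(0.0, height_noise_sd, n)
        z = z + np.where(canopy, np.clip(h, 0.0, None), 0.0)
    classification = np.where(canopy & (target > 0), 1, 2)
    return PointCloud(x, y, z, classification=classification)


def simulate_ground_cloud(config: SimConfig,
                          seed: int | np.random.SeedSequence) -> PointCloud:
    """Bare-ground scan of the whole site (taken right after a harvest)."""
    rng = np.random.default_rng(seed)
    w, h = config.site_size()
    n = rng.poisson(config.ground_point_density * w * h)
    x = rng.uniform(0, w, n)
    y = rng.uniform(0, h, n)
    z = dem_elevation(x, y) + rng.normal(0.0, 0.004, n)
    return PointCloud(x, y, z, classification=np.full(n, 2))


# --- band rasters ----------------------------------------------------------

_SOIL = {"green": 0.12, "red": 0.18, "red_edge": 0.20, "nir": 0.24}


def _plot_reflectance(band: str, dm_t_ha: float, legume_frac: float) -> float:
    """Plot-mean reflectance as a saturating function of harvest DM yield.

    Saturation sets in at moderate yields (the classic dense-canopy
    reflectance saturation), so spectral data alone cannot separate
    high-yielding plots — the regime in which canopy height carries the
    complementary signal."""
    g = 1.0 - np.exp(-dm_t_ha / 1.2)
    if band == "nir":
        return 0.18 + 0.42 * g
    if band == "red":
        return 0.08 + 0.22 * np.exp(-dm_t_ha / 1.0)
    if band == "green":
        return 0.07 + 0.05 * g + 0.010 * legume_frac
    if band == "red_edge":
        return 0.15 + 0.20 * g + 0.012 * legume_frac
    raise ValueError(band)


def simulate_band_rasters(truth: pd.DataFrame, polygons: dict[str, Polygon],
                          config: SimConfig, year: int, harvest: int,
                          seed: int | np.random.SeedSequence,
                          clip_budget: float = 0.05) -> dict[str, RasterGrid]:
    """The four co-registered reflectance rasters of one flight.

    Pathways carry bare-soil reflectance; each plot gets its saturating
    DM-driven level plus spatially autocorrelated noise with the
    treatment-specific correlation length.  Values are clipped to [0, 1]; if
    more than ``clip_budget`` of a plot's cells need clipping the
    configuration is rejected.
    """
    rng = np.random.default_rng(seed)
    gs = config.ms_gridspec()
    treatments = {t.label: t for t in config.treatments}
    rows = truth[(truth["year"] == year) & (truth["harvest"] == harvest)]
    rows = rows.set_index("plot_id")
    out: dict[str, RasterGrid] = {}
    soil_noise = {b: gaussian_random_field((gs.n_rows, gs.n_cols),
                                           config.ms_cell_m, 0.30, rng)
                  for b in BAND_NAMES}
    for bnd in BAND_NAMES:
        grid = gs.empty_grid()
        grid.values[:] = np.clip(_SOIL[bnd] + 0.02 * soil_noise[bnd], 0, 1)
        out[bnd] = grid
    for plot_id, poly in polygons.items():
        if plot_id not in rows.index:
            continue
        rec = rows.loc[plot_id]
        t = treatments[rec["treatment"]]
        xmin, ymin, xmax, ymax = poly.bounds
        c = config.ms_cell_m
        j0 = int(np.floor(xmin / c)); j1 = int(np.ceil(xmax / c))
        i0 = int(np.floor(ymin / c)); i1 = int(np.ceil(ymax / c))
        ny, nx = i1 - i0, j1 - j0
        patch = gaussian_random_field((ny, nx), c,
                                      t.texture_correlation_length_m, rng)
        for bnd in BAND_NAMES:
            base = _plot_reflectance(bnd, float(rec["DM_t_ha"]),
                                     float(rec["legume_prop"]))
            # plot-level illumination / calibration bias: uneven image
            # overlap and view-angle effects do not average out per plot
            ps = config.plot_reflectance_sd
            base += float(np.clip(rng.normal(0.0, ps), -2 * ps, 2 * ps))
            sd = config.reflectance_sd * (1.0 if bnd in ("nir", "red_edge")
                                          else 0.5)
            vals = base + sd * patch
            n_clip = np.count_nonzero((vals < 0) | (vals > 1))
            if n_clip > clip_budget * vals.size:
                raise ValueError(
                    f"plot {plot_id} band {bnd}: {n_clip}/{vals.size} cells "
                    "outside [0,1] exceeds the clipping budget")
            out[bnd].values[i0:i1, j0:j1] = np.clip(vals, 0, 1)
    return out


# --- the full experiment ---------------------------------------------------

@dataclass
class SceneBundle:
    """Everything one simulated experiment produces."""

    config: SimConfig
    truth: pd.DataFrame            # analysis table (exclusions dropped)
    truth_full: pd.DataFrame       # including excluded plot-harvests
    polygons: dict[str, Polygon]
    properties: dict[str, dict]
    clouds: dict[tuple[str, int, int], PointCloud]
    ground_cloud: PointCloud
    bands: dict[tuple[int, int], dict[str, RasterGrid]]

    def truth_csv_text(self) -> str:
        cols = ["plot_id", "year", "harvest", "treatment", "FM_t_ha",
                "DM_t_ha", "N_conc_pct", "N_amount_kg_ha", "legume_prop"]
        return self.truth[cols].to_csv(index=False, float_format="%.6f")

    def write(self, outdir) -> None:
        from pathlib import Path
        from . import gio
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "truth.csv").write_text(self.truth_csv_text())
        gio.write_plot_polygons(self.polygons, self.properties,
                                outdir / "plots.geojson")
        gio.write_xyz(self.ground_cloud, outdir / "ground.xyz")
        for (plot_id, year, harvest), cloud in self.clouds.items():
            gio.write_xyz(cloud, outdir / f"cloud_{plot_id}_y{year}h{harvest}.xyz")
        for (year, harvest), bands in self.bands.items():
            for bnd, grid in bands.items():
                gio.write_geotiff(grid, outdir / f"band_{bnd}_y{year}h{harvest}.tif",
                                  dtype="uint16")


def _truth_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    records = []
    for yr in config.years:
        for h in range(1, config.harvests_per_year + 1):
            for rep in range(1, config.n_replicates + 1):
                for t in config.treatments:
                    lp = t.legume_proportion
                    fm_mult = yr.fm_mult(lp)
                    h_mult = yr.height_mult(lp)
                    lf = yr.realized_legume_fraction(lp)
                    h_pot = t.base_height[h - 1] * h_mult
                    height = h_pot * (1 + rng.normal(0, config.height_cv))
                    height = max(height, 0.02)
                    cover = float(np.clip(
                        rng.normal(t.cover_mean, config.cover_sd), 0.30, 0.99))
                    fm_pot = t.base_fm_annual * _HARVEST_WEIGHTS[
                        (h - 1) % len(_HARVEST_WEIGHTS)] * fm_mult
                    fm = (fm_pot * (height / h_pot)
                          * (1 + 0.5 * cover) / (1 + 0.5 * t.cover_mean)
                          * (1 + rng.normal(0, config.biomass_cv)))
                    fm = max(fm, 0.2)
                    dm = fm * t.dm_content * (1 + rng.normal(0, 0.03))
                    dm = float(np.clip(dm, 0.05, fm))
                    n_conc = max(0.5, lf * t.n_conc_legume
                                 + (1 - lf) * t.n_conc_grass
                                 + rng.normal(0, config.n_conc_sd))
                    legume_prop = (lf if lp in (0.0, 1.0) else float(
                        np.clip(lf + rng.normal(0, 0.03), 0.0, 1.0)))
                    records.append({
                        "plot_id": f"{t.label}_B{rep}", "year": yr.year,
                        "harvest": h, "treatment": t.label, "block": rep,
                        "FM_t_ha": round(fm, 6), "DM_t_ha": round(dm, 6),
                        "N_conc_pct": round(n_conc, 6),
                        "N_amount_kg_ha": round(dm * 10.0 * n_conc, 6),
                        "legume_prop": round(legume_prop, 6),
                        "mean_height_m": round(height, 6),
                        "cover": round(cover, 6),
                    })
    return pd.DataFrame.from_records(records)


def simulate_experiment(config: SimConfig | None = None) -> SceneBundle:
    """Generate a complete synthetic experiment (deterministic per seed)."""
    config = SimConfig() if config is None else config
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    truth_seed, ground_seed, cloud_root, band_root = ss.spawn(4)

    truth_full = _truth_table(config, np.random.default_rng(truth_seed))
    excl = set(config.exclusions)
    mask = truth_full.apply(
        lambda r: (r["treatment"], r["block"], r["year"], r["harvest"]) in excl,
        axis=1)
    truth = truth_full[~mask].reset_index(drop=True)

    polygons, props = config.layout()
    ground = simulate_ground_cloud(config, ground_seed)
    treatments = {t.label: t for t in config.treatments}

    clouds: dict[tuple[str, int, int], PointCloud] = {}
    cloud_seeds = iter(cloud_root.spawn(len(truth_full)))
    for _, row in truth_full.iterrows():
        t = treatments[row["treatment"]]
        key = (row["plot_id"], int(row["year"]), int(row["harvest"]))
        clouds[key] = simulate_plot_cloud(
            t, polygons[row["plot_id"]], 1.0, config.point_density,
            next(cloud_seeds), harvest=int(row["harvest"]),
            mean_height=float(row["mean_height_m"]),
            cover=float(row["cover"]), height_noise_sd=config.height_noise_sd,
            cell_size=config.csh_cell_m)

    bands: dict[tuple[int, int], dict[str, RasterGrid]] = {}
    n_scenes = len(config.years) * config.harvests_per_year
    band_seeds = iter(band_root.spawn(n_scenes))
    for yr in config.years:
        for h in range(1, config.harvests_per_year + 1):
            bands[(yr.year, h)] = simulate_band_rasters(
                truth_full, polygons, config, yr.year, h, next(band_seeds))
    return SceneBundle(config, truth, truth_full, polygons, props, clouds,
                       ground, bands)


def table_hash(df: pd.DataFrame) -> str:
    """Stable content hash of a table (used for determinism checks)."""
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()
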