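"""End-to-end orchestration: scene -> features -> selection -> models.

The feature table has one row per plot-harvest sample and three predictor
variants:

* ``CSH``   — 15 canopy height metrics + 8 texture features of the mean-CSH
  raster (23 predictors, structural information only);
* ``MS``    — 4 band means + 13 vegetation indices + 8 texture features per
  band (49 predictors, spectral information only);
* ``Fusion`` — the union of both (72 predictors).

Responses are fresh matter (FM, t/ha), dry matter (DM, t/ha) and
difference-method nitrogen fixation (NFix, kg/ha; absent for pure-grass
rows).  Stage outputs are cached under the run directory keyed by a
fingerprint of the configuration, so an unchanged stage is never
recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import agronomy, heights, spectral, texture
from .core import GridSpec, RasterGrid
from .modeling import ModelSummary, norm_dev, repeated_modeling, year_effect_test
from .selection import SelectionConfig, SelectionResult, select_variables
from .synthio import BAND_NAMES, SceneBundle, SimConfig, simulate_experiment

logger = logging.getLogger(__name__)

KEYS = ["plot_id", "year", "harvest"]
CSH_METRIC_COLS = [f"csh_{m}" for m in heights.METRIC_NAMES]
CSH_TEXTURE_COLS = [f"csh_mean_{f}" for f in texture.FEATURE_NAMES]
BAND_MEAN_COLS = [f"band_{b}" for b in BAND_NAMES]
VI_COLS = list(spectral.VI_REGISTRY)
BAND_TEXTURE_COLS = [f"{b}_{f}" for b in BAND_NAMES
                     for f in texture.FEATURE_NAMES]
RESPONSES = {"FM": "FM_t_ha", "DM": "DM_t_ha", "NFix": "NFix_kg_ha"}


def variant_predictors(variant: str) -> list[str]:
    if variant == "CSH":
        return CSH_METRIC_COLS + CSH_TEXTURE_COLS
    if variant == "MS":
        return BAND_MEAN_COLS + VI_COLS + BAND_TEXTURE_COLS
    if variant == "Fusion":
        return variant_predictors("CSH") + variant_predictors("MS")
    raise ValueError(f"unknown variant {variant!r}")


# --------------------------------------------------------------------------
# feature extraction stages
# --------------------------------------------------------------------------

def build_dem(bundle: SceneBundle) -> RasterGrid:
    """DEM raster from the bare-ground scan (mean z per cell, gaps filled
    from the nearest surveyed cell)."""
    dem = heights.rasterize_surface(bundle.ground_cloud,
                                    bundle.config.csh_gridspec(),
                                    aggregator="mean")
    vals = dem.values
    missing = ~np.isfinite(vals)
    if missing.any():
        _, (ii, jj) = ndimage.distance_transform_edt(
            missing, return_distances=True, return_indices=True)
        dem.values[:] = vals[ii, jj]
    return dem


def height_stage(bundle: SceneBundle, dem: RasterGrid | None = None,
                 aggregator: str = "max"
                 ) -> tuple[pd.DataFrame, dict[tuple, RasterGrid]]:
    """Per plot-harvest CSH metrics and the mean-CSH rasters for texture.

    The metric surface uses the top-of-canopy aggregator (default max);
    texture always runs on the smoother mean-aggregated CSH."""
    dem = build_dem(bundle) if dem is None else dem
    strip = bundle.config.excluded_strip_m
    rows = []
    csh_mean_rasters: dict[tuple, RasterGrid] = {}
    for _, rec in bundle.truth.iterrows():
        key = (rec["plot_id"], int(rec["year"]), int(rec["harvest"]))
        poly = bundle.polygons[rec["plot_id"]]
        cloud = bundle.clouds[key]
        dem_crop = dem.crop(*poly.bounds)
        gs = GridSpec(dem_crop.x0, dem_crop.y0, dem_crop.cell_size,
                      dem_crop.n_rows, dem_crop.n_cols, dem_crop.crs)
        dsm_top = heights.rasterize_surface(cloud, gs, aggregator=aggregator)
        dsm_mean = heights.rasterize_surface(cloud, gs, aggregator="mean")
        csh_top = heights.compute_csh(dsm_top, dem_crop).grid
        csh_mean_rasters[key] = heights.compute_csh(dsm_mean, dem_crop).grid
        metrics = heights.plot_csh_metrics(csh_top, poly, strip)
        rows.append({"plot_id": key[0], "year": key[1], "harvest": key[2],
                     **metrics.to_dict()})
    return pd.DataFrame(rows), csh_mean_rasters


def spectral_stage(bundle: SceneBundle) -> pd.DataFrame:
    """Band means and vegetation indices per plot-harvest."""
    strip = bundle.config.excluded_strip_m
    rows = []
    for _, rec in bundle.truth.iterrows():
        key = (rec["plot_id"], int(rec["year"]), int(rec["harvest"]))
        poly = bundle.polygons[rec["plot_id"]]
        scene = bundle.bands[(key[1], key[2])]
        cropped = {b: g.crop(*poly.bounds) for b, g in scene.items()}
        record = spectral.spectral_record(cropped, poly, strip)
        rows.append({"plot_id": key[0], "year": key[1], "harvest": key[2],
                     **record})
    return pd.DataFrame(rows)


def texture_stage(bundle: SceneBundle,
                  csh_mean_rasters: dict[tuple, RasterGrid],
                  radius: int = 2, n_levels: int = 8,
                  offsets: list[tuple[int, int]] = [(0, 1)]) -> pd.DataFrame:
    """Eight texture features per layer (mean CSH + 4 bands) per plot.

    Quantization ranges are fixed per flight scene — [0, p99.9] of the
    scene's CSH values, min/max of each band — so features are comparable
    across the plots of one scene.
    """
    strip = bundle.config.excluded_strip_m
    margin = (radius + max(abs(d) for off in offsets for d in off) + 1)
    rows: list[dict] = []

    scene_keys = sorted({(y, h) for (_, y, h) in csh_mean_rasters})
    csh_range: dict[tuple, tuple[float, float]] = {}
    for sk in scene_keys:
        vals = np.concatenate([
            r.values[np.isfinite(r.values)]
            for (pid, y, h), r in csh_mean_rasters.items() if (y, h) == sk])
        csh_range[sk] = (0.0, max(float(np.percentile(vals, 99.9)), 1e-6))
    band_range: dict[tuple, dict[str, tuple[float, float]]] = {}
    for sk in scene_keys:
        band_range[sk] = {}
        for b, g in bundle.bands[sk].items():
            v = g.values[np.isfinite(g.values)]
            band_range[sk][b] = (float(v.min()), float(v.max()))

    for _, rec in bundle.truth.iterrows():
        key = (rec["plot_id"], int(rec["year"]), int(rec["harvest"]))
        sk = (key[1], key[2])
        poly = bundle.polygons[rec["plot_id"]]
        row = {"plot_id": key[0], "year": key[1], "harvest": key[2]}

        feats = texture.texture_image(csh_mean_rasters[key], radius=radius,
                                      offsets=offsets, n_levels=n_levels,
                                      value_range=csh_range[sk])
        tv = texture.plot_texture_means(feats, poly, strip, layer="csh_mean")
        row.update(tv.to_dict(prefix="csh_mean_"))

        for b, grid in bundle.bands[sk].items():
            xmin, ymin, xmax, ymax = poly.bounds
            pad = margin * grid.cell_size
            crop = grid.crop(xmin - pad, ymin - pad, xmax + pad, ymax + pad)
            feats = texture.texture_image(crop, radius=radius, offsets=offsets,
                                          n_levels=n_levels,
                                          value_range=band_range[sk][b])
            tv = texture.plot_texture_means(feats, poly, strip, layer=b)
            row.update(tv.to_dict(prefix=f"{b}_"))
        rows.append(row)
    return pd.DataFrame(rows)


def agronomy_stage(bundle: SceneBundle) -> pd.DataFrame:
    """Ground-truth responses: FM, DM and difference-method NFix per row."""
    truth = bundle.truth.copy()
    nfix = agronomy.nfix_table(truth)
    merged = truth.merge(
        nfix[KEYS + ["NFix_kg_ha"]], on=KEYS, how="left")
    return merged


def assemble_features(height_df: pd.DataFrame, spectral_df: pd.DataFrame,
                      texture_df: pd.DataFrame,
                      truth: pd.DataFrame) -> pd.DataFrame:
    """Join the per-stage tables into the master feature table.

    Feature keys absent from the truth table are orphans and raise; truth
    rows missing from a feature table (e.g. a lost texture file) are
    dropped with a log entry, as are rows with any missing predictor."""
    truth_keys = set(map(tuple, truth[KEYS].itertuples(index=False)))
    table = truth.copy()
    for name, df in (("heights", height_df), ("spectral", spectral_df),
                     ("texture", texture_df)):
        fkeys = set(map(tuple, df[KEYS].itertuples(index=False)))
        orphans = fkeys - truth_keys
        if orphans:
            raise ValueError(f"{name} table has keys absent from the truth "
                             f"table: {sorted(orphans)[:5]}")
        lost = truth_keys - fkeys
        if lost:
            logger.info("%s table misses %d plot-harvest rows; dropped",
                        name, len(lost))
        table = table.merge(df, on=KEYS, how="inner")
    predictors = variant_predictors("Fusion")
    incomplete = table[predictors].isna().any(axis=1)
    if incomplete.any():
        logger.info("dropping %d rows with missing predictors",
                    int(incomplete.sum()))
        table = table[~incomplete]
    dup = table.duplicated(subset=KEYS)
    if dup.any():
        raise ValueError("duplicate plot-harvest keys in assembled table")
    for resp, col in RESPONSES.items():
        table = table.rename(columns={col: resp}) if col in table.columns \
            else table
    return table.reset_index(drop=True)


def extract_features(bundle: SceneBundle) -> pd.DataFrame:
    """All stages in sequence on an in-memory scene."""
    height_df, csh_mean = height_stage(bundle)
    spec_df = spectral_stage(bundle)
    tex_df = texture_stage(bundle, csh_mean)
    truth = agronomy_stage(bundle)
    return assemble_features(height_df, spec_df, tex_df, truth)


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    variants: list[str] = field(default_factory=lambda: ["CSH", "MS", "Fusion"])
    responses: list[str] = field(default_factory=lambda: ["FM", "DM", "NFix"])
    n_splits: int = 100
    n_trees: int = 500
    tune_mtry: bool = True
    run_selection: bool = True
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    seed: int = 0
    outdir: str = "fusionfield_run"
    make_plots: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.variants or not self.responses:
            raise ValueError("need at least one variant and one response")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        sel = SelectionConfig(**raw.pop("selection", {}))
        return cls(sim=sim, selection=sel, **raw)

    def fingerprint(self, *parts: str) -> str:
        payload = json.dumps(
            {"config": dataclasses.asdict(self), "parts": parts},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _cached_csv(path: Path, fingerprint: str, compute) -> pd.DataFrame:
    meta = path.with_suffix(".fingerprint")
    if path.exists() and meta.exists() and meta.read_text() == fingerprint:
        logger.info("stage cached: %s", path.name)
        return pd.read_csv(path)
    df = compute()
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    meta.write_text(fingerprint)
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Simulate (or reuse cached features), select, model, evaluate.

    Returns the machine-readable summary (also written to
    ``<outdir>/report.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    def compute_features() -> pd.DataFrame:
        config.sim.seed = config.sim.seed or config.seed
        bundle = simulate_experiment(config.sim)
        return extract_features(bundle)

    table = _cached_csv(outdir / "features.csv",
                        config.fingerprint("features"), compute_features)

    report: dict = {"schema_version": 1, "seed": config.seed,
                    "n_rows": {r: int(table[r].notna().sum())
                               for r in config.responses},
                    "models": {}}
    summaries: dict[tuple[str, str], ModelSummary] = {}
    for variant in config.variants:
        for response in config.responses:
            key = f"{variant}_{response}"
            predictors = variant_predictors(variant)
            data = table.dropna(subset=[response]).reset_index(drop=True)
            if config.run_selection:
                sel_path = outdir / f"selection_{key}.json"
                fp = config.fingerprint("selection", key)
                meta = sel_path.with_suffix(".fingerprint")
                if sel_path.exists() and meta.exists() \
                        and meta.read_text() == fp:
                    sel = json.loads(sel_path.read_text())
                    selected = sel["prediction_set"]
                else:
                    result = select_variables(data[predictors], data[response],
                                              seed=config.seed,
                                              config=config.selection)
                    sel_path.write_text(json.dumps(result.to_dict(), indent=1))
                    meta.write_text(fp)
                    selected = result.prediction_set
            else:
                selected = predictors
            summary = repeated_modeling(
                data, selected, response, n_splits=config.n_splits,
                master_seed=config.seed, n_trees=config.n_trees,
                tune=config.tune_mtry, variant=variant)
            summaries[(variant, response)] = summary
            report["models"][key] = {
                "predictors_used": selected,
                "r2_val": summary.r2_distribution,
                "rrmsep_pct": summary.rrmsep_distribution,
                "top_importance": summary.importance_ranking.head(10)
                .to_dict(orient="records"),
                "median_validation_appearances":
                    float(summary.appearance_counts.median()),
            }

    # year effect on prediction quality, per mixture, on the fusion model
    eval_variant = "Fusion" if "Fusion" in config.variants else config.variants[0]
    report["year_effect"] = {}
    for response in config.responses:
        summary = summaries[(eval_variant, response)]
        data = table.dropna(subset=[response]).reset_index(drop=True)
        preds = summary.predictions_frame(data)
        mixtures = preds[preds["treatment"].isin(["CG", "LG"])].copy()
        mixtures["mixture"] = mixtures["treatment"]
        try:
            ye = year_effect_test(mixtures)
        except ValueError as err:
            report["year_effect"][response] = {"error": str(err)}
            continue
        report["year_effect"][response] = {
            mix: {"H": r["H"], "p": r["p"], "letters": r["letters"]}
            for mix, r in ye.items()}

    if config.make_plots:
        from . import plots
        figdir = outdir / "figures"
        figdir.mkdir(exist_ok=True)
        plots.accuracy_boxplots(summaries, figdir / "accuracy.png")
        plots.importance_boxplot(
            summaries[(eval_variant, config.responses[0])],
            figdir / "importance.png")

    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
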