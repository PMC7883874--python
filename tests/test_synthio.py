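"""The synthetic experiment generator: design arithmetic, determinism,
calibration envelopes and the structural links the analysis relies on."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from fusionfield.agronomy import nfix_table
from fusionfield.synthio import (SimConfig, TreatmentSpec, YearSpec,
                                 default_treatments, gaussian_random_field,
                                 dem_elevation, simulate_band_rasters,
                                 simulate_experiment, simulate_plot_cloud)
from fusionfield.texture import glcm, haralick_features, quantize


class TestDesignArithmetic:
    def test_default_config_yields_140_modeling_rows(self, default_bundle):
        assert len(default_bundle.truth) == 140
        assert len(default_bundle.truth_full) == 144

    def test_single_block_single_harvest(self):
        cfg = SimConfig(seed=0, n_replicates=1, years=[YearSpec(1)],
                        harvests_per_year=1, exclusions=[],
                        point_density=200, ground_point_density=200)
        b = simulate_experiment(cfg)
        assert len(b.truth) == 6
        assert len(b.clouds) == 6
        assert set(b.truth["treatment"]) == {t.label for t in
                                             default_treatments()}

    def test_every_plot_harvest_has_cloud_and_raster_coverage(self, default_bundle):
        b = default_bundle
        for _, r in b.truth.iterrows():
            key = (r["plot_id"], r["year"], r["harvest"])
            assert key in b.clouds
            assert (r["year"], r["harvest"]) in b.bands
        gs = b.bands[(1, 1)]["nir"]
        for poly in b.polygons.values():
            xmin, ymin, xmax, ymax = poly.bounds
            bx = gs.bounds
            assert bx[0] <= xmin and bx[1] <= ymin
            assert bx[2] >= xmax and bx[3] >= ymax

    def test_same_seed_byte_identical_truth(self):
        cfg = dict(n_replicates=2, years=[YearSpec(1)], harvests_per_year=1,
                   exclusions=[], point_density=100, ground_point_density=100)
        a = simulate_experiment(SimConfig(seed=9, **cfg))
        b = simulate_experiment(SimConfig(seed=9, **cfg))
        assert a.truth_csv_text() == b.truth_csv_text()
        k = list(a.clouds)[0]
        np.testing.assert_array_equal(a.clouds[k].z, b.clouds[k].z)
        np.testing.assert_array_equal(a.bands[(1, 1)]["red"].values,
                                      b.bands[(1, 1)]["red"].values)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="cell budget"):
            SimConfig(max_cells=1000).validate()
        with pytest.raises(ValueError, match="positive"):
            SimConfig(point_density=-1).validate()
        with pytest.raises(ValueError, match="legume_proportion"):
            TreatmentSpec("G_CG", 0.5, (0.3,), 10.0, 0.2).validate(1)


class TestCalibrationEnvelopes:
    """Treatment-year mean annual totals stay inside realistic field ranges."""

    def test_fm_dm_annual_envelopes(self, default_bundle):
        t = default_bundle.truth_full
        ann = (t.groupby(["treatment", "year", "block"])
               [["FM_t_ha", "DM_t_ha"]].sum()
               .groupby(["treatment", "year"]).mean())
        assert ann["FM_t_ha"].min() >= 10.36
        assert ann["FM_t_ha"].max() <= 103.94
        assert ann["DM_t_ha"].min() >= 3.05
        assert ann["DM_t_ha"].max() <= 14.70

    def test_nfix_annual_envelope_and_positivity(self, default_bundle):
        nf = nfix_table(default_bundle.truth_full)
        ann = (nf.groupby(["treatment", "year", "block"])["NFix_kg_ha"].sum()
               .groupby(["treatment", "year"]).mean())
        assert ann.min() >= 59.73
        assert ann.max() <= 369.24
        # difference method yields positive fixation for legume swards
        assert (ann > 0).all()
        assert (nf["NFix_kg_ha"] > 0).mean() > 0.97

    def test_nfix_has_94_rows_under_default_exclusions(self, default_bundle):
        assert len(nfix_table(default_bundle.truth)) == 94

    def test_drought_year_suppresses_legume_but_not_grass(self, default_bundle):
        t = default_bundle.truth_full
        ann = (t.groupby(["treatment", "year", "block"])["FM_t_ha"].sum()
               .groupby(["treatment", "year"]).mean())
        assert ann[("L_CG", 1)] < ann[("L_CG", 2)]
        assert ann[("G_CG", 1)] > ann[("G_CG", 2)]


class TestPlotCloud:
    FOOT = box(0, 0, 1.0, 1.0)

    def test_bare_plot_stays_on_dem(self):
        spec = TreatmentSpec("G_CG", 0.0, (0.0,), 10.0, 0.28)
        pc = simulate_plot_cloud(spec, self.FOOT, 1.0, 2000, seed=0)
        resid = pc.z - dem_elevation(pc.x, pc.y)
        assert np.abs(resid).max() < 0.02

    def test_climate_multiplier_halves_mean_canopy_height(self):
        spec = default_treatments()[0]
        full = simulate_plot_cloud(spec, self.FOOT, 1.0, 20000, seed=3)
        half = simulate_plot_cloud(spec, self.FOOT, 0.5, 20000, seed=3)
        h_full = (full.z - dem_elevation(full.x, full.y))[full.classification == 1]
        h_half = (half.z - dem_elevation(half.x, half.y))[half.classification == 1]
        assert h_half.mean() == pytest.approx(h_full.mean() / 2, rel=0.05)
        assert h_full.mean() == pytest.approx(spec.base_height[0], rel=0.05)

    def test_point_count_follows_density(self):
        spec = default_treatments()[0]
        pc = simulate_plot_cloud(spec, self.FOOT, 1.0, 2000, seed=1)
        assert abs(len(pc) - 2000) < 4 * np.sqrt(2000)

    def test_canopy_heights_right_skewed(self):
        from scipy import stats
        spec = default_treatments()[2]  # pure legume, low patchiness
        pc = simulate_plot_cloud(spec, self.FOOT, 1.0, 20000, seed=2)
        h = (pc.z - dem_elevation(pc.x, pc.y))[pc.classification == 1]
        assert stats.skew(h) > 0.2

    def test_mixtures_more_heterogeneous_than_pure_stands(self):
        treats = {t.label: t for t in default_treatments()}
        foot = box(0, 0, 1.5, 6.0)

        def rel_spread(label):
            sds = []
            for seed in range(5):
                pc = simulate_plot_cloud(treats[label], foot, 1.0, 3000,
                                         seed=seed)
                h = (pc.z - dem_elevation(pc.x, pc.y))[pc.classification == 1]
                sds.append(h.std() / h.mean())
            return np.mean(sds)

        assert rel_spread("CG") > rel_spread("L_CG")


class TestBandRasters:
    def test_nir_strictly_increases_with_dm(self):
        cfg = SimConfig(seed=0, n_replicates=1, years=[YearSpec(1)],
                        harvests_per_year=1, exclusions=[])
        polygons, _ = cfg.layout()
        ids = list(polygons)[:2]
        truth = pd.DataFrame([
            {"plot_id": ids[0], "year": 1, "harvest": 1, "treatment": "CG",
             "DM_t_ha": 2.0, "legume_prop": 0.4},
            {"plot_id": ids[1], "year": 1, "harvest": 1, "treatment": "CG",
             "DM_t_ha": 10.0, "legume_prop": 0.4},
        ])
        bands = simulate_band_rasters(truth, polygons, cfg, 1, 1, seed=0)
        from fusionfield.core import zonal_mean
        lo = zonal_mean(bands["nir"], polygons[ids[0]])
        hi = zonal_mean(bands["nir"], polygons[ids[1]])
        assert hi > lo
        red_lo = zonal_mean(bands["red"], polygons[ids[0]])
        red_hi = zonal_mean(bands["red"], polygons[ids[1]])
        assert red_hi < red_lo

    def test_reflectances_bounded(self, default_bundle):
        for scene in default_bundle.bands.values():
            for g in scene.values():
                v = g.values[np.isfinite(g.values)]
                assert v.min() >= 0.0 and v.max() <= 1.0

    def test_zero_noise_gives_constant_plot_and_unit_glcm_energy(self):
        cfg = SimConfig(seed=0, n_replicates=1, years=[YearSpec(1)],
                        harvests_per_year=1, exclusions=[],
                        reflectance_sd=0.0, plot_reflectance_sd=0.0)
        polygons, _ = cfg.layout()
        pid = list(polygons)[0]
        truth = pd.DataFrame([{"plot_id": pid, "year": 1, "harvest": 1,
                               "treatment": "CG", "DM_t_ha": 5.0,
                               "legume_prop": 0.4}])
        bands = simulate_band_rasters(truth, polygons, cfg, 1, 1, seed=0)
        poly = polygons[pid].buffer(-0.2)  # interior, away from soil edge
        crop = bands["nir"].crop(*poly.bounds)
        assert crop.values.std() == pytest.approx(0.0, abs=1e-12)
        with pytest.warns(UserWarning):
            q = quantize(crop.values, 8)
        f = haralick_features(glcm(q, [(0, 1)], n_levels=8))
        assert f.energy == 1.0

    def test_short_correlation_length_raises_texture_entropy(self, rng):
        rng_span = (-3.5, 3.5)
        white = gaussian_random_field((60, 60), 0.05, 0.0, rng)
        smooth = gaussian_random_field((60, 60), 0.05, 0.4, rng)
        fw = haralick_features(glcm(quantize(white, 8, rng_span), [(0, 1)],
                                    n_levels=8))
        fs = haralick_features(glcm(quantize(smooth, 8, rng_span), [(0, 1)],
                                    n_levels=8))
        assert fw.entropy > fs.entropy
        # i.i.d. comparison: white-noise field entropy is near the maximum
        iid = haralick_features(glcm(
            quantize(rng.standard_normal((60, 60)), 8, rng_span), [(0, 1)],
            n_levels=8))
        assert fw.entropy == pytest.approx(iid.entropy, rel=0.05)
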