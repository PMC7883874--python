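"""From a point cloud to the fifteen crop-surface-height metrics.

Rasterises a simulated plot cloud to a 5 cm digital surface model, subtracts
the bare-ground DEM (CSH = DSM - DEM) and summarises the plot.
"""

from shapely.geometry import box

from fusionfield.core import GridSpec
from fusionfield.heights import compute_csh, plot_csh_metrics, rasterize_surface
from fusionfield.synthio import default_treatments, simulate_plot_cloud, simulate_ground_cloud, SimConfig

plot = box(1.0, 1.0, 2.5, 7.0)          # 1.5 x 6 m plot
spec = default_treatments()[0]           # clover-grass mixture, ~0.5 m sward
cloud = simulate_plot_cloud(spec, plot, climate_mult=1.0, density=2000, seed=7)

ground = simulate_ground_cloud(SimConfig(seed=7, n_replicates=1,
                                         plot_length_m=6.0), seed=8)
gs = GridSpec.from_bounds(*plot.bounds, cell_size=0.05)
dsm = rasterize_surface(cloud, gs, aggregator="max")
dem = rasterize_surface(ground.subset(
    (ground.x >= 1.0) & (ground.x <= 2.5)
    & (ground.y >= 1.0) & (ground.y <= 7.0)), gs, aggregator="mean")
csh = compute_csh(dsm, dem).grid

m = plot_csh_metrics(csh, plot, excluded_strip_m=1.5)
print(f"mean CSH  {m.mean:.3f} m   (sward target was "
      f"{spec.base_height[0]:.2f} m before top-of-canopy gridding)")
print(f"p95       {m.p95:.3f} m   max {m.max:.3f} m")
print(f"sd        {m.sd:.3f} m   skewness {m.skewness:.2f}  relief {m.relief:.2f}")
print("\nThe max-aggregated surface sits above the point mean; positive"
      "\nskewness and a mid-range relief are typical for patchy swards.")
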