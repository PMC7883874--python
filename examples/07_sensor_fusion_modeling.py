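"""Repeated stratified-split modeling: structure vs spectra vs fusion.

Builds a reduced synthetic scene, extracts all 72 predictors and compares
the three predictor variants on fresh matter with repeated 75/25 splits.
Expect fusion to match or beat both single-sensor models.  (~2 min.)
"""

from fusionfield.modeling import repeated_modeling
from fusionfield.pipeline import extract_features, variant_predictors
from fusionfield.synthio import SimConfig, simulate_experiment

bundle = simulate_experiment(SimConfig(seed=11))
table = extract_features(bundle)

print(f"{'variant':8s} {'median R2_val':>14s} {'median rRMSEP':>14s}")
for variant in ("CSH", "MS", "Fusion"):
    s = repeated_modeling(table, variant_predictors(variant), "FM",
                          n_splits=10, master_seed=11, n_trees=120,
                          tune=False, variant=variant)
    print(f"{variant:8s} {s.r2_distribution['median']:14.3f} "
          f"{s.rrmsep_distribution['median']:13.2f}%")
print("\nrRMSEP is the prediction RMSE relative to the observed range."
      "\nHeight-only models miss the spectral nitrogen/density signal,"
      "\nspectra saturate at high biomass; their fusion is the most accurate.")
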