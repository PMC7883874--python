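"""Ground-truth arithmetic: quadrat scaling, N amounts, and the
difference-method estimate of symbiotic nitrogen fixation.

The difference method attributes the extra nitrogen a legume-containing
sward accumulates, relative to a paired non-fixing pure-grass reference, to
biological fixation:

    N_Fix = N_L - N_R        [kg ha^-1]

where N_L is the N amount of the legume (pure stand or mixture) and N_R the
N amount of the pure grass reference.  The reference is matched by block and
mixture type (the grass companion sown for that mixture); if the block's
reference plot is missing, the treatment mean of the remaining grass
replicates is used instead.  Negative N_Fix values are retained (they are
meaningful under the method: the reference outgrowing the legume sward) and
flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: mixture/legume treatment -> its pure-grass reference treatment
REFERENCE_TREATMENT = {"CG": "G_CG", "L_CG": "G_CG", "LG": "G_LG", "L_LG": "G_LG"}
GRASS_TREATMENTS = ("G_CG", "G_LG")


@dataclass
class NFixRecord:
    plot_id: str
    year: int
    harvest: int
    n_l: float
    n_r: float
    n_fix: float
    negative: bool = False
    reference: str = "block"  # "block" or "treatment_mean"


def scale_to_per_hectare(weight_g: float, quadrat_area_m2: float = 0.25) -> float:
    """Quadrat weight (g) to t ha^-1:  g m^-2 x 0.01."""
    if quadrat_area_m2 <= 0:
        raise ValueError("quadrat area must be positive")
    if weight_g < 0:
        raise ValueError("negative sample weight")
    return weight_g / quadrat_area_m2 * 0.01


def n_amount(dm_t_ha: float, n_conc_pct: float) -> float:
    """N amount (kg ha^-1) from DM yield (t ha^-1) and N concentration (% DM)."""
    if dm_t_ha < 0 or n_conc_pct < 0:
        raise ValueError("inputs must be non-negative")
    if n_conc_pct > 10:
        warnings.warn(f"implausible N concentration {n_conc_pct}% of DM",
                      stacklevel=2)
    return dm_t_ha * 1000.0 * n_conc_pct / 100.0


def nfix_difference(n_l: float, n_r: float) -> float:
    """Difference-method fixation: N_L - N_R (may be negative)."""
    if n_l < 0 or n_r < 0:
        raise ValueError("N amounts must be non-negative")
    return n_l - n_r


def samples_to_truth(samples: pd.DataFrame) -> pd.DataFrame:
    """Scale destructive quadrat samples to per-hectare yields.

    Expects columns plot_id, year, harvest, treatment, fresh_weight_g,
    dry_weight_g, quadrat_area_m2, n_conc; duplicate quadrats per
    plot-harvest are averaged before scaling.
    """
    if (samples["dry_weight_g"] > samples["fresh_weight_g"]).any():
        raise ValueError("dry weight exceeds fresh weight in some sample")
    keys = ["plot_id", "year", "harvest", "treatment"]
    agg = samples.groupby(keys, as_index=False).agg(
        fresh_weight_g=("fresh_weight_g", "mean"),
        dry_weight_g=("dry_weight_g", "mean"),
        quadrat_area_m2=("quadrat_area_m2", "mean"),
        n_conc=("n_conc", "mean"),
    )
    agg["FM_t_ha"] = [scale_to_per_hectare(w, a) for w, a in
                      zip(agg["fresh_weight_g"], agg["quadrat_area_m2"])]
    agg["DM_t_ha"] = [scale_to_per_hectare(w, a) for w, a in
                      zip(agg["dry_weight_g"], agg["quadrat_area_m2"])]
    agg["N_amount_kg_ha"] = [n_amount(dm, nc) for dm, nc in
                             zip(agg["DM_t_ha"], agg["n_conc"])]
    return agg[keys + ["FM_t_ha", "DM_t_ha", "n_conc", "N_amount_kg_ha"]]


def nfix_table(truth: pd.DataFrame) -> pd.DataFrame:
    """Per plot-harvest N_Fix for every legume-containing sample.

    ``truth`` needs columns plot_id, year, harvest, treatment, block,
    N_amount_kg_ha.  Pure-grass rows never receive an N_Fix value.  Rows
    whose reference cannot be resolved at all (no grass replicate for that
    year/harvest) are dropped with a log entry.
    """
    required = {"plot_id", "year", "harvest", "treatment", "block",
                "N_amount_kg_ha"}
    missing = required - set(truth.columns)
    if missing:
        raise ValueError(f"truth table misses columns {sorted(missing)}")
    grass = truth[truth["treatment"].isin(GRASS_TREATMENTS)]
    records: list[dict] = []
    legume_rows = truth[truth["treatment"].isin(REFERENCE_TREATMENT)]
    for _, row in legume_rows.iterrows():
        ref_treat = REFERENCE_TREATMENT[row["treatment"]]
        pool = grass[(grass["treatment"] == ref_treat)
                     & (grass["year"] == row["year"])
                     & (grass["harvest"] == row["harvest"])]
        block_ref = pool[pool["block"] == row["block"]]
        if len(block_ref):
            n_r = float(block_ref["N_amount_kg_ha"].iloc[0])
            ref_kind = "block"
        elif len(pool):
            n_r = float(pool["N_amount_kg_ha"].mean())
            ref_kind = "treatment_mean"
            logger.info("plot %s y%s h%s: block reference %s missing, using "
                        "treatment mean of %d replicates", row["plot_id"],
                        row["year"], row["harvest"], ref_treat, len(pool))
        else:
            logger.warning("plot %s y%s h%s: no reference %s at all, dropped",
                           row["plot_id"], row["year"], row["harvest"], ref_treat)
            continue
        n_l = float(row["N_amount_kg_ha"])
        n_fix = nfix_difference(n_l, n_r)
        records.append({
            "plot_id": row["plot_id"], "year": row["year"],
            "harvest": row["harvest"], "treatment": row["treatment"],
            "block": row["block"], "N_L_kg_ha": n_l, "N_R_kg_ha": n_r,
            "NFix_kg_ha": n_fix, "negative_flag": n_fix < 0,
            "reference": ref_kind,
        })
    return pd.DataFrame.from_records(records)


def annual_sums(table: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    """Cumulative annual totals (sum of the harvests) per plot and year."""
    return (table.groupby(["plot_id", "year", "treatment"], as_index=False)
            [value_cols].sum())
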