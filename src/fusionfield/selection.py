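"""Three-step random-forest variable selection (thresholding ->
interpretation -> prediction).

The procedure ranks variables by permutation importance averaged over many
forests and then prunes in three stages:

1. *Thresholding*: the standard deviation of each variable's importance is
   regressed on its rank with a CART tree; the minimum predicted value is
   the threshold, and variables whose **mean** importance falls below it are
   discarded (noise variables have uniformly small, low-variance
   importance, so the tree's floor separates them).
2. *Interpretation*: nested forests over the importance-ordered prefixes of
   the retained set; each prefix's OOB error is averaged over repeated
   runs, and the smallest prefix whose mean OOB error is within one
   standard deviation (of the minimizing prefix's runs) of the minimum is
   kept.
3. *Prediction*: a greedy forward pass over the interpretation set, keeping
   a variable only if it lowers the mean OOB error by more than the mean
   absolute OOB fluctuation observed among the noisy post-interpretation
   prefixes.  The first (top-ranked) variable is always kept, so the set is
   never empty.

Every stage is deterministic given (table, response, seed): ties in
importance are broken by column name, and all run seeds are spawned from
one seed sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .modeling import RandomForestOOB


@dataclass
class SelectionConfig:
    n_runs_threshold: int = 50
    n_runs_interpretation: int = 25
    n_runs_prediction: int = 25
    n_trees: int = 500
    min_samples_leaf: int = 5


@dataclass
class SelectionResult:
    ranked: pd.DataFrame                 # variable, mean_importance, sd_importance
    threshold_value: float
    retained_after_threshold: list[str]
    interpretation_set: list[str]
    prediction_set: list[str]
    oob_trace: list[float]               # one mean OOB error per nested prefix

    def __post_init__(self) -> None:
        assert set(self.prediction_set) <= set(self.interpretation_set)
        assert set(self.interpretation_set) <= set(self.retained_after_threshold)

    def to_dict(self) -> dict:
        return {
            "ranked": self.ranked.to_dict(orient="records"),
            "threshold_value": self.threshold_value,
            "retained_after_threshold": self.retained_after_threshold,
            "interpretation_set": self.interpretation_set,
            "prediction_set": self.prediction_set,
            "oob_trace": self.oob_trace,
        }


def _spawned_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31 - 1))
            for s in np.random.SeedSequence(seed).spawn(n)]


def importance_runs(X: pd.DataFrame, y, n_runs: int = 50, seed: int = 0,
                    n_trees: int = 500, mtry: int | None = None) -> pd.DataFrame:
    """Mean and sd of OOB permutation importance over repeated forests.

    Returns one row per variable sorted by decreasing mean importance
    (ties broken by column name for reproducibility)."""
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two predictors")
    if len(y) < 10:
        raise ValueError("need at least 10 samples")
    if np.unique(y).size < 2:
        raise ValueError("constant response")
    Xv = X.to_numpy(dtype=float)
    imps = np.empty((n_runs, X.shape[1]))
    for k, s in enumerate(_spawned_seeds(seed, n_runs)):
        rf = RandomForestOOB(n_trees=n_trees, mtry=mtry, random_state=s)
        rf.fit(Xv, y)
        imps[k] = rf.permutation_importance(np.random.default_rng(s))
    df = pd.DataFrame({
        "variable": X.columns,
        "mean_importance": imps.mean(axis=0),
        "sd_importance": imps.std(axis=0, ddof=1) if n_runs > 1
        else np.zeros(X.shape[1]),
    })
    return (df.sort_values(["mean_importance", "variable"],
                           ascending=[False, True])
            .reset_index(drop=True))


def threshold_step(ranked: pd.DataFrame) -> tuple[list[str], float]:
    """Discard variables whose mean importance falls below the CART floor.

    The threshold is the minimum prediction of a regression tree fitted to
    importance-sd versus rank.  If everything would be discarded the top
    ceil(sqrt(p)) variables are kept with a warning."""
    if len(ranked) == 0:
        raise ValueError("empty ranking")
    if len(ranked) == 1:
        return list(ranked["variable"]), float(ranked["sd_importance"].iloc[0])
    rank = np.arange(len(ranked), dtype=float).reshape(-1, 1)
    sd = ranked["sd_importance"].to_numpy(dtype=float)
    tree = DecisionTreeRegressor(min_samples_leaf=max(1, len(ranked) // 10),
                                 random_state=0)
    tree.fit(rank, sd)
    threshold = float(tree.predict(rank).min())
    keep = ranked["mean_importance"].to_numpy() >= threshold
    if not keep.any():
        p = len(ranked)
        k = int(np.ceil(np.sqrt(p)))
        warnings.warn(f"threshold {threshold:.3g} discards every variable; "
                      f"falling back to the top {k}", stacklevel=2)
        keep = np.zeros(p, dtype=bool)
        keep[:k] = True
    return list(ranked.loc[keep, "variable"]), threshold


def _mean_oob(X: np.ndarray, y: np.ndarray, cols: list[int], n_runs: int,
              seeds: list[int], n_trees: int) -> tuple[float, float]:
    """Mean and sd of the OOB error of repeated forests on a column subset."""
    errors = np.empty(n_runs)
    for k in range(n_runs):
        rf = RandomForestOOB(n_trees=n_trees,
                             mtry=max(1, int(np.ceil(len(cols) / 3))),
                             random_state=seeds[k])
        rf.fit(X[:, cols], y)
        errors[k] = rf.oob_mse()
    return float(errors.mean()), float(errors.std(ddof=1)) if n_runs > 1 else 0.0


def interpretation_step(X: pd.DataFrame, y, retained: list[str],
                        n_runs: int = 25, seed: int = 0,
                        n_trees: int = 500) -> tuple[list[str], list[float]]:
    """Smallest importance-ordered prefix within one sd of the minimum OOB.

    Returns the interpretation set and the full OOB trace (one mean error
    per nested prefix of the retained list)."""
    if not retained:
        raise ValueError("retained set is empty")
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    Xv = X[retained].to_numpy(dtype=float)
    seeds = _spawned_seeds(seed, n_runs)
    trace, sds = [], []
    for k in range(1, len(retained) + 1):
        m, s = _mean_oob(Xv, y, list(range(k)), n_runs, seeds, n_trees)
        trace.append(m)
        sds.append(s)
    kmin = int(np.argmin(trace))
    cutoff = trace[kmin] + sds[kmin]
    ksel = next(k for k, m in enumerate(trace) if m <= cutoff)
    return retained[:ksel + 1], trace


def prediction_step(X: pd.DataFrame, y, interpretation_set: list[str],
                    oob_trace: list[float] | None = None,
                    retained: list[str] | None = None,
                    n_runs: int = 25, seed: int = 0,
                    n_trees: int = 500) -> list[str]:
    """Greedy forward pass keeping variables whose OOB gain beats the noise.

    The noise level is the mean absolute step of the OOB trace over the
    post-interpretation prefixes (the "noisy" variables); with no such
    prefixes the step threshold is 0 and only strictly improving variables
    are added.  The first variable is always kept."""
    if not interpretation_set:
        raise ValueError("interpretation set is empty")
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if oob_trace is not None and retained is not None \
            and len(oob_trace) > len(interpretation_set):
        tail = np.asarray(oob_trace[len(interpretation_set) - 1:])
        noise_jump = float(np.abs(np.diff(tail)).mean())
    else:
        noise_jump = 0.0
    seeds = _spawned_seeds(seed, n_runs)
    Xv = X[interpretation_set].to_numpy(dtype=float)
    current = [0]
    current_oob, _ = _mean_oob(Xv, y, current, n_runs, seeds, n_trees)
    for j in range(1, len(interpretation_set)):
        cand_oob, _ = _mean_oob(Xv, y, current + [j], n_runs, seeds, n_trees)
        if current_oob - cand_oob > noise_jump:
            current.append(j)
            current_oob = cand_oob
    return [interpretation_set[j] for j in current]


def select_variables(X: pd.DataFrame, y, seed: int = 0,
                     config: SelectionConfig | None = None) -> SelectionResult:
    """Run all three selection steps on a predictor table."""
    config = config or SelectionConfig()
    s1, s2, s3 = _spawned_seeds(seed, 3)
    ranked = importance_runs(X, y, n_runs=config.n_runs_threshold, seed=s1,
                             n_trees=config.n_trees)
    retained, threshold = threshold_step(ranked)
    interp, trace = interpretation_step(
        X, y, retained, n_runs=config.n_runs_interpretation, seed=s2,
        n_trees=config.n_trees)
    pred = prediction_step(X, y, interp, oob_trace=trace, retained=retained,
                           n_runs=config.n_runs_prediction, seed=s3,
                           n_trees=config.n_trees)
    return SelectionResult(ranked=ranked, threshold_value=threshold,
                           retained_after_threshold=retained,
                           interpretation_set=interp, prediction_set=pred,
                           oob_trace=trace)
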