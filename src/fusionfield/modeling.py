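"""Repeated stratified-split random-forest regression and its metrics.

The estimation protocol: the feature table is split 100 times into a 75 %
calibration and 25 % validation part such that every year, harvest date and
treatment is represented in both parts; per split, mtry is tuned by
cross-validation on the calibration rows, a random forest is fitted, and
validation accuracy is summarised as

    R2_val  = 1 - sum (y - yhat)^2 / sum (y - ybar)^2
    rRMSEP  = 100 * RMSE / (max(y) - min(y))        [%]

with distributions (median, quartiles, 5/95 percentiles) reported over the
splits.  Variable importance is the permutation increase in out-of-bag (OOB)
mean squared error, aggregated by median over splits.  A per-sample
normalized deviation, norm.dev = (yhat - y)/(yhat + y) in [-1, 1], feeds a
Kruskal-Wallis / Dunn post-hoc test of the sampling-year effect per mixture.

The forest is a bagged ensemble of scikit-learn regression trees with
explicit bootstrap bookkeeping: per-tree OOB index masks are required for
OOB error and OOB permutation importance, which the stock sklearn forest
does not expose.  Tree-level settings follow the classic regression-forest
defaults (mtry = p/3, node size 5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

STRATA_KEYS = ("year", "harvest", "treatment")


# --------------------------------------------------------------------------
# random forest with OOB bookkeeping
# --------------------------------------------------------------------------

class RandomForestOOB:
    """Bagged regression trees exposing OOB error and permutation importance.

    Parameters
    ----------
    n_trees : ensemble size (500 is the stability default; smaller values
        are adequate for the repeated studies bundled with the package).
    mtry : candidate variables per split; ``None`` means ceil(p / 3).
    """

    def __init__(self, n_trees: int = 500, mtry: int | None = None,
                 min_samples_leaf: int = 5, random_state: int | None = None):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state
        self.trees_: list[DecisionTreeRegressor] = []
        self.oob_masks_: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForestOOB":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        mtry = int(np.ceil(p / 3)) if self.mtry is None else self.mtry
        if mtry > p:
            warnings.warn(f"mtry={mtry} exceeds p={p}; clamped to p",
                          stacklevel=2)
            mtry = p
        if mtry < 1:
            raise ValueError("mtry must be at least 1")
        self.mtry_ = mtry
        self._X, self._y = X, y
        rng = np.random.default_rng(self.random_state)
        self.trees_, self.oob_masks_ = [], []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = DecisionTreeRegressor(
                max_features=mtry, min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2 ** 31 - 1)))
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            self.oob_masks_.append(oob)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        acc = np.zeros(X.shape[0])
        for tree in self.trees_:
            acc += tree.predict(X)
        return acc / len(self.trees_)

    def oob_prediction(self) -> np.ndarray:
        """Per-sample mean prediction of the trees that did not see it
        (NaN for samples in every bootstrap, vanishingly rare)."""
        n = self._X.shape[0]
        total = np.zeros(n)
        count = np.zeros(n)
        for tree, oob in zip(self.trees_, self.oob_masks_):
            if oob.any():
                total[oob] += tree.predict(self._X[oob])
                count[oob] += 1
        with np.errstate(invalid="ignore"):
            pred = total / count
        pred[count == 0] = np.nan
        return pred

    def oob_mse(self) -> float:
        pred = self.oob_prediction()
        ok = np.isfinite(pred)
        return float(np.mean((self._y[ok] - pred[ok]) ** 2))

    def permutation_importance(self, rng: np.random.Generator | int | None = None
                               ) -> np.ndarray:
        """Increase in OOB MSE when each variable is permuted.

        One permutation per variable per forest (the per-tree permutation of
        the classic implementation averages out over repeated runs).  The
        permuted design matrices are stacked so each tree predicts once.
        """
        rng = np.random.default_rng(rng)
        X, y = self._X, self._y
        n, p = X.shape
        Xp = np.repeat(X[None, :, :], p, axis=0)
        for j in range(p):
            Xp[j, :, j] = X[rng.permutation(n), j]
        flat = Xp.reshape(p * n, p)
        inc = np.zeros(p)
        weight = 0
        for tree, oob in zip(self.trees_, self.oob_masks_):
            if not oob.any():
                continue
            base = np.mean((y[oob] - tree.predict(X[oob])) ** 2)
            perm_pred = tree.predict(flat).reshape(p, n)
            perm_mse = np.mean((y[None, oob] - perm_pred[:, oob]) ** 2, axis=1)
            inc += perm_mse - base
            weight += 1
        return inc / max(weight, 1)


def fit_rf(X, y, mtry: int | None = None, n_trees: int = 500,
           seed: int | None = None) -> RandomForestOOB:
    """Convenience constructor-and-fit."""
    return RandomForestOOB(n_trees=n_trees, mtry=mtry,
                           random_state=seed).fit(np.asarray(X), np.asarray(y))


# --------------------------------------------------------------------------
# accuracy metrics
# --------------------------------------------------------------------------

def r2_val(observed, predicted, ybar: str = "observed") -> float:
    """Validation coefficient of determination.

    ``ybar="observed"`` (default) centres the total sum of squares on the
    observed mean — the convention that makes R2 comparable across models;
    ``ybar="predicted"`` centres it on the mean prediction instead.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two observations")
    centre = y.mean() if ybar == "observed" else yhat.mean()
    ss_tot = float(((y - centre) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant observations: R2 undefined")
    return float(1.0 - ((y - yhat) ** 2).sum() / ss_tot)


def rrmsep(observed, predicted) -> float:
    """Root mean squared error of prediction relative to the observed range, %."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    rng_y = y.max() - y.min()
    if rng_y <= 0:
        raise ValueError("zero observed range: rRMSEP undefined")
    rmse = float(np.sqrt(((y - yhat) ** 2).mean()))
    return 100.0 * rmse / rng_y


def norm_dev(observed, predicted) -> np.ndarray:
    """(yhat - y) / (yhat + y) per sample; in [-1, 1] for positive values.

    Positive values flag overestimation.  A vanishing sum yields NaN with a
    warning."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    s = yhat + y
    bad = s == 0
    if bad.any():
        warnings.warn(f"{bad.sum()} samples with yhat + y == 0: norm.dev NaN",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (yhat - y) / s
    return np.where(bad, np.nan, out)


# --------------------------------------------------------------------------
# stratified splitting
# --------------------------------------------------------------------------

def stratified_split(table: pd.DataFrame, cal_fraction: float = 0.75,
                     seed: int | None = None,
                     strata: tuple[str, ...] = STRATA_KEYS,
                     max_tries: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Random calibration/validation split with marginal stratum coverage.

    Both parts contain at least one row from every level of every stratum
    key (year, harvest date, treatment).  Implemented by rejection sampling;
    a level with fewer than two rows makes coverage infeasible and raises.
    Returns positional (calibration, validation) index arrays — disjoint and
    exhaustive.
    """
    n = len(table)
    for key in strata:
        counts = table[key].value_counts()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"stratum {key}={bad} has fewer than 2 rows; "
                             "coverage in both subsets is infeasible")
    n_val = max(1, int(round((1 - cal_fraction) * n)))
    rng = np.random.default_rng(seed)
    levels = {key: set(table[key].unique()) for key in strata}
    for _ in range(max_tries):
        perm = rng.permutation(n)
        val = np.sort(perm[:n_val])
        cal = np.sort(perm[n_val:])
        ok = True
        for key in strata:
            col = table[key].to_numpy()
            if set(col[val]) != levels[key] or set(col[cal]) != levels[key]:
                ok = False
                break
        if ok:
            return cal, val
    raise RuntimeError("could not find a covering split "
                       f"in {max_tries} attempts")


def tune_mtry(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int,
              cv_folds: int = 5, grid_halfwidth: int = 2) -> int:
    """Cross-validated mtry choice on the calibration rows.

    The grid is centred on the ceil(p/3) regression default,
    {default - hw ... default + hw} clamped to [1, p]."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    default = int(np.ceil(p / 3))
    grid = sorted({int(np.clip(m, 1, p))
                   for m in range(default - grid_halfwidth,
                                  default + grid_halfwidth + 1)})
    if len(grid) == 1:
        return grid[0]
    kf = KFold(n_splits=min(cv_folds, len(y)), shuffle=True, random_state=seed)
    best_mtry, best_mse = grid[0], np.inf
    for k, m in enumerate(grid):
        mse = 0.0
        for f, (tr, te) in enumerate(kf.split(X)):
            rf = fit_rf(X[tr], y[tr], mtry=m, n_trees=n_trees,
                        seed=seed * 1000 + k * 10 + f)
            mse += float(((y[te] - rf.predict(X[te])) ** 2).mean())
        if mse < best_mse - 1e-12:
            best_mse, best_mtry = mse, m
    return best_mtry


# --------------------------------------------------------------------------
# repeated modeling
# --------------------------------------------------------------------------

@dataclass
class SplitResult:
    split_index: int
    seed: int
    mtry: int
    val_index: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray
    r2_val: float
    rrmsep: float
    importance: pd.Series


@dataclass
class ModelSummary:
    variant: str
    response: str
    predictors: list[str]
    splits: list[SplitResult]
    r2_distribution: dict[str, float]
    rrmsep_distribution: dict[str, float]
    importance_ranking: pd.DataFrame      # variable, median importance
    appearance_counts: pd.Series          # per-sample validation appearances

    def predictions_frame(self, table: pd.DataFrame | None = None) -> pd.DataFrame:
        frames = []
        for s in self.splits:
            df = pd.DataFrame({
                "split_index": s.split_index, "row": s.val_index,
                "observed": s.observed, "predicted": s.predicted,
            })
            frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        out["norm_dev"] = norm_dev(out["observed"], out["predicted"])
        if table is not None:
            keys = table.reset_index(drop=True)
            for col in ("plot_id", "year", "harvest", "treatment"):
                if col in keys.columns:
                    out[col] = keys[col].to_numpy()[out["row"].to_numpy()]
        return out


def _distribution(values: np.ndarray) -> dict[str, float]:
    q = np.percentile(values, [5, 25, 50, 75, 95])
    return {"p5": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
            "q3": float(q[3]), "p95": float(q[4]), "mean": float(values.mean())}


def repeated_modeling(table: pd.DataFrame, predictors: list[str],
                      response: str, n_splits: int = 100,
                      master_seed: int = 0, n_trees: int = 500,
                      tune: bool = True, cv_folds: int = 5,
                      cal_fraction: float = 0.75,
                      ybar: str = "observed",
                      variant: str = "") -> ModelSummary:
    """Repeated stratified-split validation of a random-forest model.

    ``table`` must contain the predictor columns, the response, and the
    stratification keys; rows with a missing response are dropped first.
    The master seed deterministically spawns one seed per split.
    """
    data = table.dropna(subset=[response]).reset_index(drop=True)
    X = data[predictors].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1))
             for s in ss.spawn(n_splits)]
    splits: list[SplitResult] = []
    appearances = np.zeros(len(data), dtype=int)
    for k in range(n_splits):
        seed = seeds[k]
        cal, val = stratified_split(data, cal_fraction, seed)
        appearances[val] += 1
        if tune:
            mtry = tune_mtry(X[cal], y[cal], n_trees=n_trees, seed=seed,
                             cv_folds=cv_folds)
        else:
            mtry = min(int(np.ceil(len(predictors) / 3)), len(predictors))
        rf = fit_rf(X[cal], y[cal], mtry=mtry, n_trees=n_trees, seed=seed)
        pred = rf.predict(X[val])
        imp = pd.Series(rf.permutation_importance(np.random.default_rng(seed)),
                        index=predictors)
        splits.append(SplitResult(
            split_index=k, seed=seed, mtry=mtry, val_index=val,
            observed=y[val], predicted=pred,
            r2_val=r2_val(y[val], pred, ybar=ybar),
            rrmsep=rrmsep(y[val], pred), importance=imp))
    imp_matrix = pd.DataFrame([s.importance for s in splits])
    ranking = (imp_matrix.median().rename("median_importance")
               .sort_values(ascending=False).reset_index()
               .rename(columns={"index": "variable"}))
    return ModelSummary(
        variant=variant, response=response, predictors=list(predictors),
        splits=splits,
        r2_distribution=_distribution(np.array([s.r2_val for s in splits])),
        rrmsep_distribution=_distribution(np.array([s.rrmsep for s in splits])),
        importance_ranking=ranking,
        appearance_counts=pd.Series(appearances, name="n_validation"),
    )


# --------------------------------------------------------------------------
# year-effect statistics (Kruskal-Wallis + Dunn post hoc)
# --------------------------------------------------------------------------

def dunn_test(groups: dict, p_adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise rank comparison after a Kruskal-Wallis test.

    Tie-corrected z statistics on the pooled mean ranks; two-sided p-values
    adjusted by Holm's step-down method by default.
    """
    labels = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in labels]
    pooled = np.concatenate(values)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for lab, v in zip(labels, values):
        mean_ranks[lab] = ranks[start:start + v.size].mean()
        sizes[lab] = v.size
        start += v.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (N - 1))
    rows = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            la, lb = labels[a], labels[b]
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[la] + 1.0 / sizes[lb]))
            z = (mean_ranks[la] - mean_ranks[lb]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": la, "group_b": lb, "z": z, "p": p})
    df = pd.DataFrame(rows)
    if p_adjust == "holm":
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank_i, idx in enumerate(np.argsort(df["p"].to_numpy())):
            running = max(running, (m - rank_i) * df["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        df["p_adjusted"] = adj
    elif p_adjust in (None, "none"):
        df["p_adjusted"] = df["p"]
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    return df


def compact_letters(labels: list, pairs_significant: dict) -> dict:
    """Compact letter display: groups sharing a letter do not differ.

    Greedy insert-and-absorb over the non-significance graph; adequate for
    the handful of year groups compared here."""
    letter_sets: list[set] = []
    for lab in labels:
        placed = False
        for s in letter_sets:
            if all(not pairs_significant.get(frozenset((lab, other)), False)
                   for other in s):
                s.add(lab)
                placed = True
        if not placed:
            letter_sets.append({lab})
    # drop subsets
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, s in zip(alphabet, letter_sets):
        for lab in labels:
            if lab in s:
                out[lab] += letter
    return out


def year_effect_test(records: pd.DataFrame, value: str = "norm_dev",
                     group: str = "year", by: str = "mixture",
                     alpha: float = 0.05) -> dict:
    """Kruskal-Wallis + Dunn test of the grouping effect, per mixture.

    Returns per-mixture H, p, the Dunn pairwise table and a compact-letter
    display of significant differences."""
    report: dict = {}
    for mix, sub in records.groupby(by):
        groups = {g: grp[value].dropna().to_numpy()
                  for g, grp in sub.groupby(group)}
        if len(groups) < 2:
            raise ValueError(f"{by}={mix}: need at least two {group} groups")
        for g, v in groups.items():
            if v.size < 3:
                raise ValueError(f"{by}={mix}, {group}={g}: fewer than 3 values")
        pooled = np.concatenate(list(groups.values()))
        if np.unique(pooled).size < 2:
            raise ValueError(f"{by}={mix}: all values tied; test degenerate")
        H, p = stats.kruskal(*groups.values())
        dunn = dunn_test(groups)
        sig = {frozenset((r["group_a"], r["group_b"])): r["p_adjusted"] < alpha
               for _, r in dunn.iterrows()}
        letters = compact_letters(list(groups), sig)
        report[mix] = {"H": float(H), "p": float(p), "dunn": dunn,
                       "letters": letters}
    return report
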