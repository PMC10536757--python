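"""Model fitting, cross-validation, buffer sweeps, and city transfer.

Three regression families are supported — a linear model, gradient-boosted
trees, and an RBF support-vector machine — all fit on standardized inputs and
outputs. Within-city performance is estimated with fivefold cross-validation
(folds stratified by target quartile); RMSE, MAE, and R-squared are computed
on the pooled out-of-fold predictions. R-squared is the squared Pearson
correlation between out-of-fold predictions and observations (zero when the
predictions are constant), so it always lies in [0, 1].

Transfer: a model fitted on one city is applied unchanged to another.
Features are standardized with the training city's statistics everywhere;
targets are standardized within city by default, because the two cities may
define the same count differently (e.g. annualized vs rush-hour traffic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVR

MODEL_FAMILIES = ("linear", "gbt", "svm")

#: Fixed hyperparameter grids tuned inside each training fold.
GBT_DEPTHS = (2, 3, 4)
GBT_N_ESTIMATORS = 200
GBT_LEARNING_RATE = 0.1
SVM_COSTS = (0.25, 1.0, 4.0)

#: Default radii for the intersection buffer sweep: 50, 100, ..., 2000 m.
DEFAULT_SWEEP_RADII = tuple(range(50, 2001, 50))


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationStats:
    means: dict[str, float]
    sds: dict[str, float]
    source: str  # provenance: which dataset the stats were estimated on

    @classmethod
    def fit(cls, df: pd.DataFrame, source: str) -> "StandardizationStats":
        means, sds = {}, {}
        for col in df.columns:
            v = df[col].to_numpy(dtype=float)
            mu = float(np.mean(v))
            sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            if sd <= 0:
                raise ValueError(
                    f"variable {col!r} has zero standard deviation on {source!r}"
                )
            means[col], sds[col] = mu, sd
        return cls(means=means, sds=sds, source=source)


def standardize(df: pd.DataFrame, stats: StandardizationStats) -> pd.DataFrame:
    """(x - mean) / sd per column, using the supplied (possibly out-of-sample)
    statistics."""
    out = {}
    for col in df.columns:
        if col not in stats.means:
            raise KeyError(f"no standardization stats for variable {col!r}")
        out[col] = (df[col].to_numpy(dtype=float) - stats.means[col]) / stats.sds[col]
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def mae(pred: np.ndarray, obs: np.ndarray) -> float:
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    return float(np.mean(np.abs(pred - obs)))


def r2_corr(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation of predictions vs observations.

    Returns 0 when either vector is constant (a degenerate predictor has no
    explanatory power), keeping the statistic in [0, 1].
    """
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    r = float(np.corrcoef(pred, obs)[0, 1])
    return r * r


# ---------------------------------------------------------------------------
# Cross-validated fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model_family: str
    target_name: str
    cv_rmse: float
    cv_r2: float
    cv_mae: float
    seed: int
    fold_assignments: np.ndarray
    fold_rmses: np.ndarray
    buffer_m: Optional[float] = None
    n: int = 0
    chosen_params: dict = field(default_factory=dict)
    model: object = None
    feature_names: tuple[str, ...] = ()


def _make_estimator(family: str, params: dict, seed: int):
    if family == "linear":
        return LinearRegression()
    if family == "gbt":
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=GBT_N_ESTIMATORS,
            learning_rate=GBT_LEARNING_RATE,
            max_depth=params["max_depth"],
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
    if family == "svm":
        return SVR(kernel="rbf", C=params["C"], gamma="scale")
    raise ValueError(f"unknown model family {family!r}")


def _param_grid(family: str) -> list[dict]:
    if family == "gbt":
        return [{"max_depth": d} for d in GBT_DEPTHS]
    if family == "svm":
        return [{"C": c} for c in SVM_COSTS]
    return [{}]


def _select_params(
    X: np.ndarray, y: np.ndarray, family: str, seed: int
) -> dict:
    """Pick grid parameters by inner 3-fold CV RMSE (first-best tie break)."""
    grid = _param_grid(family)
    if len(grid) == 1:
        return grid[0]
    inner = KFold(n_splits=3, shuffle=True, random_state=seed)
    best, best_score = grid[0], math.inf
    for params in grid:
        errs = []
        for tr, va in inner.split(X):
            est = _make_estimator(family, params, seed)
            est.fit(X[tr], y[tr])
            errs.append(rmse(est.predict(X[va]), y[va]))
        score = float(np.mean(errs))
        if score < best_score - 1e-12:
            best, best_score = params, score
    return best


def _quartile_strata(y: np.ndarray) -> np.ndarray:
    ranks = pd.Series(y).rank(method="first").to_numpy()
    q = np.ceil(ranks * 4 / len(y)).astype(int)
    return q


def fit_cv(
    features: pd.DataFrame,
    target: pd.Series,
    family: str = "linear",
    k: int = 5,
    seed: int = 0,
    target_name: str = "",
    buffer_m: Optional[float] = None,
) -> FitResult:
    """Fivefold (by default) cross-validated fit of one model family.

    Folds are stratified by target quartile and derived deterministically
    from ``seed``; out-of-fold predictions are pooled before computing RMSE,
    R-squared, and MAE. The returned result also carries a final model fitted
    on the full data (with grid parameters re-selected on the full data) for
    use in transfer evaluation.
    """
    X = features.to_numpy(dtype=float)
    y = target.to_numpy(dtype=float)
    n = len(y)
    if n < k:
        raise ValueError(f"n={n} is smaller than k={k}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in features or target")

    strata = _quartile_strata(y)
    stratum_sizes = np.bincount(strata)
    if stratum_sizes[stratum_sizes > 0].min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X, strata)
    else:  # too few per quartile to stratify
        splits = KFold(n_splits=k, shuffle=True, random_state=seed).split(X)
    pooled = np.empty(n)
    assignments = np.empty(n, dtype=int)
    fold_rmses = []
    for fold, (tr, te) in enumerate(splits):
        params = _select_params(X[tr], y[tr], family, seed)
        est = _make_estimator(family, params, seed)
        est.fit(X[tr], y[tr])
        pred = np.asarray(est.predict(X[te]), dtype=float)
        pooled[te] = pred
        assignments[te] = fold
        fold_rmses.append(rmse(pred, y[te]))

    final_params = _select_params(X, y, family, seed)
    final = _make_estimator(family, final_params, seed)
    final.fit(X, y)

    return FitResult(
        model_family=family,
        target_name=target_name,
        cv_rmse=rmse(pooled, y),
        cv_r2=r2_corr(pooled, y),
        cv_mae=mae(pooled, y),
        seed=seed,
        fold_assignments=assignments,
        fold_rmses=np.array(fold_rmses),
        buffer_m=buffer_m,
        n=n,
        chosen_params=final_params,
        model=final,
        feature_names=tuple(features.columns),
    )


# ---------------------------------------------------------------------------
# Transfer
# ---------------------------------------------------------------------------

@dataclass
class TransferResult:
    test_rmse: float
    test_r2: float
    test_mae: float
    calibration_gap: float  # mean prediction - mean observation


def evaluate_transfer(
    fit: FitResult,
    features: pd.DataFrame,
    target: pd.Series,
) -> TransferResult:
    """Apply a fitted model unchanged to another city's (standardized) data.

    ``features`` must already be standardized with the training city's stats
    and ``target`` with the agreed policy (within-city by default); the
    caller owns that policy and its provenance.
    """
    cols = tuple(features.columns)
    if cols != fit.feature_names:
        raise ValueError(
            f"feature columns {cols} do not match the fitted model's "
            f"{fit.feature_names}"
        )
    pred = np.asarray(fit.model.predict(features.to_numpy(dtype=float)), float)
    obs = target.to_numpy(dtype=float)
    return TransferResult(
        test_rmse=rmse(pred, obs),
        test_r2=r2_corr(pred, obs),
        test_mae=mae(pred, obs),
        calibration_gap=float(np.mean(pred) - np.mean(obs)),
    )


# ---------------------------------------------------------------------------
# Buffer sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    table: pd.DataFrame  # columns: buffer_m, family, cv_rmse, cv_r2, cv_mae, n
    argmin_radius: float
    selected_radius: float  # 1-SE rule


def sweep_buffers(
    anchors: pd.DataFrame,  # columns: id, x, y
    point_coords: pd.DataFrame,  # columns: point_id, x, y
    image_features: pd.DataFrame,  # point_id + one column per feature
    target: pd.Series,  # indexed by anchor id
    radii: Sequence[float] = DEFAULT_SWEEP_RADII,
    families: Sequence[str] = ("linear",),
    k: int = 5,
    seed: int = 0,
    target_name: str = "",
) -> SweepResult:
    """Fit every (radius, family) pair on Euclidean-disc buffer features.

    For each radius, each anchor's features are the unweighted means of the
    image-level features of sample points within that distance; anchors with
    no in-range imagery are dropped for that radius. The selected buffer is
    the smallest radius whose best-family cv_rmse is within one standard
    error of the global minimum (1-SE rule); the raw argmin is also reported.
    """
    radii = sorted(float(r) for r in radii)
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    feat_cols = [c for c in image_features.columns if c != "point_id"]
    pts = point_coords.merge(image_features, on="point_id")
    pxy = pts[["x", "y"]].to_numpy(float)
    pfeat = pts[feat_cols].to_numpy(float)
    axy = anchors[["x", "y"]].to_numpy(float)
    ids = anchors["id"].astype(str).to_list()
    y_all = target.reindex(ids).to_numpy(float)

    d = np.hypot(
        axy[:, [0]] - pxy[None, :, 0], axy[:, [1]] - pxy[None, :, 1]
    )  # (n_anchors, n_images)

    rows = []
    fits: dict[tuple[float, str], FitResult] = {}
    for r in radii:
        member = d <= r
        counts = member.sum(axis=1)
        ok = counts > 0
        if ok.sum() < k:
            for fam in families:
                rows.append(
                    dict(buffer_m=r, family=fam, cv_rmse=np.nan, cv_r2=np.nan,
                         cv_mae=np.nan, n=int(ok.sum()))
                )
            continue
        means = (member[ok] @ pfeat) / counts[ok, None]
        Xr = pd.DataFrame(means, columns=feat_cols)
        yr = pd.Series(y_all[ok])
        for fam in families:
            fit = fit_cv(Xr, yr, family=fam, k=k, seed=seed,
                         target_name=target_name, buffer_m=r)
            fits[(r, fam)] = fit
            rows.append(
                dict(buffer_m=r, family=fam, cv_rmse=fit.cv_rmse,
                     cv_r2=fit.cv_r2, cv_mae=fit.cv_mae, n=fit.n)
            )
    table = pd.DataFrame(rows)

    best_per_radius = table.groupby("buffer_m")["cv_rmse"].min()
    valid = best_per_radius.dropna()
    if valid.empty:
        raise ValueError("no radius produced a fittable dataset")
    argmin_radius = float(valid.idxmin())
    best_row = table[
        (table["buffer_m"] == argmin_radius)
        & (table["cv_rmse"] == valid.min())
    ].iloc[0]
    best_fit = fits[(argmin_radius, best_row["family"])]
    se = float(
        np.std(best_fit.fold_rmses, ddof=1) / math.sqrt(len(best_fit.fold_rmses))
    )
    threshold = valid.min() + se
    selected_radius = float(valid[valid <= threshold].index.min())
    return SweepResult(
        table=table, argmin_radius=argmin_radius, selected_radius=selected_radius
    )


# ---------------------------------------------------------------------------
# Sidewalk classification accuracy
# ---------------------------------------------------------------------------

@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else math.nan

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def sidewalk_accuracy(
    labels_pred: Mapping[str, bool], labels_truth: Mapping[str, bool]
) -> ConfusionSummary:
    """Per-segment confusion counts against the municipal ground truth.

    Both mappings must cover exactly the same segment ids; segments with a
    missing predicted label should be dropped by the caller beforehand.
    """
    if set(labels_pred) != set(labels_truth):
        only_p = sorted(set(labels_pred) - set(labels_truth))[:3]
        only_t = sorted(set(labels_truth) - set(labels_pred))[:3]
        raise ValueError(
            f"segment id mismatch (pred-only {only_p}, truth-only {only_t})"
        )
    tp = fp = tn = fn = 0
    for sid, truth in labels_truth.items():
        pred = labels_pred[sid]
        if truth and pred:
            tp += 1
        elif truth and not pred:
            fn += 1
        elif not truth and pred:
            fp += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)
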