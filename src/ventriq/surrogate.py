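"""Gradient-boosted tree surrogates of the reduced-order simulator.

The surrogate maps material-parameter features (plus time, or element
centroid coordinates) to pressure, volume or stress targets with an
XGBoost regression ensemble (squared-error objective, ``gbtree`` booster).
Hyperparameters are chosen by exhaustive grid search with k-fold cross
validation *grouped by cardiac cycle / LV model*: rows within one cycle
are strongly dependent, so a cycle never straddles a fold boundary.

Model quality is reported per test group — the coefficient of
determination

    R^2 = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2

and the mean absolute error ``MAE = sum |y_i - yhat_i| / n`` — then
averaged across groups with a population (n-divisor) standard deviation.
Feature importance uses total split gain, normalized to shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import GroupKFold

__all__ = [
    "SurrogateError",
    "SchemaError",
    "DataError",
    "EvaluationError",
    "HyperparamGrid",
    "SurrogateModel",
    "GridSearchResult",
    "EvalReport",
    "grid_search",
    "fit",
    "predict",
    "r2_score",
    "mae",
    "evaluate",
    "feature_importance",
    "series_summary",
    "pv_summary",
    "summary_error_table",
]

#: non-feature bookkeeping columns recognized in dataset tables
_ID_COLUMNS = ("cycle_id", "model_id", "element_id")

#: fixed backend settings shared by grid search and final fits
_BACKEND = dict(tree_method="hist", max_bin=64, n_jobs=1, verbosity=0,
                objective="reg:squarederror")


class SurrogateError(ValueError):
    pass


class SchemaError(SurrogateError):
    """Feature columns do not match the trained schema."""


class DataError(SurrogateError):
    """Training table contains invalid values."""


class EvaluationError(SurrogateError):
    """A score is undefined for the given data (e.g. zero-variance target)."""


@dataclass(frozen=True)
class HyperparamGrid:
    """Exhaustive search grid for the boosted-tree surrogate."""

    learning_rate: Tuple[float, ...] = (0.01, 0.05, 0.1)
    n_estimators: Tuple[int, ...] = (500, 1000, 1500)
    max_depth: Tuple[int, ...] = (7, 15, 20)
    cv_folds: int = 3

    def __post_init__(self) -> None:
        if not (self.learning_rate and self.n_estimators and self.max_depth):
            raise SurrogateError("grid value lists must be non-empty")
        if self.cv_folds < 2:
            raise SurrogateError("cv_folds must be >= 2")

    @property
    def n_combinations(self) -> int:
        return len(self.learning_rate) * len(self.n_estimators) * len(self.max_depth)


@dataclass
class SurrogateModel:
    """A fitted boosted-tree ensemble with its frozen feature schema."""

    booster: xgb.XGBRegressor
    feature_names: Tuple[str, ...]
    target: str
    hyperparams: Dict[str, float]
    seed: int

    def save(self, path: str) -> None:
        import json, pathlib

        p = pathlib.Path(path)
        raw = (self.booster.get_booster()
               if isinstance(self.booster, xgb.XGBRegressor) else self.booster)
        raw.save_model(p.with_suffix(".ubj"))
        meta = {
            "feature_names": list(self.feature_names),
            "target": self.target,
            "hyperparams": self.hyperparams,
            "seed": self.seed,
        }
        p.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str) -> "SurrogateModel":
        import json, pathlib

        p = pathlib.Path(path)
        meta = json.loads(p.with_suffix(".meta.json").read_text())
        booster = xgb.Booster()
        booster.load_model(str(p.with_suffix(".ubj")))
        return cls(
            booster=booster,
            feature_names=tuple(meta["feature_names"]),
            target=meta["target"],
            hyperparams=meta["hyperparams"],
            seed=meta["seed"],
        )


@dataclass(frozen=True)
class GridSearchResult:
    best_params: Dict[str, float]
    cv_results: pd.DataFrame  # one row per combination with mean CV R^2


@dataclass(frozen=True)
class EvalReport:
    """Per-group R^2 and MAE with mean +/- population SD across groups."""

    target: str
    group_key: str
    group_ids: Tuple[int, ...]
    r2_values: Tuple[float, ...]
    mae_values: Tuple[float, ...]

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.r2_values))

    @property
    def r2_sd(self) -> float:
        return float(np.std(self.r2_values))  # population SD

    @property
    def mae_mean(self) -> float:
        return float(np.mean(self.mae_values))

    @property
    def mae_sd(self) -> float:
        return float(np.std(self.mae_values))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.group_key: self.group_ids,
            "r2": self.r2_values,
            "mae": self.mae_values,
        })

    def summary(self) -> Dict[str, float]:
        return {
            "r2_mean": self.r2_mean,
            "r2_sd": self.r2_sd,
            "mae_mean": self.mae_mean,
            "mae_sd": self.mae_sd,
            "n_groups": len(self.group_ids),
        }


def r2_score(y, yhat) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise EvaluationError("y and yhat must have the same length")
    if y.size < 2:
        raise EvaluationError("R^2 needs at least 2 data points")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise EvaluationError("R^2 undefined for a zero-variance target")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def mae(y, yhat) -> float:
    """Mean absolute error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise EvaluationError("y and yhat must have the same length")
    if y.size < 1:
        raise EvaluationError("MAE needs at least 1 data point")
    return float(np.mean(np.abs(y - yhat)))


def _feature_columns(
    table: pd.DataFrame, target: str, features: Optional[Sequence[str]]
) -> Tuple[str, ...]:
    if features is not None:
        missing = [c for c in features if c not in table.columns]
        if missing:
            raise SchemaError(f"missing feature columns: {missing}")
        return tuple(features)
    return tuple(
        c for c in table.columns if c != target and c not in _ID_COLUMNS
    )


def _check_features(table: pd.DataFrame, cols: Sequence[str]) -> None:
    bad = [c for c in cols if not np.all(np.isfinite(table[c].to_numpy(dtype=float)))]
    if bad:
        raise DataError(f"non-finite values in feature columns: {bad}")


def grid_search(
    table: pd.DataFrame,
    target: str,
    grid: HyperparamGrid,
    seed: int,
    group_key: str = "cycle_id",
    features: Optional[Sequence[str]] = None,
) -> GridSearchResult:
    """Exhaustive grouped-CV grid search maximizing mean validation R^2.

    Folds are built with :class:`~sklearn.model_selection.GroupKFold` on
    ``group_key`` so that no cycle/model id crosses a fold boundary.  For
    each (learning_rate, max_depth) pair a single ensemble with the
    largest tree count is boosted per fold, and the smaller tree counts
    are scored from its leading trees — boosting is sequential, so this is
    exactly the exhaustive search at a fraction of the cost.  Ties are
    broken toward smaller ``n_estimators``, then smaller ``max_depth``,
    then smaller ``learning_rate``.
    """
    if group_key not in table.columns:
        raise SchemaError(f"grouping column {group_key!r} not in table")
    cols = _feature_columns(table, target, features)
    _check_features(table, cols)
    y_all = table[target].to_numpy(dtype=float)
    if float(np.var(y_all)) == 0.0:
        raise EvaluationError("target has zero variance; grid search undefined")
    groups = table[group_key].to_numpy()
    if len(np.unique(groups)) < grid.cv_folds:
        raise EvaluationError("need at least cv_folds distinct groups")
    X_all = table[list(cols)].to_numpy(dtype=float)

    n_list = sorted(grid.n_estimators)
    n_max = n_list[-1]
    scores: Dict[Tuple[float, int, int], list] = {
        (lr, n, d): []
        for lr, n, d in product(grid.learning_rate, n_list, grid.max_depth)
    }
    splitter = GroupKFold(n_splits=grid.cv_folds)
    for train_idx, val_idx in splitter.split(X_all, y_all, groups):
        X_tr, y_tr = X_all[train_idx], y_all[train_idx]
        X_va, y_va = X_all[val_idx], y_all[val_idx]
        dva = xgb.DMatrix(X_va)
        for lr in grid.learning_rate:
            for depth in grid.max_depth:
                model = xgb.XGBRegressor(
                    learning_rate=lr, max_depth=depth, n_estimators=n_max,
                    random_state=seed, **_BACKEND,
                )
                model.fit(X_tr, y_tr)
                booster = model.get_booster()
                for n in n_list:
                    yhat = booster.predict(dva, iteration_range=(0, n))
                    scores[(lr, n, depth)].append(r2_score(y_va, yhat))

    rows = []
    for (lr, n, depth), vals in scores.items():
        rows.append({
            "learning_rate": lr, "n_estimators": n, "max_depth": depth,
            "cv_r2_mean": float(np.mean(vals)),
        })
    cv_results = pd.DataFrame(rows)
    best_row = max(
        rows,
        key=lambda r: (
            r["cv_r2_mean"], -r["n_estimators"], -r["max_depth"], -r["learning_rate"],
        ),
    )
    best = {
        "learning_rate": float(best_row["learning_rate"]),
        "n_estimators": int(best_row["n_estimators"]),
        "max_depth": int(best_row["max_depth"]),
    }
    return GridSearchResult(best_params=best, cv_results=cv_results)


def fit(
    table: pd.DataFrame,
    target: str,
    hyperparams: Dict[str, float],
    seed: int,
    features: Optional[Sequence[str]] = None,
) -> SurrogateModel:
    """Fit the boosted-tree surrogate with fixed hyperparameters."""
    cols = _feature_columns(table, target, features)
    _check_features(table, cols)
    y = table[target].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise DataError(f"non-finite values in target column {target!r}")
    model = xgb.XGBRegressor(
        learning_rate=float(hyperparams["learning_rate"]),
        n_estimators=int(hyperparams["n_estimators"]),
        max_depth=int(hyperparams["max_depth"]),
        random_state=seed, **_BACKEND,
    )
    model.fit(table[list(cols)], y)
    return SurrogateModel(
        booster=model,
        feature_names=cols,
        target=target,
        hyperparams=dict(hyperparams),
        seed=seed,
    )


def predict(model: SurrogateModel, X: pd.DataFrame) -> np.ndarray:
    """Predict on feature rows; columns are realigned to the trained order."""
    extra = [c for c in X.columns if c not in model.feature_names and c not in _ID_COLUMNS
             and c != model.target]
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing or extra:
        raise SchemaError(
            f"feature mismatch: missing {missing or 'none'}, unexpected {extra or 'none'}"
        )
    feats = X[list(model.feature_names)]
    if isinstance(model.booster, xgb.Booster):
        dm = xgb.DMatrix(feats.to_numpy(dtype=float),
                         feature_names=list(model.feature_names))
        out = model.booster.predict(dm)
    else:
        out = model.booster.predict(feats)
    if not np.all(np.isfinite(out)):
        raise SurrogateError("non-finite predictions")
    return np.asarray(out, dtype=float)


def evaluate(
    model: SurrogateModel,
    test: pd.DataFrame,
    group_key: str,
) -> EvalReport:
    """Per-group R^2 and MAE on held-out data, grouped by cycle/model id."""
    if group_key not in test.columns:
        raise SchemaError(f"grouping column {group_key!r} not in table")
    if len(test) == 0:
        raise EvaluationError("empty test table")
    ids, r2s, maes = [], [], []
    for gid, frame in test.groupby(group_key, sort=True):
        if len(frame) == 0:  # pragma: no cover - groupby never yields empties
            raise EvaluationError(f"empty group {gid}")
        y = frame[model.target].to_numpy(dtype=float)
        yhat = predict(model, frame[list(model.feature_names)])
        ids.append(int(gid))
        r2s.append(r2_score(y, yhat))
        maes.append(mae(y, yhat))
    return EvalReport(
        target=model.target,
        group_key=group_key,
        group_ids=tuple(ids),
        r2_values=tuple(r2s),
        mae_values=tuple(maes),
    )


def feature_importance(model: SurrogateModel) -> Dict[str, float]:
    """Total-gain feature importance, normalized to shares summing to 1.

    Gain importance: how often each feature splits the trees, weighted by
    the loss improvement those splits produce, summed over the ensemble.
    Features never used for splitting get exactly 0.
    """
    booster = model.booster.get_booster()
    raw = booster.get_score(importance_type="total_gain")
    # booster may report f0, f1, ... when trained without names
    key_map = {f"f{i}": name for i, name in enumerate(model.feature_names)}
    shares = {name: 0.0 for name in model.feature_names}
    for key, val in raw.items():
        shares[key_map.get(key, key)] = float(val)
    total = sum(shares.values())
    if total <= 0:
        raise SurrogateError("model has no splits; importance undefined")
    return {name: val / total for name, val in shares.items()}


def series_summary(t: np.ndarray, y: np.ndarray) -> Dict[str, float]:
    """Min, max, time of max (earliest tie) and max time derivative.

    The derivative uses central differences in the interior and one-sided
    differences at the endpoints.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 3:
        raise SurrogateError("series_summary needs at least 3 samples")
    dy = np.gradient(y, t)
    return {
        "min": float(y.min()),
        "max": float(y.max()),
        "time_to_max": float(t[int(np.argmax(y))]),
        "max_derivative": float(dy.max()),
    }


def pv_summary(trace) -> Dict[str, Dict[str, float]]:
    """Summary statistics of a pressure-volume trace, per quantity."""
    return {
        "P": series_summary(trace.t, trace.P),
        "V": series_summary(trace.t, trace.V),
    }


def summary_error_table(truth, predicted) -> pd.DataFrame:
    """Truth-vs-predicted summary comparison with percent errors.

    ``truth`` and ``predicted`` are traces (or any objects with t/P/V);
    returns rows (quantity, metric, truth, predicted, pct_error).
    """
    rows = []
    s_true = pv_summary(truth)
    s_pred = pv_summary(predicted)
    for qty in ("P", "V"):
        for metric in ("min", "max", "time_to_max", "max_derivative"):
            tv = s_true[qty][metric]
            pv = s_pred[qty][metric]
            err = abs(pv - tv) / abs(tv) * 100.0 if tv != 0 else np.nan
            rows.append({
                "quantity": qty, "metric": metric,
                "truth": tv, "predicted": pv, "pct_error": err,
            })
    return pd.DataFrame(rows)
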