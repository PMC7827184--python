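"""Gradient-boosted regression of ddG on sequence-derived features.

The modelling surface follows the Model/Results convention:

>>> model = StabilityModel(X, y)            # or StabilityModel.from_dataset(...)
>>> res = model.fit()
>>> res.predict(X_new)
>>> res.group_importance()
>>> print(res.summary())

``StabilityModel.crossval`` runs the repeated k-fold protocol used to
benchmark stability predictors (default 5 folds, 100 repeats: each repeat
reshuffles the records, trains on 80% and tests on the held-out 20%, and the
fold-level Pearson correlation / MSE / MAE are averaged).
``StabilityModel.select_hyperparameters`` is an exhaustive grid search
scored by mean cross-validated PCC.

Everything is deterministic given the seed: the learner runs single-threaded
with a fixed random state, and every shuffle derives from the config seed.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import KFold, ParameterGrid

from seqddg.evalstats import mae as _mae
from seqddg.evalstats import mse as _mse
from seqddg.evalstats import pearson as _pearson
from seqddg.features import FeatureConfig, featurize_dataset

#: Replaceable default hyperparameter grid for select_hyperparameters().
DEFAULT_GRID = {
    "n_estimators": [200, 500],
    "max_depth": [3, 5, 7],
    "learning_rate": [0.05, 0.1],
    "subsample": [0.8, 1.0],
}


@dataclass
class ModelConfig:
    """Boosting hyperparameters, the search grid, and the seed."""

    n_estimators: int = 500
    max_depth: int = 5
    learning_rate: float = 0.05
    subsample: float = 0.8
    colsample_bytree: float = 0.8
    reg_lambda: float = 1.0
    grid: dict[str, list] = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})
    seed: int = 0
    n_jobs: int = 1  # single-threaded deterministic mode is the default

    def params(self) -> dict[str, Any]:
        return {
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "learning_rate": self.learning_rate,
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_bytree,
            "reg_lambda": self.reg_lambda,
        }

    def replace(self, **kwargs) -> "ModelConfig":
        cfg = ModelConfig(**{**self.__dict__, **kwargs})
        return cfg


def _make_estimator(cfg: ModelConfig) -> xgb.XGBRegressor:
    return xgb.XGBRegressor(
        objective="reg:squarederror",
        tree_method="hist",
        random_state=cfg.seed,
        n_jobs=cfg.n_jobs,
        **cfg.params(),
    )


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


@dataclass
class TrainedModel:
    """A fitted boosted-tree ensemble plus its feature schema and provenance."""

    estimator: xgb.XGBRegressor
    schema: list[str]
    config: ModelConfig
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        """Persist to a single self-describing JSON file."""
        raw = self.estimator.get_booster().save_raw(raw_format="json")
        payload = {
            "format_version": 1,
            "schema": self.schema,
            "config": {k: v for k, v in self.config.__dict__.items() if k != "grid"},
            "grid": self.config.grid,
            "metadata": self.metadata,
            "booster": json.loads(bytes(raw)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = ModelConfig(**payload["config"], grid=payload.get("grid", {}))
        est = _make_estimator(cfg)
        est.load_model(bytearray(json.dumps(payload["booster"]).encode()))
        return cls(
            estimator=est,
            schema=list(payload["schema"]),
            config=cfg,
            metadata=payload.get("metadata", {}),
        )


@dataclass
class CVReport:
    """Fold-level metrics of a repeated k-fold cross-validation.

    ``table`` has one row per (repeat, fold) with columns
    repeat, fold, n_test, pcc, mse, mae; ``assignments`` maps each record to
    its test fold, one integer row per repeat.
    """

    table: pd.DataFrame
    assignments: np.ndarray
    folds: int
    repeats: int
    seed: int

    @property
    def mean_pcc(self) -> float:
        return float(self.table["pcc"].mean())

    @property
    def sd_pcc(self) -> float:
        return float(self.table["pcc"].std(ddof=1))

    @property
    def mean_mse(self) -> float:
        return float(self.table["mse"].mean())

    @property
    def mean_mae(self) -> float:
        return float(self.table["mae"].mean())

    def aggregates(self) -> dict[str, float]:
        return {
            "mean_pcc": self.mean_pcc,
            "sd_pcc": self.sd_pcc,
            "mean_mse": self.mean_mse,
            "sd_mse": float(self.table["mse"].std(ddof=1)),
            "mean_mae": self.mean_mae,
            "sd_mae": float(self.table["mae"].std(ddof=1)),
        }


# ---------------------------------------------------------------------------
# Functional layer
# ---------------------------------------------------------------------------

def train(X, y, cfg: ModelConfig | None = None) -> TrainedModel:
    """Fit the boosted-tree ensemble. Deterministic given cfg.seed."""
    cfg = cfg or ModelConfig()
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError(f"X has {len(X)} rows but y has {len(y)} targets")
    if len(y) < 2:
        raise ValueError("need at least 2 training rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets contain non-finite values")
    est = _make_estimator(cfg)
    est.fit(X, y)
    meta = {
        "n": len(y),
        "date": datetime.date.today().isoformat(),
        "seed": cfg.seed,
    }
    return TrainedModel(estimator=est, schema=list(X.columns), config=cfg, metadata=meta)


def predict(m: TrainedModel, X) -> np.ndarray:
    """Predicted ddG (kcal/mol), one value per row of X."""
    X = _as_frame(X)
    if len(X) == 0:
        return np.zeros(0)
    if list(X.columns) != m.schema:
        missing = [c for c in m.schema if c not in X.columns]
        extra = [c for c in X.columns if c not in m.schema]
        raise ValueError(
            f"feature schema mismatch: missing {missing[:5]}, extra {extra[:5]}"
        )
    return np.asarray(m.estimator.predict(X), dtype=float)


def _cv_metrics(est_cfg: ModelConfig, X: pd.DataFrame, y: np.ndarray,
                train_idx, test_idx) -> tuple[float, float, float]:
    m = train(X.iloc[train_idx], y[train_idx], est_cfg)
    pred = predict(m, X.iloc[test_idx])
    obs = y[test_idx]
    return _pearson(pred, obs), _mse(pred, obs), _mae(pred, obs)


def repeated_cv(
    X,
    y,
    cfg: ModelConfig | None = None,
    folds: int = 5,
    repeats: int = 100,
    seed: int | None = None,
) -> CVReport:
    """Repeated k-fold cross-validation with fresh shuffles per repeat.

    Fold sizes differ by at most one; every record is tested exactly once
    per repeat. Reproducible bit-for-bit from (data, config, seed).
    """
    cfg = cfg or ModelConfig()
    seed = cfg.seed if seed is None else seed
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"need at least {folds} records, got {n}")
    rows = []
    assignments = np.full((repeats, n), -1, dtype=int)
    for rep in range(repeats):
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for k, (tr, te) in enumerate(splitter.split(X)):
            assignments[rep, te] = k
            pcc, mse_, mae_ = _cv_metrics(cfg, X, y, tr, te)
            rows.append(
                {"repeat": rep, "fold": k, "n_test": len(te),
                 "pcc": pcc, "mse": mse_, "mae": mae_}
            )
        if np.any(assignments[rep] < 0):
            raise AssertionError("fold split did not cover every record")
    return CVReport(
        table=pd.DataFrame(rows),
        assignments=assignments,
        folds=folds,
        repeats=repeats,
        seed=seed,
    )


def grid_search(
    X, y, cfg: ModelConfig | None = None, folds: int = 5
) -> ModelConfig:
    """Exhaustive hyperparameter search scored by mean cross-validated PCC.

    Ties break toward the lower mean MSE, then toward grid order. Grid
    points that fail to fit are recorded and skipped; if every point fails
    an error is raised.
    """
    cfg = cfg or ModelConfig()
    if not cfg.grid:
        raise ValueError("hyperparameter grid is empty")
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    results = []
    failures = []
    for i, point in enumerate(ParameterGrid(cfg.grid)):
        candidate = cfg.replace(**point)
        try:
            splitter = KFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
            pccs, mses = [], []
            for tr, te in splitter.split(X):
                pcc, mse_, _ = _cv_metrics(candidate, X, y, tr, te)
                pccs.append(pcc)
                mses.append(mse_)
            results.append((i, candidate, float(np.mean(pccs)), float(np.mean(mses))))
        except Exception as exc:  # noqa: BLE001 - record and skip failing points
            failures.append((point, repr(exc)))
    if not results:
        raise RuntimeError(f"every grid point failed to fit: {failures}")
    # best mean PCC; tie -> lowest MSE, then first in grid order
    results.sort(key=lambda t: (-t[2], t[3], t[0]))
    return results[0][1]


def group_feature_importance(m: TrainedModel) -> dict[str, float]:
    """Gain-based importance summed within feature groups, normalized to 1.

    Feature groups are the prefix before the first ``.`` in each schema
    column (features without a dot form the group ``other``). Features the
    ensemble never splits on contribute zero gain.
    """
    try:
        booster = m.estimator.get_booster()
    except Exception as exc:
        raise ValueError("model is not fitted") from exc
    gains = booster.get_score(importance_type="gain")
    # get_score omits unused features; weight gain by split count for the
    # standard "total gain" attribution
    totals = booster.get_score(importance_type="total_gain")
    groups: dict[str, float] = {}
    for col in m.schema:
        group = col.split(".", 1)[0] if "." in col else "other"
        groups[group] = groups.get(group, 0.0) + totals.get(col, 0.0)
    total = sum(groups.values())
    if total <= 0:
        # no splits at all (e.g. constant target): report uniform importance
        return {g: 1.0 / len(groups) for g in groups}
    return {g: v / total for g, v in groups.items()}


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class StabilityModel:
    """Boosted-tree regression of ddG on sequence-derived features.

    Parameters
    ----------
    X : DataFrame or array
        Feature table, one row per mutation. Column names of the form
        ``group.name`` attribute features to descriptor groups.
    y : array
        Experimental targets (ddG in kcal/mol, or stability scores).
    config : ModelConfig, optional
        Boosting hyperparameters and seed.
    """

    def __init__(self, X, y, config: ModelConfig | None = None):
        self.X = _as_frame(X)
        self.y = np.asarray(y, dtype=float)
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        self.config = config or ModelConfig()

    @classmethod
    def from_dataset(
        cls,
        ds,
        pssms,
        feature_config: FeatureConfig | None = None,
        config: ModelConfig | None = None,
    ) -> "StabilityModel":
        """Featurize a MutationDataset (with its PSSMs) and build the model."""
        feature_config = feature_config or FeatureConfig()
        X = featurize_dataset(ds, pssms, feature_config)
        return cls(X, ds.targets, config=config)

    def fit(self) -> "StabilityResults":
        trained = train(self.X, self.y, self.config)
        return StabilityResults(self, trained)

    def crossval(
        self, folds: int = 5, repeats: int = 100, seed: int | None = None
    ) -> CVReport:
        return repeated_cv(self.X, self.y, self.config, folds, repeats, seed)

    def select_hyperparameters(self, folds: int = 5) -> ModelConfig:
        """Grid-search the config's grid; returns the winning ModelConfig."""
        return grid_search(self.X, self.y, self.config, folds)


class StabilityResults:
    """Results of a fitted :class:`StabilityModel`."""

    def __init__(self, model: StabilityModel, trained: TrainedModel):
        self.model = model
        self.trained = trained
        self.fittedvalues = predict(trained, model.X)

    def predict(self, X) -> np.ndarray:
        """Predicted ddG (kcal/mol) for new feature rows."""
        return predict(self.trained, X)

    def group_importance(self) -> dict[str, float]:
        """Normalized gain importance per feature group."""
        return group_feature_importance(self.trained)

    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    def save(self, path) -> None:
        self.trained.save(path)

    def summary(self) -> str:
        """Plain-text summary: fit configuration, in-sample metrics, importances."""
        y, yhat = self.model.y, self.fittedvalues
        lines = [
            "Stability regression (gradient-boosted trees)",
            "=" * 46,
            f"n observations      {len(y):>10d}",
            f"n features          {self.model.X.shape[1]:>10d}",
            f"trees / depth / lr  {self.trained.config.n_estimators:>6d} /"
            f" {self.trained.config.max_depth} / {self.trained.config.learning_rate}",
            f"seed                {self.trained.config.seed:>10d}",
            "-" * 46,
            f"in-sample PCC       {_pearson(yhat, y):>10.3f}",
            f"in-sample MSE       {_mse(yhat, y):>10.3f}",
            f"in-sample MAE       {_mae(yhat, y):>10.3f}",
            "-" * 46,
            "group importance (normalized gain)",
        ]
        for g, v in sorted(self.group_importance().items(), key=lambda kv: -kv[1]):
            lines.append(f"  {g:<18s}{v:>10.3f}")
        return "\n".join(lines)
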