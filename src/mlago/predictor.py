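"""K_m regression on hierarchical one-hot features.

Targets are log10(K_m / mM) throughout; the two evaluation metrics are
the root-mean-square error between log10-scaled estimated and reference
vectors (which doubles as the implausibility objective of the constrained
estimator) and the coefficient of determination R² about the reference
mean. Four learner families are supported: k-nearest neighbors, elastic
net, random forest (scikit-learn) and gradient boosting (XGBoost).
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor

from mlago.features import EncodingScheme, build_scheme, encode_queries, encode_table, load_scheme, save_scheme
from mlago.km_dataset import KmTable

logger = logging.getLogger(__name__)

ALGORITHMS = ("nearest_neighbors", "elastic_net", "random_forest", "gradient_boosting")

#: global K_m search bounds (mM); predictions are clipped into this box
KM_LOWER_MM = 1e-5
KM_UPPER_MM = 1e3

#: small default hyperparameter grids; override with problem-specific grids
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "nearest_neighbors": {"n_neighbors": [3, 5, 10]},
    "elastic_net": {"alpha": [1e-3, 1e-2, 1e-1], "l1_ratio": [0.2, 0.5, 0.8]},
    "random_forest": {"n_estimators": [100], "max_features": ["sqrt", 0.3]},
    "gradient_boosting": {"n_estimators": [200], "max_depth": [6], "learning_rate": [0.1, 0.3]},
}


# ---------------------------------------------------------------------------
# metrics


def rmse(q: np.ndarray, q_ref: np.ndarray) -> float:
    """Root-mean-square difference between two log10-scaled vectors.

    Symmetric in its arguments; zero iff the vectors are equal.
    """
    q = np.asarray(q, dtype=float)
    q_ref = np.asarray(q_ref, dtype=float)
    if q.shape != q_ref.shape:
        raise ValueError(f"length mismatch: {q.shape} vs {q_ref.shape}")
    if q.size == 0:
        raise ValueError("empty vectors")
    if not (np.isfinite(q).all() and np.isfinite(q_ref).all()):
        raise ValueError("non-finite entries")
    return float(np.sqrt(np.mean((q - q_ref) ** 2)))


def r_squared(q: np.ndarray, q_ref: np.ndarray) -> float:
    """Coefficient of determination of estimates ``q`` against references.

    ``1 − Σ(q_i − q_i*)² / Σ(q_i* − q̄*)²`` with ``q̄*`` the mean of the
    reference vector. Undefined (raises) for a constant reference.
    """
    q = np.asarray(q, dtype=float)
    q_ref = np.asarray(q_ref, dtype=float)
    if q.shape != q_ref.shape:
        raise ValueError("length mismatch")
    if q.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(np.sum((q_ref - q_ref.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant reference vector: R^2 undefined")
    ss_res = float(np.sum((q - q_ref) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# configuration and fitting


@dataclass(frozen=True)
class PredictorConfig:
    algorithm: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")


@dataclass
class TrainedPredictor:
    scheme: EncodingScheme
    model: object
    config: PredictorConfig
    training_summary: dict = field(default_factory=dict)


@dataclass
class CVResult:
    per_fold_rmse: list[float]
    per_fold_r2: list[float]
    rounds: int
    k: int

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.per_fold_rmse))

    @property
    def mean_r2(self) -> float:
        return float(np.nanmean(self.per_fold_r2))


def _make_estimator(config: PredictorConfig):
    hp = dict(config.hyperparameters)
    if config.algorithm == "nearest_neighbors":
        return KNeighborsRegressor(**{"n_neighbors": 5, **hp})
    if config.algorithm == "elastic_net":
        return ElasticNet(random_state=config.seed, **{"alpha": 1e-2, "l1_ratio": 0.5, **hp})
    if config.algorithm == "random_forest":
        return RandomForestRegressor(
            random_state=config.seed, n_jobs=1, **{"n_estimators": 100, **hp}
        )
    if config.algorithm == "gradient_boosting":
        from xgboost import XGBRegressor

        return XGBRegressor(
            random_state=config.seed, n_jobs=1, verbosity=0,
            **{"n_estimators": 200, "max_depth": 6, "learning_rate": 0.1, **hp},
        )
    raise ValueError(config.algorithm)  # unreachable


def fit(config: PredictorConfig, table: KmTable) -> TrainedPredictor:
    """Build the encoding scheme from ``table`` and fit the regressor on log10 K_m."""
    if len(table) == 0:
        raise ValueError("empty training table")
    scheme = build_scheme(table)
    X, y = encode_table(scheme, table)
    model = _make_estimator(config)
    model.fit(X, y)
    train_rmse = rmse(model.predict(X), y)
    summary = {"n_train": len(table), "total_dim": scheme.total_dim, "train_rmse": train_rmse}
    return TrainedPredictor(scheme=scheme, model=model, config=config, training_summary=summary)


def predict_km(predictor: TrainedPredictor, queries: Sequence) -> np.ndarray:
    """Predicted K_m in mM for (EC, compound, organism) queries.

    Back-transforms the model's log10 output and clips into the global
    search bounds [1e-5, 1e3] mM. Unknown categories degrade to zero
    feature blocks (warning logged by the encoder).
    """
    X = encode_queries(predictor.scheme, queries)
    if len(X) == 0:
        return np.zeros(0)
    q = np.asarray(predictor.model.predict(X), dtype=float)
    return np.clip(10.0 ** q, KM_LOWER_MM, KM_UPPER_MM)


def predict_log10_km(predictor: TrainedPredictor, queries: Sequence) -> np.ndarray:
    """log10(K_m/mM) predictions clipped to the global search bounds."""
    return np.log10(predict_km(predictor, queries))


# ---------------------------------------------------------------------------
# cross-validation and tuning


def cross_validate(
    config: PredictorConfig,
    table: KmTable,
    k: int = 5,
    rounds: int = 4,
    seed: int = 0,
) -> CVResult:
    """``rounds`` independent rounds of ``k``-fold cross-validation.

    Round ``r`` reshuffles folds with seed ``seed + r``. The encoding
    scheme is rebuilt on each training fold, so categories present only in
    the held-out fold contribute zero blocks at validation time (no
    leakage).
    """
    n = len(table)
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    df = table.df
    fold_rmse: list[float] = []
    fold_r2: list[float] = []
    for r in range(rounds):
        kf = KFold(n_splits=k, shuffle=True, random_state=seed + r)
        for train_idx, val_idx in kf.split(df):
            train_tab = KmTable(df.iloc[train_idx])
            val_tab = KmTable(df.iloc[val_idx])
            pred = fit(config, train_tab)
            Xv, yv = encode_table(pred.scheme, val_tab)
            qv = np.asarray(pred.model.predict(Xv), dtype=float)
            fold_rmse.append(rmse(qv, yv))
            try:
                fold_r2.append(r_squared(qv, yv))
            except ValueError:  # constant held-out targets: R^2 undefined
                fold_r2.append(float("nan"))
    return CVResult(per_fold_rmse=fold_rmse, per_fold_r2=fold_r2, rounds=rounds, k=k)


def tune_hyperparameters(
    algorithm: str,
    grid: Mapping[str, Sequence] | None,
    table: KmTable,
    k: int = 5,
    rounds: int = 1,
    seed: int = 0,
) -> tuple[PredictorConfig, pd.DataFrame]:
    """Grid search minimizing mean CV RMSE.

    Returns the winning :class:`PredictorConfig` and the full score table
    (one row per grid point, in enumeration order). Ties are broken by
    earlier grid order.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[algorithm]
    names = list(grid)
    combos = list(product(*(grid[n] for n in names)))
    if not combos:
        raise ValueError("empty hyperparameter grid")
    rows = []
    best: tuple[float, int] | None = None
    for i, combo in enumerate(combos):
        hp = dict(zip(names, combo))
        cv = cross_validate(PredictorConfig(algorithm, hp, seed), table, k=k, rounds=rounds, seed=seed)
        rows.append({**hp, "mean_cv_rmse": cv.mean_rmse, "mean_cv_r2": cv.mean_r2})
        if best is None or cv.mean_rmse < best[0]:
            best = (cv.mean_rmse, i)
    scores = pd.DataFrame(rows)
    win = dict(zip(names, combos[best[1]]))
    logger.info("tune_hyperparameters(%s): best %s (mean CV RMSE %.4f)", algorithm, win, best[0])
    return PredictorConfig(algorithm, win, seed), scores


# ---------------------------------------------------------------------------
# persistence: model pickle + scheme sidecar + config manifest


def save_predictor(predictor: TrainedPredictor, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "model.pkl", "wb") as fh:
        pickle.dump(predictor.model, fh)
    save_scheme(predictor.scheme, d / "scheme.txt")
    manifest = {
        "algorithm": predictor.config.algorithm,
        "hyperparameters": dict(predictor.config.hyperparameters),
        "seed": predictor.config.seed,
        "training_summary": predictor.training_summary,
    }
    (d / "config.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")


def load_predictor(directory: str | Path) -> TrainedPredictor:
    d = Path(directory)
    with open(d / "model.pkl", "rb") as fh:
        model = pickle.load(fh)
    scheme = load_scheme(d / "scheme.txt")
    manifest = json.loads((d / "config.json").read_text(encoding="utf-8"))
    config = PredictorConfig(manifest["algorithm"], manifest["hyperparameters"], manifest["seed"])
    return TrainedPredictor(scheme=scheme, model=model, config=config,
                            training_summary=manifest.get("training_summary", {}))
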