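"""Supervised diversity prediction from fingerprints.

A Random Forest regressor maps fingerprint rows to alpha-diversity values.
Hyperparameters are tuned by a randomized search: the per-split feature
budget is drawn from {1, ..., n_features} and the minimum leaf size from
{1, ..., 5}; candidates are scored by k-fold cross-validated R^2 and the
best one is refit on the full training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, cross_val_score

from ._rng import rng_from
from .errors import AlignmentError, ConfigurationError
from .tables import CountTable


@dataclass
class RFSearchSpec:
    """Randomized-search configuration for the forest regressor."""

    n_candidates: int = 100
    cv_folds: int = 5
    max_features_range: tuple[int, int] | None = None  # default (1, n_features)
    min_samples_leaf_range: tuple[int, int] = (1, 5)
    n_trees: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_candidates < 1:
            raise ConfigurationError("n_candidates must be >= 1")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds must be >= 2")


@dataclass
class RegressorBundle:
    """A fitted forest plus the search records needed to reproduce it."""

    model: RandomForestRegressor
    component_ids: list[str]
    best_params: dict
    cv_table: pd.DataFrame
    seed: int


def _align_targets(ct: CountTable, targets) -> np.ndarray:
    """Targets as an array ordered like the table's samples."""
    if isinstance(targets, pd.DataFrame):
        if set(targets["sample_id"]) != set(ct.sample_ids):
            raise AlignmentError("targets and fingerprints disagree on samples")
        series = targets.set_index("sample_id")["value"]
        return series.loc[ct.sample_ids].to_numpy(dtype=float)
    y = np.asarray(targets, dtype=float)
    if len(y) != ct.n_samples:
        raise AlignmentError("one target per fingerprint row required")
    return y


def fit_diversity_regressor(
    train_fingerprints: CountTable,
    train_targets,
    spec: RFSearchSpec | None = None,
) -> RegressorBundle:
    """Randomized hyperparameter search + refit on the full training set.

    ``train_targets`` is either an array aligned with the table rows or a
    tidy frame with ``sample_id``/``value`` columns for a single order q.
    """
    spec = spec or RFSearchSpec()
    X = train_fingerprints.counts
    y = _align_targets(train_fingerprints, train_targets)
    n, d = X.shape
    if n < spec.cv_folds:
        raise ConfigurationError(
            f"{n} samples cannot be split into {spec.cv_folds} folds"
        )
    lo, hi = spec.max_features_range or (1, d)
    lo_l, hi_l = spec.min_samples_leaf_range
    rng = rng_from(spec.seed, "rf-search")
    candidates = [
        {
            "max_features": int(rng.integers(lo, hi + 1)),
            "min_samples_leaf": int(rng.integers(lo_l, hi_l + 1)),
        }
        for _ in range(spec.n_candidates)
    ]
    cv = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed % 2**32)
    records = []
    for idx, params in enumerate(candidates):
        model = RandomForestRegressor(
            n_estimators=spec.n_trees,
            random_state=spec.seed % 2**32,
            **params,
        )
        scores = cross_val_score(model, X, y, cv=cv, scoring="r2")
        records.append(
            {
                "candidate": idx,
                **params,
                "mean_cv_r2": float(np.mean(scores)),
                "std_cv_r2": float(np.std(scores)),
            }
        )
    cv_table = pd.DataFrame(records)
    best_idx = int(cv_table["mean_cv_r2"].idxmax())
    best_params = candidates[best_idx]
    model = RandomForestRegressor(
        n_estimators=spec.n_trees, random_state=spec.seed % 2**32, **best_params
    )
    model.fit(X, y)
    return RegressorBundle(
        model=model,
        component_ids=list(train_fingerprints.component_ids),
        best_params=best_params,
        cv_table=cv_table,
        seed=spec.seed,
    )


def predict_diversity(bundle: RegressorBundle, test_fingerprints: CountTable) -> pd.DataFrame:
    """One prediction per test sample, columns (sample_id, value)."""
    if test_fingerprints.component_ids != bundle.component_ids:
        raise AlignmentError("test fingerprint columns differ from training columns")
    preds = bundle.model.predict(test_fingerprints.counts)
    return pd.DataFrame(
        {"sample_id": test_fingerprints.sample_ids, "value": preds}
    )
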