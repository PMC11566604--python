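"""Predicting astrocytic Ca2+ from neuronal activity.

Random-forest regression on lagged neuronal features quantifies how much of
the astrocytic signal's variance the neuronal signal explains, per region and
behavioral state.  Validation uses blocked (contiguous-in-time) cross-
validation so that the strong autocorrelation of Ca2+ traces cannot leak
between train and test folds; variance explained is pooled over held-out
folds: VE = 1 - SSE/SST.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

__all__ = ["PredictionResult", "build_lagged_features", "fit_variance_explained"]


@dataclass
class PredictionResult:
    variance_explained: float
    region: str
    state: str
    lags_s: np.ndarray
    n_rows: int
    n_folds: int
    seed: int
    model: str = "RandomForestRegressor"
    n_estimators: int = 100

    def __post_init__(self) -> None:
        if self.variance_explained > 1.0 + 1e-12:
            raise ValueError("variance explained cannot exceed 1")


def build_lagged_features(
    neuron_z: np.ndarray, lags_s: np.ndarray, rate_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix of the neuronal trace at each configured lag.

    Row t holds neuron_z[t - lag] for each lag; rows with incomplete history
    (the first max-lag samples) are dropped.  Returns (features, target_idx)
    where target_idx are the trace indices each row is aligned to.
    """
    z = np.asarray(neuron_z, dtype=float)
    lags_s = np.asarray(lags_s, dtype=float)
    if lags_s.size == 0:
        raise ValueError("empty lag set")
    lag_samples = np.round(lags_s * rate_hz).astype(int)
    max_lag = int(lag_samples.max())
    if max_lag >= len(z):
        raise ValueError("max lag exceeds trace length")
    idx = np.arange(max_lag, len(z))
    feats = np.column_stack([z[idx - L] for L in lag_samples])
    return feats, idx


def fit_variance_explained(
    features: np.ndarray,
    target: np.ndarray,
    seed: int,
    n_folds: int = 5,
    n_estimators: int = 100,
    region: str = "",
    state: str = "",
    lags_s: np.ndarray | None = None,
) -> PredictionResult:
    """Blocked-CV random-forest variance explained of ``target`` from ``features``."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("features and target are misaligned")
    if np.ptp(y) == 0:
        raise ValueError("constant target: variance explained undefined")
    if X.shape[0] < 10 * X.shape[1]:
        raise ValueError("need at least 10x more rows than features")

    bounds = np.linspace(0, len(y), n_folds + 1).astype(int)
    sse = 0.0
    y_heldout = []
    preds = []
    for k in range(n_folds):
        lo, hi = bounds[k], bounds[k + 1]
        test = np.zeros(len(y), dtype=bool)
        test[lo:hi] = True
        model = RandomForestRegressor(
            n_estimators=n_estimators,
            random_state=seed,
            n_jobs=1,
            min_samples_leaf=5,
        )
        model.fit(X[~test], y[~test])
        p = model.predict(X[test])
        preds.append(p)
        y_heldout.append(y[test])
        sse += float(((y[test] - p) ** 2).sum())
    y_all = np.concatenate(y_heldout)
    sst = float(((y_all - y_all.mean()) ** 2).sum())
    ve = 1.0 - sse / sst
    return PredictionResult(
        variance_explained=float(ve),
        region=region,
        state=state,
        lags_s=np.arange(0, 11.0) if lags_s is None else np.asarray(lags_s, float),
        n_rows=int(X.shape[0]),
        n_folds=n_folds,
        seed=seed,
        n_estimators=n_estimators,
    )
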