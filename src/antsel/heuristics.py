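"""Per-feature importance scorers used as ant-colony heuristic values.

Four interchangeable scorers: random-forest mean decrease in Gini
impurity (MDGI, the default), absolute Pearson correlation (PCC),
information gain with equal-width binning, and the two-class
discrimination F-score (between-class over within-class scatter).

Every scorer returns a :class:`HeuristicVector` whose values are strictly
positive: raw scores are clamped at ``1e-6 * max(score)`` so that the
heuristic exponent in the edge-probability rule is always well defined
while the ranking of informative features is preserved. ``eta0`` — the
average importance of all features, used as the heuristic value of every
*skip* edge — is the mean of the clamped scores, so both edges of a node
live on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from antsel._seeds import derive_seed

CLAMP_REL = 1e-6
F_SCORE_CAP = 1e6


@dataclass(frozen=True)
class HeuristicVector:
    method: str
    eta: np.ndarray  # strictly positive, one per feature
    eta0: float  # mean of eta

    def __post_init__(self):
        if not np.all(np.isfinite(self.eta)):
            raise ValueError("heuristic values must be finite")
        if not np.all(self.eta > 0):
            raise ValueError("heuristic values must be strictly positive")

    def __len__(self) -> int:
        return len(self.eta)

    def to_frame(self, feature_names: list[str] | None = None) -> pd.DataFrame:
        names = feature_names or [f"f{i}" for i in range(len(self.eta))]
        return pd.DataFrame({"feature_name": names, "eta": self.eta})


def _finalize(method: str, scores: np.ndarray) -> HeuristicVector:
    scores = np.asarray(scores, dtype=float)
    top = float(scores.max(initial=0.0))
    if top <= 0.0:
        # nothing discriminates: fall back to a flat, positive prior
        eta = np.ones_like(scores)
    else:
        eta = np.maximum(scores, CLAMP_REL * top)
    return HeuristicVector(method=method, eta=eta, eta0=float(eta.mean()))


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"shape mismatch: X {X.shape}, y {y.shape}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    return X, y


def mdgi(
    X: np.ndarray,
    y: np.ndarray,
    repeats: int = 10,
    trees: int = 500,
    seed: int = 0,
) -> HeuristicVector:
    """Mean decrease in Gini impurity from a random-forest ensemble.

    Fits ``repeats`` independently seeded forests of ``trees`` trees each
    and averages the per-feature impurity importances, smoothing the
    sampling noise of any single forest. Importances within one forest are
    normalized to sum to 1, which leaves the ranking (and hence the edge
    probabilities, which are scale-free up to the skip/select balance)
    unchanged.
    """
    X, y = _check_xy(X, y)
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    acc = np.zeros(X.shape[1])
    for r in range(repeats):
        rf = RandomForestClassifier(
            n_estimators=trees,
            random_state=derive_seed(seed, "mdgi", r),
            n_jobs=1,
        )
        rf.fit(X, y)
        acc += rf.feature_importances_
    return _finalize("MDGI", acc / repeats)


def pcc(X: np.ndarray, y: np.ndarray) -> HeuristicVector:
    """Absolute Pearson correlation of each feature with the 0/1 label."""
    X, y = _check_xy(X, y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r = np.where(sx == 0, 0.0, np.abs(r))
    return _finalize("PCC", r)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def info_gain(X: np.ndarray, y: np.ndarray, bins: int = 10) -> HeuristicVector:
    """Information gain H(y) - H(y | binned feature), in bits.

    Features are discretized into equal-width bins over [0, 1] (the
    encoder's output range); values outside are clipped to the range.
    """
    X, y = _check_xy(X, y)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    edges = np.linspace(0.0, 1.0, bins + 1)
    h_y = _entropy(np.bincount(y))
    n = len(y)
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        b = np.clip(np.digitize(np.clip(X[:, j], 0.0, 1.0), edges[1:-1]), 0, bins - 1)
        h_cond = 0.0
        for bv in np.unique(b):
            mask = b == bv
            h_cond += mask.sum() / n * _entropy(np.bincount(y[mask]))
        scores[j] = h_y - h_cond
    return _finalize("IG", np.maximum(scores, 0.0))


def f_score(X: np.ndarray, y: np.ndarray) -> HeuristicVector:
    """Two-class discrimination F-score: between-class over within-class scatter.

    F_j = (mean_j^+ - mean_j^-)^2 / (var_j^+ + var_j^-), with sample
    variances (ddof=1). Zero within-class variance with distinct means is
    capped at a large finite value instead of infinity.
    """
    X, y = _check_xy(X, y)
    pos, neg = X[y == 1], X[y == 0]
    num = (pos.mean(axis=0) - neg.mean(axis=0)) ** 2
    var_p = pos.var(axis=0, ddof=1) if len(pos) > 1 else np.zeros(X.shape[1])
    var_n = neg.var(axis=0, ddof=1) if len(neg) > 1 else np.zeros(X.shape[1])
    den = var_p + var_n
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / den
    f = np.where(den == 0, np.where(num > 0, F_SCORE_CAP, 0.0), f)
    return _finalize("F-score", np.minimum(f, F_SCORE_CAP))


SCORERS = {"mdgi": mdgi, "pcc": pcc, "ig": info_gain, "f_score": f_score}


def score(method: str, X: np.ndarray, y: np.ndarray, **kwargs) -> HeuristicVector:
    """Dispatch by scorer name (``mdgi``, ``pcc``, ``ig``, ``f_score``)."""
    try:
        fn = SCORERS[method.lower()]
    except KeyError:
        raise ValueError(
            f"unknown heuristic {method!r}; available: {sorted(SCORERS)}"
        ) from None
    return fn(X, y, **kwargs)
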