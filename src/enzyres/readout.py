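"""Linear readout layer: preprocessing and the two trainers.

The reservoir's measured feature vector x is turned into a computational
output by a trained linear map, y_hat = W x + b.  Features are
standardized (mean removed, unit variance; population s.d. convention) on
the training data only; zero-variance features are dropped.  A
signal-to-noise filter can remove features whose total variation does not
exceed their average within-replicate-group scatter.

Two trainers are provided, both written here in closed/convex form so
that library implementations can serve as independent cross-checks:

* ridge regression — minimizes ||y - Xw - b||^2 + alpha ||w||^2 with an
  unpenalized intercept (closed form on centred data);
* an L2-regularized squared-hinge linear classifier — minimizes
  0.5 ||w||^2 + C sum_i max(0, 1 - y_i (x_i . w + b))^2, a smooth convex
  objective solved with L-BFGS; decisions are sign(x . w + b) in {0, 1}.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize


@dataclass
class NormStats:
    """Per-feature standardization statistics captured at fit time."""

    mean: pd.Series
    sd: pd.Series
    kept: list[str]

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [f for f in self.kept if f not in X.columns]
        if missing:
            raise KeyError(f"missing features: {missing}")
        Z = X[self.kept]
        return (Z - self.mean[self.kept]) / self.sd[self.kept]


def normalize_fit_transform(
    X: pd.DataFrame, ddof: int = 0
) -> tuple[pd.DataFrame, NormStats]:
    """Standardize each feature to mean 0, s.d. 1 (population convention).

    Zero-variance columns are dropped with a warning; the returned
    statistics are reusable on held-out data without refitting.
    """
    if len(X) < 2:
        raise ValueError("need at least 2 samples to standardize")
    mean = X.mean()
    sd = X.std(ddof=ddof)
    kept = [c for c in X.columns if sd[c] > 0 and np.isfinite(sd[c])]
    dropped = [c for c in X.columns if c not in kept]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s)", stacklevel=2)
    stats = NormStats(mean=mean[kept], sd=sd[kept], kept=kept)
    return stats.transform(X), stats


def snr_filter(
    X: pd.DataFrame, groups: pd.Series | np.ndarray, threshold: float = 1.0
) -> list[str]:
    """Retain features whose total s.d. >= average within-group s.d.

    SNR_f = sd_total(f) / pooled within-group s.d., where the pooling
    averages the within-group *variances* before taking the square root
    (all with the sample n-1 convention).  Averaging variances rather
    than s.d.s avoids the small-sample downward bias of the s.d. (c4
    correction), so a feature of pure i.i.d. noise sits at SNR ~ 1 and
    is removed about half the time, which is the behaviour the filter's
    threshold of 1 presumes.  Groups with a single replicate are skipped
    (with a warning).  Features with zero total s.d. are removed; a zero
    pooled s.d. with nonzero total s.d. gives infinite SNR (retained).
    """
    groups = pd.Series(np.asarray(groups), index=X.index)
    sd_total = X.std(ddof=1)
    sizes = groups.value_counts()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        warnings.warn(
            f"skipping {len(singletons)} single-replicate group(s) in the SNR filter",
            stacklevel=2,
        )
    valid = ~groups.isin(singletons)
    within = X[valid].groupby(groups[valid]).var(ddof=1)
    if within.empty:
        raise ValueError("no group with >= 2 replicates")
    mean_within = np.sqrt(within.mean())
    retained = []
    for f in X.columns:
        if sd_total[f] == 0:
            continue
        if mean_within[f] == 0:
            retained.append(f)  # infinite SNR
        elif sd_total[f] / mean_within[f] >= threshold:
            retained.append(f)
    return retained


@dataclass
class ReadoutModel:
    """Trained linear readout: weights, intercept, and the preprocessing
    statistics needed to apply it to raw feature vectors."""

    weights: pd.Series
    intercept: float
    mode: str  # "classifier" | "regressor"
    regularization: float
    norm: NormStats | None = None

    def decision_values(self, X: pd.DataFrame) -> np.ndarray:
        Z = self.norm.transform(X) if self.norm is not None else X[self.weights.index]
        return Z.to_numpy(dtype=float) @ self.weights.to_numpy(dtype=float) + self.intercept

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        vals = self.decision_values(X)
        if self.mode == "classifier":
            return (vals > 0).astype(int)
        return vals

    # -- text serialization -------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "mode": self.mode,
            "regularization": self.regularization,
            "intercept": self.intercept,
            "features": list(self.weights.index),
            "weights": self.weights.tolist(),
        }
        if self.norm is not None:
            payload["norm"] = {
                "kept": self.norm.kept,
                "mean": self.norm.mean[self.norm.kept].tolist(),
                "sd": self.norm.sd[self.norm.kept].tolist(),
            }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ReadoutModel":
        d = json.loads(text)
        norm = None
        if "norm" in d:
            kept = d["norm"]["kept"]
            norm = NormStats(
                mean=pd.Series(d["norm"]["mean"], index=kept),
                sd=pd.Series(d["norm"]["sd"], index=kept),
                kept=kept,
            )
        return cls(
            weights=pd.Series(d["weights"], index=d["features"]),
            intercept=d["intercept"],
            mode=d["mode"],
            regularization=d["regularization"],
            norm=norm,
        )


def fit_ridge(X: pd.DataFrame, y: np.ndarray, alpha: float = 1.0) -> ReadoutModel:
    """Closed-form ridge with unpenalized intercept."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    A = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if A.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    x_mean = A.mean(axis=0)
    y_mean = y.mean()
    Ac = A - x_mean
    yc = y - y_mean
    G = Ac.T @ Ac + alpha * np.eye(A.shape[1])
    if alpha == 0 and np.linalg.matrix_rank(G) < G.shape[0]:
        raise np.linalg.LinAlgError(
            "singular normal equations with alpha=0; use alpha > 0"
        )
    w = np.linalg.solve(G, Ac.T @ yc)
    b = y_mean - x_mean @ w
    return ReadoutModel(
        weights=pd.Series(w, index=X.columns),
        intercept=float(b),
        mode="regressor",
        regularization=alpha,
    )


def fit_linear_classifier(
    X: pd.DataFrame, labels: np.ndarray, C: float = 1.0
) -> ReadoutModel:
    """L2-regularized squared-hinge linear classifier (labels in {0, 1})."""
    A = X.to_numpy(dtype=float)
    y01 = np.asarray(labels)
    classes = np.unique(y01)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if not set(classes.tolist()) <= {0, 1}:
        raise ValueError("labels must be 0/1")
    y = np.where(y01 == 1, 1.0, -1.0)
    n, p = A.shape

    def objective(theta):
        w, b = theta[:p], theta[p]
        margin = 1.0 - y * (A @ w + b)
        hinge = np.maximum(margin, 0.0)
        # the intercept is regularized alongside the weights, the usual
        # behaviour of liblinear-style solvers
        f = 0.5 * (w @ w + b * b) + C * np.sum(hinge**2)
        coef = -2.0 * C * y * hinge
        grad_w = w + A.T @ coef
        grad_b = b + coef.sum()
        return f, np.concatenate([grad_w, [grad_b]])

    res = minimize(objective, np.zeros(p + 1), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    w, b = res.x[:p], float(res.x[p])
    return ReadoutModel(
        weights=pd.Series(w, index=X.columns),
        intercept=b,
        mode="classifier",
        regularization=C,
    )


def train_readout(
    X: pd.DataFrame,
    y: np.ndarray,
    mode: str,
    alpha: float = 1.0,
    C: float = 1.0,
    snr_groups: pd.Series | np.ndarray | None = None,
) -> ReadoutModel:
    """Full training path: optional SNR filter -> standardize -> fit.

    All statistics are computed from ``X`` (the training fold) only.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if snr_groups is not None:
            keep = snr_filter(X, snr_groups)
            X = X[keep]
        Z, stats = normalize_fit_transform(X)
    if mode == "regressor":
        model = fit_ridge(Z, y, alpha=alpha)
    elif mode == "classifier":
        model = fit_linear_classifier(Z, y, C=C)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    model.norm = stats
    return model


def predict(model: ReadoutModel, X: pd.DataFrame) -> np.ndarray:
    """Apply stored normalization, then the linear map (and threshold)."""
    return model.predict(X)
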