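"""Treatment-response classifier on top of the Digital Scores.

The TR score is the linear predictor of a two-covariate logistic model,

    TR = β0 + β_post · (post-Tx Digital Score) + β_delta · (Δ Digital Score)

with the published coefficients (−8.132, 1.226, 1.146) and decision cutoff
0.76 frozen as an immutable instance; scores at or above the cutoff call
viable residual tumor.  Refitting, leave-one-out / stratified k-fold
cross-validation and an L1 (LASSO) variant are provided for model-stability
checks on new cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .evaluation import auroc, youden_cutoff

__all__ = [
    "TRModel",
    "published_model",
    "tr_score",
    "classify",
    "fit_tr",
    "loocv_auroc",
    "kfold_auroc",
    "lasso_auroc",
    "stratified_folds",
]

#: coefficient-norm bound beyond which an unpenalized fit is treated as separated
SEPARATION_BOUND = 50.0
#: minimal L2 penalty used for the separation fallback
RIDGE_ALPHA = 1e-4


@dataclass(frozen=True)
class TRModel:
    """Logistic treatment-response model (linear-predictor scale).

    ``cutoff`` lives on the same linear-predictor scale as the TR score;
    ``provenance`` is "published" for the frozen literature model or
    "fitted" for models estimated from data.
    """

    intercept: float
    beta_post: float
    beta_delta: float
    cutoff: float
    provenance: str = "fitted"
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for v in (self.intercept, self.beta_post, self.beta_delta, self.cutoff):
            if not np.isfinite(v):
                raise ValueError("model parameters must be finite")
        if self.provenance not in {"published", "fitted"}:
            raise ValueError("provenance must be 'published' or 'fitted'")

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "beta_post": self.beta_post,
            "beta_delta": self.beta_delta,
            "cutoff": self.cutoff,
            "provenance": self.provenance,
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TRModel":
        return cls(
            intercept=float(d["intercept"]),
            beta_post=float(d["beta_post"]),
            beta_delta=float(d["beta_delta"]),
            cutoff=float(d["cutoff"]),
            provenance=d.get("provenance", "fitted"),
            flags=tuple(d.get("flags", ())),
        )


_PUBLISHED = TRModel(
    intercept=-8.132,
    beta_post=1.226,
    beta_delta=1.146,
    cutoff=0.76,
    provenance="published",
)


def published_model() -> TRModel:
    """The frozen published model: TR = −8.132 + 1.226·post + 1.146·Δ, cutoff 0.76."""
    return _PUBLISHED


def tr_score(model: TRModel, post: float, delta: float) -> float:
    """Linear predictor β0 + β_post·post + β_delta·Δ (not a probability)."""
    if not (np.isfinite(post) and np.isfinite(delta)):
        raise ValueError("post and delta scores must be finite")
    return float(model.intercept + model.beta_post * post + model.beta_delta * delta)


def tr_probability(model: TRModel, post: float, delta: float) -> float:
    """Convenience logistic-link probability of viable disease."""
    return float(expit(tr_score(model, post, delta)))


def classify(model: TRModel, score: float) -> str:
    """"viable" iff score >= cutoff (boundary counted viable), else "nonviable"."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    return "viable" if score >= model.cutoff else "nonviable"


def _design(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = records[["post_score", "delta_score"]].to_numpy(dtype=float)
    lab = records["label"]
    if lab.dtype == bool:
        y = lab.to_numpy()
    else:
        y = (lab == "viable").to_numpy()
    return X, y


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    """MLE logistic fit with a flagged minimal-ridge fallback on separation."""
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y.astype(float), sm.add_constant(X)).fit(
                disp=0, maxiter=100, tol=1e-8
            )
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            params, converged = np.full(X.shape[1] + 1, np.inf), False
    separated = any("erfectSeparation" in type(w.message).__name__ for w in caught)
    if (
        converged
        and not separated
        and np.isfinite(params).all()
        and np.linalg.norm(params) < SEPARATION_BOUND
    ):
        return params, ()
    clf = LogisticRegression(C=1.0 / RIDGE_ALPHA, solver="lbfgs", max_iter=2000)
    clf.fit(X, y)
    params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
    return params, ("penalized_separation_fallback",)


def fit_tr(records: pd.DataFrame) -> TRModel:
    """Maximum-likelihood logistic fit of viability on (post, Δ) Digital Scores.

    The decision cutoff is the Youden-optimal threshold of the in-sample
    linear predictors.  Quasi-separated cohorts fall back to a minimal L2
    penalty (alpha 1e-4) and carry a flag.
    """
    X, y = _design(records)
    if y.sum() < 3 or (~y).sum() < 3:
        raise ValueError("need >= 3 records per class to fit")
    params, flags = _fit_logistic(X, y)
    lp = params[0] + X @ params[1:]
    cutoff, _, _ = youden_cutoff(lp, y)
    return TRModel(
        intercept=float(params[0]),
        beta_post=float(params[1]),
        beta_delta=float(params[2]),
        cutoff=float(cutoff),
        provenance="fitted",
        flags=flags,
    )


def _heldout_scores(X: np.ndarray, y: np.ndarray, folds: list[np.ndarray]) -> np.ndarray:
    """Linear predictors for each fold's test records from fits on the rest."""
    scores = np.empty(len(y))
    for test_idx in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        if len(np.unique(y[mask])) < 2:
            warnings.warn("a training fold lost a class; fitting anyway")
        params, _ = _fit_logistic(X[mask], y[mask])
        scores[test_idx] = params[0] + X[test_idx] @ params[1:]
    return scores


def loocv_auroc(records: pd.DataFrame) -> float:
    """Leave-one-out CV: AUROC of the n held-out linear predictors."""
    X, y = _design(records)
    if len(y) < 6:
        raise ValueError("need n >= 6 for leave-one-out cross-validation")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    folds = [np.array([i]) for i in range(len(y))]
    return auroc(_heldout_scores(X, y, folds), y)


def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified folds: per-class seeded shuffle, round-robin deal."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    pos = 0  # continue the deal across classes so k = n yields singleton folds
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i in idx:
            folds[pos % k].append(int(i))
            pos += 1
    return [np.array(sorted(f), dtype=int) for f in folds if f]


def kfold_auroc(records: pd.DataFrame, k: int = 10, seed: int = 0) -> float:
    """Stratified k-fold CV: single AUROC of the pooled held-out predictors."""
    X, y = _design(records)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(y):
        raise ValueError("k cannot exceed the number of records")
    return auroc(_heldout_scores(X, y, stratified_folds(y, k, seed)), y)


def _lasso_path_grid(X_std: np.ndarray, y: np.ndarray, n_grid: int = 50) -> np.ndarray:
    """Log-spaced penalties from the null point down four decades."""
    n = len(y)
    lam_max = np.abs(X_std.T @ (y - y.mean())).max() / n
    return np.geomspace(lam_max, lam_max * 1e-4, n_grid)


def _l1_fit(X_std: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    n = len(y)
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear", max_iter=5000, tol=1e-8
    )
    clf.fit(X_std, y)
    return np.concatenate([clf.intercept_, clf.coef_.ravel()])


def lasso_auroc(records: pd.DataFrame, seed: int = 0) -> tuple[float, float]:
    """L1-penalized logistic over a 50-point penalty grid.

    The penalty is chosen by stratified 5-fold cross-validated deviance on
    internally standardized predictors; the returned AUROC pools the
    held-out linear predictors at that penalty.  Returns (auroc, penalty).
    """
    X, y = _design(records)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("zero-variance predictor; LASSO path undefined")
    X_std = (X - X.mean(axis=0)) / sd
    grid = _lasso_path_grid(X_std, y)
    folds = stratified_folds(y, 5, seed)

    best_lam, best_dev = None, np.inf
    for lam in grid:
        dev = 0.0
        for test_idx in folds:
            mask = np.ones(len(y), dtype=bool)
            mask[test_idx] = False
            params = _l1_fit(X_std[mask], y[mask], lam)
            p = expit(params[0] + X_std[test_idx] @ params[1:])
            p = np.clip(p, 1e-12, 1 - 1e-12)
            dev -= 2.0 * np.sum(y[test_idx] * np.log(p) + (1 - y[test_idx]) * np.log(1 - p))
        if dev < best_dev - 1e-12:
            best_dev, best_lam = dev, lam

    heldout = np.empty(len(y))
    for test_idx in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        params = _l1_fit(X_std[mask], y[mask], best_lam)
        heldout[test_idx] = params[0] + X_std[test_idx] @ params[1:]
    if np.allclose(heldout, heldout[0]):
        return 0.5, float(best_lam)  # null model: no discrimination
    return auroc(heldout, y), float(best_lam)
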