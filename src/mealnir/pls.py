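"""PLS1 regression by NIPALS, cross-validation and latent-variable choice.

The single-response NIPALS recursion: with X centred and y centred,

    w_k = X'y / ||X'y||        (weight)
    t_k = X w_k                (score)
    p_k = X't_k / t_k't_k      (x-loading)
    q_k = y't_k / t_k't_k      (y-loading)
    X <- X - t_k p_k' ;  y <- y - q_k t_k   (deflation)

after K components the regression vector in centred coordinates is
``b = W (P'W)^{-1} q``, and predictions are ``y_mean + (X - x_mean) b``.
For PLS1 each component is a single pass (no inner iteration), but a
convergence guard is kept for safety.

Latent-variable count is chosen by minimising RMSECV under a cap
(default 10, the conventional complexity limit for these models), with
ties broken toward the smaller, more parsimonious model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "CVResult",
    "fit_pls1",
    "predict",
    "cross_validate",
    "select_n_lv",
    "cv_folds",
    "PLSError",
]

LV_CAP_DEFAULT = 10


class PLSError(ValueError):
    pass


@dataclass(frozen=True)
class PLSModel:
    """Fitted PLS1 model (all arrays in centred coordinates)."""

    n_lv: int
    weights: np.ndarray       # (p, K)
    x_loadings: np.ndarray    # (p, K)
    y_loadings: np.ndarray    # (K,)
    coef: np.ndarray          # (p,) regression vector
    x_mean: np.ndarray        # (p,)
    y_mean: float
    scores: np.ndarray        # (n, K) training scores
    explained_y_variance: np.ndarray  # (K,) cumulative fraction of SSY
    metadata: dict = field(default_factory=dict)

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coef)

    def to_json(self) -> str:
        doc = {
            "n_lv": self.n_lv,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "explained_y_variance": self.explained_y_variance.tolist(),
            "metadata": self.metadata,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PLSModel":
        doc = json.loads(text)
        return cls(
            n_lv=int(doc["n_lv"]),
            weights=np.asarray(doc["weights"], dtype=float),
            x_loadings=np.asarray(doc["x_loadings"], dtype=float),
            y_loadings=np.asarray(doc["y_loadings"], dtype=float),
            coef=np.asarray(doc["coef"], dtype=float),
            x_mean=np.asarray(doc["x_mean"], dtype=float),
            y_mean=float(doc["y_mean"]),
            scores=np.zeros((0, int(doc["n_lv"]))),
            explained_y_variance=np.asarray(
                doc["explained_y_variance"], dtype=float
            ),
            metadata=doc.get("metadata", {}),
        )


@dataclass(frozen=True)
class CVResult:
    """Per-LV RMSECV curve and the chosen complexity."""

    rmsecv: np.ndarray  # index k -> RMSECV with k+1 latent variables
    scheme: str
    chosen_n_lv: int

    def __post_init__(self) -> None:
        if np.any(self.rmsecv < 0):
            raise PLSError("RMSECV values must be non-negative")


def fit_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    metadata: dict | None = None,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> PLSModel:
    """Fit a single-response PLS model with ``n_lv`` components."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise PLSError("X rows and y length differ")
    if not (1 <= n_lv <= min(n - 1, p)):
        raise PLSError(
            f"n_lv={n_lv} outside valid range [1, {min(n - 1, p)}]"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    ssy = float(yc @ yc)
    if ssy <= 1e-300:
        raise PLSError("zero-variance response")

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    explained = np.zeros(n_lv)
    Xd, yd = Xc.copy(), yc.copy()
    for k in range(n_lv):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm <= 1e-300:
            raise PLSError(f"rank deficiency at component {k + 1}")
        w /= norm
        # PLS1 converges in one pass; guarded loop for safety
        for _ in range(max_iter):
            t = Xd @ w
            tt = float(t @ t)
            if tt <= 1e-300:
                raise PLSError(f"vanishing score at component {k + 1}")
            w_new = Xd.T @ yd
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = Xd @ w
        tt = float(t @ t)
        pk = Xd.T @ t / tt
        qk = float(yd @ t / tt)
        Xd -= np.outer(t, pk)
        yd -= qk * t
        W[:, k], P[:, k], q[k], T[:, k] = w, pk, qk, t
        explained[k] = 1.0 - float(yd @ yd) / ssy

    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_lv=n_lv,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        x_mean=x_mean,
        y_mean=y_mean,
        scores=T,
        explained_y_variance=explained,
        metadata=metadata or {},
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict the response in original units."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coef.shape[0]:
        raise PLSError(
            f"expected {model.coef.shape[0]} wavelengths, got {X.shape[1]}"
        )
    return model.y_mean + (X - model.x_mean) @ model.coef


def cv_folds(n: int, scheme: str = "venetian", n_splits: int = 10):
    """Index sets of held-out samples for a CV scheme.

    venetian  -- fold k holds out indices k, k+s, k+2s, ... (interleaved)
    blocks    -- contiguous blocks
    loo       -- leave-one-out
    """
    if scheme == "loo":
        return [np.array([i]) for i in range(n)]
    n_splits = min(n_splits, n)
    if n_splits < 2:
        raise PLSError("cross-validation needs at least two folds")
    if scheme == "venetian":
        return [np.arange(k, n, n_splits) for k in range(n_splits)]
    if scheme == "blocks":
        return [np.array_split(np.arange(n), n_splits)[k] for k in range(n_splits)]
    raise PLSError(f"unknown CV scheme {scheme!r}")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    max_lv: int,
    scheme: str = "venetian",
    n_splits: int = 10,
    cap: int = LV_CAP_DEFAULT,
) -> CVResult:
    """RMSECV per latent-variable count, refitting within each fold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if max_lv < 1:
        raise PLSError("max_lv must be >= 1")
    folds = cv_folds(n, scheme, n_splits)
    for f in folds:
        if n - f.size < 2:
            raise PLSError("a fold leaves fewer than two training samples")
    max_lv = min(max_lv, min(n - max(f.size for f in folds) - 1, X.shape[1]))
    press = np.zeros(max_lv)
    for held in folds:
        keep = np.setdiff1d(np.arange(n), held)
        Xk = X[keep]
        # deflation exhausts a rank-r matrix after r components; past
        # that the model (and RMSECV) is unchanged
        rank = np.linalg.matrix_rank(Xk - Xk.mean(axis=0))
        kmax = min(max_lv, max(int(rank), 1))
        model = fit_pls1(Xk, y[keep], kmax)
        # predictions with k components reuse the kmax-component decomposition
        for k in range(1, max_lv + 1):
            kk = min(k, kmax)
            coef_k = model.weights[:, :kk] @ np.linalg.solve(
                model.x_loadings[:, :kk].T @ model.weights[:, :kk],
                model.y_loadings[:kk],
            )
            pred = model.y_mean + (X[held] - model.x_mean) @ coef_k
            press[k - 1] += float(np.sum((y[held] - pred) ** 2))
    rmsecv = np.sqrt(press / n)
    result = CVResult(rmsecv=rmsecv, scheme=f"{scheme}({len(folds)})", chosen_n_lv=1)
    chosen = select_n_lv(result, cap=cap)
    return CVResult(rmsecv=rmsecv, scheme=result.scheme, chosen_n_lv=chosen)


def select_n_lv(cv: CVResult, cap: int = LV_CAP_DEFAULT) -> int:
    """Smallest LV count attaining the minimum RMSECV within the cap."""
    if cv.rmsecv.size == 0:
        raise PLSError("empty cross-validation result")
    usable = cv.rmsecv[: min(cap, cv.rmsecv.size)]
    return int(np.argmin(usable)) + 1
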