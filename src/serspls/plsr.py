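"""Univariate-response partial least squares regression (NIPALS).

The calibration model at the heart of the package, written from scratch.
Spectra are mean-centered, latent variables are extracted in sequence so
that each score t_k = X_c w_k maximizes covariance with the (deflated)
concentration vector, and prediction is the centered spectrum times the
regression coefficient plus the mean calibration concentration:

    w_k = X_cᵀ y_c / ‖X_cᵀ y_c‖          (unit weight)
    t_k = X_c w_k                          (score / latent variable)
    p_k = X_cᵀ t_k / (t_kᵀ t_k)            (spectral loading)
    q_k = y_cᵀ t_k / (t_kᵀ t_k)            (response loading)
    X_c ← X_c − t_k p_kᵀ,  y_c ← y_c − q_k t_k
    b = W (Pᵀ W)⁻¹ q,   ŷ(x) = (x − x̄)·b + ȳ

Only centering is applied — no per-channel variance scaling — and
predictions are never clipped, so blank samples may come out slightly
negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import WindowSet

__all__ = [
    "PLSRModel",
    "FitDiagnostics",
    "mean_center",
    "fit_nipals",
    "predict",
    "select_components_cv",
    "r_squared",
    "rmse",
]

_PINV_RCOND = 1e-10
_DEFLATION_EPS = 1e-12


@dataclass
class PLSRModel:
    """Fitted PLSR calibration model.

    ``W``/``P`` are (n_channels, A) weight/loading matrices, ``q`` the A
    response loadings, ``b`` the channel-space regression coefficient
    (mg/L per intensity unit). ``wavenumbers`` and ``windows`` record the
    channel layout the model expects at prediction time.
    """

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    P: np.ndarray
    q: np.ndarray
    b: np.ndarray
    n_components: int
    wavenumbers: np.ndarray | None = None
    windows: WindowSet | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return len(self.x_mean)

    def predict(self, X: np.ndarray) -> np.ndarray | float:
        return predict(self, X)


@dataclass
class FitDiagnostics:
    """Per-fit byproducts: scores, covariance captured, early-stop flag."""

    scores: np.ndarray  # (n_samples, A)
    covariance: np.ndarray  # cov(t_k, y residual) before each deflation
    requested_components: int
    early_stopped: bool = False
    rmsecv: np.ndarray | None = None


def mean_center(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Column-center X and center y; returns (X_c, y_c, x_mean, y_mean)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 2:
        raise ValueError("mean centering needs at least 2 rows")
    if X.shape[0] != len(y):
        raise ValueError(f"X has {X.shape[0]} rows but y has {len(y)} entries")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    return X - x_mean, y - y_mean, x_mean, y_mean


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """Core extract-and-deflate loop on already-centered data.

    Returns (W, P, q, T, early_stopped); may return fewer components than
    requested when deflation degenerates (covariance numerically zero).
    """
    n, m = Xc.shape
    Xr = Xc.copy()
    yr = yc.copy()
    Ws, Ps, qs, Ts, covs = [], [], [], [], []
    early = False
    for _ in range(n_components):
        s = Xr.T @ yr
        s_norm = np.linalg.norm(s)
        # degeneracy judged against the current deflated magnitudes, so the
        # loop runs to full rank on wide matrices where both factors shrink
        scale = max(
            np.linalg.norm(Xr, ord="fro") * np.linalg.norm(yr), np.finfo(float).tiny
        )
        if s_norm <= _DEFLATION_EPS * scale:
            early = True
            break
        w = s / s_norm
        t = Xr @ w
        tt = float(t @ t)
        if tt <= _DEFLATION_EPS * float(np.linalg.norm(Xr, ord="fro") ** 2):
            early = True
            break
        p = Xr.T @ t / tt
        qk = float(yr @ t) / tt
        covs.append(float(t @ yr) / max(n - 1, 1))
        Xr = Xr - np.outer(t, p)
        yr = yr - qk * t
        Ws.append(w)
        Ps.append(p)
        qs.append(qk)
        Ts.append(t)
    if not Ws:
        raise ValueError("no latent variable could be extracted: X carries no covariance with y")
    W = np.column_stack(Ws)
    P = np.column_stack(Ps)
    q = np.asarray(qs)
    T = np.column_stack(Ts)
    return W, P, q, T, np.asarray(covs), early


def _coefficient(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """b = W (PᵀW)⁻¹ q, falling back to a pseudo-inverse when singular."""
    PtW = P.T @ W
    try:
        inner = np.linalg.solve(PtW, q)
    except np.linalg.LinAlgError:
        inner = np.linalg.pinv(PtW, rcond=_PINV_RCOND) @ q
    return W @ inner


def fit_nipals(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    *,
    wavenumbers: np.ndarray | None = None,
    windows: WindowSet | None = None,
) -> tuple[PLSRModel, FitDiagnostics]:
    """Fit a univariate-response PLSR model with ``n_components`` latent variables.

    Raises when ``n_components`` exceeds min(rows − 1, channels); if the
    data's rank runs out earlier, the fit stops at the components found and
    flags ``early_stopped`` in the diagnostics.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    limit = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= limit:
        raise ValueError(
            f"n_components must be in [1, {limit}] for a {X.shape[0]}x{X.shape[1]} matrix, "
            f"got {n_components}"
        )
    Xc, yc, x_mean, y_mean = mean_center(X, y)
    W, P, q, T, covs, early = _nipals(Xc, yc, n_components)
    b = _coefficient(W, P, q)
    model = PLSRModel(
        x_mean=x_mean,
        y_mean=y_mean,
        W=W,
        P=P,
        q=q,
        b=b,
        n_components=W.shape[1],
        wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers, dtype=float),
        windows=windows,
    )
    diag = FitDiagnostics(
        scores=T, covariance=covs, requested_components=n_components, early_stopped=early
    )
    return model, diag


def predict(model: PLSRModel, X: np.ndarray) -> np.ndarray | float:
    """ŷ = (x − x̄)·b + ȳ for one spectrum (1-D) or a stack (2-D)."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    if X2.shape[1] != model.n_channels:
        raise ValueError(
            f"channel mismatch: model expects {model.n_channels} channels, "
            f"input has {X2.shape[1]}"
        )
    out = (X2 - model.x_mean) @ model.b + model.y_mean
    return float(out[0]) if single else out


def select_components_cv(
    X: np.ndarray,
    y: np.ndarray,
    a_max: int | None = None,
) -> tuple[int, np.ndarray]:
    """Leave-one-sample-out choice of the number of latent variables.

    Returns (A*, RMSECV curve over 1…a_max). A* minimizes RMSECV; curve
    values indistinguishable from the minimum (within 1e-9 of the response
    scale) count as ties, broken toward the smallest A so that rank-limited
    noiseless data selects the true rank rather than a numerically jittered
    larger count.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("cross-validation needs at least 3 samples")
    cap = min(n - 2, X.shape[1])
    a_max = cap if a_max is None else min(a_max, cap)
    if a_max < 1:
        raise ValueError("a_max must allow at least one component")

    press = np.zeros(a_max)
    for i in range(n):
        keep = np.arange(n) != i
        Xc, yc, x_mean, y_mean = mean_center(X[keep], y[keep])
        W, P, q, _, _, _ = _nipals(Xc, yc, a_max)
        found = W.shape[1]
        xi = X[i] - x_mean
        pred_last = y_mean
        for a in range(1, a_max + 1):
            if a <= found:
                b_a = _coefficient(W[:, :a], P[:, :a], q[:a])
                pred_last = float(xi @ b_a) + y_mean
            press[a - 1] += (pred_last - y[i]) ** 2
    rmsecv = np.sqrt(press / n)
    tol = 1e-9 * max(float(np.std(y)), 1.0)
    a_star = int(np.flatnonzero(rmsecv <= rmsecv.min() + tol)[0]) + 1
    return a_star, rmsecv


def r_squared(pred: np.ndarray, actual: np.ndarray) -> float:
    """Squared Pearson correlation between predicted and actual values.

    This is the R² of the best straight line through the predicted-vs-actual
    scatter, so it is symmetric in its arguments and invariant to affine
    rescaling of either; it is *not* 1 − SS_res/SS_tot.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if len(pred) != len(actual):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(actual)}")
    if len(pred) < 2:
        raise ValueError("r_squared needs at least 2 points")
    if np.std(actual) == 0 or np.std(pred) == 0:
        raise ValueError("r_squared undefined for a constant argument")
    r = np.corrcoef(pred, actual)[0, 1]
    return float(r * r)


def rmse(pred: np.ndarray, actual: np.ndarray) -> float:
    """Root-mean-square error between predicted and actual (mg/L)."""
    pred = np.asarray(pred, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if len(pred) != len(actual):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(actual)}")
    if len(pred) == 0:
        raise ValueError("rmse needs at least one point")
    return float(np.sqrt(np.mean((pred - actual) ** 2)))
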