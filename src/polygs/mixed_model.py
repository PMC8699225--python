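"""REML variance components and BLUP prediction.

Single-random-effect model ``y = X beta + g + e`` with
``g ~ N(0, K sigma_g^2)`` and ``e ~ N(0, I sigma_e^2)``.  The restricted
likelihood is profiled on the variance ratio ``delta = sigma_e^2 / sigma_g^2``
after one eigendecomposition of K projected against the fixed effects
(EMMA-style), so the 1-D optimization in ``log delta`` is exact up to grid
refinement and cannot fail to converge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize

from polygs.dosage_io import PhenotypeVector
from polygs.grm import KinshipMatrix

logger = logging.getLogger(__name__)

LOG_DELTA_BOUNDS = (-8.0, 8.0)
_PSD_RTOL = 1e-8


@dataclass
class VarianceComponents:
    """REML estimates of genetic and residual variance."""

    sigma_g2: float
    sigma_e2: float
    reml_loglik: float
    boundary: bool = False

    @property
    def delta(self) -> float:
        """Variance ratio sigma_e^2 / sigma_g^2 (inf at the h2=0 boundary)."""
        if self.sigma_g2 == 0:
            return np.inf
        return self.sigma_e2 / self.sigma_g2

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


@dataclass
class GEBVResult:
    """Predicted genetic values with the fixed effects that produced them."""

    gebv: np.ndarray
    sample_ids: list[str]
    sets: np.ndarray  # "train" / "test" per individual
    fixed_effects: np.ndarray
    model: str
    vc: VarianceComponents


@dataclass
class MarkerEffects:
    """Ridge-type per-marker effect estimates."""

    u: np.ndarray
    fixed_effects: np.ndarray
    lam: float
    vc: VarianceComponents | None = None


def _as_design(X, n: int) -> np.ndarray:
    if X is None:
        return np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("fixed-effect design rows do not match phenotype length")
    return X


def reml_profile(
    y: np.ndarray, X: np.ndarray, K: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Project out fixed effects and diagonalize K on the residual space.

    Returns ``(xi, u)``: eigenvalues of Q'KQ and rotated data V'Q'y, from
    which the restricted likelihood at any delta is a closed form.
    """
    n, q = X.shape
    Qfull, _ = linalg.qr(X)
    Q2 = Qfull[:, q:]  # orthonormal basis of the residual space
    A = Q2.T @ K @ Q2
    xi, V = linalg.eigh((A + A.T) / 2.0)
    lmax = max(xi.max(), 0.0)
    if xi.min() < -_PSD_RTOL * max(lmax, 1.0):
        raise ValueError(
            f"kinship matrix is not PSD on the residual space "
            f"(min eigenvalue {xi.min():.3e})"
        )
    xi = np.clip(xi, 0.0, None)
    u = V.T @ (Q2.T @ y)
    return xi, u


def reml_loglik_at(log_delta: float, xi: np.ndarray, u: np.ndarray) -> float:
    """Restricted log-likelihood profiled over sigma_g^2 at fixed delta."""
    delta = np.exp(log_delta)
    denom = xi + delta
    nq = xi.size
    sigma_g2 = float(np.sum(u**2 / denom) / nq)
    return -0.5 * (
        nq * np.log(2.0 * np.pi) + nq * np.log(sigma_g2) + np.sum(np.log(denom)) + nq
    )


def reml_fit(
    y: PhenotypeVector | np.ndarray,
    K: KinshipMatrix | np.ndarray,
    X: np.ndarray | None = None,
    grid_points: int = 161,
) -> VarianceComponents:
    """REML fit of (sigma_g^2, sigma_e^2) by 1-D search in log delta.

    A coarse grid over ``log delta in [-8, 8]`` locates the basin; bounded
    scalar refinement polishes it.  Solutions pinned at either bound are
    returned with ``boundary=True`` (h2 -> 1 or h2 -> 0 respectively).
    """
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, float)
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    n = yv.size
    if n < 5:
        raise ValueError("need at least 5 observations for REML")
    if np.ptp(yv) == 0:
        raise ValueError("constant phenotype")
    Xd = _as_design(X, n)
    if Kv.shape != (n, n):
        raise ValueError("kinship dimension does not match phenotype length")

    xi, u = reml_profile(yv, Xd, Kv)
    lo, hi = LOG_DELTA_BOUNDS
    grid = np.linspace(lo, hi, grid_points)
    ll = np.array([reml_loglik_at(g, xi, u) for g in grid])
    i = int(np.argmax(ll))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        lambda g: -reml_loglik_at(g, xi, u), bounds=(a, b), method="bounded",
        options={"xatol": 1e-10},
    )
    log_delta = float(res.x)
    loglik = -float(res.fun)
    boundary = log_delta <= lo + 1e-3 or log_delta >= hi - 1e-3
    if boundary:
        logger.info("REML solution at log-delta boundary (%.2f)", log_delta)
    delta = np.exp(log_delta)
    sigma_g2 = float(np.sum(u**2 / (xi + delta)) / xi.size)
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=delta * sigma_g2,
        reml_loglik=loglik,
        boundary=boundary,
    )


def gblup_predict(
    y_train: PhenotypeVector | np.ndarray,
    K_full: KinshipMatrix,
    train_ids: list[str],
    test_ids: list[str],
    vc: VarianceComponents | None = None,
    X_full: np.ndarray | None = None,
) -> GEBVResult:
    """BLUP of genetic values for training and held-out individuals.

    ``g_hat[test] = K[test,train] (K[train,train] + delta I)^-1 (y - X beta)``
    with beta estimated by generalized least squares on the training block.
    ``vc`` defaults to a fresh REML fit on the training block.
    """
    yv = y_train.values if isinstance(y_train, PhenotypeVector) else np.asarray(y_train, float)
    pos = {s: i for i, s in enumerate(K_full.sample_ids)}
    missing = [s for s in list(train_ids) + list(test_ids) if s not in pos]
    if missing:
        raise ValueError(f"ids not in kinship matrix: {missing[:5]}")
    if set(train_ids) & set(test_ids):
        raise ValueError("train and test ids overlap")
    tr = np.array([pos[s] for s in train_ids])
    te = np.array([pos[s] for s in test_ids])
    if yv.size != tr.size:
        raise ValueError("y_train length does not match train_ids")

    n_full = K_full.n_samples
    Xf = _as_design(X_full, n_full) if X_full is not None else np.ones((n_full, 1))
    Xtr = Xf[tr]
    Ktt = K_full.submatrix(tr)
    if vc is None:
        vc = reml_fit(yv, Ktt, X=Xtr if X_full is not None else None)
    delta = vc.delta
    if not np.isfinite(delta):  # h2 = 0: total shrinkage, GLS becomes OLS
        beta = linalg.lstsq(Xtr, yv)[0]
        ghat = np.zeros(tr.size + te.size)
    else:
        C = Ktt + delta * np.eye(tr.size)
        cond = np.linalg.cond(C)
        if cond > 1e12:
            raise ValueError(
                f"(K_train + delta I) is numerically singular (cond={cond:.2e})"
            )
        cho = linalg.cho_factor(C)
        Ciy = linalg.cho_solve(cho, yv)
        CiX = linalg.cho_solve(cho, Xtr)
        beta = linalg.solve(Xtr.T @ CiX, Xtr.T @ Ciy, assume_a="sym")
        alpha = linalg.cho_solve(cho, yv - Xtr @ beta)
        g_train = Ktt @ alpha
        g_test = K_full.submatrix(te, tr) @ alpha
        ghat = np.concatenate([g_train, g_test])

    ids = [K_full.sample_ids[i] for i in np.concatenate([tr, te]).astype(int)]
    sets = np.array(["train"] * tr.size + ["test"] * te.size)
    return GEBVResult(
        gebv=ghat,
        sample_ids=ids,
        sets=sets,
        fixed_effects=np.atleast_1d(beta),
        model=f"gblup:{K_full.method}",
        vc=vc,
    )


def rrblup_solve(
    y: PhenotypeVector | np.ndarray,
    Zm: np.ndarray,
    lambda_policy: str = "reml",
    lam: float | None = None,
    scaling_constant: float | None = None,
    X: np.ndarray | None = None,
) -> MarkerEffects:
    """Ridge-type marker-effect estimates from a centered dosage matrix.

    Solves ``u = Zm' (Zm Zm' + lambda c I)^-1 (y - X beta)`` where
    ``c`` normalizes the implied kinship ``Zm Zm' / c`` (default: mean
    diagonal one) and ``lambda`` is the REML delta on that kinship
    (``lambda_policy='reml'``) or a supplied value (``'fixed'``).
    Projecting ``Zm u`` reproduces GBLUP genetic values exactly.
    """
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, float)
    Zm = np.asarray(Zm, dtype=float)
    n, m = Zm.shape
    if yv.size != n:
        raise ValueError("phenotype length does not match marker matrix rows")
    if np.max(np.abs(Zm.mean(axis=0))) > 1e-6 * max(np.abs(Zm).max(), 1.0):
        raise ValueError("Zm must be column-centered")
    Xd = _as_design(X, n)
    ZZt = Zm @ Zm.T
    c = scaling_constant if scaling_constant is not None else float(np.trace(ZZt) / n)
    if c <= 0:
        raise ValueError("degenerate marker matrix (zero variance)")

    vc = None
    if lambda_policy == "reml":
        vc = reml_fit(yv, ZZt / c, X=X)
        lam = vc.delta
    elif lambda_policy == "fixed":
        if lam is None:
            raise ValueError("lambda_policy='fixed' requires lam")
    else:
        raise ValueError(f"unknown lambda_policy: {lambda_policy!r}")

    if not np.isfinite(lam):
        beta = linalg.lstsq(Xd, yv)[0]
        return MarkerEffects(np.zeros(m), np.atleast_1d(beta), lam, vc)

    C = ZZt + lam * c * np.eye(n)
    cho = linalg.cho_factor(C)
    CiX = linalg.cho_solve(cho, Xd)
    Ciy = linalg.cho_solve(cho, yv)
    beta = linalg.solve(Xd.T @ CiX, Xd.T @ Ciy, assume_a="sym")
    u = Zm.T @ linalg.cho_solve(cho, yv - Xd @ beta)
    return MarkerEffects(u, np.atleast_1d(beta), float(lam), vc)
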