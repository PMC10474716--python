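"""Genomic BLUP: trace-scaled GRM, two-component REML, closed-form prediction.

The genomic relationship matrix is ``G_a = M M' / s`` with
``s = trace(M M') / r``, computed on the dosage coding exactly as provided
(no centring unless requested), so ``trace(G_a) = r`` by construction.

The line-effects model ``y = 1 mu* + a + e*`` with ``a ~ N(0, sigma2_a G_a)``
and ``e* ~ N(0, sigma2 I)`` is fitted by REML: one eigendecomposition of
``G_a`` reduces the likelihood to diagonal form and the profile over the
ratio ``sigma2_a / sigma2`` is searched in 1-D.  Prediction uses the
mixed-model closed forms

    mu*_hat = (1' H^-1 1)^-1 1' H^-1 y,
    a_tilde = G_a H^-1 (y - 1 mu*_hat),       H = sigma2 I + sigma2_a G_a,

on the training block; held-out lines are predicted through the
cross-block rows of the full GRM (the BLUP of an unobserved effect).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .data import MarkerMatrix
from .optim import golden_section


@dataclass
class GRM:
    """Trace-scaled additive relationship matrix."""

    matrix: np.ndarray
    scale_s: float
    line_ids: list

    def __post_init__(self) -> None:
        A = self.matrix
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    @property
    def r(self) -> int:
        return self.matrix.shape[0]


@dataclass
class VarianceEstimates:
    sigma2_e: float
    sigma2_a: float
    loglik: float
    boundary_flag: bool = False

    def __post_init__(self) -> None:
        if self.sigma2_e < 0 or self.sigma2_a < 0:
            raise ValueError("variance components must be >= 0")


def build_grm(m: MarkerMatrix, center: bool = False) -> GRM:
    """G_a = M M' / s with s = trace(M M') / r (optionally column-centred)."""
    if m.has_missing:
        raise ValueError("marker matrix has missing values; impute first")
    X = m.dosages
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    mmT = X @ X.T
    s = float(np.trace(mmT)) / m.n_lines
    if s <= 0:
        raise ValueError("degenerate marker matrix (trace(MM')/r = 0)")
    return GRM(mmT / s, s, list(m.line_ids))


def reml_profile_loglik(y: np.ndarray, G: GRM, log_ratio: float) -> float:
    """Profiled REML log-likelihood at log(sigma2_a / sigma2_e).

    mu and the residual variance are profiled out; constants independent of
    the ratio are dropped consistently.
    """
    d, U = np.linalg.eigh(G.matrix)
    return _profile_loglik_rotated(np.asarray(y, float), d, U, log_ratio)


def _profile_loglik_rotated(y, d, U, log_ratio) -> float:
    n = y.size
    phi = np.exp(log_ratio)
    v = phi * np.clip(d, 0.0, None) + 1.0
    yt = U.T @ y
    xt = U.T @ np.ones(n)
    w = 1.0 / v
    xwx = np.sum(w * xt * xt)
    mu = np.sum(w * xt * yt) / xwx
    res = yt - xt * mu
    ypy = np.sum(w * res * res)
    return -0.5 * (np.sum(np.log(v)) + np.log(xwx) + (n - 1) * np.log(ypy))


def reml_two_vc(
    y: np.ndarray, G: GRM, log_ratio_bounds: Tuple[float, float] = (-12.0, 12.0)
) -> VarianceEstimates:
    """REML estimates of (sigma2_e, sigma2_a) by profiled 1-D search."""
    y = np.asarray(y, dtype=float)
    if y.size != G.r:
        raise ValueError(f"length(y)={y.size} != r={G.r}")
    if y.size < 3:
        raise ValueError("need at least 3 lines for variance estimation")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")
    d, U = np.linalg.eigh(G.matrix)
    if d.min() < -1e-8:
        raise ValueError(f"GRM not PSD (min eigenvalue {d.min():.3e})")

    def neg(ll):
        return -_profile_loglik_rotated(y, d, U, ll)

    lo, hi = log_ratio_bounds
    ll_hat, neg_min = golden_section(neg, lo, hi, tol=1e-8)
    at_edge = ll_hat < lo + 1e-3 or ll_hat > hi - 1e-3
    # flat profile (e.g. G = I): the split is non-identifiable
    span = abs(neg(lo) - neg_min) + abs(neg(hi) - neg_min)
    flat = span < 1e-6
    phi = float(np.exp(ll_hat))

    n = y.size
    v = phi * np.clip(d, 0.0, None) + 1.0
    yt, xt = U.T @ y, U.T @ np.ones(n)
    w = 1.0 / v
    xwx = np.sum(w * xt * xt)
    mu = np.sum(w * xt * yt) / xwx
    res = yt - xt * mu
    ypy = np.sum(w * res * res)
    sigma2_e = float(ypy / (n - 1))
    sigma2_a = float(phi * sigma2_e)
    return VarianceEstimates(
        sigma2_e=sigma2_e,
        sigma2_a=sigma2_a,
        loglik=float(-neg_min),
        boundary_flag=bool(at_edge or flat),
    )


def gblup_predict(
    y_train: np.ndarray,
    G_full: GRM,
    train_index: Sequence[int],
    variances: VarianceEstimates,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Closed-form GBLUP over all lines given training responses.

    Returns ``(mu_star_hat, a_tilde, y_tilde)`` with one entry per line of
    ``G_full`` (training lines get their in-sample BLUP, the rest the
    cross-block prediction of an unobserved additive effect).
    """
    y_train = np.asarray(y_train, dtype=float)
    train = np.asarray(train_index, dtype=int)
    if train.size == 0:
        raise ValueError("train_index must be nonempty")
    if y_train.size != train.size:
        raise ValueError("y_train and train_index lengths differ")
    s2e, s2a = variances.sigma2_e, variances.sigma2_a
    if s2e == 0 and s2a == 0:
        raise ValueError("singular H: sigma2_e = sigma2_a = 0")
    Gtt = G_full.matrix[np.ix_(train, train)]
    H = s2e * np.eye(train.size) + s2a * Gtt
    Hinv_y = np.linalg.solve(H, y_train)
    Hinv_1 = np.linalg.solve(H, np.ones(train.size))
    mu = float(np.sum(Hinv_y) / np.sum(Hinv_1))
    resid = np.linalg.solve(H, y_train - mu)
    a_all = s2a * (G_full.matrix[:, train] @ resid)
    y_all = mu + a_all
    return mu, a_all, y_all


def ridge_marker_blup(
    M_train: np.ndarray,
    y_train: np.ndarray,
    scale_s: float,
    variances: VarianceEstimates,
    mu: Optional[float] = None,
) -> Tuple[float, np.ndarray]:
    """Equivalent marker-effect ridge solution (penalty s * sigma2 / sigma2_a).

    Provided for the GBLUP/RR-BLUP duality: ``M q_tilde + mu`` reproduces
    the GBLUP predictions when the same training set and variances are used.
    """
    s2e, s2a = variances.sigma2_e, variances.sigma2_a
    if s2a <= 0:
        raise ValueError("sigma2_a must be > 0 for the marker-effect form")
    Xt = np.asarray(M_train, float)
    yt = np.asarray(y_train, float)
    if mu is None:
        H = s2e * np.eye(yt.size) + (s2a / scale_s) * (Xt @ Xt.T)
        Hinv_y = np.linalg.solve(H, yt)
        Hinv_1 = np.linalg.solve(H, np.ones(yt.size))
        mu = float(np.sum(Hinv_y) / np.sum(Hinv_1))
    lam = scale_s * s2e / s2a
    q = np.linalg.solve(Xt.T @ Xt + lam * np.eye(Xt.shape[1]), Xt.T @ (yt - mu))
    return mu, q
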