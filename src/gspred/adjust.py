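"""Single-trial line-effects model, generalized heritability, de-regression.

The model is ``y = 1*mu + Z_g g + e`` with ``g ~ N(0, sigma2_g I_r)`` and
``e ~ N(0, sigma2_e I_n)``: a grand mean plus iid line effects, fitted to
plot-level yields.  Spatial trend in the plots is absorbed by the residual.
REML estimation profiles the likelihood over the variance ratio
``lambda = sigma2_e / sigma2_g``; because ``Z_g' Z_g`` is diagonal (the
per-line replication counts) every quantity has a closed form in lambda, so
the 1-D search is exact and cheap at any trial size.

Downstream methods consume the fit through three quantities per line: the
eBLUP ``g_tilde``, its prediction error variance (PEV), and the genetic
variance estimate.  ``deregress`` un-shrinks the eBLUPs,

    y_i = mu_hat + g_tilde_i / (1 - PEV_i / sigma2_g_hat),

producing adjusted yields whose regression on true genetic merit has unit
slope; ``generalized_h2`` is the Cullis-style trial-level repeatability
``1 - mean pairwise PEV of line differences / (2 sigma2_g_hat)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .data import PlotTable
from .optim import golden_section

logger = logging.getLogger(__name__)


@dataclass
class BlupFit:
    """Fitted single-trial line model."""

    line_ids: list
    mu_hat: float
    g_tilde: np.ndarray
    pev: np.ndarray
    sigma2_g_hat: float
    sigma2_e_hat: float
    loglik: float
    g_error_cov: np.ndarray  # r x r error covariance of (g_tilde - g)
    boundary_flag: bool = False
    lambda_hat: float = float("nan")
    counts: Optional[np.ndarray] = None


def _aggregate(plots: PlotTable):
    df = plots.df
    grp = df.groupby("line_id", sort=True)["yield"]
    line_ids = list(grp.count().index)
    counts = grp.count().to_numpy(float)
    sums = grp.sum().to_numpy(float)
    y = df["yield"].to_numpy(float)
    return line_ids, counts, sums, y


def _profile_pieces(lam: float, counts, sums, y):
    """Closed-form GLS pieces for V0 = Z Z' + lam I via Woodbury.

    Returns (yPy, gls_mu, log|V0|, 1'V0^-1 1) with V0 in sigma2_g units.
    """
    n = y.size
    r = counts.size
    d = counts + lam
    yy = float(y @ y)
    y_v_y = (yy - np.sum(sums**2 / d)) / lam
    one_v_one = (n - np.sum(counts**2 / d)) / lam
    one_v_y = (y.sum() - np.sum(counts * sums / d)) / lam
    logdet = (n - r) * np.log(lam) + np.sum(np.log(d))
    mu = one_v_y / one_v_one
    ypy = y_v_y - one_v_y**2 / one_v_one
    return ypy, mu, logdet, one_v_one


def reml_profile_loglik(plots: PlotTable, log_lambda: float) -> float:
    """Profiled REML log-likelihood at a given log variance ratio.

    Both sigma2_g and mu are profiled out; constants independent of lambda
    are dropped consistently, so differences across lambda are exact.
    """
    _, counts, sums, y = _aggregate(plots)
    n = y.size
    lam = float(np.exp(log_lambda))
    ypy, _, logdet, one_v_one = _profile_pieces(lam, counts, sums, y)
    return -0.5 * ((n - 1) * np.log(ypy) + logdet + np.log(one_v_one))


def fit_line_blup(plots: PlotTable, log_lambda_bounds=(-12.0, 12.0)) -> BlupFit:
    """REML fit of the iid line-effects model to a plot table."""
    line_ids, counts, sums, y = _aggregate(plots)
    r = counts.size
    n = y.size
    if r < 2:
        raise ValueError("need at least 2 lines")
    if n <= r + 1 and not np.all(counts >= 2):
        logger.warning(
            "only %d plots for %d lines; variance separation is weakly identified",
            n, r,
        )

    def neg_loglik(ll):
        lam = np.exp(ll)
        ypy, _, logdet, ovo = _profile_pieces(lam, counts, sums, y)
        return 0.5 * ((n - 1) * np.log(ypy) + logdet + np.log(ovo))

    lo, hi = log_lambda_bounds
    ll_hat, _ = golden_section(neg_loglik, lo, hi, tol=1e-8)
    boundary = ll_hat < lo + 1e-3 or ll_hat > hi - 1e-3
    lam = float(np.exp(ll_hat))

    ypy, mu_hat, logdet, one_v_one = _profile_pieces(lam, counts, sums, y)
    sigma2_g = ypy / (n - 1)
    sigma2_e = lam * sigma2_g
    g_tilde = (sums - counts * mu_hat) / (counts + lam)

    # error covariance of g_tilde - g: sigma2_e * C22^{-1} where
    # C22 = diag(n_i + lam) - n n'/n_tot  (mu absorbed), Sherman-Morrison.
    d = counts + lam
    t = counts / d
    s0 = n - np.sum(counts * t)
    cov = sigma2_e * (np.diag(1.0 / d) + np.outer(t, t) / s0)
    pev = np.diag(cov).copy()

    loglik = -0.5 * ((n - 1) * (1.0 + np.log(ypy / (n - 1))) + logdet + np.log(one_v_one))
    return BlupFit(
        line_ids=line_ids,
        mu_hat=float(mu_hat),
        g_tilde=g_tilde,
        pev=pev,
        sigma2_g_hat=float(sigma2_g),
        sigma2_e_hat=float(sigma2_e),
        loglik=float(loglik),
        g_error_cov=cov,
        boundary_flag=bool(boundary),
        lambda_hat=lam,
        counts=counts,
    )


def generalized_h2(fit: BlupFit, method: str = "pairwise") -> float:
    """Trial-level generalized (broad-sense) heritability in [0, 1].

    ``pairwise`` (default) is the Cullis form based on the mean prediction
    error variance of all line differences; ``mean_pev`` is the simpler
    ``1 - mean(PEV) / sigma2_g`` variant.
    """
    if fit.sigma2_g_hat <= 0:
        raise ValueError("sigma2_g_hat must be > 0 to define heritability")
    if method == "mean_pev":
        h2 = 1.0 - float(np.mean(fit.pev)) / fit.sigma2_g_hat
    elif method == "pairwise":
        C = fit.g_error_cov
        r = C.shape[0]
        if r < 2:
            raise ValueError("need >= 2 lines")
        diag = np.diag(C)
        # mean over i<j of (PEV_i + PEV_j - 2 C_ij); note
        # sum_{i<j} (d_i + d_j) = (r-1) sum(d)
        sum_off = (C.sum() - diag.sum()) / 2.0
        n_pairs = r * (r - 1) / 2.0
        mean_pair = ((r - 1) * diag.sum() - 2.0 * sum_off) / n_pairs
        h2 = 1.0 - mean_pair / (2.0 * fit.sigma2_g_hat)
    else:
        raise ValueError(f"unknown method '{method}'")
    return float(np.clip(h2, 0.0, 1.0))


def deregress(fit: BlupFit) -> pd.DataFrame:
    """De-regress eBLUPs into adjusted yields (one row per retained line).

    Lines with PEV >= sigma2_g (reliability <= 0, the transform is
    undefined) are excluded with a logged reason rather than clamped.
    Returns a frame with columns ``line_id`` and ``adjusted_yield``.
    """
    rel = 1.0 - fit.pev / fit.sigma2_g_hat
    keep = rel > 0
    if not keep.any():
        raise ValueError("all lines have PEV >= sigma2_g; nothing to de-regress")
    n_drop = int((~keep).sum())
    if n_drop:
        dropped = [fit.line_ids[i] for i in np.where(~keep)[0]]
        logger.warning(
            "excluding %d line(s) with reliability <= 0 from de-regression: %s",
            n_drop, dropped[:10],
        )
    y = fit.mu_hat + fit.g_tilde[keep] / rel[keep]
    return pd.DataFrame(
        {"line_id": [fit.line_ids[i] for i in np.where(keep)[0]], "adjusted_yield": y}
    )
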