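"""BayesA/BayesB whole-genome regression by Gibbs sampling.

Model (per marker j):

    y = 1 mu + M q + e,      e ~ N(0, sigma2_e I)
    q_j | delta_j, sigma2_j  = 0 with probability pi (exclusion),
                               else N(0, sigma2_j)
    sigma2_j ~ scaled-inv-chi2(nu, s2_q)
    s2_q ~ Gamma(shape_s, rate)          (rate solved from an attributed R2)
    pi ~ Beta(pi0 * p0, (1 - pi0) * p0)  so E(pi) = pi0

BayesA is the special case pi = 0 (every marker carries a slab effect); it
runs through the same sampler with pi clamped at zero, so the A == B(pi=0)
equivalence holds draw-for-draw.  Marginally the slab effects are
t(0, s2_q, nu), giving the heavy-tailed shrinkage both variants share and
the spike-and-slab feature selection that distinguishes BayesB.

Conditional updates (all conjugate):

* q_j: normal with precision (m_j'm_j / sigma2_e + 1 / sigma2_j); for
  BayesB the inclusion indicator delta_j is first drawn from the marginal
  odds with q_j integrated out.
* sigma2_j: scaled-inv-chi2(nu + 1, (nu s2_q + q_j^2) / (nu + 1)) when the
  marker is in the model; refreshed from its prior when excluded.
* s2_q: the scaled-inv-chi2 likelihood is Gamma-conjugate:
  s2_q | {sigma2_j} ~ Gamma(shape_s + p nu / 2, rate + (nu / 2) sum 1/sigma2_j).
* pi: Beta updated with exclusion/inclusion counts.
* mu, sigma2_e: normal / scaled-inv-chi2 with a weakly-informative
  scaled-inv-chi2(nu_e = 5, mode = 0.5 var(y)) residual prior.

The marker sweep runs in a numba-compiled kernel; the chain is fully
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import MarkerMatrix
from ._gibbs import gibbs_sample


@dataclass
class BayesConfig:
    """Hyperparameters of the BayesA/B hierarchy.

    pi0 is the prior mean *exclusion* probability (inclusion 0.05 means
    pi0 = 0.95); nu and shape_s follow the conventions of the reference
    Gibbs implementations (nu = 4, shape 1.1, attributed R2 = 0.5).
    """

    variant: str = "B"
    pi0: float = 0.95
    p0: Optional[float] = None  # default 10 * p, set at fit time
    nu: float = 4.0
    shape_s: float = 1.1
    target_R2: float = 0.5
    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0
    nu_e: float = 5.0
    fix_pi: Optional[float] = None  # clamp pi (used for variant A and tests)

    def __post_init__(self) -> None:
        if self.variant not in ("A", "B"):
            raise ValueError("variant must be 'A' or 'B'")
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must be in [0, 1]")
        if self.nu <= 0:
            raise ValueError("nu must be > 0")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class BayesPosterior:
    """Posterior summaries over post-burn-in thinned draws."""

    marker_ids: list
    q_mean: np.ndarray
    inclusion_prob: np.ndarray
    mu_mean: float
    sigma2_e_mean: float
    s2q_mean: float
    pi_mean: float
    n_draws: int
    delta_flip_rate: float
    trace: dict = field(default_factory=dict)


def attributed_effect_variance(
    var_y: float, target_R2: float, pi0: float, msx: float
) -> float:
    """Per-marker slab variance V_q implied by an attributed R2.

    Splits target_R2 * var(y) across the expected (1 - pi0) * p included
    markers, measured in dosage-variance units: V_q = R2 var(y) /
    ((1 - pi0) * msx) with msx the summed per-marker dosage variance.
    """
    if pi0 >= 1.0:
        raise ValueError("pi0 = 1 leaves no inclusion mass; V_q undefined")
    if msx <= 0 or var_y <= 0:
        raise ValueError("need positive var(y) and marker variance")
    return target_R2 * var_y / ((1.0 - pi0) * msx)


def solve_sq_rate(m: MarkerMatrix, y: np.ndarray, cfg: BayesConfig) -> float:
    """Rate of the Gamma prior on s2_q matching the attributed R2.

    Under sigma2_j ~ scaled-inv-chi2(nu, s2_q), E[sigma2_j | s2_q] =
    nu s2_q / (nu - 2); plugging the Gamma prior mean E[s2_q] = shape / rate
    and equating to V_q gives rate = shape * nu / ((nu - 2) * V_q).
    """
    if cfg.nu <= 2:
        raise ValueError("nu must exceed 2 for the prior mean to exist")
    y = np.asarray(y, float)
    pi0 = 0.0 if cfg.variant == "A" else cfg.pi0
    msx = float(np.sum(np.var(m.dosages, axis=0, ddof=1)))
    vq = attributed_effect_variance(float(np.var(y, ddof=1)), cfg.target_R2, pi0, msx)
    return cfg.shape_s * cfg.nu / ((cfg.nu - 2.0) * vq)


def fit_bayes(m: MarkerMatrix, y: np.ndarray, cfg: BayesConfig) -> BayesPosterior:
    """Run the Gibbs sampler and return posterior summaries."""
    y = np.asarray(y, dtype=float)
    if m.has_missing:
        raise ValueError("marker matrix has missing values; impute first")
    if y.size != m.n_lines:
        raise ValueError("length(y) must equal number of lines")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite response values")

    rate = solve_sq_rate(m, y, cfg)
    var_y = float(np.var(y, ddof=1))
    # residual prior: scaled-inv-chi2(nu_e, Se) with mode 0.5 var(y);
    # mode = nu Se / (nu + 2)  =>  Se = mode (nu + 2) / nu
    Se = 0.5 * var_y * (cfg.nu_e + 2.0) / cfg.nu_e

    if cfg.variant == "A":
        pi_fix, pi0, p0 = 0.0, 0.0, 1.0
    elif cfg.fix_pi is not None:
        pi_fix, pi0 = float(cfg.fix_pi), cfg.pi0
        p0 = cfg.p0 if cfg.p0 is not None else 10.0 * m.n_markers
    else:
        pi_fix, pi0 = -1.0, cfg.pi0
        p0 = cfg.p0 if cfg.p0 is not None else 10.0 * m.n_markers

    X = np.ascontiguousarray(m.dosages, dtype=np.float64)
    out = gibbs_sample(
        X, y, pi_fix, pi0, p0, cfg.nu, cfg.shape_s, rate, cfg.nu_e, Se,
        cfg.n_iter, cfg.burn_in, cfg.thin, cfg.seed,
    )
    q_mean, incl, mu_mean, s2e_mean, s2q_mean, pi_mean, flips, tr_mu, tr_s2e, tr_s2q, tr_pi = out
    return BayesPosterior(
        marker_ids=list(m.marker_ids),
        q_mean=q_mean,
        inclusion_prob=incl,
        mu_mean=float(mu_mean),
        sigma2_e_mean=float(s2e_mean),
        s2q_mean=float(s2q_mean),
        pi_mean=float(pi_mean),
        n_draws=(cfg.n_iter - cfg.burn_in) // cfg.thin,
        delta_flip_rate=float(flips),
        trace={"mu": tr_mu, "sigma2_e": tr_s2e, "s2_q": tr_s2q, "pi": tr_pi},
    )


def bayes_predict(post: BayesPosterior, m_new: MarkerMatrix) -> np.ndarray:
    """Posterior-mean prediction: y_hat = mu_mean + M_new q_mean."""
    if list(m_new.marker_ids) != post.marker_ids:
        for a, b in zip(m_new.marker_ids, post.marker_ids):
            if a != b:
                raise ValueError(f"marker mismatch: '{a}' vs trained '{b}'")
        raise ValueError(
            f"marker count mismatch: {m_new.n_markers} vs {len(post.marker_ids)}"
        )
    return post.mu_mean + m_new.dosages @ post.q_mean
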