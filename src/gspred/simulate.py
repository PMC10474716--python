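"""Synthetic breeding-trial data generator.

Emulates the statistical structure the prediction methods assume:

* biallelic marker dosages with chromosome/LD-block structure, generated
  from a Gaussian threshold copula with AR1 correlation along each
  chromosome (chromosomes independent);
* a sparse additive trait architecture with the narrow-sense heritability
  imposed *exactly* on the realized sample (noise is orthogonalised against
  the genetic values before scaling, so var(phenotype) = var(g) + sigma2_e
  holds to machine precision);
* partially-replicated field-trial layouts (e.g. 1.25 plots per line on
  average) with a separable AR1 x AR1 spatial residual process plus an iid
  nugget on a row x range grid.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import CODING_012, MarkerMatrix, PlotTable


@dataclass
class TraitArchitecture:
    """Ground-truth sparse additive architecture of a simulated trait."""

    causal_indices: np.ndarray  # marker indices, strictly increasing
    effects: np.ndarray         # trait units per dosage unit
    h2_target: float
    genetic_values: np.ndarray  # per-line true additive value

    def __post_init__(self) -> None:
        self.causal_indices = np.asarray(self.causal_indices, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.causal_indices.size != self.effects.size:
            raise ValueError("causal_indices and effects must have equal length")


@dataclass
class FieldTrialConfig:
    """Layout and residual structure of a partially-replicated yield trial.

    Defaults describe a realistic small-plot wheat trial: grand mean 4 t/ha,
    1.25x partial replication, moderate spatial trend (rho = 0.5 both ways)
    and a nugget of similar size to the spatial component.
    """

    n_rows: int = 40
    n_ranges: int = 40
    replication_factor: float = 1.25
    rho_row: float = 0.5
    rho_range: float = 0.5
    sigma2_spatial: float = 0.2
    sigma2_nugget: float = 0.4
    grand_mean: float = 4.0

    def __post_init__(self) -> None:
        if not (abs(self.rho_row) < 1 and abs(self.rho_range) < 1):
            raise ValueError("AR1 correlations must lie in (-1, 1)")
        if self.sigma2_spatial < 0 or self.sigma2_nugget < 0:
            raise ValueError("variance components must be >= 0")


def _split_markers(n_markers: int, n_chromosomes: int) -> np.ndarray:
    base = n_markers // n_chromosomes
    sizes = np.full(n_chromosomes, base, dtype=int)
    sizes[: n_markers - base * n_chromosomes] += 1
    return sizes


def simulate_genotypes(
    n_lines: int,
    n_markers: int,
    n_chromosomes: int = 21,
    ld_rho: float = 0.6,
    maf_range: Tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> MarkerMatrix:
    """Draw 0/1/2 dosages from an AR1 Gaussian copula within chromosomes.

    Each line carries two independent haplotypes; within a chromosome the
    latent Gaussians follow an AR1(``ld_rho``) process across adjacent
    markers, and the minor-allele indicator is obtained by thresholding at
    the quantile of a per-marker MAF drawn uniformly in ``maf_range``.
    """
    lo, hi = maf_range
    if not (0 <= ld_rho < 1):
        raise ValueError("ld_rho must be in [0, 1)")
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if n_markers < n_chromosomes:
        raise ValueError("need at least one marker per chromosome")
    rng = np.random.default_rng(seed)
    sizes = _split_markers(n_markers, n_chromosomes)
    dosage_blocks, chroms, positions = [], [], []
    for c, m in enumerate(sizes):
        maf = rng.uniform(lo, hi, size=m)
        thresh = norm.ppf(maf)
        alleles = np.zeros((n_lines, m))
        for _hap in range(2):
            z = np.empty((n_lines, m))
            z[:, 0] = rng.standard_normal(n_lines)
            if m > 1:
                eps = rng.standard_normal((n_lines, m - 1))
                w = np.sqrt(1.0 - ld_rho**2)
                for j in range(1, m):
                    z[:, j] = ld_rho * z[:, j - 1] + w * eps[:, j - 1]
            alleles += (z < thresh).astype(float)
        dosage_blocks.append(alleles)
        chroms.extend([str(c + 1)] * m)
        positions.extend(((np.arange(m) + 1) * 1_000_000).tolist())
    dosages = np.hstack(dosage_blocks)
    line_ids = [f"L{i + 1:05d}" for i in range(n_lines)]
    marker_ids = [f"M{j + 1:05d}" for j in range(n_markers)]
    gmap = pd.DataFrame({"chrom": chroms, "pos": positions})
    return MarkerMatrix(line_ids, marker_ids, dosages, map=gmap, coding=CODING_012)


def simulate_trait(
    m: MarkerMatrix,
    n_qtl: int,
    h2_target: float,
    effect_dist: str = "gaussian",
    seed: int = 0,
    grand_mean: float = 4.0,
    noise_var_null: float = 1.0,
    sd_total: Optional[float] = None,
) -> Tuple[TraitArchitecture, np.ndarray]:
    """Plant a sparse additive architecture and return line phenotypes.

    The heritability is imposed exactly on the realized sample: the drawn
    noise vector is orthogonalised against ``[1, g]`` and rescaled so that
    var(g) / (var(g) + var(noise)) equals ``h2_target``.  With ``n_qtl=0``
    the trait is pure noise with variance ``noise_var_null``.

    ``sd_total`` rescales effects, genetic values and noise by a common
    factor so the phenotypic standard deviation hits a realistic value
    (e.g. 0.5 t/ha around a 4 t/ha grand mean); h2 is unaffected.
    """
    p = m.n_markers
    if n_qtl > p:
        raise ValueError(f"n_qtl={n_qtl} exceeds number of markers {p}")
    if n_qtl > 0 and not (0 < h2_target <= 1):
        raise ValueError("h2_target must be in (0, 1] when n_qtl > 0")
    rng = np.random.default_rng(seed)
    r = m.n_lines

    if n_qtl == 0:
        noise = rng.standard_normal(r) * np.sqrt(noise_var_null)
        arch = TraitArchitecture(np.empty(0, int), np.empty(0), 0.0, np.zeros(r))
        return arch, grand_mean + noise

    causal = np.sort(rng.choice(p, size=n_qtl, replace=False))
    if effect_dist == "gaussian":
        effects = rng.standard_normal(n_qtl)
    elif effect_dist == "laplace":
        effects = rng.laplace(0.0, 1.0 / np.sqrt(2.0), size=n_qtl)
    else:
        raise ValueError(f"unknown effect_dist '{effect_dist}'")
    g = m.dosages[:, causal] @ effects
    var_g = g.var(ddof=1)
    if var_g <= 0:
        raise ValueError("degenerate architecture: genetic values have zero variance")

    if h2_target == 1.0:
        noise = np.zeros(r)
    else:
        noise = rng.standard_normal(r)
        # orthogonalise against [1, g] so variances add exactly
        basis = np.column_stack([np.ones(r), g])
        coef, *_ = np.linalg.lstsq(basis, noise, rcond=None)
        noise = noise - basis @ coef
        target = var_g * (1.0 - h2_target) / h2_target
        noise *= np.sqrt(target / noise.var(ddof=1))
    if sd_total is not None:
        c = sd_total / np.sqrt(g.var(ddof=1) + noise.var(ddof=1))
        effects, g, noise = effects * c, g * c, noise * c
    arch = TraitArchitecture(causal, effects, h2_target, g)
    return arch, grand_mean + g + noise


def perturb_architecture(
    arch: TraitArchitecture,
    m: MarkerMatrix,
    perturb_fraction: float = 0.2,
    seed: int = 0,
) -> TraitArchitecture:
    """Resample a fraction of effect variance, emulating a new trial year.

    The same causal markers are kept; each effect becomes
    ``sqrt(1-f) * old + sqrt(f) * fresh`` so the year-to-year genetic
    correlation is about ``sqrt(1-f)``.
    """
    f = perturb_fraction
    if not (0 <= f <= 1):
        raise ValueError("perturb_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sd = arch.effects.std(ddof=1) if arch.effects.size > 1 else 1.0
    fresh = rng.standard_normal(arch.effects.size) * sd
    eff = np.sqrt(1 - f) * arch.effects + np.sqrt(f) * fresh
    g = m.dosages[:, arch.causal_indices] @ eff
    return TraitArchitecture(arch.causal_indices.copy(), eff, arch.h2_target, g)


def second_year_phenotypes(
    arch: TraitArchitecture,
    m: MarkerMatrix,
    h2_target: float = 0.5,
    perturb_fraction: float = 0.2,
    seed: int = 1,
    grand_mean: float = 4.0,
) -> Tuple[TraitArchitecture, np.ndarray]:
    """Second trait realization: perturbed effects plus fresh noise.

    Keeps the first year's trait scale (effects were already scaled there).
    """
    arch2 = perturb_architecture(arch, m, perturb_fraction, seed)
    rng = np.random.default_rng(seed + 1)
    r = m.n_lines
    g = arch2.genetic_values
    noise = rng.standard_normal(r)
    basis = np.column_stack([np.ones(r), g])
    coef, *_ = np.linalg.lstsq(basis, noise, rcond=None)
    noise = noise - basis @ coef
    var_g = g.var(ddof=1)
    noise *= np.sqrt(var_g * (1 - h2_target) / h2_target / noise.var(ddof=1))
    return arch2, grand_mean + g + noise


def _ar1_chol(n: int, rho: float) -> np.ndarray:
    """Cholesky factor of the AR1(rho) correlation matrix (closed form).

    L[i, 0] = rho^i and L[i, j] = sqrt(1 - rho^2) * rho^(i-j) for 0 < j <= i.
    """
    L = np.zeros((n, n))
    L[:, 0] = rho ** np.arange(n)
    w = np.sqrt(1.0 - rho**2)
    for j in range(1, n):
        L[j:, j] = w * rho ** np.arange(n - j)
    return L


def spatial_field(
    n_rows: int, n_ranges: int, rho_row: float, rho_range: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance separable AR1(row) x AR1(range) Gaussian field.

    Computed as ``L_row @ Z @ L_range.T`` where L are AR1 Cholesky factors;
    flattening row-major gives covariance AR1_row (kron) AR1_range.
    """
    Lr = _ar1_chol(n_rows, rho_row)
    Lc = _ar1_chol(n_ranges, rho_range)
    Z = rng.standard_normal((n_rows, n_ranges))
    return Lr @ Z @ Lc.T


def simulate_field_trial(
    line_ids,
    genetic_values: np.ndarray,
    cfg: FieldTrialConfig,
    seed: int = 0,
) -> PlotTable:
    """Lay a p-rep trial on the grid and draw spatially-correlated yields.

    A random subset of lines is duplicated so the total plot count is about
    ``replication_factor * n_lines``; plots land on random distinct grid
    cells; plot yield = grand_mean + g_line + spatial + nugget.
    """
    rng = np.random.default_rng(seed)
    line_ids = [str(x) for x in line_ids]
    g = np.asarray(genetic_values, dtype=float)
    r = len(line_ids)
    n_extra = int(round((cfg.replication_factor - 1.0) * r))
    if n_extra < 0 or n_extra > r:
        raise ValueError("replication_factor must be in [1, 2] for single duplication")
    n_plots = r + n_extra
    n_cells = cfg.n_rows * cfg.n_ranges
    if n_plots > n_cells:
        raise ValueError(
            f"grid {cfg.n_rows}x{cfg.n_ranges} too small for {n_plots} plots"
        )
    dup = rng.choice(r, size=n_extra, replace=False)
    plot_line = np.concatenate([np.arange(r), dup])
    cells = rng.permutation(n_cells)[:n_plots]
    rows, ranges = cells // cfg.n_ranges, cells % cfg.n_ranges

    F = spatial_field(cfg.n_rows, cfg.n_ranges, cfg.rho_row, cfg.rho_range, rng)
    spatial = np.sqrt(cfg.sigma2_spatial) * F[rows, ranges]
    nugget = np.sqrt(cfg.sigma2_nugget) * rng.standard_normal(n_plots)
    y = cfg.grand_mean + g[plot_line] + spatial + nugget

    df = pd.DataFrame(
        {
            "plot_id": [f"P{i + 1:05d}" for i in range(n_plots)],
            "line_id": [line_ids[i] for i in plot_line],
            "row": rows,
            "range": ranges,
            "yield": y,
        }
    )
    meta = {
        "replication_factor": cfg.replication_factor,
        "grand_mean": cfg.grand_mean,
        "rho_row": cfg.rho_row,
        "rho_range": cfg.rho_range,
        "sigma2_spatial": cfg.sigma2_spatial,
        "sigma2_nugget": cfg.sigma2_nugget,
        "seed": seed,
    }
    return PlotTable(df, meta)
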