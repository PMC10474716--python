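"""Accuracy metrics, cross-validation splits, and the benchmark harness.

Accuracy follows the two-metric convention for genomic prediction with
regularised methods: Pearson correlation between observed and predicted
values, and the relative error

    RE = (1/n) sum_i |y_i - y_hat_i| / y_i,

a scale-aware mean proportional difference (observed values must be
positive; adjusted yields are).  RE is kept as a proportion internally and
rendered as a percentage only in reports.

The validation protocol is four independent random 90/10 train/validation
partitions (each split its own draw, not a rotation of one 10-fold).
``run_benchmark`` trains each requested method on each split's training
set, evaluates on the held-out lines, and collects everything into an
:class:`EvalReport`; per-method seeds are derived from the master seed by
stable hashing so adding a method never shifts another method's stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .data import MarkerMatrix
from .optim import stable_seed

KNOWN_METHODS = ("gblup", "bayesA", "bayesB", "naive_ml", "vbs_ml")


def relative_error(y_obs, y_pred) -> float:
    """Mean proportional absolute error; requires positive observations."""
    y_obs = np.asarray(y_obs, float)
    y_pred = np.asarray(y_pred, float)
    if y_obs.size == 0 or y_obs.size != y_pred.size:
        raise ValueError("y_obs and y_pred must be nonempty and equal-length")
    if np.any(y_obs <= 0):
        raise ValueError(
            "relative error divides by the observed value; exclude non-positive "
            "observations upstream"
        )
    return float(np.mean(np.abs(y_obs - y_pred) / y_obs))


def pearson(y_obs, y_pred) -> float:
    """Sample Pearson correlation; errors on constant input (undefined)."""
    y_obs = np.asarray(y_obs, float)
    y_pred = np.asarray(y_pred, float)
    if y_obs.size != y_pred.size or y_obs.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(y_obs) == 0 or np.ptp(y_pred) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    a = y_obs - y_obs.mean()
    b = y_pred - y_pred.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


@dataclass
class SplitPlan:
    """Independent random train/validation partitions."""

    n: int
    n_splits: int
    train_fraction: float
    seed: int
    train_sets: List[np.ndarray] = field(default_factory=list)
    val_sets: List[np.ndarray] = field(default_factory=list)


def make_splits(n: int, n_splits: int = 4, train_fraction: float = 0.9,
                seed: int = 0) -> SplitPlan:
    """Draw ``n_splits`` independent random train/validation partitions."""
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n))
    plan = SplitPlan(n, n_splits, train_fraction, seed)
    for _ in range(n_splits):
        perm = rng.permutation(n)
        plan.train_sets.append(np.sort(perm[:n_train]))
        plan.val_sets.append(np.sort(perm[n_train:]))
    return plan


@dataclass
class EvalReport:
    """Per method x split accuracy cells plus aggregate means."""

    cells: List[dict]
    seed: int
    config_digest: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells)

    def aggregate(self) -> pd.DataFrame:
        df = self.to_frame()
        ok = df[df["error"].isna()] if "error" in df else df
        return (
            ok.groupby("method", sort=True)[["re", "pearson"]]
            .mean(numeric_only=True)
            .reset_index()
        )

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed,
            "config_digest": self.config_digest,
            "cells": self.cells,
            "aggregate": self.aggregate().to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def _fit_predict(method: str, M: MarkerMatrix, y: np.ndarray,
                 train: np.ndarray, val: np.ndarray, cfg, seed: int):
    """Train one method on the split's training lines; predict validation."""
    from . import bayes as bayes_mod
    from . import gblup as gblup_mod
    from . import vbsml as vbsml_mod

    info: Dict[str, object] = {}
    if method == "gblup":
        G = gblup_mod.build_grm(M)
        Gtr = gblup_mod.GRM(G.matrix[np.ix_(train, train)], G.scale_s,
                            [G.line_ids[i] for i in train])
        var = gblup_mod.reml_two_vc(y[train], Gtr)
        _, _, y_all = gblup_mod.gblup_predict(y[train], G, train, var)
        info["sigma2_a"] = var.sigma2_a
        info["sigma2_e"] = var.sigma2_e
        return y_all[val], info
    if method in ("bayesA", "bayesB"):
        base = cfg or bayes_mod.BayesConfig()
        bcfg = bayes_mod.BayesConfig(
            variant="A" if method == "bayesA" else "B",
            pi0=base.pi0, p0=base.p0, nu=base.nu, shape_s=base.shape_s,
            target_R2=base.target_R2, n_iter=base.n_iter, burn_in=base.burn_in,
            thin=base.thin, seed=seed, nu_e=base.nu_e,
        )
        post = bayes_mod.fit_bayes(M.subset_lines(train), y[train], bcfg)
        pred = bayes_mod.bayes_predict(post, M.subset_lines(val))
        return pred, info
    if method in ("naive_ml", "vbs_ml"):
        spec, tcfg = cfg if cfg is not None else (None, None)
        spec = spec or vbsml_mod.NetworkSpec()
        base = tcfg or vbsml_mod.VBSTrainConfig()
        tcfg = vbsml_mod.VBSTrainConfig(**{**_cfg_dict(base), "seed": seed})
        trainer = (vbsml_mod.train_vbs if method == "vbs_ml"
                   else vbsml_mod.train_naive)
        model = trainer(M.subset_lines(train), y[train], spec, tcfg)
        if method == "vbs_ml":
            sel = model.selected
            info["n_selected"] = sel.n_selected
            info["selected_indices"] = sel.indices
        pred = vbsml_mod.predict(model, M.subset_lines(val))
        return np.asarray(pred, float), info
    raise ValueError(f"unknown method '{method}'")


def _cfg_dict(cfg) -> dict:
    from dataclasses import asdict

    return asdict(cfg)


def run_benchmark(
    M: MarkerMatrix,
    y: np.ndarray,
    methods: Sequence[str],
    plan: SplitPlan,
    configs: Optional[dict] = None,
    master_seed: int = 0,
    oracle: Optional[np.ndarray] = None,
) -> EvalReport:
    """Benchmark the requested methods over every split of the plan.

    ``configs`` maps method name to its config object (BayesConfig, or a
    (NetworkSpec, VBSTrainConfig) pair for the ML methods).  A method
    failure on one split is recorded in that cell; the report is still
    produced.  ``oracle`` injects a fixed prediction vector (harness
    sanity checks).
    """
    if not methods:
        raise ValueError("methods must be nonempty")
    configs = configs or {}
    y = np.asarray(y, float)
    cells = []
    for method in methods:
        if method not in KNOWN_METHODS and method != "oracle" and method != "train_mean":
            raise ValueError(f"unknown method '{method}'")
        for k in range(plan.n_splits):
            train, val = plan.train_sets[k], plan.val_sets[k]
            seed = stable_seed(method, k, master_seed)
            cell = {"method": method, "split": k, "seed": seed,
                    "re": None, "pearson": None, "n_selected": None,
                    "error": None}
            try:
                if method == "oracle":
                    pred = (oracle if oracle is not None else y)[val]
                elif method == "train_mean":
                    pred = np.full(val.size, y[train].mean())
                else:
                    pred, info = _fit_predict(method, M, y, train, val,
                                              configs.get(method), seed)
                    if "n_selected" in info:
                        cell["n_selected"] = info["n_selected"]
                        cell["selected_indices"] = info["selected_indices"]
                cell["re"] = relative_error(y[val], pred)
                try:
                    cell["pearson"] = pearson(y[val], pred)
                except ValueError as exc:
                    cell["error"] = f"pearson: {exc}"
            except Exception as exc:  # per-cell failure, report survives
                cell["error"] = f"{type(exc).__name__}: {exc}"
            cells.append(cell)
    return EvalReport(cells=cells, seed=master_seed)
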