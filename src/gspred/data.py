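"""Core data containers and file I/O for marker and phenotype data.

The central object is :class:`MarkerMatrix`, an ``r`` lines x ``p`` markers
allele-dosage matrix.  Two plain-text dialects are supported:

``csv``
    header row of marker IDs, first column line IDs, ``NA`` for missing.
``plink_raw``
    the PLINK ``.raw`` additive-dosage export: whitespace-delimited with six
    leading columns (FID IID PAT MAT SEX PHENOTYPE) followed by one column
    per marker, ``NA`` for missing.

Missing dosages are held as NaN internally and written back as ``NA``.
Dosage coding (0/1/2 vs -1/0/1) is auto-detected on read and carried on the
object; nothing is ever silently recoded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CODING_012 = "zero_one_two"
CODING_M11 = "minus_one_one"

_PLINK_LEAD = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class MarkerMatrix:
    """Lines x markers allele-dosage matrix with optional genetic map.

    Parameters
    ----------
    line_ids, marker_ids
        Ordered, unique identifiers.
    dosages
        ``(r, p)`` float array; NaN marks a missing call.
    map
        Optional per-marker frame with columns ``chrom`` and ``pos`` (bp).
    coding
        Dosage convention, one of ``zero_one_two`` / ``minus_one_one``.
    """

    line_ids: list
    marker_ids: list
    dosages: np.ndarray
    map: Optional[pd.DataFrame] = None
    coding: str = CODING_012

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        self.dosages = np.asarray(self.dosages, dtype=float)
        r, p = self.dosages.shape
        if r < 2 or p < 1:
            raise ValueError(f"need r >= 2 lines and p >= 1 markers, got {r}x{p}")
        _check_unique(self.line_ids, "line ID")
        _check_unique(self.marker_ids, "marker ID")
        if len(self.line_ids) != r or len(self.marker_ids) != p:
            raise ValueError("ID lengths do not match dosage matrix shape")
        if self.map is not None and len(self.map) != p:
            raise ValueError("map length must equal number of markers")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def subset_lines(self, index: Sequence[int]) -> "MarkerMatrix":
        index = np.asarray(index)
        return MarkerMatrix(
            [self.line_ids[i] for i in index],
            list(self.marker_ids),
            self.dosages[index],
            self.map,
            self.coding,
        )

    def subset_markers(self, index: Sequence[int]) -> "MarkerMatrix":
        index = np.asarray(index)
        m = self.map.iloc[index].reset_index(drop=True) if self.map is not None else None
        return MarkerMatrix(
            list(self.line_ids),
            [self.marker_ids[i] for i in index],
            self.dosages[:, index],
            m,
            self.coding,
        )


@dataclass
class PlotTable:
    """Plot-level field-trial records (one row per yield plot).

    ``df`` columns: plot_id, line_id, row, range, yield.  Row/range are
    0-based integer grid indices internally; user-facing output is 1-based.
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["plot_id", "line_id", "row", "range", "yield"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"plot table missing columns: {missing}")
        pos = list(zip(self.df["row"], self.df["range"]))
        if len(set(pos)) != len(pos):
            raise ValueError("duplicate (row, range) grid positions")
        y = self.df["yield"].to_numpy(float)
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite yield values")

    @property
    def n_plots(self) -> int:
        return len(self.df)

    @property
    def line_ids(self) -> list:
        return sorted(self.df["line_id"].astype(str).unique().tolist())


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} '{x}'")
        seen.add(x)


def detect_coding(values: np.ndarray) -> str:
    """Classify the dosage convention from the observed value set."""
    finite = values[np.isfinite(values)]
    if finite.size and finite.min() < 0:
        return CODING_M11
    return CODING_012


# ---------------------------------------------------------------------------
# marker I/O


def read_markers(path, format: str = "csv") -> MarkerMatrix:
    """Read a marker dosage matrix from ``csv`` or ``plink_raw`` text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"marker file not found: {path}")
    if path.stat().st_size == 0:
        raise ValueError(f"empty marker file: {path}")
    if format == "csv":
        return _read_markers_csv(path)
    if format == "plink_raw":
        return _read_markers_raw(path)
    raise ValueError(f"unknown marker format '{format}'")


def _read_markers_csv(path: Path) -> MarkerMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        marker_ids = header[1:]
        ncol = len(header)
        line_ids, rows = [], []
        for lineno, raw in enumerate(fh, start=2):
            parts = raw.rstrip("\n").split(",")
            if len(parts) != ncol:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(parts)} fields, expected {ncol})"
                )
            line_ids.append(parts[0])
            rows.append([math.nan if v == "NA" else float(v) for v in parts[1:]])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    dosages = np.array(rows, dtype=float)
    return MarkerMatrix(line_ids, marker_ids, dosages, coding=detect_coding(dosages))


def _read_markers_raw(path: Path) -> MarkerMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if header[: len(_PLINK_LEAD)] != _PLINK_LEAD:
            raise ValueError(f"{path}: not a PLINK .raw header")
        marker_ids = header[len(_PLINK_LEAD):]
        ncol = len(header)
        line_ids, rows = [], []
        for lineno, raw in enumerate(fh, start=2):
            parts = raw.split()
            if not parts:
                continue
            if len(parts) != ncol:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(parts)} fields, expected {ncol})"
                )
            line_ids.append(parts[1])  # IID
            rows.append(
                [math.nan if v == "NA" else float(v) for v in parts[len(_PLINK_LEAD):]]
            )
    if not rows:
        raise ValueError(f"{path}: no data rows")
    dosages = np.array(rows, dtype=float)
    return MarkerMatrix(line_ids, marker_ids, dosages, coding=detect_coding(dosages))


def _fmt(v: float) -> str:
    if math.isnan(v):
        return "NA"
    if v == int(v):
        return str(int(v))
    return repr(v)


def write_markers(m: MarkerMatrix, path, format: str = "csv") -> None:
    """Write a marker matrix; round-trips byte-identically through read."""
    path = Path(path)
    with open(path, "w") as fh:
        if format == "csv":
            fh.write("line_id," + ",".join(m.marker_ids) + "\n")
            for lid, row in zip(m.line_ids, m.dosages):
                fh.write(lid + "," + ",".join(_fmt(v) for v in row) + "\n")
        elif format == "plink_raw":
            fh.write(" ".join(_PLINK_LEAD + list(m.marker_ids)) + "\n")
            for lid, row in zip(m.line_ids, m.dosages):
                lead = [lid, lid, "0", "0", "0", "-9"]
                fh.write(" ".join(lead + [_fmt(v) for v in row]) + "\n")
        else:
            raise ValueError(f"unknown marker format '{format}'")


# ---------------------------------------------------------------------------
# phenotype I/O


def read_plots(path) -> PlotTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"plot file not found: {path}")
    df = pd.read_csv(path)
    df["line_id"] = df["line_id"].astype(str)
    return PlotTable(df)


def write_plots(plots: PlotTable, path) -> None:
    plots.df.to_csv(path, index=False)


def read_adjusted(path) -> pd.DataFrame:
    """Read an adjusted-yield table (columns line_id, adjusted_yield)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"adjusted-yield file not found: {path}")
    df = pd.read_csv(path)
    if not {"line_id", "adjusted_yield"}.issubset(df.columns):
        raise ValueError(f"{path}: need columns line_id, adjusted_yield")
    df["line_id"] = df["line_id"].astype(str)
    if df["line_id"].duplicated().any():
        dup = df["line_id"][df["line_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate line ID '{dup}' in adjusted-yield table")
    if not np.all(np.isfinite(df["adjusted_yield"].to_numpy(float))):
        raise ValueError("non-finite adjusted yields")
    return df


def write_adjusted(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# k-NN imputation


def knn_impute(m: MarkerMatrix, k: int) -> MarkerMatrix:
    """Fill missing dosages from the ``k`` nearest lines.

    Nearness is the root-mean-square dosage difference over markers observed
    in both lines (a scale-free Euclidean distance, robust to unequal
    numbers of shared markers).  For 0/1/2-coded data the imputed value is
    the mode among the neighbours that carry a call at that marker; for
    other codings it is their mean.  Non-missing cells are never touched.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if k >= m.n_lines:
        raise ValueError(f"k={k} must be smaller than the number of lines ({m.n_lines})")
    X = m.dosages
    if not np.isnan(X).any():
        return m

    obs = ~np.isnan(X)
    if not obs.any(axis=0).all():
        j = int(np.where(~obs.any(axis=0))[0][0])
        raise ValueError(f"marker '{m.marker_ids[j]}' is missing in every line")

    Xz = np.where(obs, X, 0.0)
    # pairwise sum of squared differences over mutually observed markers
    shared = obs.astype(float) @ obs.T.astype(float)
    sq = (Xz**2) @ obs.T.astype(float)
    cross = Xz @ Xz.T
    ssd = sq + sq.T - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.maximum(ssd, 0.0) / shared)
    dist[shared == 0] = np.inf

    out = X.copy()
    use_mode = m.coding == CODING_012
    r = m.n_lines
    for i in range(r):
        miss_j = np.where(np.isnan(X[i]))[0]
        if miss_j.size == 0:
            continue
        d = dist[i].copy()
        d[i] = np.inf
        order = np.argsort(d, kind="stable")
        for j in miss_j:
            donors = order[obs[order, j]][:k]
            vals = X[donors, j]
            if vals.size == 0:
                raise ValueError(
                    f"no donor line observed at marker '{m.marker_ids[j]}' "
                    f"within reach of line '{m.line_ids[i]}'"
                )
            if use_mode:
                uniq, counts = np.unique(vals, return_counts=True)
                out[i, j] = uniq[np.argmax(counts)]  # ties -> smallest dosage
            else:
                out[i, j] = vals.mean()
    return MarkerMatrix(m.line_ids, m.marker_ids, out, m.map, m.coding)
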