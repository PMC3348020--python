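"""Correlation and exhaustive best-subset multiple regression.

The analysis relates per-mutant feature values X to an experimental response
Y in three steps:

1. single-property screening with the Pearson product-moment correlation r;
2. ordinary least squares over a chosen property subset, scored by the
   multiple correlation coefficient R = corr(observed, fitted), reported in
   [0, 1];
3. exhaustive search over *all* subsets of a given size range (the original
   protocol combines three to five of 49 properties), keeping the highest R.

With a handful of observations and ~2e5-2e6 candidate models, selection
effects are severe.  The defaults are therefore honest: a fit is refused when
N < p + 2 unless ``allow_saturated=True``, every report carries (N, p) and
the enumerated search-space size, and no multiple-testing correction is
applied (none exists in the original protocol) -- the numbers let the user
judge.

Implementation note: the search enumerates subsets explicitly (no heuristic
pruning) but solves the normal equations in vectorized batches from one
precomputed Gram matrix, so the full C(49,5) ~ 1.9M-model search runs in
seconds on one CPU.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .errors import (
    CollinearityError,
    InsufficientDataError,
    SearchSpaceError,
    UndefinedStatisticError,
)
from .features import FeatureMatrix

_EPS = 1e-12


# ---------------------------------------------------------------------------
# result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    """Signed Pearson correlation of one feature column with the response."""

    column_id: str
    r: float
    n: int


@dataclass(frozen=True)
class SubsetRegressionResult:
    """An OLS fit of the response on one property subset.

    ``coefficients`` holds the intercept first, then one slope per column in
    ``column_ids`` order.  ``R`` is the multiple correlation coefficient,
    corr(observed, fitted), reported non-negative; for a single column it
    equals |r| of that column.
    """

    column_ids: tuple[str, ...]
    coefficients: np.ndarray
    R: float
    fitted: np.ndarray
    n: int

    @property
    def size(self) -> int:
        return len(self.column_ids)

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[1:]

    def to_dict(self) -> dict:
        return {
            "columns": list(self.column_ids),
            "intercept": self.intercept,
            "slopes": [float(s) for s in self.slopes],
            "R": float(self.R),
            "N": self.n,
        }


@dataclass
class SearchReport:
    """Ranked outcome of an exhaustive subset search.

    ``results`` is best-first: R descending, ties broken by smaller subset,
    then lexicographic column ids.  ``n_models`` is the exact number of
    subsets enumerated (sum of binomial coefficients); ``skipped_columns``
    lists constant columns that were excluded before enumeration.
    """

    results: list[SubsetRegressionResult]
    n_models: int
    sizes: tuple[int, ...]
    n_columns: int
    n_observations: int
    skipped_columns: list[str] = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    @property
    def best(self) -> SubsetRegressionResult:
        return self.results[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, res in enumerate(self.results, start=1):
            rows.append(
                {
                    "rank": rank,
                    "columns": "+".join(res.column_ids),
                    "size": res.size,
                    "R": res.R,
                    "intercept": res.intercept,
                    "slopes": ",".join(f"{s:.10g}" for s in res.slopes),
                    "N": res.n,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_json(self, path: str | PathLike) -> None:
        payload = {
            "n_models": self.n_models,
            "sizes": list(self.sizes),
            "n_columns": self.n_columns,
            "n_observations": self.n_observations,
            "skipped_columns": self.skipped_columns,
            "settings": self.settings,
            "results": [r.to_dict() for r in self.results],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def _as_matrix(features) -> pd.DataFrame:
    if isinstance(features, FeatureMatrix):
        return features.frame
    if isinstance(features, pd.DataFrame):
        return features
    raise TypeError("features must be a FeatureMatrix or DataFrame")


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Requires N >= 3 and non-constant vectors; a constant vector makes the
    correlation undefined (zero denominator) and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise UndefinedStatisticError(f"need N >= 3 for a correlation, got N = {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    return float(scipy.stats.pearsonr(x, y).statistic)


def correlate_all(features, y) -> tuple[list[CorrelationResult], list[str]]:
    """Correlate every feature column with the response.

    Returns (results sorted by |r| descending, ids of skipped constant
    columns).  Constant columns are reported, never silently dropped.
    """
    frame = _as_matrix(features)
    y = np.asarray(y, dtype=float)
    results: list[CorrelationResult] = []
    skipped: list[str] = []
    for col in frame.columns:
        xv = frame[col].to_numpy(dtype=float)
        if np.ptp(xv) == 0:
            skipped.append(str(col))
            continue
        results.append(CorrelationResult(column_id=str(col), r=pearson_r(xv, y), n=y.size))
    results.sort(key=lambda c: (-abs(c.r), c.column_id))
    return results, skipped


# ---------------------------------------------------------------------------
# multiple regression
# ---------------------------------------------------------------------------

def _check_sample_size(n: int, p: int, allow_saturated: bool) -> None:
    if n < p + 2 and not allow_saturated:
        raise InsufficientDataError(
            f"refusing a saturated fit: N = {n} observations for p = {p} columns "
            f"(need N >= p + 2); pass allow_saturated=True to override"
        )


def _dependent_columns(X: np.ndarray, column_ids: Sequence[str]) -> list[str]:
    """Name columns that are linearly dependent on earlier ones (QR with pivoting)."""
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * _EPS * (diag.max() if diag.size else 1.0)
    rank = int((diag > tol).sum())
    return [str(column_ids[j]) for j in sorted(piv[rank:])]


def fit_multiple_regression(
    features, y, column_ids: Sequence[str] | None = None, allow_saturated: bool = False
) -> SubsetRegressionResult:
    """Ordinary least squares of y on the given columns, with intercept.

    R is the Pearson correlation between fitted and observed responses,
    reported non-negative (for OLS with intercept this equals sqrt(R^2)).
    Refuses N < p + 2 unless ``allow_saturated``; rank-deficient designs
    raise :class:`CollinearityError` naming the dependent columns.
    """
    frame = _as_matrix(features)
    if column_ids is not None:
        frame = frame.loc[:, list(column_ids)]
    y = np.asarray(y, dtype=float)
    X = frame.to_numpy(dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"response length {len(y)} != row count {n}")
    _check_sample_size(n, p, allow_saturated)
    Xa = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xa) < p + 1:
        dep = _dependent_columns(Xa, ["<intercept>"] + [str(c) for c in frame.columns])
        raise CollinearityError(
            f"design matrix is rank deficient; dependent column(s): {', '.join(dep)}",
            columns=dep,
        )
    beta, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    fitted = Xa @ beta
    if np.ptp(fitted) <= _EPS * max(1.0, np.abs(fitted).max()) or np.ptp(y) == 0:
        R = 0.0
    else:
        R = abs(pearson_r(fitted, y))
    return SubsetRegressionResult(
        column_ids=tuple(str(c) for c in frame.columns),
        coefficients=beta,
        R=float(min(R, 1.0)),
        fitted=fitted,
        n=n,
    )


def predict(model: SubsetRegressionResult, features) -> np.ndarray:
    """Apply a fitted model: intercept + sum(coefficient * feature) per row."""
    frame = _as_matrix(features)
    missing = [c for c in model.column_ids if c not in frame.columns]
    if missing:
        raise KeyError(f"feature matrix lacks model column(s): {', '.join(missing)}")
    X = frame.loc[:, list(model.column_ids)].to_numpy(dtype=float)
    return model.intercept + X @ model.slopes


# ---------------------------------------------------------------------------
# exhaustive subset search
# ---------------------------------------------------------------------------

def _chunked_combinations(p: int, s: int, chunk: int):
    it = itertools.combinations(range(p), s)
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            return
        yield np.array(block, dtype=np.intp)


def search_space_size(n_columns: int, sizes: Sequence[int]) -> int:
    return sum(math.comb(n_columns, s) for s in sizes)


def exhaustive_subset_search(
    features,
    y,
    sizes: Sequence[int] = (1, 2, 3),
    top_m: int = 10,
    allow_saturated: bool = False,
    max_models: int = 5_000_000,
    chunk_size: int = 100_000,
) -> SearchReport:
    """Fit every column subset of each requested size; rank by R.

    Enumeration is exhaustive -- every subset is solved, so no pruning can
    affect the top result.  Constant columns are excluded up front (reported
    in ``skipped_columns``); subsets whose normal equations are singular are
    ranked last.  Ties are broken by smaller subset size, then lexicographic
    column order.

    Raises :class:`SearchSpaceError` when the enumerated model count exceeds
    ``max_models`` (default 5e6), reporting the computed size.
    """
    frame = _as_matrix(features)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(frame) != n:
        raise ValueError(f"response length {n} != row count {len(frame)}")
    sizes = tuple(sorted(set(int(s) for s in sizes)))
    if not sizes or sizes[0] < 1:
        raise ValueError(f"subset sizes must be >= 1, got {sizes}")
    if np.ptp(y) == 0:
        raise UndefinedStatisticError("response is constant; R undefined")
    for s in sizes:
        _check_sample_size(n, s, allow_saturated)

    all_cols = [str(c) for c in frame.columns]
    Xall = frame.to_numpy(dtype=float)
    keep = np.ptp(Xall, axis=0) > 0
    skipped = [c for c, k in zip(all_cols, keep) if not k]
    cols = [c for c, k in zip(all_cols, keep) if k]
    X = Xall[:, keep]
    p = X.shape[1]
    if p == 0:
        raise UndefinedStatisticError("no non-constant feature columns to search")

    n_models = search_space_size(p, sizes)
    if n_models > max_models:
        raise SearchSpaceError(
            f"search space of {n_models} models exceeds the ceiling {max_models}; "
            f"raise max_models to proceed",
            n_models=n_models,
        )

    # One Gram matrix serves every subset: the intercept is column p.
    Xa = np.column_stack([X, np.ones(n)])
    G = Xa.T @ Xa
    c = Xa.T @ y
    yty = float(y @ y)
    sst = float(((y - y.mean()) ** 2).sum())

    pool_depth = max(top_m, 64)
    # candidate pool entries: (-R, size, column-id tuple)
    pool: list[tuple[float, int, tuple[str, ...]]] = []
    for s in sizes:
        for combos in _chunked_combinations(p, s, chunk_size):
            m = combos.shape[0]
            idx = np.concatenate([combos, np.full((m, 1), p, dtype=np.intp)], axis=1)
            A = G[idx[:, :, None], idx[:, None, :]]
            b = c[idx]
            try:
                beta = np.linalg.solve(A, b[..., None])[..., 0]
                sse = yty - np.einsum("ij,ij->i", beta, b)
                r2 = 1.0 - sse / sst
                r2 = np.clip(r2, 0.0, 1.0)
                R = np.sqrt(r2)
            except np.linalg.LinAlgError:
                # Some subset in the chunk is singular; fall back per subset.
                R = np.empty(m)
                for i in range(m):
                    try:
                        bi = np.linalg.solve(A[i], b[i])
                        R[i] = math.sqrt(
                            min(max(1.0 - (yty - bi @ b[i]) / sst, 0.0), 1.0)
                        )
                    except np.linalg.LinAlgError:
                        R[i] = -1.0  # singular: rank below everything
            R = np.nan_to_num(R, nan=-1.0)
            take = min(pool_depth, m)
            best_idx = np.argpartition(-R, take - 1)[:take]
            for i in best_idx:
                pool.append((-float(R[i]), s, tuple(cols[j] for j in combos[i])))
        # keep the pool bounded between sizes
        pool.sort()
        del pool[pool_depth:]

    pool.sort()
    results = []
    for negR, s, col_ids in pool[:top_m]:
        if negR >= 1.0:  # singular sentinel (-R = 1.0 means R = -1)
            continue
        results.append(
            fit_multiple_regression(frame, y, column_ids=col_ids, allow_saturated=True)
        )
    return SearchReport(
        results=results,
        n_models=n_models,
        sizes=sizes,
        n_columns=p,
        n_observations=n,
        skipped_columns=skipped,
        settings={"top_m": top_m, "allow_saturated": allow_saturated,
                  "max_models": max_models},
    )
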