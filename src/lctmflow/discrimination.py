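"""Discrimination diagnostics and concordance statistics.

Three tools assess how distinguishable the latent classes are:

* degrees of separation (DoS): the smallest pairwise Mahalanobis distance
  between class mean trajectories evaluated on a time grid, scaled by
  ``1/sqrt(T)`` so the value is per time point.  DoS is zero exactly when
  all mean trajectories coincide; larger values mean better-separated
  classes.
* posterior-weighted residual envelopes: per class and time bin, the
  weighted mean and local SD of subject residuals (weights = posterior
  probabilities).  Non-parallel upper/lower boundaries indicate residual
  heteroscedasticity, i.e. a covariance structure the model fails to
  capture.
* Cohen's kappa on cross-tabulations, unweighted or with linear/quadratic
  disagreement weights, optionally maximised over row-label permutations
  (latent classes carry no intrinsic order, so comparing them with an
  external categorisation requires choosing a labelling).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .data_model import (
    DataError,
    FittedModel,
    SufficientSummaries,
    TrajectoryDataset,
    build_design,
)
from .gmm_fit import NumericalError, marginal_covariance

__all__ = [
    "DiscriminationReport",
    "EnvelopeReport",
    "ConcordanceTable",
    "degrees_of_separation",
    "envelope_residuals",
    "weighted_kappa",
    "model_concordance",
    "cross_tabulate",
]


# --------------------------------------------------------------------------
# Degrees of separation
# --------------------------------------------------------------------------

@dataclass
class DiscriminationReport:
    dos: float
    pairwise: np.ndarray       # (K, K) Mahalanobis distances on the grid
    grid: np.ndarray

    def to_dict(self) -> dict:
        return {"dos": self.dos, "pairwise": self.pairwise.tolist(),
                "grid": self.grid.tolist()}


def degrees_of_separation(model: FittedModel, grid: np.ndarray) -> DiscriminationReport:
    """Mahalanobis separation of class mean trajectories on a time grid.

    The pooled covariance is the mixing-proportion-weighted average of the
    class marginal covariances on the grid; the reported DoS is the
    minimum pairwise distance divided by ``sqrt(T)`` (T grid points), so
    doubling the mean separation doubles DoS and identical trajectories
    give exactly zero.
    """
    grid = np.asarray(grid, dtype=float)
    T = grid.shape[0]
    if T < 2:
        raise DataError("DoS needs a grid of at least 2 time points")
    s = model.structure
    t = s.time_transform.apply(grid)
    X = np.vander(t, s.fixed_degree + 1, increasing=True)
    Z = X[:, : s.n_random]
    K = model.n_classes
    mu = np.stack([X @ model.beta[k] for k in range(K)])
    Vbar = np.zeros((T, T))
    for k in range(K):
        Vbar += model.pi[k] * marginal_covariance(model, Z, k)
    try:
        cho = np.linalg.cholesky(Vbar)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("pooled grid covariance is singular") from exc
    d = np.zeros((K, K))
    for k, l in itertools.combinations(range(K), 2):
        w = solve_triangular(cho, mu[k] - mu[l], lower=True)
        d[k, l] = d[l, k] = float(np.sqrt(np.dot(w, w)))
    if K < 2:
        dos = 0.0
    else:
        dos = float(min(d[k, l] for k, l in itertools.combinations(range(K), 2)) / np.sqrt(T))
    return DiscriminationReport(dos=dos, pairwise=d, grid=grid)


# --------------------------------------------------------------------------
# Residual envelopes
# --------------------------------------------------------------------------

@dataclass
class EnvelopeReport:
    """Posterior-weighted residual envelope per class and time bin.

    ``mean``, ``sd``, ``lower``, ``upper`` are (K, T) arrays on
    ``bin_times``; bins whose effective posterior weight falls below the
    floor are ``nan``.  ``parallel`` flags classes whose boundary width is
    roughly constant over time (homoscedastic residuals).
    """

    bin_times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    effective_weight: np.ndarray
    parallel: np.ndarray       # (K,) booleans
    parallel_tolerance: float

    def to_frame(self) -> pd.DataFrame:
        K, T = self.mean.shape
        rows = []
        for k in range(K):
            for t in range(T):
                rows.append({"class": k + 1, "time": self.bin_times[t],
                             "mean": self.mean[k, t], "sd": self.sd[k, t],
                             "lower": self.lower[k, t], "upper": self.upper[k, t],
                             "effective_weight": self.effective_weight[k, t]})
        return pd.DataFrame(rows)


def envelope_residuals(model: FittedModel,
                       dataset: TrajectoryDataset | SufficientSummaries,
                       grid: np.ndarray | None = None,
                       bin_width: float = 5.0,
                       weight_floor: float = 1.0,
                       parallel_tolerance: float = 0.5) -> EnvelopeReport:
    """Class- and time-specific weighted local residual mean and SD.

    Residuals are computed against each candidate class mean (``y_ij -
    x_ij' beta_k``) for every subject and weighted by the posterior
    probability ``p_ik``.  Observations are grouped by exact time when the
    design has few distinct times, otherwise into ``bin_width``-wide bins;
    ``grid`` forces explicit bin centres.  A class is flagged ``parallel``
    when the relative range of its boundary width across bins is below
    ``parallel_tolerance``.
    """
    design = dataset if isinstance(dataset, SufficientSummaries) \
        else build_design(dataset, model.structure)
    K = model.n_classes
    times_all = np.concatenate([s.times for s in design.subjects])
    uniq = np.unique(np.round(times_all, 6))
    if grid is not None:
        centres = np.asarray(grid, dtype=float)
    elif uniq.size <= 20:
        centres = uniq
    else:
        lo, hi = times_all.min(), times_all.max()
        edges = np.arange(lo, hi + bin_width, bin_width)
        centres = 0.5 * (edges[:-1] + edges[1:])
    T = centres.size
    w_sum = np.zeros((K, T))
    wr_sum = np.zeros((K, T))
    wr2_sum = np.zeros((K, T))
    for i, s in enumerate(design.subjects):
        bins = np.argmin(np.abs(s.times[:, None] - centres[None, :]), axis=1)
        for k in range(K):
            w = model.posterior[i, k]
            if w <= 0:
                continue
            r = s.y - s.X @ model.beta[k]
            np.add.at(w_sum[k], bins, w)
            np.add.at(wr_sum[k], bins, w * r)
            np.add.at(wr2_sum[k], bins, w * r * r)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = wr_sum / w_sum
        var = np.maximum(wr2_sum / w_sum - mean ** 2, 0.0)
    sd = np.sqrt(var)
    missing = w_sum < weight_floor
    if missing.all():
        raise DataError("every (class, time-bin) cell is below the weight floor")
    mean[missing] = np.nan
    sd[missing] = np.nan
    parallel = np.zeros(K, dtype=bool)
    for k in range(K):
        s_k = sd[k][~np.isnan(sd[k])]
        if s_k.size >= 2 and s_k.mean() > 0:
            parallel[k] = (s_k.max() - s_k.min()) / s_k.mean() < parallel_tolerance
        else:
            parallel[k] = True
    return EnvelopeReport(bin_times=centres, mean=mean, sd=sd,
                          lower=mean - sd, upper=mean + sd,
                          effective_weight=w_sum, parallel=parallel,
                          parallel_tolerance=parallel_tolerance)


# --------------------------------------------------------------------------
# Kappa concordance
# --------------------------------------------------------------------------

def _kappa_from_table(table: np.ndarray, scheme: str) -> float:
    K, C = table.shape
    total = table.sum()
    if total <= 0:
        return float("nan")
    p = table / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    i, j = np.indices((K, C))
    denom = max(max(K, C) - 1, 1)
    if scheme == "unweighted":
        w = (i != j).astype(float)
    elif scheme == "linear":
        w = np.abs(i - j) / denom
    elif scheme == "quadratic":
        w = (np.abs(i - j) / denom) ** 2
    else:
        raise DataError(f"unknown kappa weighting scheme {scheme!r}")
    po = float((w * p).sum())
    pe = float((w * np.outer(r, c)).sum())
    if pe == 0.0:
        return float("nan")  # degenerate marginals: agreement expected with certainty
    return 1.0 - po / pe


def weighted_kappa(table: np.ndarray, weights: str = "unweighted",
                   optimize_assignment: bool = False):
    """Cohen's kappa from a count cross-tabulation.

    ``weights`` is one of ``unweighted``, ``linear`` (``|i-j|/(K-1)``) or
    ``quadratic`` (its square).  With ``optimize_assignment`` the kappa is
    maximised over permutations of the row labels (exhaustive, exact for
    up to 8 rows) and the winning permutation is returned alongside;
    otherwise the permutation returned is the identity.

    Returns ``(kappa, assignment)``.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise DataError("kappa needs a 2-D count table")
    if (table < 0).any():
        raise DataError("negative counts in cross-tabulation")
    K = table.shape[0]
    if not optimize_assignment:
        return _kappa_from_table(table, weights), tuple(range(K))
    if K > 8:
        raise DataError("exhaustive assignment optimisation supports at most 8 rows")
    best = (-np.inf, tuple(range(K)))
    for perm in itertools.permutations(range(K)):
        val = _kappa_from_table(table[list(perm)], weights)
        if not np.isnan(val) and val > best[0]:
            best = (val, perm)
    return best


@dataclass
class ConcordanceTable:
    """Cross-tabulation of two labelings plus the kappa statistics."""

    table: np.ndarray
    row_labels: list
    col_labels: list
    kappa: float
    kappa_weighted: float
    weighting: str
    assignment: tuple

    def to_dict(self) -> dict:
        return {"table": self.table.tolist(), "row_labels": list(self.row_labels),
                "col_labels": list(self.col_labels), "kappa": self.kappa,
                "kappa_weighted": self.kappa_weighted, "weighting": self.weighting,
                "assignment": list(self.assignment)}


def cross_tabulate(rows: np.ndarray, cols: np.ndarray,
                   n_rows: int | None = None, n_cols: int | None = None) -> np.ndarray:
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    if rows.shape != cols.shape:
        raise DataError("labelings have different lengths")
    R = n_rows or int(rows.max()) + 1
    C = n_cols or int(cols.max()) + 1
    table = np.zeros((R, C), dtype=float)
    np.add.at(table, (rows, cols), 1.0)
    return table


def model_concordance(model_a: FittedModel, model_b: FittedModel,
                      weights: str = "quadratic",
                      optimize_assignment: bool = True) -> ConcordanceTable:
    """Agreement of modal class assignments between two fits of the same subjects.

    Because class labels are arbitrary in each model, the unweighted kappa
    is maximised over row permutations by default.
    """
    ids_a = list(model_a.subject_ids)
    ids_b = list(model_b.subject_ids)
    if ids_a != ids_b:
        diff = len(set(map(str, ids_a)).symmetric_difference(set(map(str, ids_b))))
        raise DataError(f"models were fitted to different subjects ({diff} differ)")
    table = cross_tabulate(model_a.assignment, model_b.assignment,
                           n_rows=model_a.n_classes, n_cols=model_b.n_classes)
    kap, assign = weighted_kappa(table, "unweighted", optimize_assignment)
    if table.shape[0] == table.shape[1]:
        kap_w, _ = weighted_kappa(table, weights, optimize_assignment)
    else:
        kap_w = float("nan")
    return ConcordanceTable(table=table,
                            row_labels=[f"class_{k+1}" for k in range(model_a.n_classes)],
                            col_labels=[f"class_{k+1}" for k in range(model_b.n_classes)],
                            kappa=kap, kappa_weighted=kap_w, weighting=weights,
                            assignment=assign)
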