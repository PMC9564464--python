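"""QAP correlation and MRQAP regression for dyadic matrices.

Dyadic observations violate the independence assumptions of ordinary
inference: the n(n-1) off-diagonal cells of a square matrix share rows
and columns.  The quadratic assignment procedure keeps the observed
statistic (a Pearson correlation, or OLS coefficients) but builds its
null distribution by relabeling nodes — permuting rows and columns of
one matrix *simultaneously* — which preserves the dyadic dependence
structure exactly.  Reported tails: ``p_ge`` (``p_le``) is the fraction
of permuted statistics at least (at most) the observed one, ties
counting in both tails, and ``sig`` is the tail on the observed sign
side.

The regression is OLS with intercept on the vectorized off-diagonals;
the permutation scheme is the classic Y-permutation (the outcome matrix
is relabeled, all coefficients refit each draw).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import DistanceMatrix, DirectedNetwork, DyadMatrix

__all__ = [
    "difference_matrix",
    "proximity_matrix",
    "binary_network_as_dyads",
    "QAPCorrelation",
    "MRQAP",
    "QapCorrelationResult",
    "QapRegressionResult",
    "qap_correlation",
    "qap_regression",
]

_TIE_TOL = 1e-12


def difference_matrix(values) -> DyadMatrix:
    """Symmetric absolute-difference matrix |v_i - v_j| of a per-region
    attribute (a pandas Series indexed by region)."""
    values = pd.Series(values)
    if values.isna().any():
        missing = values.index[values.isna()].tolist()
        raise ValueError(f"missing attribute value for regions {missing}")
    v = values.to_numpy(dtype=float)
    return DyadMatrix(list(values.index), np.abs(v[:, None] - v[None, :]))


def proximity_matrix(
    dist: DistanceMatrix,
    mode: str = "inverse_distance",
    border_pairs=None,
) -> DyadMatrix:
    """Geographic proximity as a dyadic covariate.

    ``"inverse_distance"``: m_ij = 1/d_ij (zero diagonal) — closer pairs
    score higher, so a positive coefficient means proximity favours a
    tie.  ``"border_adjacency"``: m_ij = 1 iff {i, j} is listed in
    ``border_pairs`` (a set of label pairs).
    """
    n = dist.n
    if mode == "inverse_distance":
        m = np.zeros((n, n))
        off = ~np.eye(n, dtype=bool)
        m[off] = 1.0 / dist.d[off]
    elif mode == "border_adjacency":
        if border_pairs is None:
            raise ValueError("border_adjacency mode requires border_pairs")
        pairs = {frozenset(p) for p in border_pairs}
        m = np.zeros((n, n))
        for i, a in enumerate(dist.labels):
            for j, b in enumerate(dist.labels):
                if i != j and frozenset((a, b)) in pairs:
                    m[i, j] = 1.0
    else:
        raise ValueError(f"unknown proximity mode {mode!r}")
    return DyadMatrix(list(dist.labels), m)


def binary_network_as_dyads(net: DirectedNetwork) -> DyadMatrix:
    """The association network in the outcome-matrix role."""
    return DyadMatrix(list(net.labels), net.a.astype(float))


def _check_labels(mats) -> list:
    labels = mats[0].labels
    for m in mats[1:]:
        if m.labels != labels:
            raise ValueError("dyadic matrices have inconsistent region labels")
    return labels


def _offdiag_idx(n: int):
    rows, cols = np.nonzero(~np.eye(n, dtype=bool))
    return rows, cols


def _perm_offdiag(m: np.ndarray, perms: np.ndarray, rows, cols) -> np.ndarray:
    """Off-diagonal vectors of m under each node relabeling (one row per
    permutation)."""
    return m[perms[:, rows], perms[:, cols]]


def _tails(perm_stats: np.ndarray, observed: float):
    p_ge = float(np.mean(perm_stats >= observed - _TIE_TOL))
    p_le = float(np.mean(perm_stats <= observed + _TIE_TOL))
    return p_ge, p_le


@dataclass
class QapCorrelationResult:
    coefficient: float
    sig: float
    perm_mean: float
    perm_sd: float
    perm_min: float
    perm_max: float
    p_ge: float
    p_le: float
    n_perm: int
    seed: int | None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


class QAPCorrelation(BaseEstimator):
    """Permutation test of the correlation between two dyadic matrices.

    ``fit(a, b)`` computes the Pearson correlation of the off-diagonal
    vectorizations and its QAP null distribution (rows and columns of
    ``b`` permuted simultaneously, ``n_perm`` draws).

    Attributes: ``coefficient_``, ``sig_``, ``p_ge_``, ``p_le_``,
    ``perm_mean_``, ``perm_sd_``, ``perm_min_``, ``perm_max_``.
    """

    def __init__(self, n_perm: int = 5000, seed: int | None = None):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, a: DyadMatrix, b: DyadMatrix):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        _check_labels([a, b])
        n = a.n
        rows, cols = _offdiag_idx(n)
        av = a.m[rows, cols]
        bv = b.m[rows, cols]
        if av.std() < _TIE_TOL or bv.std() < _TIE_TOL:
            raise ValueError(
                "off-diagonal vector has zero variance; correlation undefined"
            )
        observed = float(np.corrcoef(av, bv)[0, 1])

        rng = np.random.default_rng(self.seed)
        perms = np.array([rng.permutation(n) for _ in range(self.n_perm)])
        bp = _perm_offdiag(b.m, perms, rows, cols)
        ac = av - av.mean()
        bc = bp - bp.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(ac) * np.linalg.norm(bc, axis=1)
        # a permutation cannot change the variance of b's off-diagonal
        # unless b's diagonal differs from zero pattern-wise; guard anyway
        denom = np.where(denom < _TIE_TOL, np.inf, denom)
        perm_r = (bc @ ac) / denom

        p_ge, p_le = _tails(perm_r, observed)
        self.coefficient_ = observed
        self.perm_r_ = perm_r
        self.perm_mean_ = float(perm_r.mean())
        self.perm_sd_ = float(perm_r.std(ddof=1)) if self.n_perm > 1 else 0.0
        self.perm_min_ = float(perm_r.min())
        self.perm_max_ = float(perm_r.max())
        self.p_ge_ = p_ge
        self.p_le_ = p_le
        self.sig_ = min(p_ge, p_le)
        return self

    def result_(self) -> QapCorrelationResult:
        return QapCorrelationResult(
            coefficient=self.coefficient_, sig=self.sig_,
            perm_mean=self.perm_mean_, perm_sd=self.perm_sd_,
            perm_min=self.perm_min_, perm_max=self.perm_max_,
            p_ge=self.p_ge_, p_le=self.p_le_,
            n_perm=self.n_perm, seed=self.seed,
        )


def qap_correlation(
    a: DyadMatrix, b: DyadMatrix, n_perm: int = 5000, seed: int | None = None
) -> QapCorrelationResult:
    """Functional wrapper over :class:`QAPCorrelation`."""
    return QAPCorrelation(n_perm=n_perm, seed=seed).fit(a, b).result_()


@dataclass
class QapRegressionResult:
    table: pd.DataFrame
    intercept: float
    r_squared: float
    adj_r_squared: float
    n_perm: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "coefficients": self.table.to_dict(orient="index"),
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


class MRQAP(BaseEstimator):
    """Multiple regression QAP: OLS on dyads, Y-permutation inference.

    ``fit(xs, y)`` regresses the off-diagonal of ``y`` on those of the
    covariate matrices ``xs`` (a mapping name -> DyadMatrix, or a
    sequence named X1, X2, ...), with intercept, then refits under
    ``n_perm`` simultaneous row/column relabelings of ``y``.

    Attributes: ``coef_``, ``std_coef_`` (coefficients scaled by
    sd(x)/sd(y)), ``intercept_``, ``r_squared_``, ``adj_r_squared_``,
    ``p_ge_``, ``p_le_``, ``sig_`` (per covariate, observed-sign tail),
    ``names_``, ``table_``.
    """

    def __init__(self, n_perm: int = 10000, seed: int | None = None):
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, xs, y: DyadMatrix):
        if isinstance(xs, Mapping):
            names = list(xs.keys())
            mats = list(xs.values())
        else:
            mats = list(xs)
            names = [f"X{k + 1}" for k in range(len(mats))]
        if not mats:
            raise ValueError("at least one covariate matrix is required")
        _check_labels(mats + [y])
        n = y.n
        m = n * (n - 1)
        p = len(mats)
        if m <= p + 1:
            raise ValueError("more covariates than dyads")

        rows, cols = _offdiag_idx(n)
        xcols = np.column_stack([x.m[rows, cols] for x in mats])
        yv = y.m[rows, cols]

        # fit on z-scored covariates for numerical stability across wildly
        # different attribute scales; unscale coefficients afterwards
        mx = xcols.mean(axis=0)
        sx = xcols.std(axis=0)
        self._check_collinearity(xcols, sx, names)
        Z = np.column_stack([np.ones(m), (xcols - mx) / sx])
        pinv = np.linalg.pinv(Z)
        bz = pinv @ yv
        fitted = Z @ bz
        resid = yv - fitted
        ss_tot = ((yv - yv.mean()) ** 2).sum()
        if ss_tot < _TIE_TOL:
            raise ValueError("outcome off-diagonal has zero variance")
        r2 = 1.0 - (resid ** 2).sum() / ss_tot
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - p - 1)

        rng = np.random.default_rng(self.seed)
        perms = np.array([rng.permutation(n) for _ in range(self.n_perm)])
        yp = _perm_offdiag(y.m, perms, rows, cols)  # (n_perm, m)
        betas = yp @ pinv.T  # (n_perm, p+1), standardized-x scale

        # tails are invariant under the positive rescaling bz_k -> bz_k/sd_k
        p_ge = np.empty(p)
        p_le = np.empty(p)
        for k in range(p):
            p_ge[k], p_le[k] = _tails(betas[:, k + 1], bz[k + 1])
        sig = np.where(bz[1:] >= 0, p_ge, p_le)

        sy = yv.std()
        self.names_ = names
        self.coef_ = bz[1:] / sx
        self.intercept_ = float(bz[0] - (self.coef_ * mx).sum())
        self.std_coef_ = bz[1:] / sy
        self.r_squared_ = float(r2)
        self.adj_r_squared_ = float(adj)
        self.p_ge_ = p_ge
        self.p_le_ = p_le
        self.sig_ = sig
        self.table_ = pd.DataFrame(
            {
                "coefficient": self.coef_,
                "std_coefficient": self.std_coef_,
                "significance": sig,
                "p_ge": p_ge,
                "p_le": p_le,
            },
            index=pd.Index(names, name="variable"),
        )
        return self

    @staticmethod
    def _check_collinearity(xcols: np.ndarray, sx: np.ndarray, names) -> None:
        offenders = [f"{names[k]} (constant)"
                     for k in range(len(sx)) if sx[k] < _TIE_TOL]
        if not offenders:
            z = (xcols - xcols.mean(axis=0)) / sx
            rank = np.linalg.matrix_rank(z)
            if rank == z.shape[1]:
                return
            c = np.corrcoef(z.T) if z.shape[1] > 1 else np.ones((1, 1))
            for a in range(z.shape[1]):
                for b in range(a + 1, z.shape[1]):
                    if abs(c[a, b]) > 1 - 1e-9:
                        offenders.append(f"{names[a]} ~ {names[b]}")
        raise ValueError(
            "collinear covariate matrices: " + (", ".join(offenders) or
                                                "rank-deficient design")
        )

    def result_(self) -> QapRegressionResult:
        return QapRegressionResult(
            table=self.table_.copy(),
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            adj_r_squared=self.adj_r_squared_,
            n_perm=self.n_perm,
            seed=self.seed,
        )


def qap_regression(
    y: DyadMatrix, xs, n_perm: int = 10000, seed: int | None = None
) -> QapRegressionResult:
    """Functional wrapper over :class:`MRQAP`."""
    return MRQAP(n_perm=n_perm, seed=seed).fit(xs, y).result_()
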