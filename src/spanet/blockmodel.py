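"""CONCOR blockmodeling, block flow accounting, and spillover roles.

CONCOR (CONvergence of iterated CORrelations) clusters nodes by
structural equivalence: each node's profile is its adjacency row and
column concatenated; correlating profiles, then repeatedly correlating
the rows of the correlation matrix itself, drives every off-diagonal
entry towards +1 or -1, and the sign pattern splits the nodes in two.
Applying the split recursively to submatrices of the first correlation
matrix yields 2^depth blocks at most (groups of one or two nodes are
not split further).

The reduced network over blocks is summarized three ways: a flow table
counting each block's ties inside and outside (with expected and actual
internal-tie ratios), a block-to-block density matrix, and a binary
image matrix cut at the overall network density.  Each block is then
assigned one of four spillover roles from its received/sent tie ratio
rho: predominantly receiving (net benefit), predominantly sending (net
spillover), exchanging heavily in both directions (two-way spillover),
or mediating between other blocks (broker).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .containers import DirectedNetwork

__all__ = [
    "BlockPartition",
    "ConcorBlockModel",
    "concor_partition",
    "block_flow_summary",
    "block_density_matrix",
    "image_matrix",
    "classify_roles",
    "ROLES",
]

ROLES = ("net_benefit", "net_spillover", "two_way_spillover", "broker")

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


def roman(i: int) -> str:
    return _ROMAN[i] if i < len(_ROMAN) else str(i + 1)


def _safe_corrcoef(m: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; zero-variance rows correlate 0."""
    m = np.asarray(m, dtype=float)
    centered = m - m.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    const = norms < 1e-12
    if const.any():
        warnings.warn(
            f"{const.sum()} constant node profile(s); correlations set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
        norms = np.where(const, 1.0, norms)
    r = (centered @ centered.T) / np.outer(norms, norms)
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def _iterate_correlations(c: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Correlate rows of c with itself until off-diagonals polarize to +-1."""
    off = ~np.eye(c.shape[0], dtype=bool)
    for _ in range(max_iter):
        if np.abs(np.abs(c[off]) - 1.0).max() <= tol:
            break
        c = _safe_corrcoef(c)
    return c


def _split_group(c_sub: np.ndarray, tol: float, max_iter: int):
    """Bipartition local indices 0..m-1 by the sign pattern of the
    converged correlation matrix; returns (group_a, group_b), b possibly
    empty when the group does not polarize."""
    r = _iterate_correlations(c_sub, tol, max_iter)
    ref = r[0]
    ambiguous = np.abs(np.abs(ref) - 1.0) > tol
    ambiguous[0] = False
    a = [j for j in range(len(ref)) if not ambiguous[j] and ref[j] > 0]
    b = [j for j in range(len(ref)) if not ambiguous[j] and ref[j] <= 0 and j != 0]
    if 0 not in a:
        a.insert(0, 0)
    for j in np.nonzero(ambiguous)[0]:
        mean_a = r[j, a].mean() if a else -np.inf
        mean_b = r[j, b].mean() if b else -np.inf
        (a if mean_a >= mean_b else b).append(int(j))
    return sorted(a), sorted(b)


def _recurse(c1: np.ndarray, idx: list, depth: int, tol: float, max_iter: int):
    if depth == 0 or len(idx) <= 2:
        return [idx]
    sub = c1[np.ix_(idx, idx)]
    la, lb = _split_group(sub, tol, max_iter)
    if not lb:
        return [idx]
    ga = [idx[j] for j in la]
    gb = [idx[j] for j in lb]
    return (
        _recurse(c1, ga, depth - 1, tol, max_iter)
        + _recurse(c1, gb, depth - 1, tol, max_iter)
    )


@dataclass
class BlockPartition:
    """A CONCOR partition: node label -> block index (0-based)."""

    assignment: dict
    depth: int
    n_blocks: int

    def block_of(self, labels) -> np.ndarray:
        return np.array([self.assignment[x] for x in labels])

    @property
    def block_labels(self) -> list:
        return [roman(i) for i in range(self.n_blocks)]

    def members(self, k: int) -> list:
        return [x for x, b in self.assignment.items() if b == k]

    def sizes(self) -> np.ndarray:
        return np.bincount(
            np.fromiter(self.assignment.values(), dtype=int),
            minlength=self.n_blocks,
        )


class ConcorBlockModel(ClusterMixin, BaseEstimator):
    """Structural-equivalence clustering by convergent correlations.

    Parameters
    ----------
    depth : recursive split depth; at most ``2**depth`` blocks.
    conv_tol : convergence/concentration criterion — iteration stops
        when every off-diagonal correlation is within ``conv_tol`` of
        +-1; entries farther than that from +-1 at the split are
        assigned by their mean correlation to each side.
    max_iter : cap on correlation iterations per split.
    profiles : ``"both"`` concatenates each node's adjacency row and
        column (the usual choice for directed data); ``"rows"`` /
        ``"columns"`` use one orientation only.

    Attributes
    ----------
    labels_ : block index per node (0-based, ordered by each block's
        first member).
    n_blocks_ : number of blocks found.
    partition_ : the fitted :class:`BlockPartition`.
    """

    def __init__(self, depth: int = 2, conv_tol: float = 0.2,
                 max_iter: int = 25, profiles: str = "both"):
        self.depth = depth
        self.conv_tol = conv_tol
        self.max_iter = max_iter
        self.profiles = profiles

    def fit(self, X, y=None):
        if isinstance(X, DirectedNetwork):
            a, labels = X.a, X.labels
        elif isinstance(X, pd.DataFrame):
            a, labels = X.to_numpy(), list(X.index)
        else:
            a = np.asarray(X)
            labels = list(range(a.shape[0]))
        a = a.astype(float)
        n = a.shape[0]
        if a.ndim != 2 or a.shape[1] != n:
            raise ValueError("adjacency must be square")
        if n < 4:
            raise ValueError("CONCOR requires at least 4 nodes")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.profiles == "both":
            prof = np.hstack([a, a.T])
        elif self.profiles == "rows":
            prof = a
        elif self.profiles == "columns":
            prof = a.T
        else:
            raise ValueError(f"unknown profiles option {self.profiles!r}")

        c1 = _safe_corrcoef(prof)
        groups = _recurse(c1, list(range(n)), self.depth,
                          self.conv_tol, self.max_iter)
        groups = sorted(groups, key=lambda g: g[0])
        labels_ = np.empty(n, dtype=int)
        for k, g in enumerate(groups):
            labels_[g] = k
        self.labels_ = labels_
        self.n_blocks_ = len(groups)
        self.partition_ = BlockPartition(
            assignment={labels[i]: int(labels_[i]) for i in range(n)},
            depth=self.depth,
            n_blocks=self.n_blocks_,
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def concor_partition(
    net: DirectedNetwork,
    depth: int = 2,
    conv_tol: float = 0.2,
    max_iter: int = 25,
    profiles: str = "both",
) -> BlockPartition:
    """Functional wrapper over :class:`ConcorBlockModel`."""
    model = ConcorBlockModel(depth=depth, conv_tol=conv_tol,
                             max_iter=max_iter, profiles=profiles)
    return model.fit(net).partition_


def classify_roles(received, sent, thresholds=(2.0, 1.0, 0.25)) -> list:
    """Spillover role per block from total received/sent tie counts.

    With rho = received / sent (totals include internal ties, which
    count on both sides): rho >= 2 -> net_benefit; 1 <= rho < 2 ->
    two_way_spillover; 0.25 <= rho < 1 -> broker; rho < 0.25 ->
    net_spillover.  The cutoffs are configurable; they are a calibrated
    operationalization of qualitative role descriptions, not canonical
    constants.  Blocks that send nothing are 'unclassifiable'.
    """
    t_benefit, t_two_way, t_spill = thresholds
    roles = []
    for r, s in zip(np.asarray(received, float), np.asarray(sent, float)):
        if s == 0:
            roles.append("unclassifiable")
            continue
        rho = r / s
        if rho >= t_benefit:
            roles.append("net_benefit")
        elif rho >= t_two_way:
            roles.append("two_way_spillover")
        elif rho >= t_spill:
            roles.append("broker")
        else:
            roles.append("net_spillover")
    return roles


def _arc_counts(net: DirectedNetwork, part: BlockPartition) -> np.ndarray:
    """K x K matrix of arc counts between blocks."""
    b = part.block_of(net.labels)
    k = part.n_blocks
    counts = np.zeros((k, k), dtype=int)
    src, dst = np.nonzero(net.a)
    np.add.at(counts, (b[src], b[dst]), 1)
    return counts


def block_flow_summary(
    net: DirectedNetwork,
    part: BlockPartition,
    role_thresholds=(2.0, 1.0, 0.25),
) -> pd.DataFrame:
    """Per-block tie accounting with internal ratios and roles.

    ``inside_received``/``inside_sent`` both count the block's internal
    arcs (each internal arc is received and sent by the same block);
    the expected internal ratio is 100 (n_k - 1)/(n - 1) and the actual
    internal ratio 100 inside / (inside + outside_sent).
    """
    missing = [x for x in net.labels if x not in part.assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes {missing}")
    counts = _arc_counts(net, part)
    sizes = part.sizes()
    n = net.n
    inside = np.diag(counts)
    out_sent = counts.sum(axis=1) - inside
    out_recv = counts.sum(axis=0) - inside
    sent = inside + out_sent
    recv = inside + out_recv
    with np.errstate(divide="ignore", invalid="ignore"):
        actual = np.where(sent > 0, 100.0 * inside / sent, 0.0)
    expected = 100.0 * (sizes - 1) / (n - 1)
    return pd.DataFrame(
        {
            "n_members": sizes,
            "inside_received": inside,
            "outside_received": out_recv,
            "inside_sent": inside,
            "outside_sent": out_sent,
            "expected_internal_ratio": expected,
            "actual_internal_ratio": actual,
            "role": classify_roles(recv, sent, role_thresholds),
        },
        index=pd.Index(part.block_labels, name="block"),
    )


def block_density_matrix(net: DirectedNetwork, part: BlockPartition) -> pd.DataFrame:
    """Block-to-block densities: arcs over possible ties n_k*n_l
    (n_k*(n_k - 1) on the diagonal; single-member diagonals are 0)."""
    counts = _arc_counts(net, part).astype(float)
    sizes = part.sizes().astype(float)
    possible = np.outer(sizes, sizes)
    np.fill_diagonal(possible, sizes * (sizes - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(possible > 0, counts / possible, 0.0)
    labels = part.block_labels
    return pd.DataFrame(d, index=pd.Index(labels, name="block"), columns=labels)


def image_matrix(
    dm: pd.DataFrame,
    overall_density: float,
    strict: bool = False,
) -> pd.DataFrame:
    """Binarize a block density matrix at the overall network density
    (>= by default; ``strict=True`` uses >)."""
    vals = dm.to_numpy(dtype=float)
    b = vals > overall_density if strict else vals >= overall_density
    return pd.DataFrame(b.astype(int), index=dm.index, columns=dm.columns)
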