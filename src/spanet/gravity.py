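"""Modified-gravity construction of the directed association network.

A dyad's interaction intensity follows a gravity law with IPAT-style
masses: the "mass" of region *i* is the fourth root of the product of
its gross regional product G, population P, technology level T and
pollutant concentration C, and the intensity decays with the square of
the inter-capital distance D.  The intensity is split asymmetrically by
each side's pollution share,

    y_ij = k_ij * (G_i P_i T_i C_i)^(1/4) (G_j P_j T_j C_j)^(1/4) / D_ij^2,
    k_ij = C_i / (C_i + C_j),

so a dyad's two directed intensities differ only through k.  The binary
network records a directed tie i->j wherever y_ij exceeds the mean of
row i — each region's own intensity scale sets its threshold, which
makes the network invariant to rescaling any single row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DistanceMatrix, DirectedNetwork, GravityMatrix

__all__ = ["gravity_matrix", "binarize_row_mean"]

_GRAVITY_ATTRS = ("grp", "population", "tech", "pm25")


def gravity_matrix(panel_year: pd.DataFrame, dist: DistanceMatrix) -> GravityMatrix:
    """Gravity intensities for one cross-section of regional attributes.

    Parameters
    ----------
    panel_year : DataFrame indexed by region with columns ``grp``,
        ``population``, ``tech``, ``pm25`` (all strictly positive), in
        any row order; rows are aligned to ``dist.labels``.
    dist : inter-region distances with strictly positive off-diagonal.
    """
    missing = [c for c in _GRAVITY_ATTRS if c not in panel_year.columns]
    if missing:
        raise ValueError(f"panel cross-section lacks columns {missing}")
    try:
        sub = panel_year.loc[dist.labels, list(_GRAVITY_ATTRS)]
    except KeyError as exc:
        raise ValueError(
            "panel regions do not match distance-matrix labels"
        ) from exc
    vals = sub.to_numpy(dtype=float)
    if (vals <= 0).any():
        bad = sub.index[(vals <= 0).any(axis=1)].tolist()
        raise ValueError(f"gravity attributes must be strictly positive: {bad}")

    g, p, t, c = vals.T
    mass = (g * p * t * c) ** 0.25
    k = c[:, None] / (c[:, None] + c[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        y = k * np.outer(mass, mass) / dist.d ** 2
    np.fill_diagonal(y, 0.0)
    np.fill_diagonal(k, 0.5)
    return GravityMatrix(list(dist.labels), y, k)


def binarize_row_mean(
    g: GravityMatrix,
    strict: bool = True,
    include_diagonal: bool = False,
) -> DirectedNetwork:
    """Dichotomize a gravity matrix at each row's mean intensity.

    Row *i*'s critical value is the mean of its off-diagonal entries
    (``include_diagonal=True`` averages over the structural zeros too,
    for sensitivity checks); ``a_ij = 1`` iff ``y_ij`` exceeds it.  Ties
    at exactly the mean map to 0 under the default strict rule.
    """
    n = g.n
    if n < 2:
        raise ValueError("need at least 2 regions to binarize")
    if include_diagonal:
        thresh = g.y.mean(axis=1)
    else:
        thresh = g.y.sum(axis=1) / (n - 1)
    a = g.y > thresh[:, None] if strict else g.y >= thresh[:, None]
    a = a.astype(int)
    np.fill_diagonal(a, 0)
    return DirectedNetwork(list(g.labels), a)
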