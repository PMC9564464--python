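"""Synthetic regional panels, planted-block networks, and dyadic designs.

The real inputs of this kind of analysis — a provincial statistical
panel and an inter-capital distance matrix — are not redistributable, so
every downstream stage is exercised on generated data with the same
statistical shape: positive, right-skewed regional attributes that are
persistent within a region over time, and Euclidean distances on a
km-like scale.  Two further generators plant known structure (a block
partition; a dyadic linear effect) so that blockmodel recovery and QAP
inference can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DistanceMatrix, DirectedNetwork, DyadMatrix

__all__ = [
    "PanelParams",
    "PANEL_COLUMNS",
    "generate_panel",
    "generate_block_network",
    "generate_dyadic_design",
]

#: Long-panel column order: region id, calendar year, the four gravity
#: attributes (population, gross regional product, technology level as
#: patent counts, PM2.5 concentration) and the six dyadic covariates
#: (economic development, technological innovation, government
#: intervention, environmental regulation, industrial structure, car
#: ownership).
PANEL_COLUMNS = [
    "region", "year",
    "population", "grp", "tech", "pm25",
    "gdp", "ti", "gov", "er", "is", "co",
]

_ATTRS = PANEL_COLUMNS[2:]


@dataclass
class PanelParams:
    """Log-normal marginals and dependence structure of the panel.

    ``log_mean``/``log_sd`` give the location and scale of each attribute
    on the log scale; defaults put magnitudes in the range of provincial
    statistics (population in persons, product in constant-price currency
    units, patents granted, PM2.5 in µg/m³, fiscal and industrial shares
    as fractions).  ``rho`` is the common cross-attribute correlation of
    the regional log-attributes (bigger, richer regions patent more and
    pollute more); ``year_sd`` is the within-region year-to-year log
    noise, and ``growth`` a deterministic annual log-drift per attribute.
    """

    log_mean: dict = field(default_factory=lambda: {
        "population": np.log(4.5e7), "grp": np.log(2.2e12),
        "tech": np.log(3.0e4), "pm25": np.log(35.0),
        "gdp": np.log(6.0e4), "ti": np.log(1.5e4),
        "gov": np.log(0.25), "er": np.log(5.0e9),
        "is": np.log(0.40), "co": np.log(8.0e6),
    })
    log_sd: dict = field(default_factory=lambda: {
        "population": 0.6, "grp": 0.8, "tech": 1.0, "pm25": 0.35,
        "gdp": 0.4, "ti": 0.9, "gov": 0.3, "er": 0.8,
        "is": 0.2, "co": 0.7,
    })
    rho: float = 0.5
    year_sd: float = 0.05
    growth: dict = field(default_factory=lambda: {
        "grp": 0.06, "gdp": 0.06, "tech": 0.08, "co": 0.08,
        "pm25": -0.02,
    })
    first_year: int = 2009
    coord_range: tuple = (100.0, 3000.0)


def generate_panel(
    n_regions: int = 31,
    years: int = 12,
    seed: int | None = None,
    params: PanelParams | None = None,
):
    """Generate a region-by-year attribute panel and a distance matrix.

    Returns ``(panel, dist)`` where ``panel`` is a long-format DataFrame
    with columns :data:`PANEL_COLUMNS` (one row per region-year, all
    attributes strictly positive) and ``dist`` a
    :class:`~spanet.containers.DistanceMatrix` of Euclidean distances
    between regions placed uniformly on a square, rescaled so that
    off-diagonal distances span ``params.coord_range`` km.

    Regional attributes are log-normal with an equicorrelated latent
    structure: each region draws a base log-attribute vector once, and
    each year adds independent noise plus a deterministic drift, so
    attributes are persistent within a region — the feature the gravity
    model's masses rely on.  Deterministic given ``seed``.
    """
    if n_regions < 4:
        raise ValueError("n_regions must be >= 4")
    if years < 1:
        raise ValueError("years must be >= 1")
    params = params or PanelParams()
    rng = np.random.default_rng(seed)
    p = len(_ATTRS)

    # equicorrelated gaussian log-attributes via a single common factor
    rho = float(params.rho)
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    common = rng.standard_normal((n_regions, 1))
    unique = rng.standard_normal((n_regions, p))
    z = np.sqrt(rho) * common + np.sqrt(1 - rho) * unique

    mu = np.array([params.log_mean[a] for a in _ATTRS])
    sd = np.array([params.log_sd[a] for a in _ATTRS])
    growth = np.array([params.growth.get(a, 0.0) for a in _ATTRS])
    base = mu + sd * z  # (n_regions, p) log-attributes, year 0

    labels = [f"R{i + 1:02d}" for i in range(n_regions)]
    rows = []
    for t in range(years):
        noise = params.year_sd * rng.standard_normal((n_regions, p))
        vals = np.exp(base + growth * t + noise)
        for r in range(n_regions):
            rows.append([labels[r], params.first_year + t, *vals[r]])
    panel = pd.DataFrame(rows, columns=PANEL_COLUMNS)

    coords = rng.uniform(0.0, 1.0, size=(n_regions, 2))
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    off = ~np.eye(n_regions, dtype=bool)
    lo, hi = params.coord_range
    dmin, dmax = d[off].min(), d[off].max()
    scaled = np.zeros_like(d)
    scaled[off] = lo + (d[off] - dmin) * (hi - lo) / (dmax - dmin)
    return panel, DistanceMatrix(labels, scaled)


def panel_year(panel: pd.DataFrame, year: int) -> pd.DataFrame:
    """One year's cross-section, indexed by region, in panel region order."""
    sub = panel[panel["year"] == year]
    if sub.empty:
        raise ValueError(f"year {year} not present in panel")
    return sub.set_index("region")


def generate_block_network(
    sizes,
    p_in: float,
    p_out: float,
    seed: int | None = None,
) -> DirectedNetwork:
    """Directed planted-partition graph: arc i->j with prob p_in within a
    block, p_out between blocks; no self-loops."""
    sizes = list(sizes)
    if any(s < 1 for s in sizes) or not sizes:
        raise ValueError("block sizes must be positive")
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("require 0 <= p_out < p_in <= 1 for planted structure")
    n = sum(sizes)
    block = np.repeat(np.arange(len(sizes)), sizes)
    rng = np.random.default_rng(seed)
    prob = np.where(block[:, None] == block[None, :], p_in, p_out)
    a = (rng.random((n, n)) < prob).astype(int)
    np.fill_diagonal(a, 0)
    labels = [f"N{i + 1:02d}" for i in range(n)]
    return DirectedNetwork(labels, a)


def generate_dyadic_design(
    n: int,
    n_covariates: int = 1,
    betas=None,
    noise_sd: float = 1.0,
    seed: int | None = None,
):
    """Dyadic linear design for QAP parameter-recovery tests.

    Draws ``n_covariates`` standard-normal node attributes, forms the
    symmetric absolute-difference matrix of each, and builds
    ``Y = sum_k beta_k X_k + eps`` on the off-diagonal (eps iid Gaussian
    with sd ``noise_sd``; diagonal zero).  Returns ``(Y, [X_1, ...])`` as
    :class:`~spanet.containers.DyadMatrix`.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if betas is None:
        betas = np.ones(n_covariates)
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (n_covariates,):
        raise ValueError("betas must have one entry per covariate")
    rng = np.random.default_rng(seed)
    labels = [f"N{i + 1:02d}" for i in range(n)]
    xs = []
    y = np.zeros((n, n))
    for k in range(n_covariates):
        v = rng.standard_normal(n)
        x = np.abs(v[:, None] - v[None, :])
        xs.append(DyadMatrix(labels, x))
        y += betas[k] * x
    if noise_sd:
        y += noise_sd * rng.standard_normal((n, n))
    np.fill_diagonal(y, 0.0)
    return DyadMatrix(labels, y), xs
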