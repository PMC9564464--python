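"""End-to-end orchestration: panel -> yearly networks -> report bundle.

`run_pipeline` is a pure function of (inputs, config, seed): it builds
one gravity network per year from that year's attributes, computes the
whole-network index series, and on the final year produces the
centrality table, the CONCOR blockmodel outputs and the QAP analyses.
`verify_fixtures` recomputes every report-level quantity derivable from
the packaged worked-example tables and reports pass/fail per check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import DistanceMatrix, DirectedNetwork
from . import whole
from .blockmodel import (
    ConcorBlockModel,
    block_density_matrix,
    block_flow_summary,
    classify_roles,
    image_matrix,
)
from .centrality import centrality_table
from .fixtures import load_fixtures
from .gravity import binarize_row_mean, gravity_matrix
from .qap import (
    binary_network_as_dyads,
    difference_matrix,
    proximity_matrix,
    qap_correlation,
    qap_regression,
)
from .synthetic import PANEL_COLUMNS, panel_year

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "verify_fixtures"]

DEFAULT_QAP_COVARIATES = ["gdp", "ti", "gov", "er", "is", "co"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, serializable to/from YAML."""

    panel_path: str
    distance_path: str
    out_dir: str | None = None
    years: list | None = None          # None = every year in the panel
    final_year: int | None = None      # None = last analyzed year
    strict_ties: bool = True           # gravity row-mean rule: > vs >=
    include_diagonal_in_mean: bool = False
    degree_convention: str = "neighbor"
    symmetrize: bool = True
    concor_depth: int = 2
    concor_tol: float = 0.2
    concor_max_iter: int = 25
    role_thresholds: tuple = (2.0, 1.0, 0.25)
    qap_covariates: list = field(default_factory=lambda: list(DEFAULT_QAP_COVARIATES))
    qap_n_perm: int = 5000
    mrqap_n_perm: int = 10000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.role_thresholds is not None:
            cfg.role_thresholds = tuple(cfg.role_thresholds)
        return cfg


@dataclass
class ReportBundle:
    whole_series: pd.DataFrame
    centrality: pd.DataFrame
    block_assignment: pd.Series
    block_flows: pd.DataFrame
    block_density: pd.DataFrame
    image: pd.DataFrame
    qap_correlations: pd.DataFrame
    qap_regression: pd.DataFrame
    manifest: dict


def _load_inputs(config: PipelineConfig):
    panel_path = Path(config.panel_path)
    dist_path = Path(config.distance_path)
    for p in (panel_path, dist_path):
        if not p.exists():
            raise FileNotFoundError(f"pipeline input not found: {p}")
    panel = pd.read_csv(panel_path)
    missing = [c for c in PANEL_COLUMNS[:6] if c not in panel.columns]
    if missing:
        raise ValueError(f"panel file {panel_path} lacks columns {missing}")
    dist = DistanceMatrix.from_csv(dist_path)
    return panel, dist


def _stage(name):
    """Re-raise stage failures with the stage name attached."""
    import contextlib

    @contextlib.contextmanager
    def ctx():
        try:
            yield
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    return ctx()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages; write outputs if ``config.out_dir`` is set."""
    panel, dist = _load_inputs(config)
    years = sorted(panel["year"].unique())
    if config.years is not None:
        years = [y for y in years if y in set(config.years)]
        if not years:
            raise ValueError("no panel years match the configured year range")
    final_year = config.final_year if config.final_year is not None else years[-1]

    nets: dict[int, DirectedNetwork] = {}
    records = []
    with _stage("gravity_network"):
        for y in years:
            gm = gravity_matrix(panel_year(panel, y), dist)
            net = binarize_row_mean(
                gm,
                strict=config.strict_ties,
                include_diagonal=config.include_diagonal_in_mean,
            )
            nets[y] = net
            rec = whole.summarize(net).to_dict()
            rec["year"] = y
            records.append(rec)
    whole_series = pd.DataFrame(records).set_index("year")

    final_net = nets[final_year]
    with _stage("centrality"):
        cent = centrality_table(
            final_net,
            degree_convention=config.degree_convention,
            symmetrize=config.symmetrize,
            decimals=None,
        )

    with _stage("blockmodel"):
        model = ConcorBlockModel(
            depth=config.concor_depth,
            conv_tol=config.concor_tol,
            max_iter=config.concor_max_iter,
        ).fit(final_net)
        part = model.partition_
        flows = block_flow_summary(final_net, part, config.role_thresholds)
        dens = block_density_matrix(final_net, part)
        img = image_matrix(dens, whole.density(final_net))
        assignment = pd.Series(
            {r: part.block_labels[b] for r, b in part.assignment.items()},
            name="block",
        ).reindex(final_net.labels)
        assignment.index.name = "region"

    with _stage("qap"):
        y_dyads = binary_network_as_dyads(final_net)
        period_mean = (
            panel[panel["year"].isin(years)]
            .groupby("region")[config.qap_covariates]
            .mean()
            .loc[dist.labels]
        )
        xs = {"gd": proximity_matrix(dist, "inverse_distance")}
        for cov in config.qap_covariates:
            xs[cov] = difference_matrix(period_mean[cov])
        corr_rows = []
        for name, x in xs.items():
            res = qap_correlation(
                x, y_dyads, n_perm=config.qap_n_perm, seed=config.seed
            )
            row = res.to_dict()
            row["variable"] = name
            corr_rows.append(row)
        qap_corr = pd.DataFrame(corr_rows).set_index("variable")
        reg = qap_regression(
            y_dyads, xs, n_perm=config.mrqap_n_perm, seed=config.seed
        )
        reg_table = reg.table.copy()

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "years": [int(y) for y in years],
        "final_year": int(final_year),
        "seed": config.seed,
        "n_regions": final_net.n,
        "qap_model": {
            "r_squared": reg.r_squared,
            "adj_r_squared": reg.adj_r_squared,
            "n_perm": reg.n_perm,
        },
    }
    bundle = ReportBundle(
        whole_series=whole_series,
        centrality=cent,
        block_assignment=assignment,
        block_flows=flows,
        block_density=dens,
        image=img,
        qap_correlations=qap_corr,
        qap_regression=reg_table,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_bundle(bundle, nets, final_year, Path(config.out_dir))
    return bundle


def _write_bundle(bundle: ReportBundle, nets, final_year, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    bundle.whole_series.to_csv(out / "whole_network_series.csv")
    bundle.centrality.round(3).to_csv(out / "centrality.csv")
    bundle.block_assignment.to_csv(out / "block_assignment.csv")
    bundle.block_flows.to_csv(out / "block_flows.csv")
    bundle.block_density.round(3).to_csv(out / "block_density.csv")
    bundle.image.to_csv(out / "image_matrix.csv")
    bundle.qap_correlations.to_csv(out / "qap_correlations.csv")
    bundle.qap_regression.to_csv(out / "qap_regression.csv")
    net = nets[final_year]
    net.to_csv(out / f"network_{final_year}.csv")
    net.to_edge_list().to_csv(out / f"edges_{final_year}.csv", index=False)
    net.to_graphml(out / f"network_{final_year}.graphml")
    full = {
        "manifest": bundle.manifest,
        "whole_network": bundle.whole_series.reset_index().to_dict("records"),
        "centrality": bundle.centrality.reset_index().to_dict("records"),
        "block_flows": bundle.block_flows.reset_index().to_dict("records"),
        "qap_correlations":
            bundle.qap_correlations.reset_index().to_dict("records"),
        "qap_regression":
            bundle.qap_regression.reset_index().to_dict("records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(full, fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# fixture verification harness
# ---------------------------------------------------------------------------

def _check(report, name, expected, actual, tol=0.0):
    if isinstance(expected, (int, float)):
        ok = abs(actual - expected) <= tol
    else:
        ok = actual == expected
    report[name] = {"expected": expected, "actual": actual, "passed": bool(ok)}


def verify_fixtures() -> dict:
    """Recompute every report-level quantity derivable from the packaged
    worked-example tables; returns {check: {expected, actual, passed}}.

    Failures are reported, never raised.  One check
    (``table3_weighted_average_density``) is held only to printed-table
    rounding: the published block density matrix and flow table disagree
    by two arcs, so the size-weighted average reproduces the overall
    density to ~3e-3, not exactly.
    """
    fx = load_fixtures()
    t1, t2, t3, t4 = fx.table1, fx.table2, fx.table3, fx.table4
    sizes = fx.block_sizes.to_numpy()
    n = len(t1)
    report: dict = {}

    out_sum = int(t1["out_degree"].sum())
    in_sum = int(t1["in_degree"].sum())
    _check(report, "table1_degree_balance", out_sum, in_sum)
    _check(report, "total_arcs", 250, out_sum)
    _check(report, "degree_mean", 42.80, round(t1["degree"].mean(), 2))
    _check(report, "out_degree_mean", 8.06, round(t1["out_degree"].mean(), 2))
    _check(report, "betweenness_mean", 2.047, round(t1["betweenness"].mean(), 3))
    _check(report, "betweenness_total", 63.446, round(t1["betweenness"].sum(), 3))
    top6 = t1["betweenness"].nlargest(6).sum()
    _check(report, "betweenness_top6_total", 47.542, round(top6, 3))
    _check(report, "closeness_mean", 63.99, t1["closeness"].mean(), tol=0.05)
    _check(report, "network_density", 0.2688, round(out_sum / (n * (n - 1)), 4))

    inside = t2["inside_sent"].to_numpy()
    out_sent = t2["outside_sent"].to_numpy()
    out_recv = t2["outside_received"].to_numpy()
    _check(report, "table2_inside_total", 120, int(inside.sum()))
    _check(report, "table2_outside_sent_total", 130, int(out_sent.sum()))
    _check(report, "table2_outside_received_total", 130, int(out_recv.sum()))
    _check(report, "table2_plus_table1_arcs", out_sum,
           int(inside.sum() + out_sent.sum()))

    actual_ratio = np.rint(100.0 * inside / (inside + out_sent)).astype(int)
    _check(report, "actual_internal_ratios",
           t2["actual_internal_ratio"].tolist(), actual_ratio.tolist())
    # the printed expected column mixes two formulas: (n_k-1)/(n-1) for
    # blocks I-II and n_k/(n-1) for III-IV; check the table's own arithmetic
    printed = t2["expected_internal_ratio"].to_numpy()
    mixed = np.rint(100.0 * np.array(
        [sizes[0] - 1, sizes[1] - 1, sizes[2], sizes[3]]) / (n - 1)).astype(int)
    _check(report, "expected_internal_ratios_as_printed",
           printed.tolist(), mixed.tolist())

    diag_counts = np.rint(
        np.diag(t3.to_numpy()) * sizes * (sizes - 1)).astype(int)
    _check(report, "table3_diagonal_matches_inside_counts",
           inside.tolist(), diag_counts.tolist())

    img = image_matrix(t3, 0.2688)
    _check(report, "image_matrix_matches",
           t4.to_numpy().tolist(), img.to_numpy().tolist())

    recv = t2["inside_received"] + t2["outside_received"]
    sent = t2["inside_sent"] + t2["outside_sent"]
    roles = classify_roles(recv.to_numpy(), sent.to_numpy())
    _check(report, "block_roles",
           ["net_benefit", "net_spillover", "two_way_spillover", "broker"],
           roles)

    possible = np.outer(sizes, sizes).astype(float)
    np.fill_diagonal(possible, sizes * (sizes - 1))
    weighted = (t3.to_numpy() * possible).sum() / (n * (n - 1))
    _check(report, "table3_weighted_average_density", 0.2688,
           float(weighted), tol=0.005)
    return report
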