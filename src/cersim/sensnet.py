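"""Parametric sensitivity scans and the signed interaction network.

Each of the 29 reaction rates (or each enzyme) is scaled across a
logarithmic fold-change grid under mass action; the effect on every
sphingolipid is the log2 AUC ratio against the unscaled control.  The
network view keeps, at a single representative fold change (default 4),
the (factor -> metabolite) pairs whose raw AUC ratio deviates from 1 by
more than a kind-specific threshold: 0.01 for rates, 0.001 for enzymes.
Edge sign encodes the direction of the effect (up: the increase of the
rate increases the species' exposure), edge weight is |log2 AUC ratio|,
so doubling and halving a concentration give equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .model import ModelSpec
from .perturb import default_grid, log2_auc_ratio, scale_enzyme, scale_reaction
from .simulate import simulate_ode

__all__ = [
    "SensScanConfig",
    "RATE_THRESHOLD",
    "ENZYME_THRESHOLD",
    "sensitivity_scan",
    "build_network",
    "export_network",
    "read_network",
]

RATE_THRESHOLD = 0.01  # on |raw AUC ratio - 1|
ENZYME_THRESHOLD = 0.001

RATE_GRID = (0.01, 0.04, 0.25, 1.0, 4.0, 16.0, 100.0)
ENZYME_GRID = (0.01, 0.1, 1.0, 4.0, 10.0)


@dataclass
class SensScanConfig:
    """Scan configuration: what to scale and over which grid."""

    target_kind: str = "rate"  # "rate" | "enzyme"
    fc_grid: tuple[float, ...] | None = None
    report_fc: float = 4.0
    t_end: float = 24.0

    def __post_init__(self) -> None:
        if self.target_kind not in ("rate", "enzyme"):
            raise ValueError("target_kind must be 'rate' or 'enzyme'")
        if self.fc_grid is None:
            self.fc_grid = RATE_GRID if self.target_kind == "rate" else ENZYME_GRID
        if any(f <= 0 for f in self.fc_grid):
            raise ValueError("fold-change grid must be positive")
        if 1.0 not in self.fc_grid:
            raise ValueError("fold-change grid must contain 1")
        if self.report_fc not in self.fc_grid:
            raise ValueError("report_fc must be in the grid")


def sensitivity_scan(
    model: ModelSpec, config: SensScanConfig
) -> dict[float, pd.DataFrame]:
    """One log2-AUC-ratio table (targets x species) per grid value.

    Simulation failures are recorded as NaN cells and the scan continues.
    """
    grid = default_grid(config.t_end)
    control = simulate_ode(model, grid)
    if config.target_kind == "rate":
        targets = [r.id for r in model.reactions]
        scaler = scale_reaction
    else:
        targets = list(model.enzymes)
        scaler = scale_enzyme
    out: dict[float, pd.DataFrame] = {}
    for f in config.fc_grid:
        rows = {}
        for tgt in targets:
            if f == 1.0:
                rows[tgt] = log2_auc_ratio(control, control)
                continue
            try:
                rows[tgt] = log2_auc_ratio(
                    simulate_ode(scaler(model, tgt, f), grid), control
                )
            except RuntimeError:
                rows[tgt] = pd.Series(np.nan, index=list(control.species))
        table = pd.DataFrame(rows).T
        table.index.name = config.target_kind
        out[float(f)] = table
    return out


def build_network(
    table: pd.DataFrame,
    target_kind: str,
    threshold: float | None = None,
) -> nx.DiGraph:
    """Signed, weighted bipartite factor -> metabolite network.

    ``table`` holds log2 AUC ratios at the report fold change (rows:
    factors, columns: metabolites).  An edge is kept iff the *raw* AUC
    ratio deviates from 1 by more than the kind-specific threshold (note
    the deliberate asymmetry: the filter is on the ratio, the weight on
    its base-2 logarithm).  Node sizes are the incident edge counts,
    stored as a ``degree`` attribute.
    """
    if target_kind not in ("rate", "enzyme"):
        raise ValueError("target_kind must be 'rate' or 'enzyme'")
    if threshold is None:
        threshold = RATE_THRESHOLD if target_kind == "rate" else ENZYME_THRESHOLD
    net = nx.DiGraph(target_kind=target_kind, threshold=float(threshold))
    for factor in table.index:
        net.add_node(str(factor), kind="factor")
    for met in table.columns:
        net.add_node(str(met), kind="metabolite")
    for factor in table.index:
        for met in table.columns:
            log2_ratio = table.loc[factor, met]
            if not np.isfinite(log2_ratio):
                continue
            raw_ratio = 2.0**log2_ratio
            if abs(raw_ratio - 1.0) > threshold:
                net.add_edge(
                    str(factor),
                    str(met),
                    sign="up" if log2_ratio > 0 else "down",
                    weight=float(abs(log2_ratio)),
                )
    for node in net.nodes:
        net.nodes[node]["degree"] = int(net.in_degree(node) + net.out_degree(node))
    return net


def _edge_frame(net: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {
            "source": u,
            "target": v,
            "sign": d["sign"],
            "weight": d["weight"],
            "source_kind": net.nodes[u]["kind"],
            "target_kind": net.nodes[v]["kind"],
            "source_degree": net.nodes[u]["degree"],
            "target_degree": net.nodes[v]["degree"],
        }
        for u, v, d in net.edges(data=True)
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "source", "target", "sign", "weight",
            "source_kind", "target_kind", "source_degree", "target_degree",
        ],
    )
    return frame.sort_values(["source", "target"], ignore_index=True)


def export_network(net: nx.DiGraph, path: str) -> None:
    """Write the network as GraphML (.graphml) or edge-list CSV (.csv)."""
    path = str(path)
    if path.endswith(".graphml"):
        nx.write_graphml(net, path)
    elif path.endswith(".csv"):
        _edge_frame(net).to_csv(path, index=False)
    else:
        raise ValueError("unsupported network format (use .graphml or .csv)")


def read_network(path: str) -> nx.DiGraph:
    """Inverse of :func:`export_network`."""
    path = str(path)
    if path.endswith(".graphml"):
        g = nx.read_graphml(path)
        net = nx.DiGraph(**g.graph)
        for n, d in g.nodes(data=True):
            net.add_node(n, kind=d["kind"], degree=int(d["degree"]))
        for u, v, d in g.edges(data=True):
            net.add_edge(u, v, sign=d["sign"], weight=float(d["weight"]))
        return net
    if path.endswith(".csv"):
        frame = pd.read_csv(path, float_precision="round_trip")
        net = nx.DiGraph()
        for _, row in frame.iterrows():
            net.add_node(row["source"], kind=row["source_kind"],
                         degree=int(row["source_degree"]))
            net.add_node(row["target"], kind=row["target_kind"],
                         degree=int(row["target_degree"]))
            net.add_edge(row["source"], row["target"], sign=row["sign"],
                         weight=float(row["weight"]))
        return net
    raise ValueError("unsupported network format (use .graphml or .csv)")
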