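"""Dynamic Network Analysis (DyNA): signed per-window correlation networks.

For each consecutive time window, mediator pairs whose trajectories move in
parallel (or anti-parallel) are linked: an undirected edge is created when
the Pearson correlation of the pooled within-window observations satisfies
|r| >= stringency (default 0.7).  Network complexity for a window is the
degree sum over (n - 1):

    complexity = (N_1 + N_2 + ... + N_n) / (n - 1) = 2|E| / (n - 1)

where N_i is the number of connections of mediator i and n is the total
number of mediators analysed.  Complexity counts negative edges identically
to positive ones (the statistic is about co-movement, not direction).

Observations are pooled across subjects AND time points within the window:
with two-point daily windows this is the only strategy that yields usable
sample sizes.  A per-subject first-difference variant is available via
``strategy="subject_delta"``.  No multiple-testing correction is applied —
the procedure is a fixed-threshold rule, and there is no randomness
anywhere in this module.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .panel import MediatorPanel, TimeWindow, window_observations

logger = logging.getLogger("inflamnet")

DEFAULT_STRINGENCY = 0.7
#: Pearson r on fewer than 4 points is dominated by noise; such pairs never form edges.
DEFAULT_MIN_PAIRS = 4

__all__ = [
    "DynaNetwork",
    "ComplexityTrajectory",
    "build_network",
    "network_complexity",
    "complexity_trajectory",
    "total_connections",
    "negative_fraction",
    "focus_subnetwork",
    "edges_frame",
    "write_edge_list",
    "write_sif",
]


@dataclass
class DynaNetwork:
    """One time window's signed, thresholded correlation network.

    ``graph`` is an undirected :class:`networkx.Graph` whose node set is the
    full mediator list (isolated mediators included) and whose edges carry
    ``r`` (Pearson correlation), ``sign`` (``"+"``/``"-"``) and ``n_pairs``
    (complete observation pairs used).
    """

    window: TimeWindow
    mediators: list[str]
    graph: nx.Graph = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.mediators)

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    @property
    def negative_count(self) -> int:
        return sum(1 for _, _, d in self.graph.edges(data=True) if d["sign"] == "-")

    def degree(self, mediator: str) -> int:
        return self.graph.degree(mediator)


@dataclass
class ComplexityTrajectory:
    """Per-window complexity scores for one group/condition."""

    group: str
    points: list[tuple[str, float, int]]  # (window label, complexity, edge count)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["window", "complexity", "edges"]).assign(
            group=self.group
        )[["group", "window", "edges", "complexity"]]


def _transform_values(df: pd.DataFrame, transform: str) -> pd.DataFrame:
    if transform == "raw":
        return df
    if transform == "log10p":
        out = df.copy()
        out["value"] = np.log10(1.0 + out["value"])
        return out
    raise ValueError(f"unknown transform {transform!r}; expected 'raw' or 'log10p'")


def _paired_matrix(obs: pd.DataFrame, mediators: list[str]) -> pd.DataFrame:
    """Pivot windowed observations to one column per mediator.

    Rows are pooled (subject, time) samples; under ``subject_delta`` they are
    within-subject first differences between consecutive window samples.
    """
    return obs.pivot(index=["subject", "time"], columns="mediator", values="value").reindex(
        columns=mediators
    )


def build_network(
    panel: MediatorPanel,
    group: str,
    window: TimeWindow,
    stringency: float = DEFAULT_STRINGENCY,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    transform: str = "raw",
    strategy: str = "pooled",
) -> DynaNetwork:
    """Build the signed correlation network for one group and window.

    For every unordered mediator pair the group's within-window observations
    are pooled; the Pearson r is computed over samples where both mediators
    are non-missing, and an edge is created iff the pair has at least
    ``min_pairs`` complete observations, neither vector is constant, and
    |r| >= ``stringency``.  Constant vectors yield no edge (r is undefined
    there; no co-movement is the conservative reading).  Ties at |r| exactly
    equal to the threshold are kept.
    """
    if not 0.0 < stringency <= 1.0:
        raise ValueError("stringency must be in (0, 1]")
    mediators = list(panel.mediators)
    if len(mediators) < 2:
        raise ValueError("need at least 2 mediators to build a network")
    subjects = panel.group_subjects(group)  # raises on unknown group
    obs = window_observations(panel, window, subjects=subjects)
    obs = _transform_values(obs, transform)

    g = nx.Graph()
    g.add_nodes_from(mediators)
    if obs.empty:
        return DynaNetwork(window, mediators, g)

    wide = _paired_matrix(obs, mediators)
    if strategy == "subject_delta":
        wide = wide.groupby(level="subject").diff().dropna(how="all")
    elif strategy != "pooled":
        raise ValueError(f"unknown strategy {strategy!r}")
    x = wide.to_numpy(dtype=float)

    for i, j in itertools.combinations(range(len(mediators)), 2):
        both = ~np.isnan(x[:, i]) & ~np.isnan(x[:, j])
        n_pairs = int(both.sum())
        if n_pairs < max(min_pairs, 2):
            continue
        a, b = x[both, i], x[both, j]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue  # zero variance: r undefined, no edge
        r = float(np.corrcoef(a, b)[0, 1])
        if abs(r) >= stringency:
            g.add_edge(
                mediators[i], mediators[j],
                r=r, sign="+" if r > 0 else "-", n_pairs=n_pairs,
            )
    return DynaNetwork(window, mediators, g)


def network_complexity(net: DynaNetwork) -> float:
    """Degree-sum complexity: sum_i N_i / (n - 1), identically 2|E|/(n-1)."""
    if net.n < 2:
        raise ValueError("complexity requires at least 2 mediators")
    degree_sum = sum(d for _, d in net.graph.degree())
    return degree_sum / (net.n - 1)


def complexity_trajectory(
    panel: MediatorPanel,
    group: str,
    schedule: list[TimeWindow],
    stringency: float = DEFAULT_STRINGENCY,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    **kwargs,
) -> tuple[ComplexityTrajectory, list[DynaNetwork]]:
    """One complexity point per window, in schedule order.

    Windows with no computable pairs yield complexity 0 (logged).  Returns
    the trajectory together with the underlying per-window networks.
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    nets: list[DynaNetwork] = []
    points: list[tuple[str, float, int]] = []
    for window in schedule:
        net = build_network(panel, group, window, stringency, min_pairs, **kwargs)
        if net.edge_count == 0:
            logger.debug("group %s window %s: no edges", group, window.label)
        nets.append(net)
        points.append((window.label, network_complexity(net), net.edge_count))
    return ComplexityTrajectory(group, points), nets


def total_connections(networks: list[DynaNetwork]) -> int:
    """Total connections across all time intervals: sum over windows of |E|."""
    return sum(net.edge_count for net in networks)


def negative_fraction(networks: list[DynaNetwork]) -> tuple[int, int, float]:
    """Count anti-correlated (negative) edges across windows.

    Returns ``(negatives, total, fraction)``; the fraction is reported as
    0.0 when there are no edges at all (flagged by ``total == 0``).
    """
    negatives = sum(net.negative_count for net in networks)
    total = sum(net.edge_count for net in networks)
    fraction = negatives / total if total else 0.0
    return negatives, total, fraction


def focus_subnetwork(net: DynaNetwork, mediator: str) -> DynaNetwork:
    """Restrict the network to edges incident to one mediator of interest.

    The node set is unchanged; only edges touching ``mediator`` (e.g. the
    HMGB1-centred connections of a window) survive.
    """
    if mediator not in net.mediators:
        raise ValueError(f"mediator {mediator!r} not in network")
    g = nx.Graph()
    g.add_nodes_from(net.mediators)
    for u, v, d in net.graph.edges(data=True):
        if mediator in (u, v):
            g.add_edge(u, v, **d)
    return DynaNetwork(net.window, list(net.mediators), g)


# -- tabular export ------------------------------------------------------------


def edges_frame(networks: list[DynaNetwork]) -> pd.DataFrame:
    """Edge list over windows: window, mediator_a, mediator_b, r, sign, n_pairs.

    Pairs are ordered ``mediator_a < mediator_b`` lexicographically.
    """
    rows = []
    for net in networks:
        for u, v, d in net.graph.edges(data=True):
            a, b = sorted((u, v))
            rows.append((net.window.label, a, b, d["r"], d["sign"], d["n_pairs"]))
    df = pd.DataFrame(rows, columns=["window", "mediator_a", "mediator_b", "r", "sign", "n_pairs"])
    return df.sort_values(["window", "mediator_a", "mediator_b"], kind="mergesort").reset_index(
        drop=True
    )


def write_edge_list(networks: list[DynaNetwork], path) -> None:
    edges_frame(networks).to_csv(path, index=False)


def write_sif(net: DynaNetwork, path) -> None:
    """SIF export (node relation node) for graph viewers; relation is the sign."""
    with open(path, "w") as fh:
        for u, v, d in net.graph.edges(data=True):
            a, b = sorted((u, v))
            fh.write(f"{a}\t{'pos' if d['sign'] == '+' else 'neg'}\t{b}\n")
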