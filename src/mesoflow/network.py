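"""Directed-network topology of trial-averaged TE matrices.

The trial-averaged TE matrix is read as a weighted directed graph (nodes =
recording modules, edge weights = TE in nats, no self-loops).  Percolation
prunes links of increasing weight while tracking the fraction of nodes in
the giant strongly connected component (GSCC); the threshold at which the
GSCC first starts to fragment — the descent point — balances the removal of
spurious weak links against the loss of informative ones, and its height
indexes network complexity (a stronger giant component needs more link
removal to fragment).  Hubs are nodes whose out-degree exceeds the mean by
more than two SDs of the degree distribution; comparing hub sets between
the movement-generation (Go) and movement-inhibition (correct Stop)
conditions partitions the nodes into four clusters: C_1 (Go-only hubs),
C_2 (Stop-only hubs), C_3 (hubs in both) and C_4 (never hubs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import kruskal, mannwhitneyu

from .te import TEMatrix

logger = logging.getLogger("mesoflow.network")

__all__ = [
    "PercolationCurve",
    "DegreeProfile",
    "ClusterAssignment",
    "gscc",
    "percolation_curve",
    "threshold_for_analysis",
    "vertex_degrees",
    "detect_hubs",
    "assign_clusters",
    "robustness_curves",
    "compare_groups",
    "CLUSTER_LABELS",
]

CLUSTER_LABELS = ("C1", "C2", "C3", "C4")


def _as_matrix(te) -> np.ndarray:
    if isinstance(te, TEMatrix):
        return te.values
    return np.asarray(te, dtype=float)


def _digraph(values: np.ndarray, min_weight_exclusive: float | None = None) -> nx.DiGraph:
    """Weighted digraph of the positive entries; optionally keep only links
    with weight strictly above a threshold."""
    g = nx.DiGraph()
    n = values.shape[0]
    g.add_nodes_from(range(n))
    src, dst = np.nonzero(values > (0.0 if min_weight_exclusive is None
                                    else min_weight_exclusive))
    for i, j in zip(src.tolist(), dst.tolist()):
        if i != j:
            g.add_edge(i, j, weight=float(values[i, j]))
    return g


def gscc(graph) -> set[int]:
    """Largest strongly connected component (ties -> smallest member index)."""
    if isinstance(graph, (TEMatrix, np.ndarray)):
        graph = _digraph(_as_matrix(graph))
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = list(nx.strongly_connected_components(graph))
    return max(comps, key=lambda s: (len(s), -min(s)))


@dataclass
class PercolationCurve:
    """GSCC fraction as a function of the link-weight pruning threshold.

    At threshold t the graph keeps the links with weight > t; the sweep
    starts at t = 0 (all positive links) and visits every distinct positive
    weight.  ``descent_point`` is the smallest threshold at which the GSCC
    fraction first drops below its initial value; ``slope`` is the secant
    magnitude of the descending segment (fraction lost per unit weight).
    """

    thresholds: np.ndarray
    gscc_fraction: np.ndarray
    descent_point: float | None
    slope: float
    n_nodes: int

    def n_steps(self) -> int:
        """Number of distinct downward steps of the curve."""
        return int(np.sum(np.diff(self.gscc_fraction) < 0))


def percolation_curve(te, slope_method: str = "secant") -> PercolationCurve:
    """Percolation of the giant strongly connected component.

    ``slope_method``: "secant" (default) uses the two endpoints of the
    descending segment; "least-squares" fits a line to the whole segment.
    """
    values = _as_matrix(te)
    n = values.shape[0]
    pos = values[values > 0]
    if pos.size == 0:
        raise ValueError("percolation requires at least one positive link")
    weights = np.unique(pos)
    thresholds = np.concatenate(([0.0], weights))
    frac = np.empty(len(thresholds))
    for k, t in enumerate(thresholds):
        frac[k] = len(gscc(_digraph(values, min_weight_exclusive=t))) / n

    below = np.nonzero(frac < frac[0])[0]
    if below.size == 0:
        descent = None
        slope = float("nan")
    else:
        i_d = int(below[0])
        descent = float(thresholds[i_d])
        t_term, f_term = thresholds[-1], frac[-1]
        if t_term == descent:
            slope = float("nan")
        elif slope_method == "secant":
            slope = float((frac[i_d] - f_term) / (t_term - descent))
        elif slope_method == "least-squares":
            seg = slice(i_d, len(thresholds))
            a = np.polyfit(thresholds[seg], frac[seg], 1)
            slope = float(-a[0])
        else:
            raise ValueError("slope_method must be 'secant' or 'least-squares'")
    return PercolationCurve(thresholds=thresholds, gscc_fraction=frac,
                            descent_point=descent, slope=slope, n_nodes=n)


def threshold_for_analysis(curve: PercolationCurve, te) -> np.ndarray:
    """Thresholded adjacency: the last configuration before fragmentation.

    Keeps the links whose weight is at least the descent point, i.e. the
    graph pruned just short of the threshold at which the GSCC begins to
    fragment — the best balance between removing spurious weak links and
    losing informative ones.  On a degenerate curve with no descent all
    positive links are retained with a warning.
    """
    values = _as_matrix(te).copy()
    if curve.descent_point is None:
        logger.warning("no descent point; retaining all positive links")
        values[values < 0] = 0.0
        return values
    values[values < curve.descent_point] = 0.0
    return values


@dataclass
class DegreeProfile:
    """Per-node in/out link counts of a (thresholded) directed graph."""

    in_degree: np.ndarray
    out_degree: np.ndarray

    def __post_init__(self):
        if int(self.in_degree.sum()) != int(self.out_degree.sum()):
            raise ValueError("in/out degree totals must both equal the link count")

    @property
    def n_links(self) -> int:
        return int(self.out_degree.sum())


def vertex_degrees(graph) -> DegreeProfile:
    """VD_i = sum_j a_ij of the binarized adjacency, split by direction."""
    a = _as_matrix(graph)
    binary = (a > 0).astype(int)
    np.fill_diagonal(binary, 0)
    return DegreeProfile(in_degree=binary.sum(axis=0),
                         out_degree=binary.sum(axis=1))


def detect_hubs(profile: DegreeProfile, direction: str = "out",
                sd_mult: float = 2.0) -> set[int]:
    """Nodes whose degree exceeds mean + ``sd_mult`` SD of the distribution.

    Cortical information-spreading hubs appear in the out-degree
    distribution; the SD uses the sample convention (ddof = 1) and the
    comparison is strict, so a uniform degree distribution has no hubs.
    """
    d = profile.out_degree if direction == "out" else profile.in_degree
    if len(d) < 5:
        raise ValueError("hub detection requires at least 5 nodes")
    thr = d.mean() + sd_mult * d.std(ddof=1)
    return {int(i) for i in np.nonzero(d > thr)[0]}


@dataclass
class ClusterAssignment:
    """Node partition by hub status across behavioral conditions."""

    labels: dict[int, str]                  # node -> C1/C2/C3/C4
    hubs: dict[str, set[int]] = field(default_factory=dict)
    anomalies: set[int] = field(default_factory=set)

    def nodes(self, label: str) -> set[int]:
        return {n for n, l in self.labels.items() if l == label}

    def sizes(self) -> dict[str, int]:
        return {lab: len(self.nodes(lab)) for lab in CLUSTER_LABELS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": sorted(self.labels),
             "cluster": [self.labels[n] for n in sorted(self.labels)],
             "anomaly": [n in self.anomalies for n in sorted(self.labels)]})


def assign_clusters(
    hubs_go: set[int],
    hubs_correct_stop: set[int],
    hubs_wrong_stop: set[int] | None = None,
    n_nodes: int | None = None,
) -> ClusterAssignment:
    """C_1 = Go-only hubs, C_2 = correct-Stop-only, C_3 = both, C_4 = never.

    Nodes that are hubs only in wrong-Stop trials are flagged as anomalies
    (none are expected: errors recruit the same clusters as the two correct
    outcomes, with no new hubs).
    """
    hubs_wrong_stop = hubs_wrong_stop or set()
    universe = hubs_go | hubs_correct_stop | hubs_wrong_stop
    if n_nodes is not None:
        if any(h >= n_nodes or h < 0 for h in universe):
            raise ValueError("hub index outside the node universe")
        nodes = range(n_nodes)
    else:
        nodes = range(max(universe) + 1 if universe else 0)
    labels = {}
    for v in nodes:
        in_go, in_stop = v in hubs_go, v in hubs_correct_stop
        if in_go and in_stop:
            labels[v] = "C3"
        elif in_go:
            labels[v] = "C1"
        elif in_stop:
            labels[v] = "C2"
        else:
            labels[v] = "C4"
    anomalies = hubs_wrong_stop - hubs_go - hubs_correct_stop
    if anomalies:
        logger.warning("nodes %s are hubs only in wrong-Stop trials",
                       sorted(anomalies))
    return ClusterAssignment(
        labels=labels,
        hubs={"go": set(hubs_go), "correct_stop": set(hubs_correct_stop),
              "wrong_stop": set(hubs_wrong_stop)},
        anomalies=anomalies,
    )


def robustness_curves(te, clusters: ClusterAssignment,
                      curve: PercolationCurve | None = None) -> pd.DataFrame:
    """Mean out-degree of each cluster as percolation progresses.

    For every pruning threshold of the percolation sweep the per-cluster
    mean VD_out is recorded; a cluster whose links carry high and robust
    information content stays on top as weak links are peeled away.  Empty
    clusters are omitted (logged).
    """
    values = _as_matrix(te)
    if curve is None:
        curve = percolation_curve(values)
    rows = []
    present = [lab for lab in CLUSTER_LABELS if clusters.nodes(lab)]
    for lab in set(CLUSTER_LABELS) - set(present):
        logger.info("cluster %s is empty; curve omitted", lab)
    for t in curve.thresholds:
        pruned = np.where(values > t, values, 0.0)
        deg = vertex_degrees(pruned)
        for lab in present:
            nodes = sorted(clusters.nodes(lab))
            rows.append({"threshold": float(t), "cluster": lab,
                         "mean_vd_out": float(deg.out_degree[nodes].mean())})
    return pd.DataFrame(rows)


def compare_groups(groups: dict[str, np.ndarray], alpha: float = 0.01) -> dict:
    """Kruskal-Wallis across groups with Bonferroni-corrected pairwise
    follow-ups (two-sided Mann-Whitney); reports H, p and adjusted p."""
    names = list(groups)
    if len(names) < 2:
        raise ValueError("group comparison requires at least 2 groups")
    samples = [np.asarray(groups[k], dtype=float) for k in names]
    h_stat, p = kruskal(*samples)
    pairs = list(combinations(range(len(names)), 2))
    m = len(pairs)
    pairwise = []
    for i, j in pairs:
        _, p_ij = mannwhitneyu(samples[i], samples[j], alternative="two-sided")
        pairwise.append({
            "group_a": names[i], "group_b": names[j],
            "p": float(p_ij), "p_adjusted": float(min(1.0, p_ij * m)),
        })
    return {
        "H": float(h_stat), "p": float(p), "alpha": alpha,
        "significant": bool(p < alpha), "pairwise": pairwise,
    }
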