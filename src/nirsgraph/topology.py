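"""Graph-theoretical characterization of subject graphs.

Metrics are computed on the *binarized* topology (an edge exists where
the thresholded weight is nonzero): density, mean degree, mean nodal
clustering, global efficiency, isolated-node ratio and giant-component
ratio. Used both for the fixed-threshold RAW vs COMPLEXITY comparison
and for the 0.2-0.6 threshold sensitivity sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .graphs import SubjectGraph, threshold_graph

METRIC_NAMES = (
    "density",
    "mean_degree",
    "clustering",
    "global_efficiency",
    "isolated_node_ratio",
    "giant_component_ratio",
)


@dataclass(frozen=True)
class TopologyMetrics:
    density: float
    mean_degree: float
    clustering: float
    global_efficiency: float
    isolated_node_ratio: float
    giant_component_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def _metrics_from_binary(A: np.ndarray) -> TopologyMetrics:
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    G = nx.from_numpy_array((A != 0).astype(int))
    n_edges = G.number_of_edges()
    degrees = np.array([d for _, d in G.degree()])
    comps = list(nx.connected_components(G))
    giant = max(len(c) for c in comps) if comps else 0
    # an isolated node is its own component of size 1; giant ratio counts it
    return TopologyMetrics(
        density=2 * n_edges / (n * (n - 1)),
        mean_degree=2 * n_edges / n,
        clustering=nx.average_clustering(G),
        global_efficiency=nx.global_efficiency(G),
        isolated_node_ratio=float((degrees == 0).mean()),
        giant_component_ratio=giant / n,
    )


def graph_metrics(g: SubjectGraph | np.ndarray) -> TopologyMetrics:
    """Six binary topology metrics of a (thresholded) graph."""
    A = g.adjacency if isinstance(g, SubjectGraph) else np.asarray(g)
    return _metrics_from_binary(A)


def threshold_sweep(
    corr: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Topology metrics across a threshold sweep (default 0.2-0.6, step 0.05)."""
    if thresholds is None:
        thresholds = np.round(np.arange(0.20, 0.601, 0.05), 2)
    rows = []
    for t in thresholds:
        A = threshold_graph(corr, float(t))
        rows.append({"threshold": float(t), **_metrics_from_binary(A).as_dict()})
    return pd.DataFrame(rows)


def edge_jaccard_overlap(ga: SubjectGraph, gb: SubjectGraph) -> float:
    """Jaccard similarity of the two graphs' edge sets (node-label pairs).

    Defined as 1 when both edge sets are empty.
    """
    if set(ga.node_labels) != set(gb.node_labels):
        raise ValueError("graphs must share a node label set")
    ea, eb = ga.edge_set(), gb.edge_set()
    union = ea | eb
    if not union:
        return 1.0
    return len(ea & eb) / len(union)


def paired_comparison(
    raw_graphs: list[SubjectGraph], cplx_graphs: list[SubjectGraph]
) -> pd.DataFrame:
    """Wilcoxon signed-rank comparison of topology metrics, per metric.

    Graphs are paired by subject id; differences are COMPLEXITY - RAW.
    All-zero differences yield statistic 0 and p = 1 (flagged degenerate).
    """
    by_id = {g.subject_id: g for g in cplx_graphs}
    pairs = [(g, by_id[g.subject_id]) for g in raw_graphs if g.subject_id in by_id]
    if len(pairs) < 6:
        warnings.warn("fewer than 6 paired subjects: exact p unreliable", stacklevel=2)
    rows = []
    for name in METRIC_NAMES:
        diffs = np.array(
            [
                getattr(graph_metrics(c), name) - getattr(graph_metrics(r), name)
                for r, c in pairs
            ]
        )
        if np.allclose(diffs, 0):
            rows.append(
                {"metric": name, "mean_diff": 0.0, "statistic": 0.0, "p": 1.0, "degenerate": True}
            )
            continue
        stat, p = stats.wilcoxon(diffs)
        rows.append(
            {
                "metric": name,
                "mean_diff": float(diffs.mean()),
                "statistic": float(stat),
                "p": float(p),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)
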