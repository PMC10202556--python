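"""Weighted graph measures on single-subject connectivity matrices.

Conventions (FA-weighted structural connectomes):

* missing edge (NaN) = no connection;
* shortest paths use edge lengths l = 1/w (stronger edge = shorter path);
* betweenness is Brandes' fractional-dependency accounting, endpoints
  excluded, normalized so a star centre scores 1;
* global efficiency is the mean inverse shortest-path length over ordered
  node pairs, unreachable pairs contributing 0;
* nodal strength is the sum of defined incident weights.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .model import Cohort

__all__ = [
    "NodeMeasures",
    "GlobalMeasures",
    "nodal_strength",
    "betweenness_centrality",
    "global_efficiency",
    "mean_nodal_strength",
    "subject_measures",
    "cohort_node_measures",
    "cohort_global_measures",
]


@dataclasses.dataclass
class NodeMeasures:
    strength: np.ndarray
    betweenness: np.ndarray


@dataclasses.dataclass
class GlobalMeasures:
    global_efficiency: float
    mean_nodal_strength: float


def nodal_strength(connectivity: np.ndarray) -> np.ndarray:
    """Sum of defined edge weights incident to each node (missing -> 0)."""
    m = np.array(connectivity, dtype=float)
    np.fill_diagonal(m, np.nan)
    return np.nansum(m, axis=1)


def _to_graph(connectivity: np.ndarray) -> nx.Graph:
    n = connectivity.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(~np.isnan(connectivity), 1))
    g.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / connectivity[i, j]) for i, j in zip(iu, ju)),
        weight="length",
    )
    return g


def betweenness_centrality(connectivity: np.ndarray) -> np.ndarray:
    """Normalized weighted betweenness on lengths l = 1/w.

    All co-minimal shortest paths are counted with fractional accounting
    (Brandes); endpoints are excluded; values are scaled so the centre of a
    star graph scores exactly 1.
    """
    g = _to_graph(connectivity)
    bc = nx.betweenness_centrality(g, normalized=True, weight="length")
    return np.array([bc[i] for i in range(connectivity.shape[0])])


def _length_matrix(connectivity: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        lengths = 1.0 / np.array(connectivity, dtype=float)
    lengths[np.isnan(connectivity)] = np.inf
    np.fill_diagonal(lengths, 0.0)
    return lengths


def global_efficiency(connectivity: np.ndarray) -> float:
    """Mean inverse shortest-path length over node pairs (unreachable -> 0)."""
    n = connectivity.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path(_length_matrix(connectivity), method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def mean_nodal_strength(connectivity: np.ndarray) -> float:
    """Arithmetic mean of nodal strengths."""
    return float(nodal_strength(connectivity).mean())


def subject_measures(connectivity: np.ndarray) -> tuple[NodeMeasures, GlobalMeasures]:
    s = nodal_strength(connectivity)
    return (
        NodeMeasures(strength=s, betweenness=betweenness_centrality(connectivity)),
        GlobalMeasures(global_efficiency=global_efficiency(connectivity),
                       mean_nodal_strength=float(s.mean())),
    )


def cohort_node_measures(cohort: Cohort) -> NodeMeasures:
    """Per-node measures computed per subject, then averaged across subjects."""
    if not cohort.subjects:
        raise ValueError("empty cohort")
    strengths = np.vstack([nodal_strength(s.connectivity) for s in cohort])
    betw = np.vstack([betweenness_centrality(s.connectivity) for s in cohort])
    return NodeMeasures(strength=strengths.mean(axis=0), betweenness=betw.mean(axis=0))


def cohort_global_measures(cohort: Cohort) -> list[GlobalMeasures]:
    """Per-subject global measures (used for group comparisons)."""
    return [
        GlobalMeasures(global_efficiency=global_efficiency(s.connectivity),
                       mean_nodal_strength=mean_nodal_strength(s.connectivity))
        for s in cohort
    ]
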