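"""Graph-theoretic characterization of windowed directed networks.

Networks are directed and weighted (|iPDC| aggregates); edge weights are
converted to path lengths by the reciprocal (a stronger connection is a
shorter path) before shortest-path computations.  Degree is counted on the
thresholded, binarized graph as in-degree + out-degree.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np

from .containers import WindowedNetwork
from .montage import mirror_map

__all__ = [
    "threshold_at_fraction",
    "edge_betweenness",
    "node_degree",
    "flip_right_to_left",
    "group_macro_areas",
]

logger = logging.getLogger(__name__)


def threshold_at_fraction(net: WindowedNetwork, fraction: float = 0.5) -> WindowedNetwork:
    """Keep edges at or above ``fraction`` of the maximum weight.

    Entries strictly below ``fraction * max`` are zeroed; at fraction 1
    only the maximal entry (and exact ties) survives.  An all-zero network
    is returned unchanged with a warning.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    adj = net.adjacency.copy()
    mx = adj.max()
    if mx <= 0:
        warnings.warn("thresholding an all-zero network", stacklevel=2)
        return net.copy()
    adj[adj < fraction * mx] = 0.0
    return net.copy(adjacency=adj)


def _to_digraph(net: WindowedNetwork) -> nx.DiGraph:
    adj = net.adjacency
    if np.any(adj < 0):
        raise ValueError("graph metrics require nonnegative weights")
    G = nx.DiGraph()
    d = net.n_nodes
    G.add_nodes_from(range(d))
    ii, jj = np.nonzero(adj)
    for i, j in zip(ii, jj):
        if i == j:
            continue
        # adjacency[i, j] is the j -> i influence; reciprocal weight = length
        G.add_edge(int(j), int(i), weight=float(adj[i, j]),
                   length=1.0 / float(adj[i, j]))
    return G


def edge_betweenness(net: WindowedNetwork) -> np.ndarray:
    """Edge betweenness centrality on the weighted directed network.

    For every directed edge, the number of all-pairs shortest paths
    (lengths = reciprocal weights) traversing it, with equal fractional
    attribution among tied shortest paths.  Returned as a d × d array in
    the same (target, source) orientation as the adjacency; absent edges
    are zero.
    """
    G = _to_digraph(net)
    bc = nx.edge_betweenness_centrality(G, normalized=False, weight="length")
    out = np.zeros_like(net.adjacency)
    for (j, i), v in bc.items():
        out[i, j] = v
    return out


def node_degree(net: WindowedNetwork) -> np.ndarray:
    """In + out degree per node on the binarized (nonzero-weight) graph."""
    adj = net.adjacency
    binary = (adj > 0).astype(int)
    np.fill_diagonal(binary, 0)
    return binary.sum(axis=0) + binary.sum(axis=1)


def flip_right_to_left(net: WindowedNetwork, montage: list[str] | None = None) -> WindowedNetwork:
    """Mirror a network's electrodes left-right (O2-referenced -> O1 frame).

    Rows and columns are permuted by the 10-10 mirror map so that, e.g.,
    the O2 -> F4 edge of a right-stimulation network lands on O1 -> F3.
    Midline electrodes are fixed points; applying the flip twice restores
    the original.  The montage must be left-right symmetric.
    """
    labels = montage if montage is not None else net.labels
    if labels is None:
        raise ValueError("a montage (label list) is required to flip")
    mm = mirror_map(list(labels))
    idx = {lab: i for i, lab in enumerate(labels)}
    perm = np.array([idx[mm[lab]] for lab in labels])
    adj = net.adjacency[np.ix_(perm, perm)]
    out = net.copy(adjacency=adj)
    out.labels = list(labels)
    return out


def group_macro_areas(degrees, areas: dict[str, str], labels: list[str]) -> dict[str, np.ndarray]:
    """Pool per-node degree values by macro-area membership.

    Parameters
    ----------
    degrees : array-like
        Per-node values aligned with ``labels``.
    areas : dict
        Electrode label -> macro-area name (e.g. from
        :func:`tepnet.montage.macro_area_map`); electrodes absent from the
        map are excluded (logged).
    labels : list of str
        Node labels aligned with ``degrees``.

    Raises
    ------
    ValueError
        If any area referenced by the map ends up empty.
    """
    degrees = np.asarray(degrees)
    pools: dict[str, list] = {}
    for area in set(areas.values()):
        pools[area] = []
    for lab, v in zip(labels, degrees):
        area = areas.get(lab)
        if area is None:
            logger.debug("electrode %s unassigned to any macro area; excluded", lab)
            continue
        pools[area].append(v)
    empty = [a for a, vals in pools.items() if not vals]
    if empty:
        raise ValueError(f"macro area(s) with no electrodes in the montage: {empty}")
    return {a: np.asarray(vals) for a, vals in pools.items()}
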