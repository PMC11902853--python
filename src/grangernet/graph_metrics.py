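"""Binary-network topology metrics.

Four global and four nodal properties are extracted from each subject's
binarized connectivity matrix:

* global: clustering coefficient (GCC), characteristic path length (GCLP),
  global efficiency (GE), global local efficiency (GLE);
* nodal: clustering coefficient (NCC), efficiency (NE), local efficiency
  (NLE), degree centrality (NDC).

Conventions (documented because directed binary graphs admit several):

* Distances are unweighted shortest directed (or undirected) path lengths.
* Unreachable pairs contribute 0 to efficiencies (1/inf = 0) and are
  excluded from the characteristic path length, which errors if no ordered
  pair is reachable.
* Directed clustering follows the Fagiolo generalization: all directed
  triangle motifs through a node over the motif count possible given its
  total degree, corrected for reciprocal edges.
* NDC is total degree (in + out) for directed graphs by default;
  ``degree_mode="out"`` switches to out-degree only.
* A node's neighborhood for NLE is the union of its in- and out-neighbors;
  NLE is the (directed) global efficiency of the induced subgraph, 0 when
  the node has fewer than two neighbors.

With n regions the flattened feature vector has 4 + 4n entries — 468 for
the 116-region atlas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "BinaryNetwork",
    "TopologyFeatures",
    "shortest_path_lengths",
    "global_efficiency",
    "nodal_metrics",
    "global_metrics",
    "feature_vector",
]


@dataclass
class BinaryNetwork:
    """Thresholded 0/1 adjacency; ``adjacency[i, j] = 1`` means edge i -> j."""

    adjacency: np.ndarray
    directed: bool
    density: float
    region_labels: list[str]

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got {a.shape}")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero (no self-loops)")
        if not self.directed and not np.array_equal(a, a.T):
            raise ValueError("undirected network must have symmetric adjacency")
        self.adjacency = a.astype(np.int8)
        self.region_labels = [str(l) for l in self.region_labels]
        if len(self.region_labels) != a.shape[0]:
            raise ValueError("label count must equal node count")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class TopologyFeatures:
    """Flattened topology feature vector with stable names.

    Order: [GCC, GCLP, GE, GLE] then per-region blocks
    [NCC_<label>, NE_<label>, NLE_<label>, NDC_<label>] in label order.
    """

    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.feature_names) != self.values.size:
            raise ValueError("feature name count must match vector length")


def shortest_path_lengths(net: BinaryNetwork) -> np.ndarray:
    """All-pairs unweighted shortest path lengths; inf marks unreachable."""
    d = shortest_path(
        net.adjacency, method="D", directed=net.directed, unweighted=True
    )
    return d


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    return _efficiency_from_distances(shortest_path_lengths(net))


def _clustering(net: BinaryNetwork) -> np.ndarray:
    a = net.adjacency.astype(float)
    if net.directed:
        # Fagiolo directed clustering: closed directed triangle motifs over
        # the number possible given total degree, minus reciprocal pairs.
        s = a + a.T
        num = np.diagonal(s @ s @ s)
        d_tot = a.sum(axis=0) + a.sum(axis=1)
        d_bi = np.diagonal(a @ a)
        denom = 2.0 * (d_tot * (d_tot - 1) - 2.0 * d_bi)
    else:
        num = np.diagonal(a @ a @ a)
        deg = a.sum(axis=1)
        denom = deg * (deg - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, num / denom, 0.0)
    return c


def _local_efficiency(net: BinaryNetwork) -> np.ndarray:
    a = net.adjacency
    n = net.n_nodes
    nle = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero((a[i, :] + a[:, i]) > 0)
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        d = shortest_path(sub, method="D", directed=net.directed, unweighted=True)
        nle[i] = _efficiency_from_distances(d)
    return nle


def nodal_metrics(net: BinaryNetwork, degree_mode: str = "total"):
    """Per-region NCC, NE, NLE, NDC arrays (in that order).

    ``degree_mode`` selects the directed degree convention: ``"total"``
    (in + out, the default) or ``"out"``.
    """
    if net.n_nodes < 2:
        raise ValueError("network must have at least 2 nodes")
    if degree_mode not in ("total", "out"):
        raise ValueError(f"unknown degree_mode {degree_mode!r}")
    a = net.adjacency
    d = shortest_path_lengths(net)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    ne = inv.sum(axis=1) / (net.n_nodes - 1)
    ncc = _clustering(net)
    nle = _local_efficiency(net)
    if net.directed:
        ndc = (a.sum(axis=0) + a.sum(axis=1)).astype(float)
        if degree_mode == "out":
            ndc = a.sum(axis=1).astype(float)
    else:
        ndc = a.sum(axis=1).astype(float)
    return ncc, ne, nle, ndc


@dataclass
class GlobalMetrics:
    gcc: float
    gclp: float
    ge: float
    gle: float


def global_metrics(net: BinaryNetwork) -> GlobalMetrics:
    """GCC, GCLP, GE, GLE of a binary network.

    GCC and GLE are the means of the nodal clustering and local-efficiency
    vectors; GCLP averages finite distances over reachable ordered pairs and
    is rejected when no off-diagonal pair is reachable.
    """
    ncc, _, nle, _ = nodal_metrics(net)
    d = shortest_path_lengths(net)
    mask = np.isfinite(d)
    np.fill_diagonal(mask, False)
    if not mask.any():
        raise ValueError("characteristic path length undefined: no reachable pair")
    gclp = float(d[mask].mean())
    return GlobalMetrics(
        gcc=float(ncc.mean()),
        gclp=gclp,
        ge=_efficiency_from_distances(d),
        gle=float(nle.mean()),
    )


def feature_vector(net: BinaryNetwork, degree_mode: str = "total") -> TopologyFeatures:
    """Flatten global + nodal metrics into the stable 4 + 4n feature order."""
    g = global_metrics(net)
    ncc, ne, nle, ndc = nodal_metrics(net, degree_mode=degree_mode)
    values = [g.gcc, g.gclp, g.ge, g.gle]
    names = ["GCC", "GCLP", "GE", "GLE"]
    for i, lab in enumerate(net.region_labels):
        values += [ncc[i], ne[i], nle[i], ndc[i]]
        names += [f"NCC_{lab}", f"NE_{lab}", f"NLE_{lab}", f"NDC_{lab}"]
    return TopologyFeatures(np.asarray(values), names)
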