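"""Proportional thresholding with global cost-efficiency selection.

A weighted connectivity matrix is binarized by keeping the strongest
fraction PSW of its possible off-diagonal connections (proportional
thresholding).  The retained fraction is chosen by maximizing the global
cost efficiency

    GCE(PSW) = E(PSW) - PSW

where E is the global efficiency of the binarized network: efficiency is
bought at the price of wiring cost, and the maximizer keeps dense local
and sparse long-range connections.  Following the group-level usage of a
single optimum per method, the scan averages GCE across subjects per grid
point (default grid 0.05 to 0.50, step 0.05) and applies one selected PSW
to every subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .graph_metrics import BinaryNetwork, global_efficiency

__all__ = [
    "ThresholdScan",
    "default_grid",
    "proportional_binarize",
    "global_cost_efficiency",
    "select_threshold",
]


def default_grid() -> np.ndarray:
    """PSW candidates 0.05, 0.10, ..., 0.50."""
    return np.round(np.arange(1, 11) * 0.05, 2)


@dataclass
class ThresholdScan:
    """Grid scan of mean efficiency / cost efficiency across subjects."""

    grid: np.ndarray
    mean_efficiency: np.ndarray
    mean_gce: np.ndarray
    selected_psw: float
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"psw": self.grid, "mean_E": self.mean_efficiency, "mean_GCE": self.mean_gce}
        )


def _ranked_edges(w: ConnectivityMatrix):
    """Off-diagonal entries ordered by (weight desc, row asc, col asc)."""
    n = w.n_regions
    if w.directed:
        rows, cols = np.nonzero(~np.eye(n, dtype=bool))
    else:
        rows, cols = np.triu_indices(n, k=1)
    vals = w.weights[rows, cols]
    order = np.lexsort((cols, rows, -vals))
    return rows[order], cols[order], vals[order]


def proportional_binarize(w: ConnectivityMatrix, psw: float) -> BinaryNetwork:
    """Keep the ``floor(psw * M)`` strongest off-diagonal weights.

    M counts possible connections: n(n-1) for directed matrices,
    n(n-1)/2 for undirected (retained edges are mirrored into both
    triangles).  Ties break deterministically by weight descending, then
    row index, then column index.
    """
    if not 0 < psw <= 1:
        raise ValueError(f"psw must lie in (0, 1], got {psw}")
    if np.any(w.weights < 0):
        raise ValueError("proportional thresholding needs non-negative weights; normalize first")
    n = w.n_regions
    m = n * (n - 1) if w.directed else n * (n - 1) // 2
    k = int(np.floor(psw * m))
    if k < 1:
        raise ValueError(f"psw={psw} retains no edges out of {m} possible")
    rows, cols, _ = _ranked_edges(w)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[rows[:k], cols[:k]] = 1
    if not w.directed:
        adj = adj | adj.T
    return BinaryNetwork(adj, directed=w.directed, density=k / m, region_labels=w.region_labels)


def global_cost_efficiency(w: ConnectivityMatrix, psw: float) -> float:
    """GCE = global efficiency of the binarized network minus the cost PSW."""
    return global_efficiency(proportional_binarize(w, psw)) - psw


def select_threshold(w_list: list[ConnectivityMatrix], grid=None) -> ThresholdScan:
    """Scan the PSW grid, averaging GCE across subjects, and select the
    argmax (ties to the smaller PSW).  Grid points that would retain no
    edge are skipped with a warning recorded on the scan."""
    if not w_list:
        raise ValueError("need at least one subject matrix")
    directed = w_list[0].directed
    if any(w.directed != directed for w in w_list):
        raise ValueError("matrices mix directed and undirected")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and strictly ascending")
    kept, mean_e, mean_gce, warnings = [], [], [], []
    for psw in grid:
        try:
            effs = [global_efficiency(proportional_binarize(w, psw)) for w in w_list]
        except ValueError as exc:
            warnings.append(f"psw={psw:g} skipped: {exc}")
            continue
        kept.append(psw)
        mean_e.append(float(np.mean(effs)))
        mean_gce.append(float(np.mean(effs)) - psw)
    if not kept:
        raise ValueError("no feasible grid point for these matrices")
    mean_gce_arr = np.asarray(mean_gce)
    best = int(np.argmax(mean_gce_arr))  # first max -> smaller psw on ties
    return ThresholdScan(
        grid=np.asarray(kept),
        mean_efficiency=np.asarray(mean_e),
        mean_gce=mean_gce_arr,
        selected_psw=float(kept[best]),
        warnings=warnings,
    )
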