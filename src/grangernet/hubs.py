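"""Hub-region identification from group-level weighted directed networks.

Four rankings are computed on normalized group-mean connectivity:

* Top-20 strongest connections (LCS) per group;
* Top-20 most dissimilar connections (GDC) between patient and control
  group means (largest absolute differences, sign retained to mark
  increased vs decreased coupling);
* Top-5 regions by out-strength (HODR) per group — row sums, i.e. a
  region's total driving influence;
* Top-5 regions by out-strength dissimilarity (GDR) between groups.

A region is declared a hub when it appears in at least ``min_lists`` of
the four lists (edge lists contribute both endpoints, counted at most
once per list), echoing consensus-frequency hub maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

__all__ = [
    "Edge",
    "RegionScore",
    "HubReport",
    "group_mean_matrix",
    "top_connections",
    "dissimilar_connections",
    "out_strength_ranking",
    "out_strength_dissimilarity",
    "hub_consensus",
]


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    value: float


@dataclass(frozen=True)
class RegionScore:
    region: str
    value: float


@dataclass
class HubReport:
    top_lcs: list[Edge]
    top_gdc: list[Edge]
    top_hodr: list[RegionScore]
    top_gdr: list[RegionScore]
    hub_frequency: dict[str, int]
    hubs: list[str]
    min_lists: int = 2
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "top_lcs": [vars(e) for e in self.top_lcs],
            "top_gdc": [vars(e) for e in self.top_gdc],
            "top_hodr": [vars(r) for r in self.top_hodr],
            "top_gdr": [vars(r) for r in self.top_gdr],
            "hub_frequency": self.hub_frequency,
            "hubs": self.hubs,
            "min_lists": self.min_lists,
            "warnings": self.warnings,
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def frequency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.hub_frequency.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["region", "frequency"],
        )


def group_mean_matrix(w_list: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Elementwise mean of same-shaped subject matrices."""
    if not w_list:
        raise ValueError("no matrices")
    first = w_list[0]
    for w in w_list[1:]:
        if w.weights.shape != first.weights.shape or w.region_labels != first.region_labels:
            raise ValueError("matrices differ in shape or labels")
        if w.method != first.method or w.directed != first.directed:
            raise ValueError("matrices differ in method")
    return replace(first, weights=np.mean([w.weights for w in w_list], axis=0))


def _sorted_offdiag(values: np.ndarray, directed: bool):
    n = values.shape[0]
    if directed:
        rows, cols = np.nonzero(~np.eye(n, dtype=bool))
    else:
        rows, cols = np.triu_indices(n, k=1)
    vals = values[rows, cols]
    order = np.lexsort((cols, rows, -vals))
    return rows[order], cols[order]


def top_connections(w_mean: ConnectivityMatrix, k: int = 20) -> list[Edge]:
    """The k strongest off-diagonal connections, sorted descending.

    If fewer than k connections exist the list is truncated."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rows, cols = _sorted_offdiag(w_mean.weights, w_mean.directed)
    labels = w_mean.region_labels
    k = min(k, rows.size)
    return [
        Edge(labels[r], labels[c], float(w_mean.weights[r, c]))
        for r, c in zip(rows[:k], cols[:k])
    ]


def dissimilar_connections(
    w_patient_mean: ConnectivityMatrix, w_control_mean: ConnectivityMatrix, k: int = 20
) -> list[Edge]:
    """The k connections with the largest |patient - control| difference;
    the signed difference is kept so increases and decreases stay
    distinguishable."""
    if w_patient_mean.weights.shape != w_control_mean.weights.shape:
        raise ValueError("group matrices differ in shape")
    if w_patient_mean.region_labels != w_control_mean.region_labels:
        raise ValueError("group matrices differ in labels")
    delta = w_patient_mean.weights - w_control_mean.weights
    rows, cols = _sorted_offdiag(np.abs(delta), w_patient_mean.directed)
    labels = w_patient_mean.region_labels
    k = min(max(k, 1), rows.size)
    return [
        Edge(labels[r], labels[c], float(delta[r, c]))
        for r, c in zip(rows[:k], cols[:k])
    ]


def _rank_regions(scores: np.ndarray, labels: list[str], k: int) -> list[RegionScore]:
    order = np.lexsort((np.arange(scores.size), -scores))
    k = min(max(k, 1), scores.size)
    return [RegionScore(labels[i], float(scores[i])) for i in order[:k]]


def out_strength_ranking(w_mean: ConnectivityMatrix, k: int = 5) -> list[RegionScore]:
    """Top-k regions by out-strength (row sum of outgoing weights)."""
    if not w_mean.directed:
        raise ValueError("out-strength ranking needs a directed matrix")
    return _rank_regions(w_mean.weights.sum(axis=1), w_mean.region_labels, k)


def out_strength_dissimilarity(
    w_patient_mean: ConnectivityMatrix, w_control_mean: ConnectivityMatrix, k: int = 5
) -> list[RegionScore]:
    """Top-k regions by |out-strength difference| between the groups, with
    the signed difference (patient - control) retained."""
    if w_patient_mean.weights.shape != w_control_mean.weights.shape:
        raise ValueError("group matrices differ in shape")
    if not (w_patient_mean.directed and w_control_mean.directed):
        raise ValueError("out-strength dissimilarity needs directed matrices")
    delta = w_patient_mean.weights.sum(axis=1) - w_control_mean.weights.sum(axis=1)
    order = np.lexsort((np.arange(delta.size), -np.abs(delta)))
    k = min(max(k, 1), delta.size)
    return [
        RegionScore(w_patient_mean.region_labels[i], float(delta[i])) for i in order[:k]
    ]


def hub_consensus(
    lcs: list[Edge],
    gdc: list[Edge],
    hodr: list[RegionScore],
    gdr: list[RegionScore],
    min_lists: int = 2,
) -> HubReport:
    """Count each region's appearances across the four lists and declare
    hubs where the frequency reaches ``min_lists``.  Edge lists contribute
    both endpoints, at most once per list."""
    sets = [
        {e.source for e in lcs} | {e.target for e in lcs},
        {e.source for e in gdc} | {e.target for e in gdc},
        {r.region for r in hodr},
        {r.region for r in gdr},
    ]
    freq: dict[str, int] = {}
    for s in sets:
        for region in s:
            freq[region] = freq.get(region, 0) + 1
    hubs = sorted(
        (r for r, f in freq.items() if f >= min_lists),
        key=lambda r: (-freq[r], r),
    )
    return HubReport(
        top_lcs=list(lcs),
        top_gdc=list(gdc),
        top_hodr=list(hodr),
        top_gdr=list(gdr),
        hub_frequency=freq,
        hubs=hubs,
        min_lists=min_lists,
    )
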