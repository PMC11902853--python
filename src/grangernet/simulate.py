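"""Synthetic stationary MVAR cohorts with a known directed causal graph.

No public recordings accompany the clinical study this pipeline targets,
so every downstream stage is exercised on simulated region-of-interest
signals whose ground truth is known exactly.  A subject is a realization
of a stationary vector autoregression

    x_t = sum_{k=1..p} A_k x_{t-k} + e_t,   e_t ~ N(0, Q),

with the directed causal graph given by the support of the off-diagonal
coefficients (edge i -> j iff some A_k[j, i] != 0).  A two-group cohort
plants a group difference by adding a fixed increment to the lag-1 gains
of designated edges in the patient-like group — an additive effect on
coupling strength, not on noise power, mirroring elevated directed
connectivity in the patient group.

Stationarity is enforced through the companion form: the spectral radius
of the (n*p) x (n*p) companion matrix must be < 1, checked for every
emitted subject.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .graph_metrics import BinaryNetwork
from .timeseries import ROITimeSeries, write_roi_timeseries

__all__ = [
    "SimulationSpec",
    "CohortSpec",
    "Cohort",
    "companion_matrix",
    "spectral_radius",
    "simulate_mvar",
    "make_cohort",
    "ground_truth_graph",
    "random_stable_spec",
    "order5_benchmark_spec",
    "demo_cohort_spec",
    "order_study_cohort_spec",
    "write_cohort",
]

DEFAULT_BURN_IN = 500
DEFAULT_SAMPLING_RATE_HZ = 500.0
_MAX_RADIUS = 1.0 - 1e-9


def companion_matrix(coeff_matrices: np.ndarray) -> np.ndarray:
    """Stack VAR(p) coefficients into the (n*p) x (n*p) companion form."""
    p, n, _ = coeff_matrices.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(coeff_matrices), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return comp


def spectral_radius(coeff_matrices: np.ndarray) -> float:
    """Largest eigenvalue magnitude of the companion matrix."""
    return float(np.abs(np.linalg.eigvals(companion_matrix(coeff_matrices))).max())


@dataclass
class SimulationSpec:
    """One subject's generative model (see module docstring for the recursion)."""

    n_regions: int
    order: int
    coeff_matrices: np.ndarray  # (order, n, n)
    noise_cov: np.ndarray  # (n, n), positive definite
    n_samples: int
    burn_in: int = DEFAULT_BURN_IN
    seed: int = 0
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.coeff_matrices = np.asarray(self.coeff_matrices, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        p, n, m = self.coeff_matrices.shape
        if (p, n, m) != (self.order, self.n_regions, self.n_regions):
            raise ValueError(
                f"coefficient array shape {self.coeff_matrices.shape} does not "
                f"match (order={self.order}, n={self.n_regions})"
            )
        sr = spectral_radius(self.coeff_matrices)
        if sr >= _MAX_RADIUS:
            raise ValueError(
                f"non-stationary coefficients: companion spectral radius {sr:.4f} >= 1"
            )
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise covariance must be symmetric")
        try:
            np.linalg.cholesky(self.noise_cov)
        except np.linalg.LinAlgError:
            raise ValueError("noise covariance must be positive definite")
        if self.n_samples < self.order + 1:
            raise ValueError("n_samples must be at least order + 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")
        if self.region_labels is None:
            self.region_labels = [f"ROI_{i + 1:03d}" for i in range(self.n_regions)]


@dataclass
class CohortSpec:
    """Two-group cohort: group_a is the base process, group_b gets
    ``effect_gain`` added to the lag-``effect_lag`` gain of every edge in
    ``effect_edges`` ((source, target) node indices)."""

    n_group_a: int
    n_group_b: int
    base_spec: SimulationSpec
    effect_edges: list[tuple[int, int]] = field(default_factory=list)
    effect_gain: float = 0.0
    effect_lag: int = 1
    seed: int = 0
    group_a_label: str = "HC"
    group_b_label: str = "TLE"

    def __post_init__(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("both groups need at least one subject")
        if self.effect_gain < 0:
            raise ValueError("effect_gain must be >= 0")
        if not 1 <= self.effect_lag <= self.base_spec.order:
            raise ValueError(
                f"effect_lag {self.effect_lag} outside 1..{self.base_spec.order}"
            )
        n = self.base_spec.n_regions
        for s, t in self.effect_edges:
            if not (0 <= s < n and 0 <= t < n) or s == t:
                raise ValueError(f"invalid effect edge ({s}, {t}) for {n} regions")


@dataclass
class Cohort:
    subjects: list[ROITimeSeries]
    spec: CohortSpec
    subject_seeds: list[int]

    @property
    def labels(self) -> list[str]:
        return [s.group for s in self.subjects]


def simulate_mvar(spec: SimulationSpec) -> ROITimeSeries:
    """Draw one realization of the VAR recursion, burn-in discarded."""
    rng = np.random.default_rng(spec.seed)
    p, n = spec.order, spec.n_regions
    total = spec.burn_in + spec.n_samples + p
    chol = np.linalg.cholesky(spec.noise_cov)
    innov = rng.standard_normal((total, n)) @ chol.T
    x = np.zeros((total, n))
    a = spec.coeff_matrices
    for t in range(p, total):
        acc = innov[t].copy()
        for k in range(p):
            acc += a[k] @ x[t - k - 1]
        x[t] = acc
    data = x[p + spec.burn_in :].T
    return ROITimeSeries(
        data, spec.region_labels, spec.sampling_rate_hz, subject_id="", group=""
    )


def _child_seed(seed: int, index: int) -> int:
    # deterministic per-subject seed: SeedSequence on (cohort seed, index)
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def _effect_coeffs(spec: CohortSpec) -> np.ndarray:
    a = spec.base_spec.coeff_matrices.copy()
    for s, t in spec.effect_edges:
        a[spec.effect_lag - 1, t, s] += spec.effect_gain
    return a


def make_cohort(cohort: CohortSpec) -> Cohort:
    """Simulate all subjects of both groups with reproducible per-subject seeds."""
    subjects, seeds = [], []
    n_total = cohort.n_group_a + cohort.n_group_b
    eff = _effect_coeffs(cohort)
    sr = spectral_radius(eff)
    if sr >= _MAX_RADIUS:
        raise ValueError(
            f"effect_gain {cohort.effect_gain} makes group "
            f"{cohort.group_b_label} non-stationary (spectral radius {sr:.4f})"
        )
    for i in range(n_total):
        in_b = i >= cohort.n_group_a
        group = cohort.group_b_label if in_b else cohort.group_a_label
        idx = i - cohort.n_group_a if in_b else i
        sid = f"{group}_{idx + 1:02d}"
        seed_i = _child_seed(cohort.seed, i)
        spec_i = replace(
            cohort.base_spec,
            coeff_matrices=eff if in_b else cohort.base_spec.coeff_matrices,
            seed=seed_i,
        )
        try:
            ts = simulate_mvar(spec_i)
        except ValueError as exc:
            raise ValueError(f"subject {sid}: {exc}") from exc
        subjects.append(replace(ts, subject_id=sid, group=group))
        seeds.append(seed_i)
    return Cohort(subjects, cohort, seeds)


def ground_truth_graph(spec: SimulationSpec) -> BinaryNetwork:
    """Directed adjacency: edge i -> j iff any lag has a nonzero gain of
    channel i in channel j's equation (off-diagonal support)."""
    a = spec.coeff_matrices
    adj = (np.abs(a) > 0).any(axis=0).T.astype(np.int8)  # A_k[j, i] -> adj[i, j]
    np.fill_diagonal(adj, 0)
    n = spec.n_regions
    density = float(adj.sum() / (n * (n - 1))) if n > 1 else 0.0
    return BinaryNetwork(adj, directed=True, density=density, region_labels=spec.region_labels)


def _rescale_to_radius(a: np.ndarray, target: float) -> np.ndarray:
    """Shrink coefficients until the companion spectral radius <= target."""
    a = a.copy()
    for _ in range(200):
        sr = spectral_radius(a)
        if sr <= target:
            return a
        a *= 0.98 * target / sr
    raise ValueError("could not rescale coefficients to a stable process")


def random_stable_spec(
    n_regions: int = 20,
    order: int = 2,
    n_samples: int = 1000,
    *,
    n_cross_edges: int = 30,
    cross_gain: float = 0.25,
    diag_gain: float = 0.35,
    target_radius: float = 0.9,
    seed: int = 0,
    region_labels: list[str] | None = None,
) -> SimulationSpec:
    """Random sparse stable MVAR: AR(1)-style diagonals plus ``n_cross_edges``
    random off-diagonal couplings of magnitude ``cross_gain`` placed at
    random lags, rescaled to the target companion spectral radius."""
    rng = np.random.default_rng(seed)
    a = np.zeros((order, n_regions, n_regions))
    a[0] += np.eye(n_regions) * diag_gain
    pairs = [(i, j) for i in range(n_regions) for j in range(n_regions) if i != j]
    chosen = rng.choice(len(pairs), size=min(n_cross_edges, len(pairs)), replace=False)
    for c in chosen:
        src, tgt = pairs[c]
        lag = rng.integers(order)
        a[lag, tgt, src] += cross_gain * rng.choice([-1.0, 1.0])
    a = _rescale_to_radius(a, target_radius)
    return SimulationSpec(
        n_regions=n_regions,
        order=order,
        coeff_matrices=a,
        noise_cov=np.eye(n_regions),
        n_samples=n_samples,
        seed=seed,
        region_labels=region_labels,
    )


def order5_benchmark_spec(n_channels: int = 5, n_samples: int = 1000, seed: int = 0) -> SimulationSpec:
    """Fixed 5-channel process of true order 5 for lag-order selection studies.

    Each channel follows x_t = 0.3 x_{t-1} - 0.5 x_{t-5} + ring coupling
    0.2 from its predecessor channel at lag 5, unit innovation covariance.
    The dominant lag-5 dynamics make the generating order identifiable.
    """
    a = np.zeros((5, n_channels, n_channels))
    a[0] = 0.3 * np.eye(n_channels)
    a[4] = -0.5 * np.eye(n_channels)
    for i in range(n_channels):
        a[4, i, (i - 1) % n_channels] += 0.2
    return SimulationSpec(
        n_regions=n_channels,
        order=5,
        coeff_matrices=a,
        noise_cov=np.eye(n_channels),
        n_samples=n_samples,
        seed=seed,
    )


def demo_cohort_spec(
    n_regions: int = 20,
    order: int = 2,
    n_samples: int = 1000,
    n_group_a: int = 14,
    n_group_b: int = 34,
    *,
    n_effect_edges: int = 5,
    effect_gain: float = 0.3,
    effect_lag: int = 1,
    n_effect_sources: int = 3,
    seed: int = 0,
) -> CohortSpec:
    """Study-scale synthetic cohort: 14 control-like vs 34 patient-like
    subjects, 1000 samples at 500 Hz, with the patient group's coupling
    raised by ``effect_gain`` on ``n_effect_edges`` edges leaving
    ``n_effect_sources`` designated source regions."""
    base = random_stable_spec(n_regions, order, n_samples, seed=seed)
    rng = np.random.default_rng(seed + 1)
    sources = list(range(n_effect_sources))
    edges: list[tuple[int, int]] = []
    while len(edges) < n_effect_edges:
        s = sources[len(edges) % len(sources)]
        t = int(rng.integers(n_regions))
        if t != s and (s, t) not in edges:
            edges.append((s, t))
    return CohortSpec(
        n_group_a=n_group_a,
        n_group_b=n_group_b,
        base_spec=base,
        effect_edges=edges,
        effect_gain=effect_gain,
        effect_lag=effect_lag,
        seed=seed,
    )


def order_study_cohort_spec(
    n_regions: int = 10,
    n_sources: int = 3,
    n_samples: int = 1000,
    n_group_a: int = 14,
    n_group_b: int = 34,
    *,
    effect_gain: float = 0.4,
    seed: int = 0,
) -> CohortSpec:
    """Cohort designed to isolate lag-order misspecification.

    The base process is exactly order 5 and pairwise-identifiable: source
    channels are pure white noise (so no autocorrelation aliases lag-5
    information into shorter lags) and the remaining channels carry own
    dynamics at lags 1 and 5.  The group effect adds ``effect_gain`` on
    five source->target edges at lag 5, so models of order < 5 are blind
    to the discriminative coupling while orders > 5 add only estimation
    variance.
    """
    a = np.zeros((5, n_regions, n_regions))
    for i in range(n_sources, n_regions):
        a[0, i, i] = 0.3
        a[4, i, i] = -0.4
    base = SimulationSpec(n_regions, 5, a, np.eye(n_regions), n_samples)
    rng = np.random.default_rng(seed + 77)
    edges: list[tuple[int, int]] = []
    while len(edges) < 5:
        s = int(rng.integers(n_sources))
        t = int(rng.integers(n_sources, n_regions))
        if (s, t) not in edges:
            edges.append((s, t))
    return CohortSpec(
        n_group_a=n_group_a,
        n_group_b=n_group_b,
        base_spec=base,
        effect_edges=edges,
        effect_gain=effect_gain,
        effect_lag=5,
        seed=seed,
    )


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write per-subject TSV matrices, a manifest CSV and the ground-truth
    edge list (JSON).  Returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["subject_id", "group", "path", "seed"])
        for ts, seed in zip(cohort.subjects, cohort.subject_seeds):
            p = out / f"{ts.subject_id}.tsv"
            write_roi_timeseries(ts, p)
            wr.writerow([ts.subject_id, ts.group, p.name, seed])
    gt = ground_truth_graph(cohort.spec.base_spec)
    edges = [
        {"source": gt.region_labels[i], "target": gt.region_labels[j]}
        for i, j in zip(*np.nonzero(gt.adjacency))
    ]
    with open(out / "ground_truth_edges.json", "w") as fh:
        json.dump(
            {
                "edges": edges,
                "effect_edges": [
                    {
                        "source": gt.region_labels[s],
                        "target": gt.region_labels[t],
                    }
                    for s, t in cohort.spec.effect_edges
                ],
                "effect_gain": cohort.spec.effect_gain,
            },
            fh,
            indent=1,
        )
    with open(out / "labels.txt", "w") as fh:
        fh.write("\n".join(cohort.spec.base_spec.region_labels) + "\n")
    return manifest
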