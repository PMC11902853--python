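"""End-to-end orchestration: cohort -> connectivity -> binarization ->
topology features -> group tests -> hubs -> classification.

The pipeline is driven by a :class:`PipelineConfig` (loadable from a flat
YAML file) and writes a reproducible bundle: every output directory
carries a run manifest with the config hash and the seeds used, and the
same config + seed produces a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    ConnectivityMatrix,
    average_connection_strength,
    granger_pairwise,
    normalize_weights,
    pearson_matrix,
    select_order_bic,
)
from .graph_metrics import BinaryNetwork, feature_vector
from .hubs import (
    dissimilar_connections,
    group_mean_matrix,
    hub_consensus,
    out_strength_dissimilarity,
    out_strength_ranking,
    top_connections,
)
from .simulate import demo_cohort_spec, make_cohort, write_cohort
from .stats import classify_features, group_test_table
from .thresholding import proportional_binarize, select_threshold
from .timeseries import ROITimeSeries, read_roi_timeseries, zscore

log = logging.getLogger("grangernet")

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "load_subjects",
    "save_matrix",
    "load_matrix",
]


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; unset paths mean 'simulate a cohort'."""

    out_dir: str = "results/run"
    seed: int = 0
    # input: either a manifest of TSV files or a simulated cohort
    manifest: str | None = None
    labels_path: str | None = None
    sampling_rate_hz: float = 500.0
    # simulation block (used when manifest is None)
    n_regions: int = 20
    sim_order: int = 2
    n_samples: int = 1000
    n_group_a: int = 14
    n_group_b: int = 34
    n_effect_edges: int = 5
    effect_gain: float = 0.3
    group_a_label: str = "HC"
    group_b_label: str = "TLE"
    # analysis
    methods: list[str] = field(default_factory=lambda: ["gca", "pcc"])
    order_mode: str | int = "bic"  # "bic" or a fixed integer lag order
    min_order: int = 1
    max_order: int = 10
    psw_grid: list[float] | None = None
    degree_mode: str = "total"
    # statistics / classification
    alpha: float = 0.05
    train_frac: float = 0.7
    paper_mode: bool = False
    hub_k_edges: int = 20
    hub_k_regions: int = 5
    hub_min_lists: int = 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------- I/O helpers


def save_matrix(w: ConnectivityMatrix | BinaryNetwork, path) -> None:
    """Write a matrix as TSV with a JSON sidecar describing it."""
    path = Path(path)
    if isinstance(w, ConnectivityMatrix):
        np.savetxt(path, w.weights, fmt="%.17g", delimiter="\t")
        meta = {"kind": "weights", "method": w.method, "directed": w.directed,
                "labels": w.region_labels}
    else:
        np.savetxt(path, w.adjacency, fmt="%d", delimiter="\t")
        meta = {"kind": "binary", "directed": w.directed, "density": w.density,
                "labels": w.region_labels}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_matrix(path):
    """Read a matrix written by :func:`save_matrix`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    m = np.loadtxt(path, delimiter="\t")
    if meta["kind"] == "weights":
        return ConnectivityMatrix(m, directed=meta["directed"], method=meta["method"],
                                  region_labels=meta["labels"])
    return BinaryNetwork(m.astype(np.int8), directed=meta["directed"],
                         density=meta["density"], region_labels=meta["labels"])


def load_subjects(config: PipelineConfig) -> list[ROITimeSeries]:
    """Read the cohort named by the manifest CSV (subject_id, group, path)."""
    if config.manifest is None:
        raise ValueError("config has no manifest; simulate a cohort first")
    mpath = Path(config.manifest)
    table = pd.read_csv(mpath)
    subjects = []
    for _, row in table.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = mpath.parent / p
        subjects.append(
            read_roi_timeseries(
                p,
                labels_path=config.labels_path,
                sampling_rate_hz=config.sampling_rate_hz,
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
            )
        )
    return subjects


# ------------------------------------------------------------------- stages


def stage_simulate(config: PipelineConfig, out: Path) -> list[ROITimeSeries]:
    spec = demo_cohort_spec(
        n_regions=config.n_regions,
        order=config.sim_order,
        n_samples=config.n_samples,
        n_group_a=config.n_group_a,
        n_group_b=config.n_group_b,
        n_effect_edges=config.n_effect_edges,
        effect_gain=config.effect_gain,
        seed=config.seed,
    )
    spec.group_a_label = config.group_a_label
    spec.group_b_label = config.group_b_label
    cohort = make_cohort(spec)
    write_cohort(cohort, out / "cohort")
    log.info("simulate: %d subjects written to %s", len(cohort.subjects), out / "cohort")
    return cohort.subjects


def stage_connectivity(
    subjects: list[ROITimeSeries], method: str, config: PipelineConfig
):
    """Per-subject normalized connectivity; returns (matrices, order used)."""
    method = method.lower()
    order = None
    if method == "gca":
        if config.order_mode == "bic":
            picks = [
                select_order_bic(ts, config.min_order, config.max_order)
                for ts in subjects
            ]
            vals, counts = np.unique(picks, return_counts=True)
            order = int(vals[np.argmax(counts)])  # modal, ties -> smaller
            log.info("connectivity: modal BIC order %d (picks %s)", order, picks)
        else:
            order = int(config.order_mode)
        mats = [granger_pairwise(ts, order) for ts in subjects]
    elif method == "pcc":
        mats = [pearson_matrix(ts) for ts in subjects]
    else:
        raise ValueError(f"unknown method {method!r}")
    return [normalize_weights(w) for w in mats], order


def stage_features(
    nets: list[BinaryNetwork], subject_ids: list[str], degree_mode: str
) -> pd.DataFrame:
    rows, names = [], None
    for net in nets:
        tf = feature_vector(net, degree_mode=degree_mode)
        names = tf.feature_names
        rows.append(tf.values)
    return pd.DataFrame(rows, index=subject_ids, columns=names)


def stage_hubs(normed, groups, config: PipelineConfig):
    a_mats = [w for w, g in zip(normed, groups) if g == config.group_a_label]
    b_mats = [w for w, g in zip(normed, groups) if g == config.group_b_label]
    mean_a, mean_b = group_mean_matrix(a_mats), group_mean_matrix(b_mats)
    lcs = top_connections(mean_b, config.hub_k_edges)
    gdc = dissimilar_connections(mean_b, mean_a, config.hub_k_edges)
    hodr = out_strength_ranking(mean_b, config.hub_k_regions)
    gdr = out_strength_dissimilarity(mean_b, mean_a, config.hub_k_regions)
    return hub_consensus(lcs, gdc, hodr, gdr, min_lists=config.hub_min_lists)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every configured method; returns the bundle
    summary (also written as ``run_manifest.json`` in the output dir)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.manifest is None:
        subjects = stage_simulate(config, out)
    else:
        subjects = load_subjects(config)
    subjects = [zscore(ts) for ts in subjects]
    groups = [ts.group for ts in subjects]
    ids = [ts.subject_id for ts in subjects]

    summary: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "version": __version__,
        "n_subjects": len(subjects),
        "methods": {},
    }
    for method in config.methods:
        mdir = out / method.lower()
        (mdir / "matrices").mkdir(parents=True, exist_ok=True)
        (mdir / "binary").mkdir(parents=True, exist_ok=True)
        normed, order = stage_connectivity(subjects, method, config)
        for ts, w in zip(subjects, normed):
            save_matrix(w, mdir / "matrices" / f"{ts.subject_id}.tsv")
        scan = select_threshold(normed, config.psw_grid)
        scan.to_frame().to_csv(mdir / "threshold_scan.csv", index=False)
        nets = [proportional_binarize(w, scan.selected_psw) for w in normed]
        for ts, net in zip(subjects, nets):
            save_matrix(net, mdir / "binary" / f"{ts.subject_id}.tsv")
        feats = stage_features(nets, ids, config.degree_mode)
        feats.to_csv(mdir / "features.csv")
        tests = group_test_table(
            feats, groups, config.group_a_label, config.group_b_label, config.alpha
        )
        tests.to_csv(mdir / "group_tests.csv", index=False)
        strengths = [average_connection_strength(w) for w in normed]
        method_summary = {
            "order": order,
            "selected_psw": scan.selected_psw,
            "n_significant_features": int((tests["p_value"] < config.alpha).sum()),
            "mean_connection_strength": {
                g: float(np.mean([s for s, gg in zip(strengths, groups) if gg == g]))
                for g in sorted(set(groups))
            },
        }
        if normed[0].directed:
            report = stage_hubs(normed, groups, config)
            report.write_json(mdir / "hub_report.json")
            report.frequency_frame().to_csv(mdir / "hub_frequency.csv", index=False)
            method_summary["hubs"] = report.hubs
        try:
            clf = classify_features(
                feats,
                groups,
                alpha=config.alpha,
                train_frac=config.train_frac,
                split_seed=config.seed,
                svm_seed=config.seed,
                paper_mode=config.paper_mode,
                pos_label=config.group_b_label,
            )
            (mdir / "classification.json").write_text(json.dumps(clf.to_dict(), indent=1))
            method_summary["classification"] = clf.to_dict()
        except ValueError as exc:
            method_summary["classification_error"] = str(exc)
            log.warning("classify[%s]: %s", method, exc)
        summary["methods"][method.lower()] = method_summary
        log.info("method %s done: %s", method, {k: v for k, v in method_summary.items() if k != "classification"})
    (out / "run_manifest.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
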