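"""Group statistics, feature selection and SVM classification.

Univariate group comparisons are normality-gated: each sample is screened
with a one-sample Kolmogorov-Smirnov test against a normal distribution
with that sample's mean and standard deviation; if both groups pass, an
unpaired two-sided t-test is used, otherwise a two-sided Mann-Whitney U
test (exact when both groups have at most 20 subjects, tie-corrected
normal approximation above that).  The K-S screen uses estimated moments
as named by common practice; the Lilliefors-correction caveat is noted in
the docs but not applied.

Classification follows the published protocol: topology features with a
significant Mann-Whitney difference (p < alpha, no multiple-testing
correction) feed a linear support-vector machine evaluated on a
stratified 70/30 split.  By default the screen and the standardization
statistics use the training partition only; ``paper_mode`` applies the
screen to all subjects, reproducing the original protocol at the cost of
a selection-leakage caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.svm import SVC

__all__ = [
    "GroupTestResult",
    "FeatureSelection",
    "Partition",
    "ClassificationReport",
    "normality_gated_test",
    "group_test_table",
    "select_features",
    "split_stratified",
    "train_eval_svm",
    "order_sweep",
]


@dataclass
class GroupTestResult:
    feature_name: str
    test_used: str  # "t-test" or "mann-whitney"
    statistic: float
    p_value: float
    direction: int  # sign of (group_b - group_a) location difference
    warnings: list[str] = field(default_factory=list)


def _ks_normal(sample: np.ndarray, alpha: float) -> bool:
    sd = sample.std(ddof=1)
    if sd == 0:
        return False
    return sps.kstest(sample, "norm", args=(sample.mean(), sd)).pvalue > alpha


def normality_gated_test(
    sample_a, sample_b, alpha: float = 0.05, feature_name: str = ""
) -> GroupTestResult:
    """Two-sided two-sample comparison with a K-S normality gate.

    ``direction`` is the sign of (median of b - median of a); a
    zero-variance sample forces the Mann-Whitney branch with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 observations")
    warnings = []
    degenerate = a.std(ddof=1) == 0 or b.std(ddof=1) == 0
    if degenerate:
        warnings.append("zero-variance sample: Mann-Whitney branch forced")
    normal = (not degenerate) and _ks_normal(a, alpha) and _ks_normal(b, alpha)
    if normal:
        res = sps.ttest_ind(a, b)
        used = "t-test"
    else:
        method = "exact" if max(a.size, b.size) <= 20 else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        used = "mann-whitney"
    direction = int(np.sign(np.median(b) - np.median(a)))
    return GroupTestResult(
        feature_name=feature_name,
        test_used=used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=direction,
        warnings=warnings,
    )


def group_test_table(
    features: pd.DataFrame, labels, group_a: str, group_b: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Run the normality-gated comparison per feature column; one row each."""
    labels = np.asarray(labels)
    rows = []
    for name in features.columns:
        col = features[name].to_numpy(dtype=float)
        r = normality_gated_test(
            col[labels == group_a], col[labels == group_b], alpha, feature_name=name
        )
        rows.append(
            {
                "feature": r.feature_name,
                "test": r.test_used,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FeatureSelection:
    mask: np.ndarray  # boolean over feature columns
    p_values: np.ndarray

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def select_features(features, labels, alpha: float = 0.05) -> FeatureSelection:
    """Mann-Whitney screen: keep features whose two-sided U-test p < alpha.

    No multiple-testing correction is applied (matching the published
    screen).  Call on training rows only for a leakage-free protocol.
    Constant features get p = 1.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    a, b = x[labels == classes[0]], x[labels == classes[1]]
    pvals = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if np.ptp(x[:, j]) == 0:
            continue
        pvals[j] = sps.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided").pvalue
    return FeatureSelection(mask=pvals < alpha, p_values=pvals)


@dataclass
class Partition:
    train_idx: np.ndarray
    val_idx: np.ndarray


def split_stratified(labels, train_frac: float = 0.7, seed: int = 0) -> Partition:
    """Per-class random split; training size = round(train_frac * class size)
    (round half up).  Rejects splits leaving a class empty on either side."""
    labels = np.asarray(labels)
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(seed)
    train, val = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_train = int(np.floor(train_frac * idx.size + 0.5))
        if n_train < 1 or n_train >= idx.size:
            raise ValueError(
                f"train_frac={train_frac} leaves class {cls!r} empty on one side"
            )
        perm = rng.permutation(idx)
        train.append(perm[:n_train])
        val.append(perm[n_train:])
    return Partition(np.sort(np.concatenate(train)), np.sort(np.concatenate(val)))


@dataclass
class ClassificationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    kappa: float
    roc_auc: float
    n_features_selected: int
    split_counts: dict[str, dict[str, int]]
    seed: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "kappa": self.kappa,
            "roc_auc": self.roc_auc,
            "n_features_selected": self.n_features_selected,
            "split_counts": self.split_counts,
            "seed": self.seed,
        }


def train_eval_svm(
    features,
    labels,
    partition: Partition,
    seed: int = 0,
    *,
    pos_label: str | None = None,
    kernel: str = "linear",
    C: float = 1.0,
) -> ClassificationReport:
    """Train an SVM on the training partition, score on validation.

    Features are standardized with training-set mean/sd only (zero-variance
    training columns are left unscaled).  The positive class defaults to
    the lexicographically larger label.  ROC-AUC uses the decision-function
    score.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if x.shape[1] < 1:
        raise ValueError("no features selected for classification")
    tr, va = partition.train_idx, partition.val_idx
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("binary classification requires exactly 2 classes")
    for part, name in ((tr, "training"), (va, "validation")):
        if np.unique(labels[part]).size != 2:
            raise ValueError(f"{name} partition does not contain both classes")
    if pos_label is None:
        pos_label = sorted(classes)[-1]
    mu = x[tr].mean(axis=0)
    sd = x[tr].std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd
    y = (labels == pos_label).astype(int)
    clf = SVC(kernel=kernel, C=C, random_state=seed)
    clf.fit(xs[tr], y[tr])
    pred = clf.predict(xs[va])
    score = clf.decision_function(xs[va])
    counts = {
        "train": {str(c): int((labels[tr] == c).sum()) for c in classes},
        "validation": {str(c): int((labels[va] == c).sum()) for c in classes},
    }
    return ClassificationReport(
        accuracy=float(accuracy_score(y[va], pred)),
        precision=float(precision_score(y[va], pred, zero_division=0)),
        recall=float(recall_score(y[va], pred, zero_division=0)),
        f1=float(f1_score(y[va], pred, zero_division=0)),
        kappa=float(cohen_kappa_score(y[va], pred)),
        roc_auc=float(roc_auc_score(y[va], score)),
        n_features_selected=x.shape[1],
        split_counts=counts,
        seed=seed,
    )


def classify_features(
    features: pd.DataFrame,
    labels,
    *,
    alpha: float = 0.05,
    train_frac: float = 0.7,
    split_seed: int = 0,
    svm_seed: int = 0,
    paper_mode: bool = False,
    pos_label: str | None = None,
) -> ClassificationReport:
    """Full screen-then-classify protocol on a subjects x features table."""
    labels = np.asarray(labels)
    part = split_stratified(labels, train_frac=train_frac, seed=split_seed)
    x = features.to_numpy(dtype=float)
    if paper_mode:
        sel = select_features(x, labels, alpha)
    else:
        sel = select_features(x[part.train_idx], labels[part.train_idx], alpha)
    if sel.n_selected == 0:
        raise ValueError(
            "no feature passed the Mann-Whitney screen; classification aborted"
        )
    report = train_eval_svm(
        x[:, sel.mask], labels, part, seed=svm_seed, pos_label=pos_label
    )
    report.n_features_selected = sel.n_selected
    return report


def order_sweep(
    feature_fn,
    labels,
    orders=range(1, 11),
    *,
    alpha: float = 0.05,
    train_frac: float = 0.7,
    split_seed: int = 0,
    paper_mode: bool = False,
    pos_label: str | None = None,
) -> pd.DataFrame:
    """Re-run the classification protocol at each candidate lag order.

    ``feature_fn(order)`` must return the subjects x features table built
    from connectivity at that order; the split seed is held fixed so rows
    are comparable.  Returns one report row per order.
    """
    rows = []
    for order in orders:
        feats = feature_fn(int(order))
        rep = classify_features(
            feats,
            labels,
            alpha=alpha,
            train_frac=train_frac,
            split_seed=split_seed,
            svm_seed=split_seed,
            paper_mode=paper_mode,
            pos_label=pos_label,
        )
        row = {"order": int(order)}
        row.update(rep.to_dict())
        row.pop("split_counts")
        rows.append(row)
    return pd.DataFrame(rows)
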