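"""Nodal-feature classification with fold-safe PCA and permutation testing.

Per subject, the three nodal metrics (clustering coefficient, within-module
degree z, participation coefficient) over 90 regions are concatenated into a
1 x 270 feature vector. Within every cross-validation fold, features are
standardized and reduced by PCA fit on the training rows only (components
kept until >= 90% variance), then a linear soft-margin SVM (C = 1) is
trained; accuracy, sensitivity, specificity and AUC are pooled over held-out
predictions. Significance is assessed by re-running the whole fold-safe
procedure under label permutations and comparing the real accuracy with the
5th–95th percentile band of the null accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FeatureMatrix",
    "ClassifierReport",
    "assemble_features",
    "reduce_dimensionality",
    "cross_validate",
    "permutation_test",
    "per_feature_projection",
]

BLOCKS = ("clustering", "within_module_degree", "participation")


@dataclass
class FeatureMatrix:
    """Subjects x (3 * n_nodes) nodal-feature matrix with block labels."""

    values: np.ndarray
    subject_ids: list[str]
    n_nodes: int

    def block(self, name: str) -> np.ndarray:
        i = BLOCKS.index(name)
        return self.values[:, i * self.n_nodes:(i + 1) * self.n_nodes]


@dataclass
class ClassifierReport:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    predictions: np.ndarray
    decision_values: np.ndarray
    scheme: str
    null_accuracies: np.ndarray | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    significant: bool | None = None
    per_repeat_accuracy: np.ndarray | None = field(default=None)


def assemble_features(nodal_metrics: dict[str, dict[str, np.ndarray]]) -> FeatureMatrix:
    """Concatenate per-subject nodal metrics in fixed block order.

    ``nodal_metrics`` maps subject id -> {block name -> length-n vector}.
    Block order is clustering, within-module degree, participation.
    """
    subject_ids = list(nodal_metrics)
    rows = []
    n_nodes = None
    for sid in subject_ids:
        metrics = nodal_metrics[sid]
        missing = [b for b in BLOCKS if b not in metrics]
        if missing:
            raise ValueError(f"subject {sid} is missing metrics {missing}")
        vecs = [np.asarray(metrics[b], dtype=float) for b in BLOCKS]
        if n_nodes is None:
            n_nodes = vecs[0].size
        if any(v.size != n_nodes for v in vecs):
            raise ValueError(f"subject {sid} has inconsistent node count")
        rows.append(np.concatenate(vecs))
    return FeatureMatrix(values=np.vstack(rows), subject_ids=subject_ids, n_nodes=n_nodes)


def reduce_dimensionality(train: np.ndarray, variance_kept: float = 0.90) -> PCA:
    """PCA fit on training rows only, keeping the fewest components with
    cumulative explained variance >= ``variance_kept``.

    The returned transform carries the training mean, so held-out rows are
    centered with training statistics (no leakage).
    """
    if train.shape[0] < 2:
        raise ValueError("need at least two training rows")
    full = PCA().fit(train)
    cum = np.cumsum(full.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    n_comp = min(n_comp, full.n_components_)
    return PCA(n_components=n_comp).fit(train)


def _fold_pipeline(variance_kept: float, standardize: bool, seed: int | None) -> Pipeline:
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("pca", PCA(n_components=variance_kept, svd_solver="full")))
    steps.append(("svm", SVC(kernel="linear", C=1.0, random_state=seed)))
    return Pipeline(steps)


def _make_splitter(scheme: str, seed: int | None):
    scheme = scheme.lower().replace("-", "")
    if scheme in ("loo", "leaveoneout"):
        return LeaveOneOut(), "LOO", 1
    if scheme in ("5fold", "fivefold"):
        return StratifiedKFold(5, shuffle=True, random_state=seed), "5-fold", 5
    if scheme in ("3fold", "threefold"):
        return StratifiedKFold(3, shuffle=True, random_state=seed), "3-fold", 3
    raise ValueError(f"unknown CV scheme {scheme!r}")


def cross_validate(features: np.ndarray, labels: np.ndarray, scheme: str = "loo",
                   n_repeats: int = 1, seed: int | None = None,
                   variance_kept: float = 0.90, standardize: bool = True,
                   positive_label=None) -> ClassifierReport:
    """Fold-safe cross-validated linear-SVM classification.

    For every fold the scaler and PCA are fit on the training rows only.
    k-fold schemes are stratified; with ``n_repeats`` > 1 the splits are
    re-drawn from a seed sequence and pooled accuracies averaged. LOO is
    deterministic, so repeats collapse to one pass.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("binary classification requires exactly two classes")
    pos = positive_label if positive_label is not None else classes[1]
    y_bin = (y == pos).astype(int)
    rng = np.random.default_rng(seed)
    splitter, scheme_name, _ = _make_splitter(scheme, seed)
    if scheme_name == "LOO":
        n_repeats = 1
    accs = []
    last_pred = None
    last_dec = None
    for rep in range(n_repeats):
        rep_seed = int(rng.integers(2**31 - 1))
        splitter, _, _ = _make_splitter(scheme, rep_seed)
        pred = np.empty_like(y_bin)
        dec = np.empty(y_bin.size, dtype=float)
        for train_idx, test_idx in splitter.split(X, y_bin):
            if np.unique(y_bin[train_idx]).size < 2:
                raise ValueError("single-class training fold; check stratification")
            pipe = _fold_pipeline(variance_kept, standardize, rep_seed)
            pipe.fit(X[train_idx], y_bin[train_idx])
            pred[test_idx] = pipe.predict(X[test_idx])
            dec[test_idx] = pipe.decision_function(X[test_idx])
        accs.append(float((pred == y_bin).mean()))
        last_pred, last_dec = pred, dec
    tp = int(((last_pred == 1) & (y_bin == 1)).sum())
    tn = int(((last_pred == 0) & (y_bin == 0)).sum())
    fn = int(((last_pred == 0) & (y_bin == 1)).sum())
    fp = int(((last_pred == 1) & (y_bin == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    auc = float(roc_auc_score(y_bin, last_dec))
    return ClassifierReport(
        accuracy=float(np.mean(accs)), sensitivity=float(sens), specificity=float(spec),
        auc=auc, predictions=last_pred, decision_values=last_dec,
        scheme=scheme_name, per_repeat_accuracy=np.array(accs),
    )


def permutation_test(features: np.ndarray, labels: np.ndarray, scheme: str = "loo",
                     n_perm: int = 1000, seed: int | None = None,
                     variance_kept: float = 0.90, standardize: bool = True,
                     report: ClassifierReport | None = None) -> ClassifierReport:
    """Label-shuffling chance-level test for the classification accuracy.

    The full fold-safe CV procedure is repeated ``n_perm`` times with
    permuted labels (class counts preserved); the 5th and 95th percentiles
    of null accuracy define the chance band, and the real accuracy is
    significant when it exceeds the 95th percentile.
    """
    rng = np.random.default_rng(seed)
    if report is None:
        report = cross_validate(features, labels, scheme=scheme,
                                seed=int(rng.integers(2**31 - 1)),
                                variance_kept=variance_kept, standardize=standardize)
    y = np.asarray(labels)
    null = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = y[rng.permutation(y.size)]
        null[b] = cross_validate(features, shuffled, scheme=scheme,
                                 seed=int(rng.integers(2**31 - 1)),
                                 variance_kept=variance_kept,
                                 standardize=standardize).accuracy
    report.null_accuracies = null
    report.ci_low = float(np.percentile(null, 5))
    report.ci_high = float(np.percentile(null, 95))
    report.significant = bool(report.accuracy > report.ci_high)
    return report


def per_feature_projection(features: FeatureMatrix) -> pd.DataFrame:
    """Project subjects onto the first principal axis of each metric block.

    Returns one row per subject with columns pc1_clustering,
    pc1_within_module_degree, pc1_participation. A block with zero variance
    maps to the zero coordinate.
    """
    cols = {}
    for name in BLOCKS:
        block = features.block(name)
        centered = block - block.mean(axis=0)
        if np.allclose(centered, 0):
            cols[f"pc1_{name}"] = np.zeros(block.shape[0])
            continue
        pca = PCA(n_components=1).fit(block)
        cols[f"pc1_{name}"] = pca.transform(block)[:, 0]
    df = pd.DataFrame(cols)
    df.insert(0, "subject_id", features.subject_ids)
    return df
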