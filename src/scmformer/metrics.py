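"""Evaluation suite: FOSCTTM alignment error, kNN label transfer and
generation-quality statistics.

FOSCTTM (fraction of samples closer than the true match) compares both
directions against the true-match distance d(x_i, y_i) with strict
inequality, so identical paired embeddings score exactly 0 and random
embeddings approach 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import f1_score


@dataclass
class MetricsReport:
    foscttm: float | None = None
    accuracy: float | None = None
    macro_f1: float | None = None
    pearson_per_feature: np.ndarray | None = None
    spearman_per_feature: np.ndarray | None = None
    mse: float | None = None
    rmse: float | None = None
    constant_features: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {}
        for k in ("foscttm", "accuracy", "macro_f1", "mse", "rmse"):
            v = getattr(self, k)
            if v is not None:
                out[k] = float(v)
        for k in ("pearson_per_feature", "spearman_per_feature"):
            v = getattr(self, k)
            if v is not None:
                out[k] = [float(x) for x in v]
                out[k.replace("per_feature", "mean")] = float(np.mean(v))
        if self.constant_features is not None:
            out["constant_features"] = [bool(x) for x in self.constant_features]
        return out


def foscttm(X: np.ndarray, Y: np.ndarray) -> float:
    """Fraction of samples closer than the true match; row i of X is
    paired with row i of Y.  Euclidean distance, strict inequality."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape != Y.shape:
        raise ValueError("X and Y must have identical shapes")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    D = cdist(X, Y)  # D[i, j] = d(x_i, y_j)
    true = np.diag(D)
    n1 = (D < true[:, None]).sum(axis=1)  # cells y_j closer to x_i than y_i
    n2 = (D < true[None, :]).sum(axis=0)  # cells x_j closer to y_i than x_i
    return float((n1.sum() / n + n2.sum() / n) / (2 * n))


def knn_transfer(reference: np.ndarray, ref_labels, query: np.ndarray,
                 k: int = 5) -> list[str]:
    """Majority vote among k Euclidean nearest reference neighbours.

    Vote ties are broken by the smallest cumulative neighbour distance,
    then lexicographic label order.
    """
    reference = np.asarray(reference, dtype=np.float64)
    query = np.asarray(query, dtype=np.float64)
    ref_labels = [str(l) for l in ref_labels]
    if reference.shape[0] == 0:
        raise ValueError("empty reference")
    if len(ref_labels) != reference.shape[0]:
        raise ValueError("labels length mismatch")
    if k > reference.shape[0]:
        raise ValueError(f"k={k} exceeds reference size {reference.shape[0]}")
    D = cdist(query, reference)
    nn = np.argsort(D, axis=1, kind="stable")[:, :k]
    out = []
    for qi in range(query.shape[0]):
        votes: dict[str, list] = {}
        for j in nn[qi]:
            lab = ref_labels[j]
            votes.setdefault(lab, [0, 0.0])
            votes[lab][0] += 1
            votes[lab][1] += D[qi, j]
        # max count, then min cumulative distance, then lexicographic
        best = min(votes.items(), key=lambda kv: (-kv[1][0], kv[1][1], kv[0]))
        out.append(best[0])
    return out


def classification_scores(true_labels, pred_labels) -> tuple[float, float]:
    """Accuracy and macro-F1 averaged over classes present in the truth."""
    true_labels = [str(l) for l in true_labels]
    pred_labels = [str(l) for l in pred_labels]
    if len(true_labels) == 0:
        raise ValueError("empty input")
    if len(true_labels) != len(pred_labels):
        raise ValueError("length mismatch")
    acc = float(np.mean([t == p for t, p in zip(true_labels, pred_labels)]))
    classes = sorted(set(true_labels))
    macro = float(f1_score(true_labels, pred_labels, labels=classes,
                           average="macro", zero_division=0))
    return acc, macro


def generation_scores(pred: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Per-feature Pearson/Spearman across cells plus global MSE/RMSE.

    Features constant in either matrix have undefined correlation and are
    reported as 0 with a flag.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    n_feat = pred.shape[1]
    pear = np.zeros(n_feat)
    spear = np.zeros(n_feat)
    constant = np.zeros(n_feat, dtype=bool)
    for j in range(n_feat):
        p, t = pred[:, j], truth[:, j]
        if np.ptp(p) == 0 or np.ptp(t) == 0:
            constant[j] = True
            continue
        pear[j] = pearsonr(p, t).statistic
        spear[j] = spearmanr(p, t).statistic
    mse = float(np.mean((pred - truth) ** 2))
    return MetricsReport(
        pearson_per_feature=pear,
        spearman_per_feature=spear,
        mse=mse,
        rmse=float(np.sqrt(mse)),
        constant_features=constant,
    )


def evaluate_integration(latent_a: np.ndarray, latent_b: np.ndarray,
                         labels=None, k: int = 5) -> MetricsReport:
    """FOSCTTM plus (when labels given) cross-modality label transfer
    from modality A's latents onto modality B's cells."""
    report = MetricsReport(foscttm=foscttm(latent_a, latent_b))
    if labels is not None:
        pred = knn_transfer(latent_a, labels, latent_b, k=k)
        report.accuracy, report.macro_f1 = classification_scores(labels, pred)
    return report
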