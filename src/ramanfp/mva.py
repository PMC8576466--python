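"""Single-spectrum PCA-LDA classification and its evaluation.

Spectra (rows of a preprocessed matrix) are reduced to their first
``n_pcs`` principal components (15 by default) and a linear
discriminant model is fitted on the scores.  The discriminant solves
the generalized eigenproblem  B v = l W v  (B between-class, W pooled
within-class covariance) with axes normalized so the within-class
covariance in canonical space is the identity; classification assigns
the class minimizing  1/2 ||x - m_c||^2 - log pi_c  in that whitened
canonical space (the Gaussian-posterior rule; with equal priors it is
the nearest class centroid).

Evaluation follows the spectroscopy-classification conventions:
leave-one-out cross-validation refitting PCA + LDA per fold, a 3-class
confusion matrix, PD-vs-rest sensitivity/specificity/MCC, the 3-class
accuracy/error rate, and a PD-vs-rest ROC AUC on a posterior-like
canonical-space score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats
from sklearn.decomposition import PCA

from .io import CohortDataset, ValidationError

CLASS_ORDER = ("CTRL", "PD", "AD")


@dataclass
class ComponentModel:
    """PCA loadings/scores plus LDA canonical variables."""

    mean: np.ndarray                       # grid mean removed before PCA
    pc_loadings: np.ndarray                # (n_pcs, n_features), orthonormal rows
    pc_scores: np.ndarray                  # (n_samples, n_pcs)
    explained_variance_fractions: np.ndarray
    n_pcs: int
    classes: tuple[str, ...] = ()
    cv_axes: np.ndarray | None = None      # (n_pcs, n_classes-1)
    cv_scores: np.ndarray | None = None    # (n_samples, n_classes-1)
    cv_centroids: np.ndarray | None = None  # per class, in canonical space
    priors: np.ndarray | None = None

    def project(self, matrix: np.ndarray) -> np.ndarray:
        """PC scores of new spectra (rows on the training grid)."""
        return (np.atleast_2d(matrix) - self.mean) @ self.pc_loadings.T

    def canonical(self, matrix: np.ndarray) -> np.ndarray:
        if self.cv_axes is None:
            raise ValidationError("no LDA fitted on this model")
        return self.project(matrix) @ self.cv_axes

    def predict(self, matrix: np.ndarray) -> np.ndarray:
        """Class labels via the prior-adjusted nearest-centroid rule."""
        cv = self.canonical(matrix)
        d2 = ((cv[:, None, :] - self.cv_centroids[None, :, :]) ** 2).sum(axis=2)
        score = 0.5 * d2 - np.log(self.priors)[None, :]
        return np.array([self.classes[i] for i in np.argmin(score, axis=1)])

    def pd_score(self, matrix: np.ndarray) -> np.ndarray:
        """Posterior-like PD score in canonical space (higher = more
        PD-like): softmax over -1/2 d_c^2 + log pi_c, PD column."""
        cv = self.canonical(matrix)
        i_pd = self.classes.index("PD")
        d2 = ((cv[:, None, :] - self.cv_centroids[None, :, :]) ** 2).sum(axis=2)
        logits = -0.5 * d2 + np.log(self.priors)[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        return probs[:, i_pd]


def fit_pca(matrix: np.ndarray, n_pcs: int = 15,
            random_state: int = 0) -> ComponentModel:
    """PCA with a fixed sign convention (largest-magnitude loading
    element positive), deterministic given ``random_state``."""
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    rank = min(n - 1, p)
    if n_pcs > rank:
        raise ValidationError(f"n_pcs={n_pcs} exceeds the data rank {rank}")
    solver = "full" if rank <= 60 or n_pcs > rank // 2 else "randomized"
    pca = PCA(n_components=n_pcs, svd_solver=solver, random_state=random_state)
    scores = pca.fit_transform(matrix)
    loadings = pca.components_
    signs = np.sign(loadings[np.arange(n_pcs),
                             np.argmax(np.abs(loadings), axis=1)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs[:, None]
    scores = scores * signs[None, :]
    return ComponentModel(
        mean=pca.mean_, pc_loadings=loadings, pc_scores=scores,
        explained_variance_fractions=pca.explained_variance_ratio_,
        n_pcs=n_pcs)


def fit_lda(pc_scores: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray]:
    """Canonical axes and scores maximizing between/within variance.

    Returns ``(axes, cv_scores)`` with at most (classes - 1) axes,
    normalized so the pooled within-class covariance of the canonical
    scores is the identity.  Raises when the within-class scatter is
    singular (too many PCs for the sample).
    """
    X = np.asarray(pc_scores, dtype=float)
    labels = np.asarray(labels)
    classes = [c for c in CLASS_ORDER if c in labels] or \
        sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValidationError("LDA needs >= 2 classes")
    n, p = X.shape
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for c in classes:
        Xc = X[labels == c]
        if len(Xc) < 2:
            raise ValidationError(f"class {c!r} needs >= 2 samples")
        d = Xc - Xc.mean(axis=0)
        W += d.T @ d
        m = Xc.mean(axis=0) - grand
        B += len(Xc) * np.outer(m, m)
    W /= (n - len(classes))
    B /= (n - 1)
    w_eigs = np.linalg.eigvalsh(W)
    if w_eigs[0] <= 1e-12 * max(w_eigs[-1], 1e-300):
        raise ValidationError(
            "within-class scatter is singular; reduce the number of "
            "principal components")
    try:
        evals, evecs = scipy.linalg.eigh(B, W)
    except scipy.linalg.LinAlgError as exc:
        raise ValidationError(
            "within-class scatter is singular; reduce the number of "
            "principal components") from exc
    order = np.argsort(evals)[::-1][: len(classes) - 1]
    axes = evecs[:, order]
    # fix signs: largest-magnitude element of each axis positive
    signs = np.sign(axes[np.argmax(np.abs(axes), axis=0), np.arange(axes.shape[1])])
    signs[signs == 0] = 1.0
    axes = axes * signs[None, :]
    return axes, X @ axes


def fit_component_model(matrix: np.ndarray, labels, n_pcs: int = 15,
                        random_state: int = 0) -> ComponentModel:
    """PCA followed by LDA, with centroids and priors for prediction."""
    model = fit_pca(matrix, n_pcs, random_state)
    labels = np.asarray(labels)
    axes, cv = fit_lda(model.pc_scores, labels)
    classes = tuple(c for c in CLASS_ORDER if c in labels) or \
        tuple(sorted(set(labels.tolist())))
    model.classes = classes
    model.cv_axes = axes
    model.cv_scores = cv
    model.cv_centroids = np.vstack([cv[labels == c].mean(axis=0)
                                    for c in classes])
    model.priors = np.array([(labels == c).mean() for c in classes])
    return model


@dataclass
class EvaluationReport:
    """Dual-level confusion matrix plus the standard derived metrics."""

    level: str                      # "spectrum" or "patient"
    classes: tuple[str, ...]
    confusion: np.ndarray           # rows = true class
    sensitivity: float = 0.0        # PD vs rest
    specificity: float = 0.0
    accuracy: float = 0.0           # multiclass trace/total
    per_class_recall: dict[str, float] = field(default_factory=dict)
    mcc: float = 0.0                # PD vs no-PD
    error_rate: float = 0.0
    auc: float | None = None        # PD vs rest
    n_folds: int = 0

    def as_dict(self) -> dict:
        out = {
            "level": self.level,
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "per_class_recall": self.per_class_recall,
            "mcc": self.mcc,
            "error_rate": self.error_rate,
            "n_folds": self.n_folds,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def confusion_matrix_from_labels(true, pred,
                                 classes=CLASS_ORDER) -> np.ndarray:
    true = np.asarray(true)
    pred = np.asarray(pred)
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(true, pred):
        conf[index[t], index[p]] += 1
    return conf


def confusion_metrics(confusion: np.ndarray, classes=CLASS_ORDER,
                      positive: str = "PD") -> dict[str, float]:
    """Multiclass accuracy plus positive-vs-rest collapsed metrics.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), MCC from the
    collapsed 2x2 table; accuracy and error rate are 3-class
    (trace / total).  A zero MCC denominator yields MCC = 0.
    """
    conf = np.asarray(confusion, dtype=float)
    total = conf.sum()
    if total == 0:
        raise ValidationError("empty confusion matrix")
    i = list(classes).index(positive)
    tp = conf[i, i]
    fn = conf[i, :].sum() - tp
    fp = conf[:, i].sum() - tp
    tn = total - tp - fn - fp
    accuracy = np.trace(conf) / total
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    recalls = {}
    for j, c in enumerate(classes):
        row = conf[j, :].sum()
        recalls[c] = conf[j, j] / row if row else float("nan")
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": accuracy,
        "error_rate": 1.0 - accuracy,
        "mcc": float(mcc),
        "per_class_recall": recalls,
    }


def build_report(level: str, true, pred, classes=None,
                 scores=None, n_folds: int = 0) -> EvaluationReport:
    """Assemble an EvaluationReport from per-item truths/predictions."""
    true = np.asarray(true)
    classes = tuple(classes) if classes is not None else \
        tuple(c for c in CLASS_ORDER if c in true)
    conf = confusion_matrix_from_labels(true, pred, classes)
    metrics = confusion_metrics(conf, classes)
    auc = None
    if scores is not None and "PD" in classes:
        binary = (true == "PD").astype(int)
        if 0 < binary.sum() < binary.size:
            auc = roc_auc(np.asarray(scores), binary)
    return EvaluationReport(
        level=level, classes=classes, confusion=conf,
        sensitivity=metrics["sensitivity"], specificity=metrics["specificity"],
        accuracy=metrics["accuracy"],
        per_class_recall=metrics["per_class_recall"],
        mcc=metrics["mcc"], error_rate=metrics["error_rate"],
        auc=auc, n_folds=n_folds)


def loocv_spectrum_level(dataset: CohortDataset, n_pcs: int = 15,
                         random_state: int = 0) -> EvaluationReport:
    """Leave-one-spectrum-out evaluation of the PCA-LDA model.

    Each fold refits PCA and LDA on the remaining spectra and
    classifies the held-out one; exactly n folds are run for n spectra.
    """
    matrix = dataset.intensity_matrix()
    labels = dataset.labels()
    for c in set(labels.tolist()):
        if (labels == c).sum() < 3:
            raise ValidationError(
                f"class {c!r} has too few spectra for leave-one-out")
    n = matrix.shape[0]
    preds = np.empty(n, dtype=object)
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = fit_component_model(matrix[mask], labels[mask], n_pcs,
                                    random_state)
        assert mask[i] == False and mask.sum() == n - 1  # fold bookkeeping
        preds[i] = model.predict(matrix[i][None, :])[0]
        scores[i] = model.pd_score(matrix[i][None, :])[0]
        mask[i] = True
    return build_report("spectrum", labels, preds, scores=scores, n_folds=n)


def roc_auc(scores: np.ndarray, binary_labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney probability (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels).astype(int)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both positive and negative labels")
    ranks = scipy.stats.rankdata(scores)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def anova_on_component(values, groups) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value across groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in dict.fromkeys(groups.tolist())]
    if len(samples) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    for s in samples:
        if len(s) < 2:
            raise ValidationError("every group needs >= 2 values")
    f, p = scipy.stats.f_oneway(*samples)
    return float(f), float(p)
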