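"""Augmented patient-level classification under LOPOCV.

Training examples are enlarged with label-preserving distortions
(Gaussian noise, integer shifts of the Raman axis with edge
replication, and a random linear slope), with per-class multipliers
derived from the class imbalance so augmented class sizes roughly
match.  Classifiers: SVM and random forest baselines (scikit-learn), a
fully connected network and a 1D CNN (in-package numpy engine).
Evaluation is leave-one-patient-out: every fold holds out all spectra
of one subject, augmentation and tuning happen strictly inside the
fold's training partition, and the patient label is the majority vote
over the held-out spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold, GroupKFold
from sklearn.svm import SVC

from .io import CohortDataset, RamanSpectrum, ValidationError
from .mva import CLASS_ORDER, EvaluationReport, build_report
from .nn import NetworkSpec, NeuralNetClassifier

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("svm", "rf", "fcnn", "cnn")


@dataclass
class AugmentationParams:
    """Distortion magnitudes for spectral augmentation (a.u. refer to
    normalized intensities)."""

    noise_sd: float = 0.003
    shift_max: int = 3          # grid points
    slope_max: float = 0.01     # a.u. across the full axis span
    multiplier_base: int = 10

    def __post_init__(self):
        if min(self.noise_sd, self.shift_max, self.slope_max) < 0:
            raise ValidationError("augmentation magnitudes must be >= 0")
        if self.multiplier_base < 1:
            raise ValidationError("multiplier_base must be >= 1")


@dataclass
class SearchSpace:
    """Hyper-parameter space: per name either a discrete list or a
    (low, high) continuous range."""

    space: dict[str, object] = field(default_factory=dict)
    budget: int = 20
    cv_folds: int = 10

    def __post_init__(self):
        if self.budget < 1:
            raise ValidationError("search budget must be >= 1")
        for name, spec in self.space.items():
            if isinstance(spec, (list, tuple)) and len(spec) == 0:
                raise ValidationError(f"empty range for {name}")


def derive_class_multipliers(class_counts: dict[str, int],
                             base: int = 10) -> dict[str, int]:
    """Imbalance-compensating per-class multipliers.

    multiplier_c = round(base * max_count / count_c), so the largest
    class is augmented ``base``-fold and smaller classes more, making
    augmented class sizes agree to within one original class size.
    """
    if any(c < 1 for c in class_counts.values()):
        raise ValidationError("class counts must be >= 1")
    top = max(class_counts.values())
    return {c: int(np.floor(base * top / n + 0.5))
            for c, n in class_counts.items()}


def augment_spectrum(spectrum: RamanSpectrum, params: AugmentationParams,
                     rng: np.random.Generator,
                     log: list | None = None) -> RamanSpectrum:
    """One distorted copy: integer axis shift (edge-replicated), additive
    Gaussian noise and a random linear ramp.  The label (subject/group
    provenance) is preserved; the drawn distortions can be recorded via
    ``log``."""
    y = spectrum.intensities
    u = int(rng.integers(-params.shift_max, params.shift_max + 1)) \
        if params.shift_max > 0 else 0
    out = np.empty_like(y)
    if u > 0:
        out[u:] = y[:-u]
        out[:u] = y[0]
    elif u < 0:
        out[:u] = y[-u:]
        out[u:] = y[-1]
    else:
        out[:] = y
    slope = float(rng.uniform(-params.slope_max, params.slope_max)) \
        if params.slope_max > 0 else 0.0
    if slope:
        t = np.linspace(0.0, 1.0, y.size)
        out = out + slope * t
    if params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, size=y.size)
    if log is not None:
        log.append({"source": spectrum.acquisition_id, "shift": u,
                    "slope": slope})
    return dc_replace(spectrum, intensities=out,
                      acquisition_id=spectrum.acquisition_id + "~aug")


class _SklearnWrapper:
    """Adapts sklearn classifiers to the fixed CTRL/PD/AD column order."""

    def __init__(self, model):
        self.model = model

    def fit(self, X, y):
        self.model.fit(X, y)
        self.classes_ = self.model.classes_
        return self

    def predict_proba(self, X):
        return self.model.predict_proba(X)

    def predict(self, X):
        return self.model.predict(X)


def train_classifier(kind: str, X: np.ndarray, y, spec=None, seed: int = 0):
    """Fit one of svm / rf / fcnn / cnn on a spectrum matrix.

    ``spec`` is a NetworkSpec for the neural kinds or a dict of
    estimator keyword arguments for svm/rf.  The returned model exposes
    ``predict`` and ``predict_proba`` (columns in ``model.classes_``
    order, summing to one).
    """
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise ValidationError("training set has a single class")
    if kind == "svm":
        kwargs = dict(kernel="rbf", C=10.0, gamma="scale", probability=True,
                      random_state=seed)
        kwargs.update(spec or {})
        return _SklearnWrapper(SVC(**kwargs)).fit(X, y)
    if kind == "rf":
        kwargs = dict(n_estimators=200, random_state=seed)
        kwargs.update(spec or {})
        return _SklearnWrapper(RandomForestClassifier(**kwargs)).fit(X, y)
    if kind in ("fcnn", "cnn"):
        net_spec = spec if isinstance(spec, NetworkSpec) else \
            NetworkSpec(**(spec or {}))
        return NeuralNetClassifier(net_spec, kind=kind, seed=seed).fit(X, y)
    raise ValidationError(f"unknown classifier kind {kind!r}; "
                          f"choose from {CLASSIFIER_KINDS}")


def _candidate(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        if isinstance(spec, list):
            out[name] = spec[int(rng.integers(len(spec)))]
        else:
            lo, hi = spec
            out[name] = float(rng.uniform(lo, hi))
    return out


def _encode(space: dict, params: dict) -> list[float]:
    row = []
    for name, spec in space.items():
        if isinstance(spec, list):
            row.append(float(spec.index(params[name])))
        else:
            row.append(float(params[name]))
    return row


def _cv_error(kind: str, params: dict, X, y, groups, cv_folds: int,
              seed: int, base_spec) -> float:
    """Average classification error over (group-aware) k-fold CV."""
    y = np.asarray(y)
    if kind in ("fcnn", "cnn"):
        spec = dc_replace(base_spec or NetworkSpec(), **params)
    else:
        spec = dict(base_spec or {}, **params)
    if groups is not None:
        uniq = len(set(np.asarray(groups).tolist()))
        splitter = GroupKFold(n_splits=min(cv_folds, uniq))
        folds = splitter.split(X, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=min(cv_folds, np.bincount(
            np.unique(y, return_inverse=True)[1]).min()),
            shuffle=True, random_state=seed)
        folds = splitter.split(X, y)
    errors = []
    for tr, te in folds:
        if len(set(y[tr].tolist())) < 2:
            continue
        model = train_classifier(kind, X[tr], y[tr], spec, seed)
        errors.append(float(np.mean(model.predict(X[te]) != y[te])))
    if not errors:
        raise ValidationError("no valid CV fold for tuning")
    return float(np.mean(errors))


def tune_hyperparameters(kind: str, search_space: SearchSpace, X, y,
                         groups=None, seed: int = 0, base_spec=None
                         ) -> tuple[dict, list[dict]]:
    """Propose/evaluate hyper-parameter search minimizing CV error.

    A short random phase seeds a random-forest surrogate that then
    ranks random proposals by predicted error (surrogate-guided when
    the budget permits, pure random otherwise).  Every candidate is
    scored by ``cv_folds``-fold cross-validated classification error on
    the training data only.  Returns the best parameters and the full
    trial log (one entry per evaluation, length = budget).
    """
    rng = np.random.default_rng(seed)
    space = search_space.space
    log: list[dict] = []
    tried: list[tuple[dict, float]] = []
    n_random = max(1, min(search_space.budget,
                          5 if search_space.budget > 6 else search_space.budget))
    for trial in range(search_space.budget):
        if trial < n_random or len(space) == 0:
            params = _candidate(space, rng)
        else:
            surrogate = RandomForestRegressor(n_estimators=50,
                                              random_state=seed)
            Xs = np.array([_encode(space, p) for p, _ in tried])
            ys = np.array([e for _, e in tried])
            surrogate.fit(Xs, ys)
            pool = [_candidate(space, rng) for _ in range(64)]
            pred = surrogate.predict(np.array([_encode(space, p)
                                               for p in pool]))
            params = pool[int(np.argmin(pred))]
        error = _cv_error(kind, params, X, y, groups, search_space.cv_folds,
                          seed, base_spec)
        tried.append((params, error))
        log.append({"trial": trial, "params": dict(params), "error": error})
    best = min(tried, key=lambda t: t[1])[0]
    return best, log


def majority_vote(labels, probabilities=None, classes=CLASS_ORDER) -> str:
    """Patient label from spectrum votes.

    Ties break by the largest summed class probability, remaining ties
    by the fixed class order CTRL < PD < AD.
    """
    labels = list(labels)
    if not labels:
        raise ValidationError("majority_vote needs >= 1 prediction")
    counts = {c: labels.count(c) for c in set(labels)}
    top = max(counts.values())
    tied = [c for c, n in counts.items() if n == top]
    if len(tied) == 1:
        return tied[0]
    if probabilities is not None:
        probs = np.asarray(probabilities, dtype=float)
        sums = {c: probs[:, list(classes).index(c)].sum() for c in tied}
        best = max(sums.values())
        tied = [c for c in tied if sums[c] == best]
    return min(tied, key=lambda c: list(classes).index(c))


def _augment_fold(spectra: list[RamanSpectrum], groups_of: dict[str, str],
                  params: AugmentationParams, rng: np.random.Generator
                  ) -> list[RamanSpectrum]:
    counts: dict[str, int] = {}
    for s in spectra:
        counts[groups_of[s.subject_id]] = counts.get(
            groups_of[s.subject_id], 0) + 1
    multipliers = derive_class_multipliers(counts, params.multiplier_base)
    out = []
    for s in spectra:
        m = multipliers[groups_of[s.subject_id]]
        for _ in range(m):
            out.append(augment_spectrum(s, params, rng))
    return out


def lopocv_evaluate(dataset: CohortDataset, kind: str = "cnn",
                    spec=None, augmentation: AugmentationParams | None = None,
                    seed: int = 0, search_space: SearchSpace | None = None
                    ) -> tuple[EvaluationReport, EvaluationReport]:
    """Leave-one-patient-out evaluation with fold-internal augmentation.

    One fold per subject with >= 1 spectrum; within each fold the
    training partition excludes the held-out subject entirely (checked
    programmatically), is augmented with imbalance-derived multipliers,
    and optionally tuned; the held-out subject's spectra are classified
    and the patient label is their majority vote.  Returns the
    (spectrum-level, patient-level) evaluation reports.
    """
    augmentation = augmentation or AugmentationParams()
    groups_of = {sid: rec.group for sid, rec in dataset.subjects.items()}
    counts = dataset.counts()
    fold_subjects = [sid for sid in sorted(counts) if counts[sid] > 0]
    for sid, n in counts.items():
        if n == 0:
            logger.warning("subject %s has no spectra; skipped", sid)
    per_class_subjects: dict[str, int] = {}
    for sid in fold_subjects:
        g = groups_of[sid]
        per_class_subjects[g] = per_class_subjects.get(g, 0) + 1
    if any(n < 2 for n in per_class_subjects.values()):
        raise ValidationError("need >= 2 patients per class for LOPOCV")

    spec_true, spec_pred, spec_score = [], [], []
    pat_true, pat_pred, pat_score = [], [], []
    for fold_i, sid in enumerate(fold_subjects):
        rng = np.random.default_rng((seed, fold_i))
        train = [s for s in dataset.spectra if s.subject_id != sid]
        test = [s for s in dataset.spectra if s.subject_id == sid]
        augmented = _augment_fold(train, groups_of, augmentation, rng)
        contributing = {s.subject_id for s in train} | \
            {s.subject_id for s in augmented}
        if sid in contributing:  # no-leakage guarantee
            raise AssertionError(
                f"fold {sid}: held-out subject leaked into training")
        all_train = train + augmented
        X = np.vstack([s.intensities for s in all_train])
        y = np.array([groups_of[s.subject_id] for s in all_train])
        fit_spec = spec
        if search_space is not None:
            tr_groups = np.array([s.subject_id for s in all_train])
            best, _log = tune_hyperparameters(
                kind, search_space, X, y, groups=tr_groups, seed=seed,
                base_spec=spec)
            if kind in ("fcnn", "cnn"):
                fit_spec = dc_replace(spec or NetworkSpec(), **best)
            else:
                fit_spec = dict(spec or {}, **best)
        model = train_classifier(kind, X, y, fit_spec, seed)
        Xte = np.vstack([s.intensities for s in test])
        probs = model.predict_proba(Xte)
        # reorder probability columns to the canonical class order
        order = [list(model.classes_).index(c) for c in CLASS_ORDER
                 if c in model.classes_]
        present = [c for c in CLASS_ORDER if c in model.classes_]
        probs = probs[:, order]
        preds = [present[j] for j in probs.argmax(axis=1)]
        truth = groups_of[sid]
        i_pd = present.index("PD") if "PD" in present else None
        for j, p in enumerate(preds):
            spec_true.append(truth)
            spec_pred.append(p)
            spec_score.append(probs[j, i_pd] if i_pd is not None else 0.0)
        pat_true.append(truth)
        pat_pred.append(majority_vote(preds, probs, classes=present))
        pat_score.append(float(probs[:, i_pd].mean())
                         if i_pd is not None else 0.0)

    spectrum_report = build_report("spectrum", spec_true, spec_pred,
                                   scores=spec_score,
                                   n_folds=len(fold_subjects))
    patient_report = build_report("patient", pat_true, pat_pred,
                                  scores=pat_score,
                                  n_folds=len(fold_subjects))
    return spectrum_report, patient_report


__all__ = [
    "AugmentationParams", "NetworkSpec", "SearchSpace",
    "derive_class_multipliers", "augment_spectrum", "train_classifier",
    "tune_hyperparameters", "majority_vote", "lopocv_evaluate",
]
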