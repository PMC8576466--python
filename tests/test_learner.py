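import numpy as np
import pytest

from conftest import make_gaussian_dataset
from ramanfp.io import RamanSpectrum, ValidationError
from ramanfp.learner import (AugmentationParams, SearchSpace, _augment_fold,
                             augment_spectrum, derive_class_multipliers,
                             lopocv_evaluate, majority_vote,
                             train_classifier, tune_hyperparameters)
from ramanfp.nn import NetworkSpec, NeuralNetClassifier

TINY_NET = dict(conv_blocks=[(4, 5, 2)], dense_layers=[16],
                dropout_rates=[0.2], max_epochs=40, early_stop_patience=6,
                batch_size=16)


# --------------------------------------------------------------- multipliers

def test_imbalance_multipliers():
    assert derive_class_multipliers({"CTRL": 33, "PD": 23, "AD": 10}, 10) == \
        {"CTRL": 10, "PD": 14, "AD": 33}
    assert derive_class_multipliers({"A": 7, "B": 7}, 10) == {"A": 10, "B": 10}
    assert derive_class_multipliers({"A": 5, "B": 5}, 1) == {"A": 1, "B": 1}
    counts = {"CTRL": 33, "PD": 23, "AD": 10}
    mult = derive_class_multipliers(counts, 10)
    sizes = [mult[c] * counts[c] for c in counts]
    assert max(sizes) - min(sizes) <= max(counts.values())


# -------------------------------------------------------------- augmentation

def _spectrum(n=200, seed=0):
    rng = np.random.default_rng(seed)
    axis = np.linspace(400, 1600, n)
    return RamanSpectrum(axis, np.sin(axis / 90) + rng.normal(0, 0.01, n),
                         "S0", "a0")


def test_zero_params_is_identity():
    s = _spectrum()
    out = augment_spectrum(s, AugmentationParams(noise_sd=0, shift_max=0,
                                                 slope_max=0),
                           np.random.default_rng(0))
    assert np.array_equal(out.intensities, s.intensities)
    assert out.subject_id == s.subject_id


def test_noise_injection_sd(rng):
    s = _spectrum()
    params = AugmentationParams(noise_sd=0.05, shift_max=0, slope_max=0)
    diffs = np.vstack([
        augment_spectrum(s, params, rng).intensities - s.intensities
        for _ in range(1000)])
    pointwise_sd = diffs.std(axis=0)
    assert np.mean(pointwise_sd) == pytest.approx(0.05, rel=0.05)


def test_shift_draw_matches_cross_correlation(rng):
    s = _spectrum(400)
    params = AugmentationParams(noise_sd=0, shift_max=5, slope_max=0)
    for _ in range(20):
        log = []
        out = augment_spectrum(s, params, rng, log=log)
        u = log[0]["shift"]
        assert -5 <= u <= 5
        lags = range(-6, 7)
        scores = [np.dot(np.roll(out.intensities, -lag)[6:-6],
                         s.intensities[6:-6]) for lag in lags]
        assert list(lags)[int(np.argmax(scores))] == u


def test_slope_and_edge_replication(rng):
    s = _spectrum(100)
    params = AugmentationParams(noise_sd=0, shift_max=3, slope_max=0)
    log = []
    while True:
        out = augment_spectrum(s, params, rng, log=log)
        if log[-1]["shift"] == 3:
            break
    assert np.allclose(out.intensities[:3], s.intensities[0])


def test_augment_fold_sizes_match_multipliers():
    groups = ["CTRL"] * 4 + ["PD"] * 3 + ["AD"] * 2
    ds = make_gaussian_dataset(np.random.default_rng(0), groups, n_spectra=3)
    groups_of = {sid: rec.group for sid, rec in ds.subjects.items()}
    params = AugmentationParams(multiplier_base=4)
    out = _augment_fold(ds.spectra, groups_of, params,
                        np.random.default_rng(1))
    counts = {"CTRL": 12, "PD": 9, "AD": 6}
    mult = derive_class_multipliers(counts, 4)
    augmented = {g: 0 for g in counts}
    for s in out:
        augmented[groups_of[s.subject_id]] += 1
    assert augmented == {g: mult[g] * counts[g] for g in counts}


# --------------------------------------------------------------- classifiers

def _blobs(rng, n=30, gap=10.0, n_features=40):
    a = rng.normal(0, 1, size=(n, n_features))
    b = rng.normal(0, 1, size=(n, n_features))
    b[:, :5] += gap
    X = np.vstack([a, b]).astype(np.float32)
    y = np.array(["CTRL"] * n + ["PD"] * n)
    return X, y


@pytest.mark.parametrize("kind", ["svm", "rf", "fcnn", "cnn"])
def test_separable_blobs_fit_perfectly(kind, rng):
    X, y = _blobs(rng)
    spec = TINY_NET if kind in ("fcnn", "cnn") else None
    model = train_classifier(kind, X, y, spec, seed=0)
    assert np.mean(model.predict(X) == y) == 1.0
    probs = model.predict_proba(X)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert probs.min() >= 0


def test_single_class_and_bad_spec_rejected(rng):
    X, y = _blobs(rng)
    with pytest.raises(ValidationError):
        train_classifier("svm", X, np.array(["PD"] * len(y)))
    with pytest.raises(ValidationError):
        train_classifier("cnn", X, y, dict(conv_blocks=[]))
    with pytest.raises(ValidationError):
        train_classifier("boost", X, y)


def test_network_spec_validation():
    assert NetworkSpec().validate("cnn") == []
    assert NetworkSpec(conv_blocks=[]).validate("fcnn") == []
    assert any("conv" in v for v in NetworkSpec(conv_blocks=[]).validate("cnn"))
    assert any("dropout" in v
               for v in NetworkSpec(dropout_rates=[1.5]).validate("cnn"))


def test_nn_training_is_deterministic(rng):
    X, y = _blobs(rng)
    p1 = NeuralNetClassifier(NetworkSpec(**TINY_NET), "cnn", 3).fit(
        X, y).predict_proba(X)
    p2 = NeuralNetClassifier(NetworkSpec(**TINY_NET), "cnn", 3).fit(
        X, y).predict_proba(X)
    assert np.array_equal(p1, p2)


# -------------------------------------------------------------------- tuning

def test_tuning_contract(rng):
    X, y = _blobs(rng, n=20)
    groups = np.array([f"g{i % 8}" for i in range(len(y))])
    single = SearchSpace(space={"C": [1.0]}, budget=1, cv_folds=4)
    best, log = tune_hyperparameters("svm", single, X, y, groups)
    assert best == {"C": 1.0} and len(log) == 1
    space = SearchSpace(space={"n_estimators": [5, 20]}, budget=4, cv_folds=4)
    best, log = tune_hyperparameters("rf", space, X, y, groups, seed=1)
    assert len(log) == 4
    assert all({"trial", "params", "error"} <= set(t) for t in log)
    with pytest.raises(ValidationError):
        SearchSpace(space={}, budget=0)


def test_tuning_prefers_adequate_capacity(rng):
    """A width-1 dense bottleneck provably underfits a 3-class problem;
    the search must select the wider alternative."""
    a = rng.normal(0, 0.3, size=(15, 20))
    b = rng.normal(0, 0.3, size=(15, 20)); b[:, 0] += 8
    c = rng.normal(0, 0.3, size=(15, 20)); c[:, 1] += 8
    X = np.vstack([a, b, c]).astype(np.float32)
    y = np.array(["CTRL"] * 15 + ["PD"] * 15 + ["AD"] * 15)
    space = SearchSpace(space={"dense_layers": [[1], [16]]}, budget=2,
                        cv_folds=3)
    base = NetworkSpec(conv_blocks=[], dropout_rates=[0.0], max_epochs=60,
                       early_stop_patience=10, batch_size=16)
    best, log = tune_hyperparameters("fcnn", space, X, y, seed=0,
                                     base_spec=base)
    assert best["dense_layers"] == [16]


# ------------------------------------------------------------- majority vote

def test_majority_vote_rules():
    assert majority_vote(["PD", "PD", "AD"]) == "PD"
    probs = np.array([[0.0, 0.7, 0.3], [0.0, 0.6, 0.4]])
    assert majority_vote(["PD", "AD"], probs) == "PD"
    assert majority_vote(["CTRL"] * 25) == "CTRL"
    # full tie in counts and probabilities -> fixed class order
    even = np.array([[0.5, 0.0, 0.5], [0.5, 0.0, 0.5]])
    assert majority_vote(["AD", "CTRL"], even) == "CTRL"
    with pytest.raises(ValidationError):
        majority_vote([])


def test_condorcet_patient_vote_beats_spectrum_rate(rng):
    """Independent per-spectrum errors at rate 0.3 over 21 spectra:
    majority voting lifts patient accuracy above spectrum accuracy."""
    classes = ("CTRL", "PD", "AD")
    spectrum_correct = 0
    patient_correct = 0
    n_patients, n_spectra = 100, 21
    for _ in range(n_patients):
        truth = classes[int(rng.integers(3))]
        others = [c for c in classes if c != truth]
        preds = [truth if rng.random() > 0.3 else
                 others[int(rng.integers(2))] for _ in range(n_spectra)]
        spectrum_correct += sum(p == truth for p in preds)
        patient_correct += majority_vote(preds) == truth
    assert patient_correct / n_patients > spectrum_correct / (
        n_patients * n_spectra)


# -------------------------------------------------------------------- LOPOCV

def test_lopocv_perfect_on_separated_cohort(rng):
    ds = make_gaussian_dataset(
        rng, ["CTRL"] * 3 + ["PD"] * 3 + ["AD"] * 2, n_spectra=4,
        shift_by_group={"CTRL": 0.0, "PD": 8.0, "AD": -8.0})
    aug = AugmentationParams(noise_sd=0.05, shift_max=2, slope_max=0.01,
                             multiplier_base=2)
    srep, prep = lopocv_evaluate(ds, kind="rf", augmentation=aug, seed=0)
    assert prep.accuracy == 1.0
    assert srep.accuracy == 1.0
    assert prep.n_folds == 8
    assert prep.confusion.sum() == 8


def test_lopocv_requires_two_patients_per_class(rng):
    ds = make_gaussian_dataset(rng, ["CTRL", "CTRL", "PD"], n_spectra=3)
    with pytest.raises(ValidationError, match="2 patients"):
        lopocv_evaluate(ds, kind="rf")


def test_lopocv_deterministic_given_seed(rng):
    ds = make_gaussian_dataset(
        rng, ["CTRL"] * 3 + ["PD"] * 2, n_spectra=3,
        shift_by_group={"CTRL": 0.0, "PD": 5.0})
    aug = AugmentationParams(multiplier_base=2)
    r1 = lopocv_evaluate(ds, kind="rf", augmentation=aug, seed=11)
    r2 = lopocv_evaluate(ds, kind="rf", augmentation=aug, seed=11)
    assert np.array_equal(r1[0].confusion, r2[0].confusion)
    assert np.array_equal(r1[1].confusion, r2[1].confusion)
    assert r1[0].auc == r2[0].auc
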