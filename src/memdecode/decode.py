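"""Multi-class MVPA decoding of individual memories.

The decoder follows the classic ROI-restricted searchlight + SVM
recipe: within each of k (default 10) stratified cross-validation
folds, every searchlight sphere is scored by an inner cross-validated
ECOC-SVM on the *training* trials only, the voxels of all spheres
scoring significantly above chance are pooled into the fold's feature
set,
and a linear soft-margin SVM ensemble (error-correcting output codes,
one dichotomy per class, Hamming-distance decoding) is trained on those
voxels and evaluated on the held-out trials.  Feature selection never
sees test trials, which is what keeps the fold accuracies unbiased
("double dipping" is avoided by construction).

Linear SVMs are fitted with scikit-learn's liblinear backend at fixed
C; features are z-scored with training-split statistics inside the
classifier, so decoding is invariant to global affine rescaling of the
patterns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .core import TrialPatternSet
from .searchlight import SphereSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ECOC codebook and classifier
# ---------------------------------------------------------------------------

@dataclass
class EcocCodebook:
    """Binary codewords (one row per class) over dichotomies.

    The default construction is one-vs-rest: for three classes the
    codewords are (1,0,0), (0,1,0), (0,0,1) — minimum pairwise Hamming
    distance 2 — and dichotomy d relabels class d as 1 and the rest
    as 0.
    """

    codewords: np.ndarray  # (n_classes, n_dichotomies) of 0/1

    def __post_init__(self) -> None:
        self.codewords = np.asarray(self.codewords, dtype=int)
        if len(np.unique(self.codewords, axis=0)) != self.codewords.shape[0]:
            raise ValueError("codewords must be pairwise distinct")
        for d in range(self.n_dichotomies):
            col = self.codewords[:, d]
            if col.min() == col.max():
                raise ValueError(f"dichotomy {d} does not split the classes")

    @property
    def n_classes(self) -> int:
        return self.codewords.shape[0]

    @property
    def n_dichotomies(self) -> int:
        return self.codewords.shape[1]

    def min_hamming_distance(self) -> int:
        dists = [
            int(np.sum(self.codewords[i] != self.codewords[j]))
            for i in range(self.n_classes)
            for j in range(i + 1, self.n_classes)
        ]
        return min(dists)

    def is_one_vs_rest(self) -> bool:
        return self.n_classes >= 3 and np.array_equal(
            self.codewords, np.eye(self.n_classes, dtype=int)
        )


def ecoc_codebook(n_classes: int) -> EcocCodebook:
    """One-vs-rest codebook: identity codewords for >= 3 classes, a
    single dichotomy with codewords (1,) and (0,) for two classes."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if n_classes == 2:
        return EcocCodebook(codewords=np.array([[1], [0]]))
    return EcocCodebook(codewords=np.eye(n_classes, dtype=int))


def hamming_decode(bits: np.ndarray, codebook: EcocCodebook) -> np.ndarray:
    """Class indices minimising Hamming distance to the codewords;
    ties resolve to the lowest class index."""
    bits = np.atleast_2d(np.asarray(bits, dtype=int))
    dists = (bits[:, None, :] != codebook.codewords[None, :, :]).sum(axis=2)
    return np.argmin(dists, axis=1)


class EcocSvm:
    """Linear soft-margin SVM ensemble recombined by Hamming decoding.

    One binary SVM is trained per dichotomy of the codebook; a test
    pattern's vector of binary SVM outputs is decoded to the class with
    the nearest codeword.  Features are z-scored with training-set
    statistics.  For one-vs-rest codebooks the dichotomy SVMs are fitted
    in a single liblinear call (they are independent subproblems, so the
    solutions are identical to separate fits).
    """

    def __init__(self, C: float = 1.0, codebook: EcocCodebook | None = None):
        if C <= 0:
            raise ValueError("C must be positive")
        self.C = C
        self.codebook = codebook

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EcocSvm":
        X = np.asarray(X, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain at least 2 classes")
        if self.codebook is None:
            self.codebook = ecoc_codebook(len(self.classes_))
        elif self.codebook.n_classes != len(self.classes_):
            raise ValueError("codebook does not match the number of classes")
        self._mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Xz = (X - self._mean) / self._sd
        if self.codebook.is_one_vs_rest():
            self._svm = LinearSVC(C=self.C, max_iter=5000, random_state=0)
            self._svm.fit(Xz, y_idx)
            self._dichotomy_svms = None
        else:
            self._svm = None
            self._dichotomy_svms = []
            for d in range(self.codebook.n_dichotomies):
                y_bin = self.codebook.codewords[y_idx, d]
                svm = LinearSVC(C=self.C, max_iter=5000, random_state=0)
                svm.fit(Xz, y_bin)
                self._dichotomy_svms.append(svm)
        return self

    def decision_bits(self, X: np.ndarray) -> np.ndarray:
        Xz = (np.asarray(X, dtype=np.float64) - self._mean) / self._sd
        if self._svm is not None:
            return (self._svm.decision_function(Xz) > 0).astype(int)
        bits = np.empty((Xz.shape[0], self.codebook.n_dichotomies), dtype=int)
        for d, svm in enumerate(self._dichotomy_svms):
            dec = svm.decision_function(Xz)
            positive_is_one = svm.classes_[1] == 1
            bits[:, d] = (dec > 0) == positive_is_one
        return bits

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = hamming_decode(self.decision_bits(X), self.codebook)
        return self.classes_[idx]


def ecoc_classify(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    feature_indices: np.ndarray | None = None,
    codebook: EcocCodebook | None = None,
    C: float = 1.0,
) -> np.ndarray:
    """Train the ECOC-SVM on (optionally feature-restricted) training
    patterns and return predicted labels for the test patterns."""
    if feature_indices is not None:
        if len(feature_indices) == 0:
            raise ValueError("feature_indices must be non-empty")
        train_X = train_X[:, feature_indices]
        test_X = test_X[:, feature_indices]
    clf = EcocSvm(C=C, codebook=codebook).fit(train_X, train_y)
    return clf.predict(test_X)


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Stratified k-fold partition of trials."""

    k: int
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)
    classes: np.ndarray


def make_folds(patterns: TrialPatternSet, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan over the pattern set's memory labels.

    If the smallest class has fewer than ``k`` trials, ``k`` is reduced
    to that count (and the reduction logged); a class with fewer than
    two trials is an error.
    """
    y = patterns.memory_labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has fewer than 2 trials"
        )
    k_eff = int(min(k, counts.min()))
    if k_eff < k:
        logger.info("reducing folds from %d to %d (smallest class)", k, k_eff)
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    folds = [
        (train.copy(), test.copy()) for train, test in skf.split(patterns.patterns, y)
    ]
    return FoldPlan(k=k_eff, folds=folds, classes=classes)


# ---------------------------------------------------------------------------
# searchlight feature selection
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Voxels selected for one fold, with the per-sphere training scores."""

    fold_id: int
    voxel_indices: np.ndarray
    sphere_scores: np.ndarray
    chance: float
    empty: bool = False  # no sphere cleared the threshold; best sphere used
    selection_alpha: float = 0.05


def _score_spheres(
    X: np.ndarray,
    y_idx: np.ndarray,
    spheres: SphereSet,
    codebook: EcocCodebook,
    C: float,
    inner_k: int,
    seed: int,
) -> np.ndarray:
    """Inner-CV pooled ECOC-SVM accuracy for every sphere (training data
    only).  Standardisation uses inner-training statistics; because
    z-scoring is per-feature, the full matrix is standardised once per
    inner fold and spheres slice into it."""
    classes, counts = np.unique(y_idx, return_counts=True)
    k_eff = int(min(inner_k, counts.min()))
    if k_eff < 2:
        raise ValueError("need at least 2 trials per class for sphere scoring")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    n_spheres = spheres.n_centers
    correct = np.zeros(n_spheres)
    total = 0
    ovr = codebook.is_one_vs_rest()
    for train, test in skf.split(X, y_idx):
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr = (X[train] - mu) / sd
        Xte = (X[test] - mu) / sd
        ytr, yte = y_idx[train], y_idx[test]
        total += len(test)
        for s, member in enumerate(spheres.members):
            if ovr:
                svm = LinearSVC(C=C, max_iter=5000, random_state=0)
                svm.fit(Xtr[:, member], ytr)
                dec = svm.decision_function(Xte[:, member])
                bits = (dec > 0).astype(int)
            else:
                bits = np.empty((len(test), codebook.n_dichotomies), dtype=int)
                for d in range(codebook.n_dichotomies):
                    y_bin = codebook.codewords[ytr, d]
                    svm = LinearSVC(C=C, max_iter=5000, random_state=0)
                    svm.fit(Xtr[:, member], y_bin)
                    dec = svm.decision_function(Xte[:, member])
                    positive_is_one = svm.classes_[1] == 1
                    bits[:, d] = (dec > 0) == positive_is_one
            pred = hamming_decode(bits, codebook)
            correct[s] += np.sum(pred == yte)
    return correct, total


def select_features(
    train_patterns: np.ndarray,
    train_labels: np.ndarray,
    spheres: SphereSet,
    codebook: EcocCodebook | None = None,
    chance: float | None = None,
    C: float = 1.0,
    inner_k: int = 5,
    seed: int = 0,
    fold_id: int = 0,
    alpha: float = 0.05,
) -> FeatureSet:
    """Select the fold's voxels from training trials only.

    Every sphere is scored by inner cross-validated ECOC-SVM accuracy;
    the feature set is the union of the voxels of all spheres whose
    accuracy beats chance *significantly* (one-sided binomial test at
    ``alpha`` on the pooled inner-test trial count).  The significance
    criterion keeps selections sparse under pure noise — a handful of
    spheres rather than most of the ROI — which is what makes the
    per-fold voxel counts and the information maps built from them
    informative.  If no sphere clears the threshold the single
    best-scoring sphere is returned with ``empty=True``.
    """
    from scipy import stats as _stats

    classes, y_idx = np.unique(train_labels, return_inverse=True)
    if codebook is None:
        codebook = ecoc_codebook(len(classes))
    if chance is None:
        chance = 1.0 / len(classes)
    correct, total = _score_spheres(
        np.asarray(train_patterns, dtype=np.float64),
        y_idx,
        spheres,
        codebook,
        C,
        inner_k,
        seed,
    )
    scores = correct / total
    # P(Binom(total, chance) >= correct) < alpha, and above chance at all
    pvals = _stats.binom.sf(correct - 1, total, chance)
    selected = np.flatnonzero((pvals < alpha) & (scores > chance))
    if len(selected) == 0:
        best = int(np.argmax(scores))
        return FeatureSet(
            fold_id=fold_id,
            voxel_indices=np.asarray(spheres.members[best]),
            sphere_scores=scores,
            chance=chance,
            empty=True,
            selection_alpha=alpha,
        )
    union = np.unique(np.concatenate([spheres.members[s] for s in selected]))
    return FeatureSet(
        fold_id=fold_id,
        voxel_indices=union,
        sphere_scores=scores,
        chance=chance,
        empty=False,
        selection_alpha=alpha,
    )


# ---------------------------------------------------------------------------
# cross-validated decoding
# ---------------------------------------------------------------------------

@dataclass
class DecodingResult:
    """Per-fold accuracies and feature sets for one ROI/condition decode."""

    fold_accuracies: np.ndarray
    feature_sets: list[FeatureSet]
    chance: float
    classes: np.ndarray
    confusion: np.ndarray
    n_trials: int
    seed: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_json(self, path=None) -> str:
        payload = {
            "fold_accuracies": self.fold_accuracies.tolist(),
            "mean_accuracy": self.mean_accuracy,
            "chance": self.chance,
            "classes": self.classes.tolist(),
            "confusion": self.confusion.tolist(),
            "n_trials": self.n_trials,
            "seed": self.seed,
            "fold_voxel_counts": [len(f.voxel_indices) for f in self.feature_sets],
            "fold_empty_selection": [f.empty for f in self.feature_sets],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def cross_validate(
    patterns: TrialPatternSet,
    spheres: SphereSet,
    k: int = 10,
    C: float = 1.0,
    seed: int = 0,
    inner_k: int = 5,
    selection_alpha: float = 0.05,
) -> DecodingResult:
    """k-fold cross-validated searchlight-selected ECOC-SVM decoding.

    Per fold: feature selection on the training trials, ECOC-SVM
    training on the selected voxels, evaluation on the held-out trials.
    Chance is 1/n_classes (33% for the three-memory problem).
    """
    if patterns.n_voxels != spheres.n_centers:
        raise ValueError("pattern voxel count does not match the sphere set")
    plan = make_folds(patterns, k=k, seed=seed)
    codebook = ecoc_codebook(len(plan.classes))
    chance = 1.0 / len(plan.classes)
    X = patterns.patterns
    y = patterns.memory_labels
    class_index = {c: i for i, c in enumerate(plan.classes)}
    accuracies = []
    feature_sets = []
    confusion = np.zeros((len(plan.classes), len(plan.classes)), dtype=int)
    for fold_id, (train, test) in enumerate(plan.folds):
        fs = select_features(
            X[train],
            y[train],
            spheres,
            codebook=codebook,
            chance=chance,
            C=C,
            inner_k=inner_k,
            seed=seed + fold_id,
            fold_id=fold_id,
            alpha=selection_alpha,
        )
        pred = ecoc_classify(
            X[train], y[train], X[test], fs.voxel_indices, codebook, C
        )
        accuracies.append(float(np.mean(pred == y[test])))
        feature_sets.append(fs)
        for truth, guess in zip(y[test], pred):
            confusion[class_index[truth], class_index[guess]] += 1
    return DecodingResult(
        fold_accuracies=np.asarray(accuracies),
        feature_sets=feature_sets,
        chance=chance,
        classes=plan.classes,
        confusion=confusion,
        n_trials=patterns.n_trials,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# set-level generalisation
# ---------------------------------------------------------------------------

def set_generalization(
    patterns_a: TrialPatternSet,
    patterns_b: TrialPatternSet,
    spheres: SphereSet | None = None,
    C: float = 1.0,
    seed: int = 0,
) -> float:
    """Condition decoding that must generalise across memories.

    A binary condition classifier is trained on the trials of all but
    one memory per condition and tested on the held-out memories'
    trials; the returned accuracy is averaged over every held-out-memory
    combination.  Above-chance (0.5) accuracy therefore requires a
    condition-level pattern component shared across the memories within
    each set, not memory identity.  When a sphere set is given, features
    are selected on each training split with the binary codebook.
    """
    mems_a = np.unique(patterns_a.memory_labels)
    mems_b = np.unique(patterns_b.memory_labels)
    if len(mems_a) < 2 or len(mems_b) < 2:
        raise ValueError("need at least 2 memories per condition")
    conds_a = np.unique(patterns_a.condition_labels)
    conds_b = np.unique(patterns_b.condition_labels)
    if len(conds_a) != 1 or len(conds_b) != 1 or conds_a[0] == conds_b[0]:
        raise ValueError("pattern sets must hold one distinct condition each")
    X = np.vstack([patterns_a.patterns, patterns_b.patterns])
    cond = np.concatenate(
        [patterns_a.condition_labels, patterns_b.condition_labels]
    )
    mem = np.concatenate([patterns_a.memory_labels, patterns_b.memory_labels])
    codebook = ecoc_codebook(2)
    accuracies = []
    for held_a, held_b in product(mems_a, mems_b):
        test_mask = (mem == held_a) | (mem == held_b)
        train, test = ~test_mask, test_mask
        features = None
        if spheres is not None:
            fs = select_features(
                X[train],
                cond[train],
                spheres,
                codebook=codebook,
                chance=0.5,
                C=C,
                seed=seed,
            )
            features = fs.voxel_indices
        pred = ecoc_classify(X[train], cond[train], X[test], features, codebook, C)
        accuracies.append(float(np.mean(pred == cond[test])))
    return float(np.mean(accuracies))
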