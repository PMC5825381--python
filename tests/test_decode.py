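"""ECOC-SVM decoding: codebooks, Hamming decoding, folds, searchlight
feature selection, cross-validation and set-level generalisation."""

import numpy as np
import pytest
from sklearn.svm import LinearSVC

from memdecode.core import TrialPatternSet
from memdecode.decode import (
    EcocCodebook,
    EcocSvm,
    cross_validate,
    ecoc_classify,
    ecoc_codebook,
    hamming_decode,
    make_folds,
    select_features,
    set_generalization,
)
from memdecode.searchlight import enumerate_spheres


def pattern_set(X, memories, conditions=None, trial_index=None):
    n = len(memories)
    return TrialPatternSet(
        patterns=X,
        memory_labels=np.asarray(memories),
        condition_labels=np.asarray(conditions if conditions is not None else ["c"] * n),
        roi_name="HC",
        trial_index=np.asarray(trial_index if trial_index is not None else np.arange(n)),
    )


class TestCodebook:
    def test_three_classes_one_vs_rest(self):
        cb = ecoc_codebook(3)
        assert np.array_equal(cb.codewords, np.eye(3, dtype=int))
        assert cb.min_hamming_distance() == 2

    def test_two_classes_single_dichotomy(self):
        cb = ecoc_codebook(2)
        assert cb.codewords.tolist() == [[1], [0]]

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ValueError):
            ecoc_codebook(1)

    def test_degenerate_dichotomy_rejected(self):
        with pytest.raises(ValueError):
            EcocCodebook(codewords=np.array([[1, 1], [1, 0]]))

    def test_duplicate_codewords_rejected(self):
        with pytest.raises(ValueError):
            EcocCodebook(codewords=np.array([[1, 0], [1, 0]]))


class TestHammingDecode:
    def test_exact_codeword_match(self):
        cb = ecoc_codebook(3)
        assert hamming_decode([[1, 0, 0]], cb)[0] == 0
        assert hamming_decode([[0, 0, 1]], cb)[0] == 2

    def test_tie_breaks_to_lowest_class_index(self):
        cb = ecoc_codebook(3)
        # (1,1,0) is at distance 1 from both class 0 and class 1
        assert hamming_decode([[1, 1, 0]], cb)[0] == 0

    def test_all_zero_output(self):
        cb = ecoc_codebook(3)
        # distance 1 to every class; lowest index wins
        assert hamming_decode([[0, 0, 0]], cb)[0] == 0


class TestEcocSvm:
    def test_separable_clouds_classified_perfectly(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X = np.vstack([c + 0.1 * rng.normal(size=(8, 2)) for c in centers])
        y = np.repeat(["a", "b", "c"], 8)
        clf = EcocSvm(C=1.0).fit(X, y)
        test = np.vstack([c + 0.1 * rng.normal(size=(4, 2)) for c in centers])
        expected = np.repeat(["a", "b", "c"], 4)
        assert (clf.predict(test) == expected).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            EcocSvm().fit(np.zeros((4, 2)), np.array(["a"] * 4))

    def test_nonpositive_C_rejected(self):
        with pytest.raises(ValueError):
            EcocSvm(C=0.0)

    def test_matches_exhaustive_ecoc_oracle(self, rng):
        """ECOC-Hamming predictions match an independent reimplementation
        that fits each dichotomy separately and enumerates codeword
        distances explicitly (<=12 trials, <=2 features)."""
        for trial in range(12):
            n_classes = int(rng.integers(2, 4))
            n_feat = int(rng.integers(1, 3))
            n = int(rng.integers(2 * n_classes, 13 - n_classes) // n_classes) * n_classes
            y = np.repeat(np.arange(n_classes), n // n_classes)
            X = rng.normal(size=(len(y), n_feat)) + y[:, None]
            Xte = rng.normal(size=(5, n_feat)) + rng.integers(0, n_classes, 5)[:, None]
            cb = ecoc_codebook(n_classes)
            pred = ecoc_classify(X, y, Xte, None, cb, C=1.0)

            # oracle: explicit per-dichotomy fits + brute-force decoding
            mu, sd = X.mean(axis=0), X.std(axis=0)
            sd[sd == 0] = 1.0
            Xz, Xtez = (X - mu) / sd, (Xte - mu) / sd
            bits = np.zeros((5, cb.n_dichotomies), dtype=int)
            for d in range(cb.n_dichotomies):
                y_bin = cb.codewords[y, d]
                svm = LinearSVC(C=1.0, max_iter=5000, random_state=0)
                svm.fit(Xz, y_bin)
                bits[:, d] = svm.predict(Xtez)
            oracle = []
            for row in bits:
                best, best_dist = None, None
                for c in range(n_classes):
                    dist = sum(
                        int(row[d] != cb.codewords[c, d])
                        for d in range(cb.n_dichotomies)
                    )
                    if best_dist is None or dist < best_dist:
                        best, best_dist = c, dist
                oracle.append(best)
            assert pred.tolist() == oracle, f"mismatch on case {trial}"


class TestMakeFolds:
    def test_balanced_three_class_plan(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.repeat(["a", "b", "c"], 10)
        plan = make_folds(pattern_set(X, y), k=10, seed=1)
        assert plan.k == 10
        for _, test in plan.folds:
            assert len(test) == 3
            assert len(np.unique(y[test])) == 3

    def test_folds_partition_all_trials(self, rng):
        X = rng.normal(size=(33, 4))
        y = np.array(["a"] * 11 + ["b"] * 11 + ["c"] * 11)
        plan = make_folds(pattern_set(X, y), k=10, seed=2)
        tests = np.concatenate([t for _, t in plan.folds])
        assert sorted(tests.tolist()) == list(range(33))
        for train, test in plan.folds:
            assert np.intersect1d(train, test).size == 0

    def test_same_seed_identical_plan(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.repeat(["a", "b", "c"], 10)
        p1 = make_folds(pattern_set(X, y), k=10, seed=3)
        p2 = make_folds(pattern_set(X, y), k=10, seed=3)
        for (tr1, te1), (tr2, te2) in zip(p1.folds, p2.folds):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)

    def test_k_reduced_to_smallest_class(self, rng):
        X = rng.normal(size=(13, 4))
        y = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 5)
        plan = make_folds(pattern_set(X, y), k=10, seed=4)
        assert plan.k == 4

    def test_class_with_one_trial_rejected(self, rng):
        X = rng.normal(size=(7, 4))
        y = np.array(["a"] * 3 + ["b"] * 3 + ["c"])
        with pytest.raises(ValueError):
            make_folds(pattern_set(X, y), k=3)


def blob_patterns(rng, mask, support, n_per_class=10, noise=0.05):
    """Three-class patterns whose class information lives only on
    ``support`` (flat ROI indices)."""
    n_vox = int(mask.sum())
    class_maps = np.zeros((3, n_vox))
    for c in range(3):
        class_maps[c, support] = rng.normal(size=len(support))
    X, y = [], []
    for c in range(3):
        X.append(class_maps[c] + noise * rng.normal(size=(n_per_class, n_vox)))
        y += [f"m{c}"] * n_per_class
    return np.vstack(X), np.array(y)


class TestSelectFeatures:
    def test_recovers_planted_support(self, rng):
        mask = np.ones((5, 5, 5), dtype=bool)
        spheres = enumerate_spheres(mask, 2.0)
        support = np.arange(40, 60)  # a compact block of voxels
        X, y = blob_patterns(rng, mask, support)
        fs = select_features(X, y, spheres, seed=0)
        assert not fs.empty
        recovered = np.isin(support, fs.voxel_indices).mean()
        assert recovered >= 0.9

    def test_selected_voxels_within_roi(self, rng):
        mask = np.ones((4, 4, 4), dtype=bool)
        spheres = enumerate_spheres(mask, 2.0)
        X, y = blob_patterns(rng, mask, np.arange(10), noise=2.0)
        fs = select_features(X, y, spheres, seed=1)
        assert fs.voxel_indices.min() >= 0
        assert fs.voxel_indices.max() < spheres.n_centers

    def test_scores_reported_for_every_sphere(self, rng):
        mask = np.ones((4, 4, 4), dtype=bool)
        spheres = enumerate_spheres(mask, 2.0)
        X, y = blob_patterns(rng, mask, np.arange(10))
        fs = select_features(X, y, spheres, seed=2)
        assert len(fs.sphere_scores) == spheres.n_centers
        assert (fs.sphere_scores >= 0).all() and (fs.sphere_scores <= 1).all()

    def test_selection_deterministic_given_training_data(self, rng):
        mask = np.ones((4, 4, 4), dtype=bool)
        spheres = enumerate_spheres(mask, 2.0)
        X, y = blob_patterns(rng, mask, np.arange(12), noise=1.0)
        a = select_features(X, y, spheres, seed=5)
        b = select_features(X, y, spheres, seed=5)
        assert np.array_equal(a.voxel_indices, b.voxel_indices)
        assert np.array_equal(a.sphere_scores, b.sphere_scores)


@pytest.fixture(scope="module")
def small_roi():
    mask = np.ones((3, 3, 4), dtype=bool)
    return mask, enumerate_spheres(mask, 2.0)


class TestCrossValidate:
    def test_noiseless_strong_signal_is_perfect(self, rng, small_roi):
        mask, spheres = small_roi
        X, y = blob_patterns(rng, mask, np.arange(18), noise=0.0)
        res = cross_validate(pattern_set(X, y), spheres, k=5, seed=0)
        assert res.mean_accuracy == 1.0

    def test_mean_equals_average_of_folds(self, rng, small_roi):
        mask, spheres = small_roi
        X, y = blob_patterns(rng, mask, np.arange(18), noise=1.0)
        res = cross_validate(pattern_set(X, y), spheres, k=5, seed=1)
        assert res.mean_accuracy == pytest.approx(res.fold_accuracies.mean())
        assert ((res.fold_accuracies >= 0) & (res.fold_accuracies <= 1)).all()
        assert res.chance == pytest.approx(1 / 3)
        assert res.confusion.sum() == len(y)

    def test_no_leakage_selection_depends_on_training_only(self, rng, small_roi):
        """Re-running feature selection from the fold's training trials
        alone reproduces the fold's feature set exactly."""
        mask, spheres = small_roi
        X, y = blob_patterns(rng, mask, np.arange(18), noise=0.8)
        pats = pattern_set(X, y)
        res = cross_validate(pats, spheres, k=5, seed=7)
        plan = make_folds(pats, k=5, seed=7)
        for fold_id in (0, 3):
            train, _ = plan.folds[fold_id]
            fs = select_features(
                X[train], y[train], spheres, chance=1 / 3, seed=7 + fold_id,
                fold_id=fold_id,
            )
            assert np.array_equal(
                fs.voxel_indices, res.feature_sets[fold_id].voxel_indices
            )

    def test_accuracy_invariant_to_global_affine_rescaling(self, rng, small_roi):
        mask, spheres = small_roi
        X, y = blob_patterns(rng, mask, np.arange(18), noise=0.8)
        res1 = cross_validate(pattern_set(X, y), spheres, k=5, seed=3)
        res2 = cross_validate(pattern_set(7.3 * X - 11.0, y), spheres, k=5, seed=3)
        assert np.allclose(res1.fold_accuracies, res2.fold_accuracies)

    def test_result_serialises_to_json(self, rng, small_roi, tmp_path):
        mask, spheres = small_roi
        X, y = blob_patterns(rng, mask, np.arange(18), noise=1.0)
        res = cross_validate(pattern_set(X, y), spheres, k=5, seed=4)
        import json

        payload = json.loads(res.to_json(tmp_path / "res.json"))
        assert payload["mean_accuracy"] == pytest.approx(res.mean_accuracy)
        assert len(payload["fold_voxel_counts"]) == 5


class TestSetGeneralization:
    def build(self, rng, shared_scale, n_vox=30, n_per_mem=8, noise=0.3):
        cond_vecs = rng.normal(size=(2, n_vox))
        sets = []
        for ci, cond in enumerate(["recent", "remote"]):
            X, mems = [], []
            for mi in range(3):
                mem_vec = rng.normal(size=n_vox)
                base = shared_scale * cond_vecs[ci] + mem_vec
                X.append(base + noise * rng.normal(size=(n_per_mem, n_vox)))
                mems += [f"{cond}-m{mi}"] * n_per_mem
            sets.append(
                pattern_set(
                    np.vstack(X), mems, conditions=[cond] * (3 * n_per_mem)
                )
            )
        return sets

    def test_shared_condition_component_generalises(self, rng):
        a, b = self.build(rng, shared_scale=3.0)
        assert set_generalization(a, b) > 0.9

    def test_no_shared_component_is_at_chance(self, rng):
        accs = []
        for rep in range(5):
            a, b = self.build(rng, shared_scale=0.0)
            accs.append(set_generalization(a, b))
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_fewer_than_two_memories_rejected(self, rng):
        a, b = self.build(rng, shared_scale=1.0)
        single = pattern_set(
            a.patterns[:8], a.memory_labels[:8], conditions=["recent"] * 8
        )
        with pytest.raises(ValueError):
            set_generalization(single, b)

    def test_same_condition_rejected(self, rng):
        a, _ = self.build(rng, shared_scale=1.0)
        with pytest.raises(ValueError):
            set_generalization(a, a)
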