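"""Linear SVM decoding: training, cross-validation and transfer contracts."""

import warnings

import numpy as np
import pytest

from glossmvpa.decoding import (CONTRASTS, Contrast, cross_validate, train_classifier,
                                transfer_cross_validate, transfer_decode)
from glossmvpa.design import make_design
from glossmvpa.preprocess import PatternSet, extract_patterns, select_voxels
from glossmvpa.simulate import EffectModel, make_toy_brain, simulate_subject


def _pset(X, labels, runs, voxels=None):
    return PatternSet(patterns=X, labels=np.asarray(labels, dtype=object),
                      runs=np.asarray(runs),
                      voxels=np.arange(X.shape[1]) if voxels is None else voxels)


class TestContrast:
    def test_registry_class_sets(self):
        c = CONTRASTS["mirror_anti_vs_painted"]
        assert c.positive == {"mirror", "anti_mirror"} and c.negative == {"painted"}
        assert CONTRASTS["glossy_vs_matte"].positive == {"glossy"}

    def test_overlapping_classes_rejected(self):
        with pytest.raises(ValueError):
            Contrast("bad", frozenset({"a"}), frozenset({"a", "b"}))
        with pytest.raises(ValueError):
            Contrast("bad", frozenset(), frozenset({"a"}))


class TestTrainClassifier:
    def test_separable_clusters_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.standard_normal((20, 6)) + 3,
                            rng.standard_normal((20, 6)) - 3])
        y = np.repeat([True, False], 20)
        model = train_classifier(X, y)
        assert (model.predict(X) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            train_classifier(np.zeros((5, 3)), np.ones(5, dtype=bool))

    def test_duplicated_dataset_same_boundary(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.standard_normal((20, 4)) + 2,
                            rng.standard_normal((20, 4)) - 2])
        y = np.repeat([True, False], 20)
        m1 = train_classifier(X, y)
        m2 = train_classifier(np.tile(X, (2, 1)), np.tile(y, 2))
        assert np.abs(m1.weights - m2.weights).max() < 1e-8
        assert abs(m1.bias - m2.bias) < 1e-8

    def test_balancing_centers_prediction_frequencies(self):
        """On 2:1 imbalanced null data (non-separable regime) the balanced
        penalties keep the mean predicted-class frequency near 50%."""
        rng = np.random.default_rng(0)
        rates = []
        for _ in range(100):
            X = rng.standard_normal((90, 5))
            y = np.repeat([True, False], [60, 30])
            rng.shuffle(y)
            model = train_classifier(X, y, balance=True)
            rates.append(model.predict(rng.standard_normal((60, 5))).mean())
        assert 0.45 < np.mean(rates) < 0.55


@pytest.fixture(scope="module")
def brain():
    return make_toy_brain(n_rois=1, roi_radius_mm=11.0, background_voxels=100)


def _subject_pset(brain, n_runs, model, seed):
    ds = simulate_subject(make_design("binocular", n_runs, seed), model, seed, brain=brain)
    return extract_patterns(ds, select_voxels(ds, "ROI1"), roi="ROI1")


class TestCrossValidate:
    def test_fold_sizes_7_runs(self, brain):
        """Each fold trains on 24 and tests on 4 patterns per condition."""
        ps = _subject_pset(brain, 7, EffectModel(noise_sd=1.0), seed=0)
        res = cross_validate(ps, CONTRASTS["mirror_vs_anti"])
        assert res.n_train == [48] * 7  # 24 per condition x 2 conditions
        assert res.n_test == [8] * 7    # 4 per condition x 2 conditions

    def test_fold_sizes_10_runs(self, brain):
        ps = _subject_pset(brain, 10, EffectModel(noise_sd=1.0), seed=1)
        res = cross_validate(ps, CONTRASTS["painted_vs_flat"])
        assert res.n_train == [72] * 10  # 36 per condition x 2

    def test_no_test_run_in_training(self, brain):
        """Fold bookkeeping: the test run never contributes training patterns."""
        ps = _subject_pset(brain, 5, EffectModel(noise_sd=1.0), seed=2)
        res = cross_validate(ps, CONTRASTS["mirror_vs_anti"])
        mask, _ = CONTRASTS["mirror_vs_anti"].binarize(ps.labels)
        per_run = {int(r): int(np.sum(ps.runs[mask] == r)) for r in np.unique(ps.runs)}
        for fold_run, n_tr, n_te in zip(res.fold_runs, res.n_train, res.n_test):
            assert n_te == per_run[fold_run]
            assert n_tr == sum(per_run.values()) - per_run[fold_run]

    def test_high_snr_structure_decodes_painted_vs_flat(self, brain):
        m = EffectModel(f_structure=0.3, amp_structure=3.0, noise_sd=0.3)
        ps = _subject_pset(brain, 7, m, seed=3)
        assert cross_validate(ps, CONTRASTS["painted_vs_flat"]).accuracy > 0.9

    def test_feature_order_invariance(self, brain):
        ps = _subject_pset(brain, 5, EffectModel(f_structure=0.3, amp_structure=0.6), seed=4)
        res1 = cross_validate(ps, CONTRASTS["painted_vs_flat"])
        perm = np.random.default_rng(0).permutation(ps.patterns.shape[1])
        from dataclasses import replace
        ps2 = replace(ps, patterns=ps.patterns[:, perm], voxels=ps.voxels[perm])
        res2 = cross_validate(ps2, CONTRASTS["painted_vs_flat"])
        assert res1.accuracy == res2.accuracy

    def test_missing_class_fold_skipped_with_warning(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((24, 5))
        labels = ["mirror", "anti_mirror"] * 8 + ["mirror"] * 8  # run 2 lacks anti
        runs = [0] * 8 + [1] * 8 + [2] * 8
        ps = _pset(X, labels, runs)
        with pytest.warns(UserWarning, match="skipped"):
            res = cross_validate(ps, CONTRASTS["mirror_vs_anti"])
        assert set(res.fold_runs) == {0, 1}

    def test_confusion_counts_sum_to_total(self, brain):
        ps = _subject_pset(brain, 5, EffectModel(noise_sd=1.0), seed=5)
        res = cross_validate(ps, CONTRASTS["mirror_anti_vs_painted"])
        assert res.n_total == sum(res.n_test)
        assert np.isclose(res.accuracy,
                          (res.hits + res.correct_rejections) / res.n_total)


class TestTransfer:
    def test_degenerate_transfer_equals_training_accuracy(self):
        rng = np.random.default_rng(2)
        X = np.concatenate([rng.standard_normal((12, 5)) + 1.5,
                            rng.standard_normal((12, 5)) - 1.5])
        labels = ["glossy"] * 12 + ["matte"] * 12
        runs = [0, 1, 2] * 8
        ps = _pset(X, labels, runs)
        c = CONTRASTS["glossy_vs_matte"]
        res = transfer_decode(ps, c, ps, c)
        model = train_classifier(X, np.array([l == "glossy" for l in labels]))
        train_acc = (model.predict(X) == np.array([l == "glossy" for l in labels])).mean()
        assert res.accuracy == train_acc

    def test_mismatched_voxel_lists_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((8, 4))
        a = _pset(X, ["glossy", "matte"] * 4, [0, 0, 1, 1] * 2, voxels=np.array([1, 2, 3, 4]))
        b = _pset(X, ["mirror", "painted"] * 4, [0, 0, 1, 1] * 2, voxels=np.array([9, 2, 3, 4]))
        with pytest.raises(ValueError, match="voxel lists"):
            transfer_decode(a, CONTRASTS["glossy_vs_matte"], b,
                            CONTRASTS["mirror_anti_vs_painted"])

    def test_within_session_transfer_has_no_fold_leakage(self, brain):
        """CV transfer must not memorize the shared painted blocks: on null
        data its accuracy stays near chance, unlike train-on-all transfer."""
        ps = _subject_pset(brain, 8, EffectModel(noise_sd=1.0), seed=6)
        cv = transfer_cross_validate(ps, CONTRASTS["mirror_anti_vs_painted"],
                                     CONTRASTS["flat_vs_painted"])
        full = transfer_decode(ps, CONTRASTS["mirror_anti_vs_painted"], ps,
                               CONTRASTS["flat_vs_painted"])
        # train-on-all recalls its painted training rows almost perfectly
        assert full.correct_rejections / (full.correct_rejections + full.false_alarms) > 0.9
        assert abs(cv.balanced_accuracy - 0.5) < 0.15
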