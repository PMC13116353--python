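"""Staged predictor: dimension chain, extractor contracts, auPRC oracle."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from nanoloop.core_io import GenomicInterval, MethylationIndex, make_loop
from nanoloop.features import stage1_feature_matrix
from nanoloop.model import (
    ModelBundle,
    SequenceExtractor,
    SequenceExtractorConfig,
    evaluate_auprc,
    feature_importance,
    train_stage1_methylation,
)


def small_extractor(seed=0):
    return SequenceExtractor(
        SequenceExtractorConfig(
            filters1=8, filters2=16, filters3=128, window=200, step=100
        ),
        seed=seed,
    )


class TestSequenceExtractor:
    def test_output_dimension_and_tanh_range(self):
        ex = small_extractor()
        rng = np.random.default_rng(0)
        windows = rng.random((6, 4, 200)).astype(np.float32)
        out = ex.embed_windows(windows)
        assert out.shape == (6, 128)
        assert np.all(np.abs(out) < 1.0)

    def test_duplicate_windows_idempotent_under_mean(self):
        ex = small_extractor()
        rng = np.random.default_rng(1)
        win = rng.random((1, 4, 200)).astype(np.float32)
        single = ex.embed_windows(win).mean(axis=0)
        double = ex.embed_windows(np.vstack([win, win])).mean(axis=0)
        np.testing.assert_allclose(single, double, rtol=1e-4, atol=1e-6)

    def test_frozen_weights_immutable_and_deterministic(self):
        ex = small_extractor()
        ex.freeze()
        with pytest.raises(ValueError):
            ex.params["w1"][0, 0, 0] = 1.0
        rng = np.random.default_rng(2)
        windows = rng.random((3, 4, 200)).astype(np.float32)
        np.testing.assert_array_equal(
            ex.embed_windows(windows), ex.embed_windows(windows)
        )

    def test_seeded_initialization_reproducible(self):
        a, b = small_extractor(seed=7), small_extractor(seed=7)
        assert a.checksum() == b.checksum()
        assert a.checksum() != small_extractor(seed=8).checksum()

    def test_output_dim_must_be_128(self):
        with pytest.raises(ValueError):
            SequenceExtractorConfig(filters3=64)
        with pytest.raises(ValueError):
            SequenceExtractorConfig(dropout1=1.0)


class TestStage1:
    def test_block_dimension_and_probability_range(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 20, size=(80, 21)).astype(float)
        y = (x[:, 20] > 9).astype(int)  # depends on the correlation slot
        clf = train_stage1_methylation(x, y, seed=0)
        p = clf.predict_proba(x)[:, 1]
        block22 = np.concatenate([x, p[:, None]], axis=1)
        assert block22.shape[1] == 22
        assert np.all((p >= 0) & (p <= 1))

    def test_wrong_dimension_rejected(self):
        with pytest.raises(ValueError):
            train_stage1_methylation(np.zeros((10, 20)), np.r_[np.ones(5), np.zeros(5)])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_stage1_methylation(np.zeros((10, 21)), np.ones(10))

    def test_seeded_retraining_is_reproducible(self):
        rng = np.random.default_rng(3)
        x = rng.random((60, 21))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        p1 = train_stage1_methylation(x, y, seed=5).predict_proba(x)[:, 1]
        p2 = train_stage1_methylation(x, y, seed=5).predict_proba(x)[:, 1]
        np.testing.assert_array_equal(p1, p2)


class TestEvaluateAuprc:
    def brute_force(self, scores, labels):
        """Threshold enumeration: stepwise PR integration, ties grouped."""
        scores = np.asarray(scores, float)
        labels = np.asarray(labels, int)
        n_pos = labels.sum()
        thresholds = sorted(set(scores), reverse=True)
        area, prev_recall = 0.0, 0.0
        for t in thresholds:
            sel = scores >= t
            tp = int((labels[sel] == 1).sum())
            precision = tp / sel.sum()
            recall = tp / n_pos
            area += (recall - prev_recall) * precision
            prev_recall = recall
        return area

    def test_perfect_separation(self):
        assert evaluate_auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_brute_force_agreement_small_n(self):
        rng = np.random.default_rng(0)
        for trial in range(200):
            n = int(rng.integers(2, 51))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            assert evaluate_auprc(scores, labels) == pytest.approx(
                self.brute_force(scores, labels), abs=1e-9
            )

    def test_matches_sklearn_average_precision(self):
        rng = np.random.default_rng(1)
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        assert evaluate_auprc(scores, labels) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12
        )

    def test_label_independent_scores_approach_prevalence(self):
        rng = np.random.default_rng(2)
        n, prevalence = 4000, 0.3
        labels = (rng.random(n) < prevalence).astype(int)
        scores = rng.random(n)
        # permutation null: auPRC concentrates near the prevalence
        assert evaluate_auprc(scores, labels) == pytest.approx(
            labels.mean(), abs=0.05
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_auprc([0.5, 0.6], [1, 1])


class TestTrainedBundle(object):
    """Contracts of the bundle trained once on the tiny world (conftest)."""

    def test_feature_frame_dimension_chain(self, tiny_world, tiny_bundle):
        _, data, meth, manifest = tiny_world
        loops = manifest.positives[:3]
        frame = tiny_bundle.assemble(loops, data.genome, meth)
        assert frame.shape == (3, 535)
        x21 = stage1_feature_matrix(loops, meth)
        assert x21.shape == (3, 21)

    def test_predictions_deterministic_and_bounded(self, tiny_world, tiny_bundle):
        _, data, meth, manifest = tiny_world
        loops = manifest.positives[:4]
        a = tiny_bundle.predict(loops, data.genome, meth)
        b = tiny_bundle.predict(loops, data.genome, meth)
        assert [r.probability for r in a] == [r.probability for r in b]
        assert all(0.0 <= r.probability <= 1.0 for r in a)

    def test_positives_score_above_negatives(self, tiny_world, tiny_bundle):
        _, data, meth, manifest = tiny_world
        test_loops, test_labels = manifest.subset("test")
        probs = np.array(
            [r.probability for r in tiny_bundle.predict(test_loops, data.genome, meth)]
        )
        assert probs[test_labels == 1].mean() > probs[test_labels == 0].mean()

    def test_stage1_beats_prevalence_on_validation(self, tiny_world, tiny_bundle):
        _, data, meth, manifest = tiny_world
        val_loops, val_labels = manifest.subset("val")
        x21 = stage1_feature_matrix(val_loops, meth)
        p1 = tiny_bundle.stage1.predict_proba(x21)[:, 1]
        assert evaluate_auprc(p1, val_labels) > val_labels.mean()

    def test_stage2_frozen_after_training(self, tiny_bundle):
        assert tiny_bundle.extractor.frozen
        with pytest.raises(ValueError):
            tiny_bundle.extractor.params["w1"][0, 0, 0] = 0.0

    def test_degenerate_loop_predicts_without_crash(self, tiny_world, tiny_bundle):
        _, data, meth, _ = tiny_world
        genome = dict(data.genome)
        genome["chrN"] = "N" * 60_000  # all-N chromosome, no CpGs
        loop = make_loop(
            GenomicInterval("chrN", 5000, 10000),
            GenomicInterval("chrN", 40000, 45000),
        )
        (rec,) = tiny_bundle.predict([loop], genome, meth)
        assert 0.0 <= rec.probability <= 1.0

    def test_feature_importance_named_and_sorted(self, tiny_bundle):
        ranked = feature_importance(tiny_bundle)
        assert 0 < len(ranked) <= 535
        values = [v for _, v in ranked]
        assert values == sorted(values, reverse=True)
        assert all(v >= 0 for v in values)

    def test_save_load_round_trip(self, tiny_world, tiny_bundle, tmp_path):
        _, data, meth, manifest = tiny_world
        tiny_bundle.save(tmp_path / "bundle")
        loaded = ModelBundle.load(tmp_path / "bundle")
        loops = manifest.positives[:3]
        original = [r.probability for r in tiny_bundle.predict(loops, data.genome, meth)]
        reloaded = [r.probability for r in loaded.predict(loops, data.genome, meth)]
        np.testing.assert_allclose(original, reloaded, rtol=1e-6)
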