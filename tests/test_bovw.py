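"""gridSIFT descriptors, vocabulary, encoding, classification and tiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polypcadx import bovw
from polypcadx.bovw import (ClassScores, DescriptorSet, Vocabulary,
                            build_vocabulary, confidence_tier, cross_validate,
                            encode, extract_grid_descriptors, predict, train)
from polypcadx.localization import BoundingBox
from tests.conftest import make_samples


def dset(arr):
    arr = np.asarray(arr, dtype=float)
    return DescriptorSet(descriptors=arr, grid_points=np.zeros((len(arr), 2)))


class TestDescriptors:
    def test_grid_count_matches_enumeration(self, clean_capture):
        img, _ = clean_capture
        d = extract_grid_descriptors(img, BoundingBox(10, 10, 64, 64), 8, 16)
        # floor((64-16)/8 + 1)^2 patches of 128 dims
        assert d.descriptors.shape == (49, 128)
        assert np.all(d.grid_points >= 0) and np.all(d.grid_points <= 64)

    def test_deterministic(self, clean_capture):
        img, truth = clean_capture
        a = extract_grid_descriptors(img, truth.box)
        b = extract_grid_descriptors(img, truth.box)
        assert np.array_equal(a.descriptors, b.descriptors)

    def test_constant_patch_gives_zero_descriptor(self):
        img = np.full((40, 40, 3), 77, dtype=np.uint8)
        d = extract_grid_descriptors(img, BoundingBox(4, 4, 32, 32), 8, 16)
        assert np.all(d.descriptors == 0)

    def test_norms_bounded(self, clean_capture):
        img, truth = clean_capture
        d = extract_grid_descriptors(img, truth.box)
        assert np.all(np.linalg.norm(d.descriptors, axis=1) <= 1 + 1e-6)

    def test_box_smaller_than_patch_rejected(self, clean_capture):
        img, _ = clean_capture
        with pytest.raises(ValueError):
            extract_grid_descriptors(img, BoundingBox(0, 0, 12, 12), 8, 16)


class TestVocabulary:
    def make_clouds(self, k=4, per=50, seed=0):
        rng = np.random.default_rng(seed)
        means = rng.normal(0, 1, (k, 128)) * 0.5
        pts = np.concatenate([m + 0.01 * rng.normal(size=(per, 128)) for m in means])
        return means, pts

    def test_separated_clouds_recovered(self):
        means, pts = self.make_clouds()
        vocab = build_vocabulary([dset(pts)], k=4, seed=1)
        # each true cloud mean has a center within a small radius
        d = np.linalg.norm(means[:, None, :] - vocab.centers[None, :, :], axis=2)
        assert np.all(d.min(axis=1) < 0.05)

    def test_deterministic_under_seed(self):
        _, pts = self.make_clouds()
        a = build_vocabulary([dset(pts)], k=4, seed=5)
        b = build_vocabulary([dset(pts)], k=4, seed=5)
        assert np.array_equal(a.centers, b.centers)

    def test_k_one_rejected(self):
        _, pts = self.make_clouds()
        with pytest.raises(ValueError):
            build_vocabulary([dset(pts)], k=1, seed=0)

    def test_insufficient_descriptors_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([dset(np.zeros((3, 128)))], k=8, seed=0)


class TestEncoding:
    def toy_vocab(self):
        centers = np.zeros((2, 128))
        centers[1, 0] = 1.0
        return Vocabulary(centers=centers, k=2, train_seed=0)

    def test_nearest_center_histogram(self):
        v = self.toy_vocab()
        pts = np.zeros((4, 128))
        pts[3, 0] = 0.9  # one descriptor near center B, three near A
        assert np.allclose(encode(dset(pts), v), [0.75, 0.25])

    def test_tie_goes_to_lowest_index(self):
        v = self.toy_vocab()
        pts = np.zeros((1, 128))
        pts[0, 0] = 0.5  # equidistant
        assert np.allclose(encode(dset(pts), v), [1.0, 0.0])

    def test_histogram_sums_to_one(self, clean_capture, small_model):
        img, truth = clean_capture
        h = small_model.describe(img, truth.box)
        assert h.sum() == pytest.approx(1.0)
        assert np.all(h >= 0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        centers = rng.normal(size=(5, 128))
        pts = rng.normal(size=(40, 128))
        perm = rng.permutation(5)
        h1 = encode(dset(pts), Vocabulary(centers, 5, 0))
        h2 = encode(dset(pts), Vocabulary(centers[perm], 5, 0))
        assert np.allclose(h1[perm], h2)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            encode(dset(np.zeros((0, 128))), self.toy_vocab())


class TestClassifier:
    def test_scores_sum_to_one_and_label_training_exemplar(self, small_model, clean_capture):
        img, truth = clean_capture
        scores = small_model.predict_image(img, truth.box)
        assert sum(scores.scores.values()) == pytest.approx(1.0, abs=1e-9)
        assert scores.top_class == "adenoma"

    def test_single_class_training_rejected(self):
        h = np.random.default_rng(0).dirichlet(np.ones(8), size=6)
        with pytest.raises(ValueError):
            train(h, ["adenoma"] * 6)

    def test_held_out_accuracy_on_separable_textures(self, small_model):
        test = make_samples(30, seed0=5000, radius_rng_seed=9)
        correct = sum(small_model.predict_image(img, box).top_class == lab
                      for img, box, lab in test)
        assert correct / len(test) >= 0.90


class TestConfidenceTiers:
    @pytest.mark.parametrize("top, expected", [
        (0.81, "high"),   # published high-confidence adenoma example
        (0.91, "high"),   # published high-confidence hyperplastic example
        (0.49, "low"),
        (0.34, "low"),
    ])
    def test_published_and_boundary_examples(self, top, expected):
        rest = (1 - top) / 2
        scores = {"adenoma": top, "ssl": rest, "hyperplastic": rest}
        assert confidence_tier(scores) == expected

    def test_uniform_scores_are_low_confidence(self):
        scores = {c: 1 / 3 for c in bovw.CLASSES}
        assert confidence_tier(scores) == "low"   # 0.333... >= 0.33

    @given(st.lists(st.floats(0.01, 10), min_size=3, max_size=3))
    @settings(max_examples=300, deadline=None)
    def test_tier_none_unreachable_for_three_classes(self, raw):
        p = np.array(raw) / sum(raw)
        scores = ClassScores(scores=dict(zip(bovw.CLASSES, p / p.sum())))
        assert scores.tier in ("high", "low")

    def test_top_class_tie_broken_by_fixed_order(self):
        s = ClassScores(scores={"adenoma": 0.4, "ssl": 0.4, "hyperplastic": 0.2})
        assert s.top_class == "adenoma"

    def test_invalid_score_vector_rejected(self):
        with pytest.raises(ValueError):
            ClassScores(scores={"adenoma": 0.9, "ssl": 0.9, "hyperplastic": -0.8})


class TestCrossValidation:
    def test_partition_and_determinism_and_accuracy(self):
        samples = [(f"p{i}", img, box, lab)
                   for i, (img, box, lab) in enumerate(make_samples(45, seed0=3000))]
        params = bovw.BovwParams(vocabulary_size=24)
        r1 = cross_validate(samples, folds=5, seed=2, params=params)
        r2 = cross_validate(samples, folds=5, seed=2, params=params)
        assert r1.fold_of_polyp == r2.fold_of_polyp           # same seed, same split
        assert sorted(r1.fold_of_polyp) == sorted({s[0] for s in samples})
        assert set(r1.fold_of_polyp.values()) == set(range(5))  # every fold used
        assert r1.confusion.sum() == len(samples)             # each polyp tested once
        assert r1.pooled_accuracy >= 0.90                     # separable fixtures

    def test_class_with_too_few_polyps_rejected(self):
        samples = [(f"p{i}", img, box, lab)
                   for i, (img, box, lab) in enumerate(make_samples(9, seed0=3000))]
        with pytest.raises(ValueError):
            cross_validate(samples, folds=5, seed=0,
                           params=bovw.BovwParams(vocabulary_size=8))


def test_model_save_load_round_trip(tmp_path, small_model, clean_capture):
    img, truth = clean_capture
    path = str(tmp_path / "model.npz")
    small_model.save(path)
    loaded = bovw.BovwModel.load(path)
    a = small_model.predict_image(img, truth.box)
    b = loaded.predict_image(img, truth.box)
    assert a.scores == pytest.approx(b.scores)
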