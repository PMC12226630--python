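"""Prototype computation, nearest-prototype assignment and augmented-view
majority voting."""

import numpy as np
import pytest

from conftest import VectorEncoder, encode_vectors
from planefed.contrastive import IDENTITY_AUG, AugmentationSpec
from planefed.prototypes import (
    Prototype,
    ViewEnsembleConfig,
    compute_prototypes,
    label_by_view_ensemble,
    label_client,
    nearest_prototype,
    prototype_matrix,
)


class TestComputePrototypes:
    def test_single_member_class_is_its_own_prototype(self):
        u = np.array([1.0, -2.0, 3.0])
        protos = compute_prototypes([u], [2])
        assert protos[0].class_id == 2
        np.testing.assert_array_equal(protos[0].vector, u)

    def test_symmetric_pair_averages_to_zero(self):
        u = np.array([1.0, 2.0])
        protos = compute_prototypes([u, -u], [0, 0])
        np.testing.assert_allclose(protos[0].vector, np.zeros(2), atol=1e-15)

    def test_matches_elementwise_mean_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((400, 16))
        y = np.repeat(np.arange(4), 100)
        protos = compute_prototypes(X, y)
        for p in protos:
            manual = np.zeros(16)
            members = [X[i] for i in range(400) if y[i] == p.class_id]
            for v in members:
                manual += v
            manual /= len(members)
            np.testing.assert_allclose(p.vector, manual, atol=1e-9)

    def test_missing_class_omitted_with_warning(self):
        X = np.eye(3)
        with pytest.warns(UserWarning):
            protos = compute_prototypes(X, [0, 0, 2])
        assert [p.class_id for p in protos] == [0, 2]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_prototypes(np.empty((0, 4)), [])


class TestNearestPrototype:
    @pytest.fixture
    def protos(self):
        return [Prototype(c, v) for c, v in enumerate(np.eye(3) * 2.0)]

    def test_exact_match_distance_zero(self, protos):
        cls, dist = nearest_prototype(protos[1].vector, protos)
        assert cls == 1 and dist == 0.0

    def test_equidistant_tie_goes_to_lowest_class(self, protos):
        z = (protos[0].vector + protos[1].vector) / 2
        cls, _ = nearest_prototype(z, protos)
        assert cls == 0

    def test_matches_exhaustive_comparison(self, protos):
        rng = np.random.default_rng(1)
        for _ in range(50):
            z = rng.standard_normal(3)
            dists = [np.linalg.norm(z - p.vector) for p in protos]
            cls, dist = nearest_prototype(z, protos)
            assert cls == int(np.argmin(dists))
            assert dist == pytest.approx(min(dists))

    def test_empty_prototype_list_rejected(self):
        with pytest.raises(ValueError):
            nearest_prototype(np.zeros(3), [])


class TestViewEnsembleVoting:
    def test_single_view_equals_nearest_prototype(self):
        enc = VectorEncoder(2)
        z = np.array([1.0, 3.0])
        protos = [Prototype(0, np.array([0.0, 0.0])), Prototype(1, np.array([1.0, 3.5]))]
        rec = label_by_view_ensemble(
            encode_vectors([z])[0], enc, protos, ViewEnsembleConfig(T=1, aug=IDENTITY_AUG)
        )
        assert rec.final_label == nearest_prototype(z, protos)[0]
        assert rec.vote_counts.sum() == 1

    def test_identity_views_vote_unanimously(self):
        enc = VectorEncoder(3)
        z = np.array([2.0, -1.0, 0.5])
        protos = [Prototype(c, v) for c, v in enumerate(np.eye(3) * 4.0)]
        for T in (1, 4, 8):
            rec = label_by_view_ensemble(
                encode_vectors([z])[0], enc, protos, ViewEnsembleConfig(T=T, aug=IDENTITY_AUG)
            )
            assert rec.vote_counts.max() == T
            assert rec.final_label == nearest_prototype(z, protos)[0]

    def test_vote_counts_tally_view_classes(self):
        """Majority vote equals a brute-force tally of per-view votes."""
        enc = VectorEncoder(4)
        aug = AugmentationSpec(
            hflip_prob=0.0, max_rotation_deg=0.0, max_shift_px=0.0,
            brightness_range=(0.7, 1.3), contrast_range=(1.0, 1.0),
        )
        rng = np.random.default_rng(2)
        protos = [Prototype(c, rng.standard_normal(4)) for c in range(4)]
        for T in (2, 5, 16):
            z = rng.standard_normal(4)
            rec = label_by_view_ensemble(
                encode_vectors([z])[0], enc, protos, ViewEnsembleConfig(T=T, aug=aug, seed=T)
            )
            assert rec.vote_counts.sum() == T
            tally = {c: int((rec.view_classes == c).sum()) for c in rec.class_ids}
            np.testing.assert_array_equal(
                rec.vote_counts, [tally[c] for c in rec.class_ids]
            )
            assert tally[rec.final_label] == max(tally.values())

    def test_vote_tie_broken_by_summed_distance(self):
        """1-1 vote split: the class whose supporting view sits exactly on
        its prototype (summed distance 0) wins over the closer class id."""
        enc = VectorEncoder(2)
        flip_aug = AugmentationSpec(
            hflip_prob=1.0, max_rotation_deg=0.0, max_shift_px=0.0,
            brightness_range=(1.0, 1.0), contrast_range=(1.0, 1.0),
        )
        x = np.array([[0.6, 0.5]])  # view1 -> z1=(2,0); flipped view2 -> z2=(0,2)
        z1, z2 = np.array([2.0, 0.0]), np.array([0.0, 2.0])
        protos = [
            Prototype(0, z2.copy()),  # view2 votes 0 at distance 0
            Prototype(1, z1 + np.array([0.1, 0.0])),  # view1 votes 1 at distance 0.1
        ]
        rec = label_by_view_ensemble(x, enc, protos, ViewEnsembleConfig(T=2, aug=flip_aug))
        np.testing.assert_array_equal(rec.vote_counts, [1, 1])
        assert rec.final_label == 0  # summed distance 0 beats 0.1

        # swap exactness: now class 1's supporter is exact -> class 1 wins
        protos_swapped = [
            Prototype(0, z2 + np.array([0.1, 0.0])),
            Prototype(1, z1.copy()),
        ]
        rec2 = label_by_view_ensemble(
            x, enc, protos_swapped, ViewEnsembleConfig(T=2, aug=flip_aug)
        )
        assert rec2.final_label == 1


class TestLabelClient:
    def test_pseudo_label_accuracy_on_separated_clusters(self, gaussian_clusters):
        X, y, spec = gaussian_clusters
        enc = VectorEncoder(spec.dim)
        r = spec.separation / np.sqrt(2.0)
        true_means = np.zeros((4, spec.dim))
        true_means[np.arange(4), np.arange(4)] = r
        protos = [Prototype(c, true_means[c]) for c in range(4)]
        labels, records = label_client(
            encode_vectors(X), enc, protos, ViewEnsembleConfig(T=8, aug=IDENTITY_AUG)
        )
        assert np.mean(labels == y) >= 0.99
        assert len(records) == len(y)

    def test_never_reads_input_labels(self, gaussian_clusters):
        X, y, spec = gaussian_clusters
        enc = VectorEncoder(spec.dim)
        protos = compute_prototypes(X, y)

        class Sentinel:
            def __init__(self, pixels):
                self.pixels = pixels

            @property
            def label(self):
                raise AssertionError("pseudo-labeling must not read labels")

        imgs = [Sentinel(p) for p in encode_vectors(X[:20])]
        labels, _ = label_client(imgs, enc, protos, ViewEnsembleConfig(T=2, aug=IDENTITY_AUG))
        assert len(labels) == 20

    def test_empty_dataset_gives_empty_output(self):
        enc = VectorEncoder(2)
        protos = [Prototype(0, np.zeros(2))]
        labels, records = label_client([], enc, protos, ViewEnsembleConfig(T=2))
        assert len(labels) == 0 and records == []

    def test_identity_augmentation_any_T_equals_single_view(self, gaussian_clusters):
        X, y, spec = gaussian_clusters
        enc = VectorEncoder(spec.dim)
        protos = compute_prototypes(X, y)
        imgs = encode_vectors(X[:30])
        l1, _ = label_client(imgs, enc, protos, ViewEnsembleConfig(T=1, aug=IDENTITY_AUG))
        l8, _ = label_client(imgs, enc, protos, ViewEnsembleConfig(T=8, aug=IDENTITY_AUG))
        np.testing.assert_array_equal(l1, l8)


def test_prototype_sharing_payload_is_classcount_by_dim():
    """Privacy contract: what crosses clients is exactly one vector per
    class, never per-sample data."""
    rng = np.random.default_rng(0)
    X = rng.standard_normal((100, 16))
    y = np.repeat(np.arange(4), 25)
    ids, mat = prototype_matrix(compute_prototypes(X, y))
    assert mat.shape == (4, 16)
    assert ids.tolist() == [0, 1, 2, 3]
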