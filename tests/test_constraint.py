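import numpy as np
import pytest

from molbo.constraint import (
    ConstraintDataset,
    ConstraintError,
    build_constraint_dataset,
    constraint_probability,
    desk_scale_config,
    label_latent_point,
    latent_bounding_box,
    train_constraint_classifier,
)
from molbo.vae import LatentPoint


def make_clouds(n_per_class=800, d=8, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.normal(sep, 1.0, (n_per_class, d))
    neg = rng.normal(-sep, 1.0, (n_per_class, d))
    points = np.vstack([pos, neg])
    labels = np.array([1] * n_per_class + [0] * n_per_class)
    return ConstraintDataset(points=points, labels=labels)


class TestLabellingRule:
    @pytest.mark.parametrize(
        "n_realistic,expected",
        [(21, 1), (20, 0), (0, 0), (100, 1)],
    )
    def test_strictly_more_than_twenty_percent(
        self, stub_decoder_factory, n_realistic, expected
    ):
        attempts = ["CCCCCC"] * n_realistic + ["C"] * (100 - n_realistic)
        model = stub_decoder_factory(attempts)
        z = LatentPoint(np.zeros(4))
        assert label_latent_point(model, z, n_attempts=100, seed=0) == expected

    def test_parameter_validation(self, stub_decoder_factory):
        model = stub_decoder_factory(["C"])
        z = LatentPoint(np.zeros(4))
        with pytest.raises(ConstraintError):
            label_latent_point(model, z, n_attempts=0)
        with pytest.raises(ConstraintError):
            label_latent_point(model, z, threshold=1.5)


class TestDatasetConstruction:
    def test_classes_populated_and_labels_reverifiable(self, toy_vae, toy_corpus):
        ds = build_constraint_dataset(
            toy_vae, toy_corpus[:200], n_negative=200, n_attempts=25, seed=42
        )
        assert set(ds.labels) == {0, 1}
        assert set(ds.provenance) == {"encoded-training-data", "uniform-latent-sample"}
        # balanced by default
        assert (ds.labels == 1).sum() == (ds.labels == 0).sum()
        # every positive re-labels positive under the labelling rule
        pos = ds.points[ds.labels == 1][:5]
        # (labels were assigned with per-point seeds; verify the rule holds
        # for a fresh seed, which it does for deep-in-manifold points)
        relabels = [
            label_latent_point(toy_vae, LatentPoint(z), 25, seed=7) for z in pos
        ]
        assert sum(relabels) >= 3

    def test_collapsed_bounds_leave_no_negatives(self, toy_vae, toy_corpus):
        z0 = toy_vae.encode(toy_corpus[0]).z
        degenerate = np.stack([z0, z0], axis=1)  # box collapsed onto a point
        with pytest.raises(ConstraintError, match="empty"):
            build_constraint_dataset(
                toy_vae,
                toy_corpus[:20],
                n_negative=10,
                latent_bounds=degenerate,
                n_attempts=25,
                seed=0,
            )

    def test_bounding_box_expansion(self):
        enc = np.array([[0.0, 0.0], [1.0, 2.0]])
        box = latent_bounding_box(enc, expand_fraction=0.10)
        np.testing.assert_allclose(box[:, 0], [-0.1, -0.2])
        np.testing.assert_allclose(box[:, 1], [1.1, 2.2])

    def test_dataframe_round_trip(self):
        ds = make_clouds(10, d=3)
        df = ds.to_dataframe()
        back = ConstraintDataset.from_dataframe(df)
        np.testing.assert_allclose(back.points, ds.points)
        np.testing.assert_array_equal(back.labels, ds.labels)


class TestClassifier:
    def test_separable_clouds_high_accuracy(self):
        ds = make_clouds()
        rng = np.random.default_rng(1)
        hold = rng.choice(len(ds.labels), 300, replace=False)
        mask = np.ones(len(ds.labels), bool)
        mask[hold] = False
        cm = train_constraint_classifier(
            ConstraintDataset(ds.points[mask], ds.labels[mask]),
            desk_scale_config(),
            seed=0,
        )
        pred = (cm.predict_probability(ds.points[hold]) > 0.5).astype(int)
        assert (pred == ds.labels[hold]).mean() > 0.95

    def test_permuted_labels_near_chance(self):
        ds = make_clouds()
        rng = np.random.default_rng(2)
        labels = rng.permutation(ds.labels)
        hold = rng.choice(len(labels), 300, replace=False)
        mask = np.ones(len(labels), bool)
        mask[hold] = False
        cm = train_constraint_classifier(
            ConstraintDataset(ds.points[mask], labels[mask]),
            desk_scale_config(),
            seed=0,
        )
        pred = (cm.predict_probability(ds.points[hold]) > 0.5).astype(int)
        assert abs((pred == labels[hold]).mean() - 0.5) <= 0.05

    def test_single_class_rejected(self):
        ds = make_clouds(50)
        with pytest.raises(ConstraintError):
            train_constraint_classifier(
                ConstraintDataset(ds.points[ds.labels == 1], ds.labels[ds.labels == 1]),
                seed=0,
            )

    def test_probabilities_never_saturate(self):
        ds = make_clouds(200)
        cm = train_constraint_classifier(ds, desk_scale_config(epochs=50), seed=0)
        far = np.full((1, 8), 1e3)
        for Z in (ds.points, far, -far):
            p = cm.predict_probability(Z)
            assert ((p > 0) & (p < 1)).all()

    def test_probability_decays_along_ray_into_empty_space(self):
        """Moving orthogonally to the class discriminant leaves the mean
        logit fixed while the posterior logit variance grows, so the
        averaged probability must fall monotonically from its confident
        value at the positive centroid."""
        ds = make_clouds()
        cm = train_constraint_classifier(ds, desk_scale_config(), seed=0)
        centroid = ds.points[ds.labels == 1].mean(axis=0)
        w = centroid - ds.points[ds.labels == 0].mean(axis=0)
        w /= np.linalg.norm(w)
        o = np.zeros(8)
        o[0], o[1] = 1.0, -1.0
        o -= (o @ w) * w
        o /= np.linalg.norm(o)
        probs = [
            float(cm.predict_probability((centroid + t * 10.0 * o)[None, :])[0])
            for t in range(5)
        ]
        assert all(probs[i + 1] <= probs[i] for i in range(4))
        assert probs[-1] < probs[0]

    def test_retraining_same_seed_bit_identical(self):
        ds = make_clouds(300)
        probes = np.random.default_rng(3).normal(0, 3, (10, 8))
        cfg = desk_scale_config(epochs=40)
        a = train_constraint_classifier(ds, cfg, seed=5).predict_probability(probes)
        b = train_constraint_classifier(ds, cfg, seed=5).predict_probability(probes)
        np.testing.assert_array_equal(a, b)

    def test_dimension_mismatch_rejected(self):
        cm = train_constraint_classifier(make_clouds(100), desk_scale_config(epochs=20), seed=0)
        with pytest.raises(ConstraintError, match="dimension"):
            constraint_probability(cm, LatentPoint(np.zeros(3)))

    def test_probability_contrast_on_toy_vae_data(self, toy_vae, toy_corpus):
        """Deep positive-class points score high; far outside the data and
        its bounding box the typical (median over random directions)
        probability is well below 0.5."""
        ds = build_constraint_dataset(
            toy_vae, toy_corpus[:150], n_negative=150, n_attempts=25, seed=9
        )
        cm = train_constraint_classifier(ds, desk_scale_config(), seed=9)
        pos = ds.points[ds.labels == 1]
        assert cm.predict_probability(pos).mean() > 0.5
        rng = np.random.default_rng(0)
        dirs = rng.normal(0, 1, (200, toy_vae.latent_dim))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        center = ds.points.mean(axis=0)
        radius = 8.0 * np.abs(ds.points - center).max()
        far_probs = cm.predict_probability(center + dirs * radius)
        assert np.median(far_probs) < 0.25
        assert np.median(far_probs) < cm.predict_probability(pos).mean()
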