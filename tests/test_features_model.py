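import numpy as np
import pytest

from epivmd.entropy import SampEnParams
from epivmd.features_model import (
    FEATURE_COLUMNS,
    DetectionReport,
    FeatureVector,
    FoldCounts,
    RFConfig,
    anova_screen,
    balanced_subsample,
    build_feature_vector,
    cross_validate,
    features_to_frame,
    load_features,
    save_features,
)
from epivmd.preprocess import Epoch
from epivmd.synthetic_data import GenConfig, generate_epoch_pair
from epivmd.vmd import VMDConfig

FS = 256.0


def synthetic_features(n_per_class, rng, separation=2.0):
    """Labeled feature vectors with a class shift on the entropy features."""
    out = []
    for label, shift in (("epileptic", 0.0), ("nonepileptic", separation)):
        for _ in range(n_per_class):
            out.append(
                FeatureVector(
                    sampen_imp_a=rng.normal(1.0 + shift, 0.3),
                    sampen_imp_b=rng.normal(1.0 + shift, 0.3),
                    psi=np.clip(rng.uniform(0, 1, 5), 0, 1),
                    label=label,
                )
            )
    return out


class TestBuildFeatureVector:
    def test_identical_epochs_give_unit_psi_and_equal_entropies(self, rng):
        x = rng.standard_normal(512) * 20
        a = Epoch(x, fs=FS, channel="FZCZ")
        b = Epoch(x.copy(), fs=FS, channel="CZPZ")
        fv = build_feature_vector(a, b, mu_a=0.1, mu_b=0.1)
        assert np.allclose(fv.psi, 1.0, atol=1e-12)
        assert fv.sampen_imp_a == fv.sampen_imp_b
        assert fv.values.shape == (7,)
        assert np.all(np.isfinite(fv.values))

    def test_class_direction_on_first_psi(self):
        """Strong cross-channel coupling plus the coherent ictal rhythm
        raise the low-frequency phase synchronization of epileptic pairs
        above nonepileptic pairs."""
        gen = GenConfig(seed=8)
        means = {}
        for label in ("epileptic", "nonepileptic"):
            rng = np.random.default_rng(8)
            vals = []
            for _ in range(12):
                a, b = generate_epoch_pair(label, gen, rng)
                fv = build_feature_vector(a, b, mu_a=0.13, mu_b=0.05, label=label)
                vals.append(fv.psi[0])
            means[label] = np.mean(vals)
        assert means["epileptic"] > means["nonepileptic"]

    def test_mismatched_sampling_rates_rejected(self, rng):
        a = Epoch(rng.standard_normal(512), fs=FS)
        b = Epoch(rng.standard_normal(512), fs=128.0)
        with pytest.raises(ValueError):
            build_feature_vector(a, b, 0.1, 0.1)


class TestAnovaScreen:
    def test_identical_groups(self):
        assert anova_screen([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # SSB = 13.5, SSW = 4, df = (1, 4) -> F = 13.5, P ~= 0.0213
        p = anova_screen([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.02131164, abs=1e-6)

    def test_tiny_jitter_has_large_p(self, rng):
        g0 = rng.standard_normal(400)
        g1 = g0 + 1e-6 * rng.standard_normal(400)
        assert anova_screen(g0, g1) > 0.9

    def test_degenerate_equal_constant_groups(self):
        assert anova_screen([2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_single_value_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_screen([1.0], [2.0, 3.0])


class TestCrossValidate:
    def test_perfectly_separable_is_perfect(self, rng):
        feats = synthetic_features(20, rng, separation=50.0)
        report = cross_validate(feats, RFConfig(n_trees=50, seed=0))
        assert report.accuracy == 1.0
        assert report.sensitivity == 1.0
        assert report.specificity == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        feats = synthetic_features(100, rng, separation=0.0)
        report = cross_validate(feats, RFConfig(n_trees=100, seed=1))
        # permutation null: accuracy within 3 binomial sd of 0.5
        assert abs(report.accuracy - 0.5) < 3 * np.sqrt(0.25 / 200)

    def test_metric_identities_and_counts(self, rng):
        feats = synthetic_features(15, rng, separation=1.0)
        report = cross_validate(feats, RFConfig(n_trees=50, seed=2))
        p = report.pooled
        n = len(feats)
        assert p.n == n
        assert report.accuracy == (p.tp + p.tn) / n
        assert report.sensitivity == p.tp / (p.tp + p.fn)
        assert report.specificity == p.tn / (p.tn + p.fp)
        for fold in report.folds:
            assert fold.n > 0

    def test_confusion_arithmetic(self):
        f = FoldCounts(tp=91, fn=9, tn=94, fp=6)
        assert (f.tp + f.tn) / f.n == pytest.approx(0.925)
        assert f.tp / (f.tp + f.fn) == pytest.approx(0.91)
        assert f.tn / (f.tn + f.fp) == pytest.approx(0.94)

    def test_stratification_within_one_sample(self, rng):
        feats = synthetic_features(25, rng)
        report = cross_validate(feats, RFConfig(n_trees=20, seed=3))
        labels = np.array([f.label for f in feats])
        global_frac = np.mean(labels == "epileptic")
        for fold_id in np.unique(report.fold_assignments):
            mask = report.fold_assignments == fold_id
            n_pos = np.sum(labels[mask] == "epileptic")
            assert abs(n_pos - global_frac * mask.sum()) <= 1.0

    def test_seeded_reproducibility(self, rng):
        feats = synthetic_features(15, rng)
        r1 = cross_validate(feats, RFConfig(n_trees=30, seed=7))
        r2 = cross_validate(feats, RFConfig(n_trees=30, seed=7))
        assert np.array_equal(r1.fold_assignments, r2.fold_assignments)
        assert r1.to_dict() == r2.to_dict()

    def test_insufficient_class_size_rejected(self, rng):
        feats = synthetic_features(5, rng)
        with pytest.raises(ValueError):
            cross_validate(feats, RFConfig(n_trees=10), n_folds=10)

    def test_grid_search_runs_inside_training_folds(self, rng):
        feats = synthetic_features(15, rng, separation=5.0)
        cfg = RFConfig(n_trees=20, seed=0, grid={"n_trees": [10, 20],
                                                 "n_vars_per_split": [2, 5]})
        report = cross_validate(feats, cfg, n_folds=3)
        assert report.accuracy > 0.9


class TestFeatureIO:
    def test_roundtrip(self, tmp_path, rng):
        feats = synthetic_features(4, rng)
        path = tmp_path / "features.csv"
        save_features(feats, path)
        again = load_features(path)
        assert len(again) == len(feats)
        assert list(features_to_frame(feats).columns) == list(FEATURE_COLUMNS) + ["label"]
        assert np.allclose(
            np.vstack([f.values for f in again]),
            np.vstack([f.values for f in feats]),
        )
        assert [f.label for f in again] == [f.label for f in feats]

    def test_balanced_subsample(self, rng):
        feats = synthetic_features(10, rng) + synthetic_features(5, rng)[:5]
        out = balanced_subsample(feats, rng)
        labels = [f.label for f in out]
        assert labels.count("epileptic") == labels.count("nonepileptic")

    def test_report_json(self, tmp_path, rng):
        import json

        feats = synthetic_features(12, rng)
        report = cross_validate(feats, RFConfig(n_trees=20, seed=0))
        path = tmp_path / "report.json"
        report.save_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["accuracy"] == report.accuracy
        assert loaded["config"]["seed"] == 0


class TestFeatureVectorContract:
    def test_psi_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(1.0, 1.0, np.array([0.5, 0.5, 0.5, 0.5, 1.5]))

    def test_wrong_psi_length_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(1.0, 1.0, np.array([0.5, 0.5]))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(1.0, 1.0, np.zeros(5), label="ictal")
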