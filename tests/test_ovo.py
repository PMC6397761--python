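import numpy as np
import pytest
from hypothesis import given, strategies as st

from miace.data_io import Bag, BagSet
from miace.ovo import (
    bag_confidence,
    load_model,
    predict,
    predict_hierarchical,
    save_model,
    train_hierarchical,
    train_ovo,
    train_threshold,
)
from miace.core import TargetSignature, ace_statistic
from miace.preprocess import BackgroundModel
from miace import metrics, synthetic


def brute_force_best_threshold(confidences, is_target):
    """Exhaustive scan over all midpoints plus the outside candidates."""
    c = np.asarray(confidences, dtype=float)
    y = np.asarray(is_target, dtype=bool)
    u = np.unique(c)
    candidates = np.concatenate(([u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1]]))
    accs = [np.mean((c > t) == y) for t in candidates]
    return max(accs)


class TestBagConfidence:
    @pytest.fixture
    def clf(self):
        bg = BackgroundModel.from_moments(np.zeros(2), np.eye(2))
        sig = TargetSignature.from_target(np.array([1.0, 0.0]), bg)
        from miace.ovo import BinaryClassifier

        return BinaryClassifier("A", "B", sig, threshold=0.0, training_accuracy=1.0)

    def test_identical_instances_equal_single_statistic(self, clf):
        x = np.array([0.6, 0.8])
        bag = Bag("b", np.tile(x, (4, 1)), "A")
        assert bag_confidence(bag, clf) == pytest.approx(ace_statistic(x, clf.signature))

    def test_mean_of_two_statistics(self, clf):
        # statistics cos(0)=1 and cos(90)=0 -> mean 0.5
        bag = Bag("b", np.array([[1.0, 0.0], [0.0, 1.0]]), "A")
        assert bag_confidence(bag, clf) == pytest.approx(0.5)

    def test_equals_explicit_loop(self, clf, rng):
        bag = Bag("b", rng.normal(size=(17, 2)), "A")
        expected = np.mean([ace_statistic(x, clf.signature) for x in bag.instances])
        assert bag_confidence(bag, clf) == pytest.approx(expected)


class TestTrainThreshold:
    def test_clean_separation_midpoint(self):
        res = train_threshold([0.8, 0.6, 0.2, 0.1], [True, True, False, False])
        assert res.threshold == pytest.approx(0.4)
        assert res.accuracy == 1.0

    def test_single_target_above_all(self):
        res = train_threshold([0.9, 0.2, 0.1], [True, False, False])
        assert res.accuracy == 1.0

    def test_interleaved_matches_exhaustive_scan(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 12))
            c = rng.normal(size=n)
            y = rng.random(n) < 0.5
            if y.all() or not y.any():
                y[0] = not y[0]
            res = train_threshold(c, y)
            assert res.accuracy == pytest.approx(brute_force_best_threshold(c, y))

    def test_identical_confidences_degenerate(self):
        with pytest.warns(UserWarning):
            res = train_threshold([0.3, 0.3, 0.3], [True, False, False])
        assert res.threshold == pytest.approx(0.3)
        assert res.accuracy == pytest.approx(2 / 3)
        assert res.degenerate

    def test_requires_both_bag_kinds(self):
        with pytest.raises(ValueError):
            train_threshold([0.1, 0.2], [True, True])

    @given(
        st.lists(
            st.floats(min_value=-1, max_value=1, allow_nan=False), min_size=2, max_size=10
        ),
        st.integers(min_value=0, max_value=1023),
    )
    def test_accuracy_never_below_exhaustive_scan(self, confs, mask_bits):
        flags = [(mask_bits >> i) & 1 == 1 for i in range(len(confs))]
        if all(flags) or not any(flags):
            return
        c = np.asarray(confs)
        if np.unique(c).size == 1:
            return
        res = train_threshold(confs, flags)
        assert res.accuracy >= brute_force_best_threshold(confs, flags) - 1e-12


class TestTrainOvo:
    def test_four_classes_one_mode_gives_six_classifiers(self, separable_bagset):
        _, bagset, _ = separable_bagset
        model = train_ovo(bagset, "species", pairs_mode="one")
        assert model.n_classifiers == 6
        assert model.classes == ("C01", "C02", "C03", "C04")

    def test_two_mode_doubles_classifier_count(self, separable_bagset):
        _, bagset, _ = separable_bagset
        model = train_ovo(bagset, "species", pairs_mode="two")
        assert model.n_classifiers == 12

    def test_two_classes_reduce_to_direct_thresholding(self):
        cfg = synthetic.make_config(
            n_classes=2, n_bands=40, seed=5, bags_per_class=8, instances_per_bag=(5, 10)
        )
        bagset, _ = synthetic.generate(cfg)
        model = train_ovo(bagset, "species")
        assert model.n_classifiers == 1
        clf = model.classifiers[0]
        preds = predict(bagset, model, seed=0)
        for bag, p in zip(bagset.bags, preds):
            direct = (
                clf.target_class
                if bag_confidence(bag, clf) > clf.threshold
                else clf.background_class
            )
            assert p.predicted == direct

    def test_separated_classes_train_to_perfect_accuracy(self, separable_bagset):
        _, bagset, _ = separable_bagset
        model = train_ovo(bagset, "species")
        assert all(c.training_accuracy == 1.0 for c in model.classifiers)

    def test_single_class_is_hard_error(self, tiny_bagset):
        one = tiny_bagset.subset(tiny_bagset.bags[:1])
        with pytest.raises(ValueError):
            train_ovo(one, "genus")


class TestPredict:
    def test_vote_conservation(self, separable_bagset):
        _, bagset, _ = separable_bagset
        for mode, expected in (("one", 6), ("two", 12)):
            model = train_ovo(bagset, "species", pairs_mode=mode)
            preds = predict(bagset, model, seed=0)
            for p in preds:
                assert sum(p.votes.values()) == expected

    def test_unanimous_winner_takes_c_minus_1_votes(self, separable_bagset):
        _, bagset, _ = separable_bagset
        model = train_ovo(bagset, "species")
        preds = predict(bagset, model, seed=0)
        # separable data: every classifier involving the true class agrees
        unanimous = [p for p in preds if p.votes[p.predicted] == 3]
        assert len(unanimous) == len(preds)
        assert all(p.predicted == p.truth for p in preds)

    def test_permutation_invariance(self, separable_bagset, rng):
        _, bagset, _ = separable_bagset
        model = train_ovo(bagset, "species")
        preds = {p.bag_id: p.predicted for p in predict(bagset, model, seed=3)}
        shuffled = bagset.subset([bagset.bags[i] for i in rng.permutation(bagset.n_bags)])
        preds_shuffled = {p.bag_id: p.predicted for p in predict(shuffled, model, seed=3)}
        assert preds == preds_shuffled

    def test_mode_one_and_two_agree_on_separable_data(self, separable_bagset):
        _, bagset, _ = separable_bagset
        p1 = predict(bagset, train_ovo(bagset, "species", pairs_mode="one"), seed=0)
        p2 = predict(bagset, train_ovo(bagset, "species", pairs_mode="two"), seed=0)
        assert [p.predicted for p in p1] == [p.predicted for p in p2]

    def test_tie_flag_and_seeded_resolution(self, separable_bagset):
        _, bagset, _ = separable_bagset
        model = train_ovo(bagset, "species")
        # force a three-way tie by rigging thresholds so votes come out (2,2,2,0)
        preds = predict(bagset, model, seed=0)
        assert not any(p.tie for p in preds)  # separable: no ties
        # same seed -> identical labels on repeated runs
        again = predict(bagset, model, seed=0)
        assert [p.predicted for p in preds] == [p.predicted for p in again]

    def test_forced_three_way_tie_is_flagged_and_seed_stable(self):
        from miace.ovo import BinaryClassifier, OvoModel
        from miace.data_io import BandAxis

        bg = BackgroundModel.from_moments(np.zeros(2), np.eye(2))
        sig = TargetSignature.from_target(np.array([1.0, 0.0]), bg)
        # rig thresholds so votes come out one per class: a 3-way tie
        clfs = [
            BinaryClassifier("A", "B", sig, threshold=-2.0, training_accuracy=1.0),
            BinaryClassifier("A", "C", sig, threshold=2.0, training_accuracy=1.0),
            BinaryClassifier("B", "C", sig, threshold=-2.0, training_accuracy=1.0),
        ]
        model = OvoModel(clfs, ("A", "B", "C"), "one", "genus")
        bagset = BagSet(
            [Bag("crown", np.array([[0.5, 0.5]]), "A")], BandAxis([400.0, 500.0])
        )
        p = predict(bagset, model, seed=4).predictions[0]
        assert p.tie
        assert sum(p.votes.values()) == 3
        assert set(p.votes.values()) == {1}
        assert p.predicted in {"A", "B", "C"}  # any tied class may win
        # the draw is seed-stable
        repeats = {
            predict(bagset, model, seed=4).predictions[0].predicted for _ in range(5)
        }
        assert len(repeats) == 1
        # deterministic margin rule never consults the rng
        pm = predict(bagset, model, seed=0, tie_break="margin").predictions[0]
        assert pm.tie and pm.predicted in {"A", "B", "C"}

    def test_band_mismatch_is_hard_error(self, separable_bagset, tiny_bagset):
        _, bagset, _ = separable_bagset
        model = train_ovo(bagset, "species")
        with pytest.raises(ValueError):
            predict(tiny_bagset, model, seed=0)


class TestHierarchy:
    def test_structure(self, hierarchical_bagset):
        _, bagset, _ = hierarchical_bagset
        model = train_hierarchical(bagset)
        assert model.level == "genus"
        assert model.hierarchy is not None
        assert model.hierarchy["AC"] == "ACRU"  # single species: direct map
        sub = model.hierarchy["PI"]
        assert sub.classes == ("PIEL", "PIPA", "PITA")
        assert sub.n_classifiers == 3

    def test_single_species_genus_bypasses_species_model(self, hierarchical_bagset):
        _, bagset, _ = hierarchical_bagset
        model = train_hierarchical(bagset)
        preds = predict_hierarchical(bagset, model, seed=0)
        for p in preds:
            if p.predicted_genus == "AC":
                assert p.predicted == "ACRU"
                assert p.votes == {}  # no species-level model consulted

    def test_multi_species_genus_routes_to_submodel(self, hierarchical_bagset):
        _, bagset, _ = hierarchical_bagset
        model = train_hierarchical(bagset)
        preds = predict_hierarchical(bagset, model, seed=0)
        for p in preds:
            if p.predicted_genus == "PI":
                assert p.predicted in {"PIEL", "PIPA", "PITA"}

    def test_separable_two_level_species_accuracy_is_one(self, hierarchical_bagset):
        _, bagset, _ = hierarchical_bagset
        model = train_hierarchical(bagset)
        preds = predict_hierarchical(bagset, model, seed=0)
        assert metrics.confusion(preds).accuracy == 1.0

    def test_hierarchy_required(self, separable_bagset):
        _, bagset, _ = separable_bagset
        flat = train_ovo(bagset, "species")
        with pytest.raises(ValueError):
            predict_hierarchical(bagset, flat, seed=0)


class TestPersistence:
    def test_round_trip_preserves_predictions(self, hierarchical_bagset, tmp_path):
        _, bagset, _ = hierarchical_bagset
        model = train_hierarchical(bagset)
        save_model(model, tmp_path / "model", metadata={"note": "test"})
        again, meta = load_model(tmp_path / "model")
        assert meta == {"note": "test"}
        before = [p.predicted for p in predict_hierarchical(bagset, model, seed=1)]
        after = [p.predicted for p in predict_hierarchical(bagset, again, seed=1)]
        assert before == after
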