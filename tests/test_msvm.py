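"""One-vs-one SVM construction, voting, cross-validation and tuning."""
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from watergrade.errors import TrainingError, ValidationError
from watergrade.msvm import (
    KernelSpec,
    OvoModel,
    cv_fitness,
    pso_tune,
    spec_from_position,
    train_ovo,
    vote,
)
from watergrade.pso import PsoConfig
from watergrade.synth import SynthConfig, generate


def brute_force_vote(classes, decisions, i):
    """Independent oracle: count votes explicitly for sample i."""
    votes = {c: 0 for c in classes}
    scores = {c: 0.0 for c in classes}
    for (a, b), d in decisions.items():
        winner = b if d[i] > 0 else a
        votes[winner] += 1
        scores[a] -= d[i]
        scores[b] += d[i]
    best_votes = max(votes.values())
    tied = [c for c in classes if votes[c] == best_votes]
    best_score = max(scores[c] for c in tied)
    tied = [c for c in tied if scores[c] == best_score]
    return min(tied)


class TestKernelSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kind": "linear", "C": 1.0, "r": 0.5},        # linear takes only C
            {"kind": "rbf", "C": 1.0},                      # rbf needs r
            {"kind": "rbf", "C": 1.0, "r": -1.0},
            {"kind": "rbf", "C": 1.0, "r": 0.5, "d": 2},
            {"kind": "polynomial", "C": 1.0},               # poly needs d
            {"kind": "polynomial", "C": 1.0, "d": 0},
            {"kind": "rbf", "C": 0.0, "r": 0.5},            # C must be positive
            {"kind": "sigmoid", "C": 1.0},
        ],
    )
    def test_parameter_sets_follow_the_kernel_table(self, kwargs):
        with pytest.raises(ValidationError):
            KernelSpec(**kwargs)

    def test_rbf_width_maps_to_gamma(self):
        svc = KernelSpec("rbf", C=2.0, r=0.5).make_svc()
        assert svc.gamma == pytest.approx(1.0 / 0.25)

    def test_position_decoding_is_log10(self):
        spec = spec_from_position("rbf", np.array([2.0, -1.0]))
        assert spec.C == pytest.approx(100.0) and spec.r == pytest.approx(0.1)


class TestTrainOvo:
    def test_six_classes_give_fifteen_binary_models(self):
        ds = generate(SynthConfig(n_per_class=10, seed=0))
        model = train_ovo(ds.X, ds.labels, KernelSpec("rbf", C=10.0, r=1.0))
        assert len(model.binary_models) == 15
        assert set(model.binary_models) == set(combinations(range(1, 7), 2))

    def test_two_classes_reduce_to_single_binary_model(self):
        ds = generate(SynthConfig(n_per_class={1: 15, 4: 15}, seed=1))
        model = train_ovo(ds.X, ds.labels, KernelSpec("linear", C=10.0))
        assert len(model.binary_models) == 1
        svc = model.binary_models[(1, 4)]
        direct = svc.predict(model.scaler.transform(ds.X))
        assert np.array_equal(model.predict(ds.X), direct)

    def test_separable_toy_set_is_fit_exactly(self):
        X = pd.DataFrame({"a": [0, 0.1, 1, 1.1], "b": [0, 0.1, 1, 1.1]})
        y = np.array([1, 1, 2, 2])
        model = train_ovo(X, y, KernelSpec("linear", C=1000.0))
        assert np.array_equal(model.predict(X), y)

    def test_single_class_is_a_training_error(self):
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        with pytest.raises(TrainingError):
            train_ovo(X, np.array([3, 3, 3]), KernelSpec("linear", C=1.0))

    def test_removing_a_class_shrinks_the_pair_count(self):
        ds = generate(SynthConfig(n_per_class=8, seed=3))
        keep = ds.labels != 6
        model = train_ovo(ds.X[keep], ds.labels[keep], KernelSpec("rbf", C=1.0, r=1.0))
        assert len(model.binary_models) == 5 * 4 // 2

    def test_feature_mismatch_on_predict(self):
        ds = generate(SynthConfig(n_per_class=10, seed=0))
        model = train_ovo(ds.X[["do", "codmn"]], ds.labels, KernelSpec("rbf", C=1.0, r=1.0))
        with pytest.raises(ValidationError):
            model.predict(ds.X[["do", "nh3n"]])

    def test_model_archive_roundtrip(self, tmp_path):
        ds = generate(SynthConfig(n_per_class=10, seed=5))
        model = train_ovo(ds.X, ds.labels, KernelSpec("rbf", C=5.0, r=0.8))
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = OvoModel.load(path)
        assert loaded.kernel == model.kernel
        assert np.array_equal(loaded.predict(ds.X), model.predict(ds.X))


class TestVoting:
    def test_clear_majority(self):
        # pairs over classes (1,2,3): 1 beats 2, 1 beats 3, 2 beats 3
        decisions = {(1, 2): np.array([-1.0]), (1, 3): np.array([-1.0]),
                     (2, 3): np.array([-1.0])}
        assert vote((1, 2, 3), decisions)[0] == 1

    def test_cycle_resolved_by_decision_values_then_lowest_id(self):
        # 1 beats 2, 2 beats 3, 3 beats 1: one vote each (dyadic values, so
        # the accumulated scores are exact)
        decisions = {(1, 2): np.array([-0.5, -0.5]), (2, 3): np.array([-0.75, -0.5]),
                     (1, 3): np.array([0.5, 0.5])}
        # sample 0 scores: 1 -> 0.0, 2 -> 0.25, 3 -> -0.25: class 2 wins
        # sample 1 scores: all 0.0: lowest class id wins
        assert list(vote((1, 2, 3), decisions)) == [2, 1]

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_matches_brute_force_oracle_on_random_tables(self, k, rng):
        classes = tuple(range(1, k + 1))
        for _ in range(50):
            n = int(rng.integers(1, 6))
            decisions = {
                pair: rng.normal(size=n) for pair in combinations(classes, 2)
            }
            got = vote(classes, decisions)
            want = [brute_force_vote(classes, decisions, i) for i in range(n)]
            assert list(got) == want

    def test_invariant_to_pair_iteration_order(self, rng):
        classes = (1, 2, 3, 4)
        decisions = {pair: rng.normal(size=8) for pair in combinations(classes, 2)}
        reordered = dict(reversed(list(decisions.items())))
        assert np.array_equal(vote(classes, decisions), vote(classes, reordered))


class TestCvFitness:
    def test_separable_data_has_zero_loss(self):
        ds = generate(SynthConfig(n_per_class={1: 20, 6: 20}, seed=2))
        loss = cv_fitness(ds.X, ds.labels, "rbf", [2.0, 0.0], folds=4, seed=0)
        assert loss == 0.0

    def test_permuted_labels_sit_at_chance_level(self, rng):
        ds = generate(SynthConfig(n_per_class=40, seed=4))
        y = rng.permutation(ds.labels)
        loss = cv_fitness(ds.X, y, "rbf", [0.0, 0.0], folds=5, seed=0)
        assert loss == pytest.approx(5.0 / 6.0, abs=0.08)

    def test_deterministic_given_seed(self):
        ds = generate(SynthConfig(n_per_class=15, seed=6))
        a = cv_fitness(ds.X, ds.labels, "rbf", [1.0, -0.5], folds=3, seed=9)
        b = cv_fitness(ds.X, ds.labels, "rbf", [1.0, -0.5], folds=3, seed=9)
        assert a == b

    def test_tiny_class_cannot_fold(self):
        ds = generate(SynthConfig(n_per_class={1: 3, 2: 30}, seed=0))
        with pytest.raises(TrainingError):
            cv_fitness(ds.X, ds.labels, "linear", [1.0], folds=5, seed=0)


class TestPsoTune:
    def test_collapsed_search_box_returns_that_point(self):
        ds = generate(SynthConfig(n_per_class={1: 10, 2: 10}, seed=7))
        res = pso_tune(
            ds.X, ds.labels, kernel_kind="rbf",
            search_bounds={"log10_C": (1.0, 1.0), "log10_r": (-0.5, -0.5)},
            folds=2,
        )
        assert res.kernel.C == pytest.approx(10.0)
        assert res.kernel.r == pytest.approx(10 ** -0.5)
        assert res.iterations == 0

    def test_tuning_history_is_non_increasing_and_deterministic(self):
        ds = generate(SynthConfig(n_per_class={1: 15, 3: 15, 6: 15}, seed=8))
        cfg = PsoConfig(bounds=((0, 1),), swarm_size=6, t_max=6, tol=0.0,
                        patience=10, seed=2)
        a = pso_tune(ds.X, ds.labels, "rbf", pso_cfg=cfg, folds=3, cv_seed=1)
        b = pso_tune(ds.X, ds.labels, "rbf", pso_cfg=cfg, folds=3, cv_seed=1)
        assert np.all(np.diff(a.history) <= 0)
        assert a.kernel == b.kernel and a.cv_error == b.cv_error
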