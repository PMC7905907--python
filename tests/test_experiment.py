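"""Repeated-split protocol: subset selection, reproducibility, aggregation,
cost-sensitivity of the weighting, and the GA optimizer."""

import numpy as np
import pytest

from costvote.dataio import ValidationError
from costvote.ensemble import CostSensitiveVotingEnsemble
from costvote.experiment import (DEFAULT_TUNING_SPACE, ExperimentConfig, GaConfig,
                                 IntParam, derive_seed, ga_optimize, run_experiment,
                                 run_repeat, select_feature_subset, write_outputs)
from costvote.learners import MemberSpec
from costvote.metrics import CostMatrix, compute_weights, confusion, \
    efficiency_index, misclassification_cost
from costvote.preprocess import apply_normalizer, fit_normalizer
from costvote.relief import relief_weights
from costvote.synth import ContinuousFeature, SynthConfig, generate, statlog_like

SMALL_MEMBERS = tuple(MemberSpec(n) for n in ("rf", "lr", "knn"))


def small_config(**kw) -> ExperimentConfig:
    kw.setdefault("repeats", 2)
    kw.setdefault("members", SMALL_MEMBERS)
    kw.setdefault("seed", 5)
    return ExperimentConfig(**kw)


def one_signal_dataset(seed: int, n: int = 300, p_noise: int = 7):
    features = [ContinuousFeature("signal", effect=2.5)]
    features += [ContinuousFeature(f"noise{j}") for j in range(p_noise)]
    return generate(SynthConfig(features=tuple(features), n=n, prevalence=0.5,
                                seed=seed))


class TestSelectFeatureSubset:
    def test_single_feature_is_trivial(self):
        ds = one_signal_dataset(seed=0, p_noise=0)
        ds = apply_normalizer(ds, fit_normalizer(ds))
        ranking = relief_weights(ds).ranking
        idx = np.arange(ds.n_instances)
        k, subset, curve = select_feature_subset(
            ds.take(idx[:240]), ds.take(idx[240:]), ranking, small_config())
        assert k == 1 and subset == ("signal",) and len(curve) == 1

    def test_prefers_small_informative_prefix(self):
        """With one informative feature among eight, the chosen prefix is the
        validation-E argmax (so never worse than the full feature set) and is
        small in median over seeded runs."""
        ks = []
        for seed in range(10):
            ds = one_signal_dataset(seed=100 + seed)
            ds = apply_normalizer(ds, fit_normalizer(ds))
            rng = np.random.default_rng(seed)
            idx = rng.permutation(ds.n_instances)
            train, val = ds.take(idx[:240]), ds.take(idx[240:])
            ranking = relief_weights(train).ranking
            assert ranking[0] == "signal"
            cfg = small_config(seed=seed)
            k, _, curve = select_feature_subset(train, val, ranking, cfg, seed=seed)
            assert curve[k - 1] >= curve[-1]
            assert curve[k - 1] == max(curve)
            ks.append(k)
        assert np.median(ks) <= 3

    def test_flat_curve_breaks_tie_to_smallest_k(self):
        ds = one_signal_dataset(seed=3, n=80, p_noise=2)
        ds = apply_normalizer(ds, fit_normalizer(ds))
        ranking = relief_weights(ds).ranking
        idx = np.arange(ds.n_instances)
        k, subset, curve = select_feature_subset(
            ds.take(idx[:60]), ds.take(idx[60:]), ranking,
            small_config(seed=1), seed=1)
        best = max(range(len(curve)), key=lambda i: (curve[i], -i))
        assert k == best + 1
        if len(set(curve)) == 1:  # genuinely flat -> must pick 1
            assert k == 1

    def test_incomplete_ranking_rejected(self):
        ds = one_signal_dataset(seed=4, n=60, p_noise=2)
        with pytest.raises(ValidationError):
            select_feature_subset(ds, ds, ("signal",), small_config())


class TestRunRepeat:
    def test_deterministic_for_fixed_seed(self):
        ds = generate(statlog_like(n=150, seed=8))
        cfg = small_config(seed=9)
        a = run_repeat(ds, cfg, 0)
        b = run_repeat(ds, cfg, 0)
        assert a.to_dict() == b.to_dict()

    def test_weights_sum_to_one_and_subset_is_ranking_prefix(self):
        ds = generate(statlog_like(n=120, seed=10))
        r = run_repeat(ds, small_config(seed=11), 0)
        assert sum(r.weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert r.chosen_subset == r.ranking[:r.chosen_k]
        assert r.chosen_k == int(np.nanargmax(r.e_curve)) + 1

    def test_smoke_on_small_dataset(self):
        ds = generate(SynthConfig(
            features=(ContinuousFeature("a", effect=1.0), ContinuousFeature("b")),
            n=60, prevalence=0.5, seed=12))
        cfg = small_config(repeats=1, seed=13)
        summary = run_experiment(ds, cfg)
        assert len(summary.repeats) == 1
        assert set(summary.methods) == {"rf", "lr", "knn", "ensemble"}

    def test_single_member_ensemble_equals_member(self):
        ds = generate(statlog_like(n=120, seed=14))
        cfg = small_config(members=(MemberSpec("rf"),), seed=15)
        r = run_repeat(ds, cfg, 0)
        assert r.test_metrics["ensemble"].as_dict() == \
            r.test_metrics["rf"].as_dict()


class TestRunExperiment:
    def test_aggregation_and_picks(self):
        ds = generate(statlog_like(n=150, seed=16))
        cfg = small_config(repeats=3, seed=17)
        summary = run_experiment(ds, cfg)
        for metric, v in summary.methods["ensemble"].items():
            vals = [r.test_metrics["ensemble"].as_dict()[metric]
                    for r in summary.repeats]
            assert v["mean"] == pytest.approx(np.mean(vals))
            assert v["sd"] == pytest.approx(np.std(vals, ddof=1))
        assert all(0 <= c <= 3 for c in summary.picks.values())
        always = [r.chosen_subset[0] for r in summary.repeats]
        if len(set(always)) == 1:
            assert summary.picks[always[0]] == 3

    def test_byte_identical_json_for_same_seed(self, tmp_path):
        ds = generate(statlog_like(n=120, seed=18))
        cfg = small_config(repeats=2, seed=19)
        a = run_experiment(ds, cfg).to_json()
        b = run_experiment(ds, cfg).to_json()
        assert a == b
        write_outputs(run_experiment(ds, cfg), tmp_path)
        assert (tmp_path / "summary.json").read_text() == a

    def test_derive_seed_stable_and_bounded(self):
        assert derive_seed(7, 3) == derive_seed(7, 3)
        assert derive_seed(7, 3) != derive_seed(7, 4)
        assert 0 <= derive_seed(2 ** 31 - 1, 999) < 2 ** 31


class TestCostSensitivity:
    def test_high_fn_member_never_favored_by_asymmetric_costs(self):
        """Among equal-accuracy members, cost-neutral (1,1) weighting is
        uniform while (10,1) pushes the member with the most false negatives
        below uniform — its weight under (10,1) never exceeds its weight
        under (1,1)."""
        y = np.array([1] * 10 + [0] * 10)
        # three members, all accuracy 16/20, different FN/FP mixes
        preds = [
            np.concatenate([np.zeros(4), np.ones(6), np.zeros(10)]),      # 4 FN
            np.concatenate([np.zeros(2), np.ones(8), np.ones(2), np.zeros(8)]),  # 2 FN 2 FP
            np.concatenate([np.ones(10), np.ones(4), np.zeros(6)]),       # 4 FP
        ]
        weights = {}
        for costs in ((10.0, 1.0), (1.0, 1.0)):
            cm = CostMatrix(cost_fn=costs[0], cost_fp=costs[1])
            e = []
            for p in preds:
                c = confusion(y, p.astype(int))
                assert c.accuracy == pytest.approx(0.8)
                e.append(efficiency_index(c.accuracy,
                                          misclassification_cost(c, cm), cm))
            weights[costs] = compute_weights(e, cm).weights
        np.testing.assert_allclose(weights[(1.0, 1.0)], 1 / 3)
        assert weights[(10.0, 1.0)][0] <= weights[(1.0, 1.0)][0]
        assert weights[(10.0, 1.0)][0] < weights[(10.0, 1.0)][2]


class TestEnsembleEstimator:
    def test_fit_predict_and_reweight(self):
        rng = np.random.default_rng(20)
        n = 80
        y = rng.integers(0, 2, size=n)
        y[:2], y[2:4] = 0, 1
        X = rng.normal(size=(n, 4))
        X[:, 0] += 2.0 * y
        clf = CostSensitiveVotingEnsemble(random_state=1).fit(X[:60], y[:60])
        assert clf.weights_.sum() == pytest.approx(1.0)
        assert clf.weight_source_ == "train"
        pred = clf.predict(X[60:])
        assert np.isin(pred, (0, 1)).all()
        clf.reweight(X[60:], y[60:])
        assert clf.weight_source_ == "validation"
        assert clf.weights_.sum() == pytest.approx(1.0)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        clf = CostSensitiveVotingEnsemble(cost_fn=5.0)
        assert clone(clf).cost_fn == 5.0


class TestGa:
    def test_finds_unimodal_integer_optimum(self):
        space = {"x": IntParam(0, 31)}
        fitness = lambda g: -(g["x"] - 17) ** 2
        exhaustive = max(range(32), key=lambda v: -(v - 17) ** 2)
        best, score, history = ga_optimize(
            space, fitness, GaConfig(generations=20, seed=2))
        assert best["x"] == exhaustive == 17
        assert score == 0
        assert history == sorted(history)  # elitism: best never degrades

    def test_deterministic_trajectory(self):
        space = {"x": IntParam(0, 100), "y": IntParam(0, 100)}
        fitness = lambda g: -(g["x"] - 40) ** 2 - (g["y"] - 60) ** 2
        cfg = GaConfig(generations=8, seed=3)
        r1 = ga_optimize(space, fitness, cfg)
        r2 = ga_optimize(space, fitness, cfg)
        assert r1 == r2

    def test_population_default_is_50(self):
        assert GaConfig().population == 50

    def test_empty_space_rejected(self):
        with pytest.raises(ValidationError):
            ga_optimize({}, lambda g: 0.0, GaConfig())

    def test_default_space_covers_all_tunable_members(self):
        members = {k.split(".")[0] for k in DEFAULT_TUNING_SPACE}
        assert members == {"rf", "svm", "knn", "elm"}
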