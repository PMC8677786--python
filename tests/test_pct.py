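"""Predictive clustering trees and the bagging ensemble."""

import json
import warnings

import numpy as np
import pytest

from phenoscreen import (
    Fingerprint,
    TrainingSet,
    TreeParams,
    best_split,
    ensemble_from_json,
    ensemble_to_json,
    evaluate_split,
    fit_ensemble,
    grow_tree,
    predict_ensemble,
    predict_ensemble_many,
    predict_tree,
    scenario_paper_like,
    target_variance,
)
from phenoscreen.pct import Ensemble, Leaf, PCTree

from conftest import random_records, record


def oracle_best_split(records, scale, min_leaf=1):
    """Exhaustive per-bit enumeration with numpy variance (independent of
    the vectorised search); ties grouped at 1e-12 resolve to lowest bit."""
    nbits = records[0].fingerprint.nbits
    y = np.array([(r.rfp, r.egfp) for r in records])
    s = np.asarray(scale)
    total = float((y.var(axis=0) / s**2).sum())
    n = len(records)
    scores = {}
    for bit in range(nbits):
        ones = [i for i, r in enumerate(records) if bit in r.fingerprint.bits]
        zeros = [i for i in range(n) if i not in ones]
        if len(ones) < min_leaf or len(zeros) < min_leaf:
            continue
        cost = 0.0
        for side in (ones, zeros):
            cost += len(side) / n * float((y[side].var(axis=0) / s**2).sum())
        scores[bit] = total - cost
    if not scores:
        return None
    best = max(scores.values())
    tied = [b for b, v in scores.items() if v >= best - 1e-12]
    return min(tied), best


class TestTargetVariance:
    def test_single_record_zero(self):
        assert target_variance([record("a", {0}, 1.0, 1.0)], (1, 1)) == 0.0

    def test_population_variance_example(self):
        recs = [record("a", {0}, 0.0, 0.0), record("b", {1}, 2.0, 0.0)]
        assert target_variance(recs, (1, 1)) == pytest.approx(1.0)

    def test_scale_normalisation_invariance(self):
        recs = [record("a", {0}, 0.2, 1.4), record("b", {1}, 1.0, 0.3)]
        scaled = [record(r.id, r.fingerprint.bits, r.rfp * 3, r.egfp * 3) for r in recs]
        assert target_variance(recs, (0.5, 0.7)) == pytest.approx(
            target_variance(scaled, (1.5, 2.1))
        )

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            target_variance([], (1, 1))


class TestEvaluateSplit:
    def test_perfect_separation_equals_total_variance(self):
        recs = [
            record("a", {3}, 0.2, 0.2),
            record("b", {3}, 0.2, 0.2),
            record("c", set(), 1.0, 1.0),
            record("d", set(), 1.0, 1.0),
        ]
        scale = (1.0, 1.0)
        assert evaluate_split(recs, 3, scale) == pytest.approx(
            target_variance(recs, scale)
        )

    def test_constant_bit_is_inadmissible(self):
        recs = [record("a", {1}, 0.0, 0.0), record("b", {1}, 1.0, 1.0)]
        assert evaluate_split(recs, 1, (1, 1)) == -np.inf

    def test_bad_bit_index(self):
        recs = [record("a", {0}, 0.0, 0.0), record("b", {1}, 1.0, 1.0)]
        with pytest.raises(ValueError):
            evaluate_split(recs, 99, (1, 1))

    def test_six_record_fixture_matches_oracle_on_all_bits(self):
        rng = np.random.default_rng(11)
        recs = random_records(rng, 6, 8)
        scale = (0.8, 1.2)
        y = np.array([(r.rfp, r.egfp) for r in recs])
        s = np.asarray(scale)
        total = float((y.var(axis=0) / s**2).sum())
        for bit in range(8):
            ones = [i for i, r in enumerate(recs) if bit in r.fingerprint.bits]
            zeros = [i for i in range(6) if i not in ones]
            got = evaluate_split(recs, bit, scale)
            if not ones or not zeros:
                assert got == -np.inf
                continue
            cost = sum(
                len(side) / 6 * float((y[side].var(axis=0) / s**2).sum())
                for side in (ones, zeros)
            )
            assert got == pytest.approx(total - cost, abs=1e-12)


class TestBestSplitOracle:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            recs = random_records(rng, n, 8)
            scale = (1.0, 1.0)
            expected = oracle_best_split(recs, scale)
            got = best_split(recs, scale)
            if expected is None:
                assert got is None
            else:
                assert got is not None
                assert got[0] == expected[0]
                assert got[1] == pytest.approx(expected[1], abs=1e-10)


class TestGrowTree:
    def test_constant_targets_single_leaf(self):
        recs = [record(f"r{i}", {i % 3}, 0.5, 0.7) for i in range(6)]
        tree = grow_tree(recs, TreeParams(min_leaf=1, n_trees=1))
        assert isinstance(tree.root, Leaf)
        assert tree.root.prototype == pytest.approx((0.5, 0.7))

    def test_single_bit_function_depth_one_zero_error(self):
        recs = [
            record(f"p{i}", {5}, 1.0, 1.0) for i in range(3)
        ] + [record(f"q{i}", set(), 0.0, 0.0) for i in range(3)]
        tree = grow_tree(recs, TreeParams(min_leaf=1, n_trees=1))
        assert tree.root.bit == 5
        for r in recs:
            assert predict_tree(tree, r.fingerprint) == pytest.approx((r.rfp, r.egfp))

    def test_xor_structure_depth_two_zero_error(self):
        # targets = XOR(bit0, bit1): no single bit reduces variance, yet a
        # two-level tree fits exactly
        recs = [
            record("00", set(), 0.0, 0.0),
            record("01", {1}, 1.0, 1.0),
            record("10", {0}, 1.0, 1.0),
            record("11", {0, 1}, 0.0, 0.0),
        ]
        tree = grow_tree(recs, TreeParams(min_leaf=1, n_trees=1))
        assert len(tree.leaves()) == 4
        for r in recs:
            assert predict_tree(tree, r.fingerprint) == pytest.approx((r.rfp, r.egfp))

    def test_path_split_bits_distinct(self, small_scenario):
        tree = grow_tree(
            small_scenario.training_set.records,
            TreeParams(min_leaf=2, n_trees=1),
            small_scenario.training_set.target_scale,
        )

        def walk(node, used):
            if isinstance(node, Leaf):
                return
            assert node.bit not in used
            walk(node.zero, used | {node.bit})
            walk(node.one, used | {node.bit})

        walk(tree.root, set())

    def test_chosen_reductions_nonnegative(self, small_scenario):
        tree = grow_tree(
            small_scenario.training_set.records,
            TreeParams(min_leaf=2, n_trees=1),
            small_scenario.training_set.target_scale,
        )
        assert all(s.reduction >= 0.0 for s in tree.splits())


class TestPredictTree:
    def test_single_leaf_always_prototype(self):
        tree = PCTree(root=Leaf(prototype=(0.3, 0.4), count=2), nbits=8)
        fp = Fingerprint(8, frozenset({1, 2}), 0)
        assert predict_tree(tree, fp) == (0.3, 0.4)
        assert predict_tree(tree, fp) == predict_tree(tree, fp)

    def test_nbits_mismatch(self):
        tree = PCTree(root=Leaf(prototype=(0.0, 0.0), count=1), nbits=8)
        with pytest.raises(ValueError):
            predict_tree(tree, Fingerprint(16, frozenset(), 0))


class TestEnsemble:
    def test_single_tree_no_bootstrap_equals_grow_tree(self, small_scenario):
        ts = small_scenario.training_set
        ens = fit_ensemble(ts, TreeParams(n_trees=1, bootstrap=False, min_leaf=2), seed=5)
        tree = grow_tree(ts.records, TreeParams(min_leaf=2, n_trees=1), ts.target_scale)
        for r in ts.records[:10]:
            pred = predict_ensemble(ens, r.fingerprint)
            assert (pred.rfp_mean, pred.egfp_mean) == pytest.approx(
                predict_tree(tree, r.fingerprint)
            )
            assert pred.rfp_sd == 0.0 and pred.egfp_sd == 0.0

    def test_same_seed_identical_ensembles(self, small_scenario):
        ts = small_scenario.training_set
        params = TreeParams(n_trees=8, min_leaf=2)
        a = fit_ensemble(ts, params, seed=17)
        b = fit_ensemble(ts, params, seed=17)
        assert ensemble_to_json(a) == ensemble_to_json(b)

    def test_constant_targets_all_single_leaves(self):
        recs = [record(f"r{i}", {i % 4}, 0.9, 0.9) for i in range(8)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ts = TrainingSet(recs)
        ens = fit_ensemble(ts, TreeParams(n_trees=5, min_leaf=1), seed=0)
        for tree in ens.trees:
            assert isinstance(tree.root, Leaf)
            assert tree.root.prototype == pytest.approx((0.9, 0.9))

    def test_degenerate_scale_warns_and_falls_back(self):
        recs = [record(f"r{i}", {i % 2}, 0.5, float(i)) for i in range(4)]
        with pytest.warns(UserWarning, match="zero-variance"):
            ts = TrainingSet(recs)
        assert ts.target_scale[0] == 1.0
        assert ts.target_scale[1] > 0

    def test_two_tree_mean_and_population_sd(self):
        trees = [
            PCTree(root=Leaf(prototype=(0.6, 1.0), count=1), nbits=8),
            PCTree(root=Leaf(prototype=(0.8, 1.0), count=1), nbits=8),
        ]
        ens = Ensemble(
            trees=trees,
            params=TreeParams(n_trees=2),
            seed=0,
            bootstrap_indices=[np.array([0]), np.array([0])],
            nbits=8,
        )
        pred = predict_ensemble(ens, Fingerprint(8, frozenset(), 0))
        assert pred.rfp_mean == pytest.approx(0.7)
        assert pred.rfp_sd == pytest.approx(0.1)
        assert pred.egfp_sd == 0.0

    def test_leaf_counts_sum_to_bootstrap_sample_size(self, small_scenario):
        ts = small_scenario.training_set
        ens = fit_ensemble(ts, TreeParams(n_trees=6, min_leaf=2), seed=3)
        for tree, idx in zip(ens.trees, ens.bootstrap_indices):
            assert sum(leaf.count for leaf in tree.leaves()) == idx.size

    def test_batch_prediction_matches_scalar(self, small_scenario):
        ts = small_scenario.training_set
        ens = fit_ensemble(ts, TreeParams(n_trees=6, min_leaf=2), seed=3)
        fps = [r.fingerprint for r in ts.records[:20]]
        batch = predict_ensemble_many(ens, fps)
        for fp, pred in zip(fps, batch):
            assert pred == predict_ensemble(ens, fp)

    def test_ensemble_training_mae_beats_worst_tree(self):
        # bagging averages: over seeded synthetic datasets the ensemble's
        # training MAE never exceeds its worst member tree's
        from phenoscreen.pct import _predict_tree_batch

        for seed in range(20):
            sc = scenario_paper_like(seed=seed, n=50, nbits=128, noise_sd=0.05)
            ts = sc.training_set
            ens = fit_ensemble(ts, TreeParams(n_trees=10, min_leaf=2), seed=seed + 100)
            X = ts.feature_matrix()
            Y = ts.targets()
            tree_maes = [
                np.abs(_predict_tree_batch(t, X) - Y).mean() for t in ens.trees
            ]
            stacked = np.stack([_predict_tree_batch(t, X) for t in ens.trees])
            ens_mae = np.abs(stacked.mean(axis=0) - Y).mean()
            assert ens_mae <= max(tree_maes) + 1e-12

    def test_root_splits_recover_effect_bits(self):
        # noise-free screen whose targets depend on 3 bits: roots of a
        # 50-tree ensemble concentrate on those bits
        sc = scenario_paper_like(seed=21, n=200, nbits=512, noise_sd=0.0)
        ts = sc.training_set
        ens = fit_ensemble(ts, TreeParams(n_trees=50, min_leaf=2), seed=99)
        effect_bits = {b for b, _, _ in sc.ground_truth.effect_bits}
        roots = [t.root.bit for t in ens.trees if not isinstance(t.root, Leaf)]
        frac = np.mean([b in effect_bits for b in roots])
        assert frac >= 0.8

    def test_json_round_trip_preserves_predictions(self, small_scenario):
        ts = small_scenario.training_set
        ens = fit_ensemble(ts, TreeParams(n_trees=4, min_leaf=2), seed=1)
        clone = ensemble_from_json(ensemble_to_json(ens))
        for r in ts.records[:10]:
            assert predict_ensemble(clone, r.fingerprint) == predict_ensemble(
                ens, r.fingerprint
            )
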