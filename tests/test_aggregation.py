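"""Combination/global aggregation weights and model averaging."""

import numpy as np
import pytest

import fedlatent as fl
from fedlatent.aggregation import DegenerateGroupError
from fedlatent.divergence_grouping import assign_heads
from fedlatent.fl_core import ModelParameters


def scalar_model(value):
    return ModelParameters(np.array([float(value)]), [("w", (1,))])


def make_stats(signature_factory, groups, triples):
    """triples: {client_id: (n, l, delta)}"""
    sigs = {cid: signature_factory(cid, n=t[0], l=t[1], variance=t[2])
            for cid, t in triples.items()}
    asg = fl.GroupAssignment(groups=groups)
    return asg, fl.compute_group_stats(asg, sigs)


class TestGroupStats:
    def test_totals_are_sums(self, signature_factory):
        asg, stats = make_stats(signature_factory, [[0, 1]],
                                {0: (100, 2, 1.0), 1: (300, 2, 1.0)})
        assert stats.group_totals[0][0] == 400

    def test_global_totals_conserved(self, signature_factory):
        asg, stats = make_stats(signature_factory, [[0], [1]],
                                {0: (10, 1, 2.0), 1: (20, 3, 3.0)})
        assert stats.global_totals == (30.0, 4.0, 5.0)
        assert sum(t[0] for t in stats.group_totals) == stats.global_totals[0]

    def test_missing_signature_raises(self, signature_factory):
        asg = fl.GroupAssignment(groups=[[0, 1]])
        with pytest.raises(KeyError):
            fl.compute_group_stats(asg, {0: signature_factory(0)})


class TestCombinationWeights:
    def test_hand_worked_example(self, signature_factory):
        # a=b=g=1/3: each coefficient is 1/3; weights
        # (0.25+0.5+0.5)/3 and (0.75+0.5+0.5)/3
        asg, stats = make_stats(signature_factory, [[0, 1]],
                                {0: (100, 2, 1.0), 1: (300, 2, 1.0)})
        w = fl.combination_weights([0, 1], stats, fl.AggregationConfig())
        assert w[0] == pytest.approx(0.41667, abs=5e-6)
        assert w[1] == pytest.approx(0.58333, abs=5e-6)

    def test_singleton_group_weight_one(self, signature_factory):
        asg, stats = make_stats(signature_factory, [[0]], {0: (50, 3, 0.7)})
        cfg = fl.AggregationConfig(alpha=0.2, beta=0.3, gamma=0.5)
        w = fl.combination_weights([0], stats, cfg)
        assert w[0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_clients_split_evenly(self, signature_factory):
        asg, stats = make_stats(signature_factory, [[0, 1]],
                                {0: (100, 2, 1.5), 1: (100, 2, 1.5)})
        w = fl.combination_weights([0, 1], stats,
                                   fl.AggregationConfig(alpha=0.5, beta=0.25,
                                                        gamma=0.25))
        assert w[0] == pytest.approx(0.5, abs=1e-12)
        assert w[1] == pytest.approx(0.5, abs=1e-12)

    def test_per_group_override(self, signature_factory):
        asg, stats = make_stats(signature_factory, [[0, 1]],
                                {0: (100, 2, 1.0), 1: (300, 2, 1.0)})
        cfg = fl.AggregationConfig(per_group_overrides={0: (1.0, 0.0, 0.0)})
        w = fl.combination_weights([0, 1], stats, cfg, group_index=0)
        # alpha=1 leaves only the volume term
        assert w[0] == pytest.approx(0.25, abs=1e-12)
        assert w[1] == pytest.approx(0.75, abs=1e-12)

    def test_simplex_violation_rejected(self):
        with pytest.raises(ValueError):
            fl.AggregationConfig(alpha=0.5, beta=0.5, gamma=0.5)


class TestGlobalWeights:
    def test_volume_only(self, signature_factory):
        asg, stats = make_stats(signature_factory, [[0], [1]],
                                {0: (400, 2, 1.0), 1: (600, 2, 1.0)})
        cfg = fl.AggregationConfig(alpha=1.0, beta=0.0, gamma=0.0)
        w = fl.global_weights(stats, cfg)
        np.testing.assert_allclose(w, [0.4, 0.6], atol=1e-12)

    def test_single_group(self, signature_factory):
        asg, stats = make_stats(signature_factory, [[0, 1]],
                                {0: (10, 1, 1.0), 1: (20, 2, 2.0)})
        w = fl.global_weights(stats, fl.AggregationConfig())
        assert w[0] == pytest.approx(1.0, abs=1e-12)

    def test_identical_groups_split_evenly(self, signature_factory):
        asg, stats = make_stats(signature_factory, [[0], [1]],
                                {0: (100, 2, 1.0), 1: (100, 2, 1.0)})
        w = fl.global_weights(stats, fl.AggregationConfig())
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-12)

    def test_zero_variance_total_degenerate(self, signature_factory):
        sigs = {0: signature_factory(0, variance=0.0)}
        asg = fl.GroupAssignment(groups=[[0]])
        stats = fl.compute_group_stats(asg, sigs)
        with pytest.raises(DegenerateGroupError):
            fl.global_weights(stats, fl.AggregationConfig())


def test_weight_conservation_over_random_simplex():
    """500 random (a, b, g) on the simplex and random stats: both weight
    levels sum to 1 and are non-negative."""
    rng = np.random.default_rng(8)
    for _ in range(500):
        a, b, g = rng.dirichlet([1.0, 1.0, 1.0])
        cfg = fl.AggregationConfig(alpha=a, beta=b, gamma=g)
        k = int(rng.integers(2, 6))
        sigs = {
            i: fl.LatentSignature(histogram=np.array([0.5, 0.5]),
                                  variance=float(rng.uniform(0.1, 5.0)),
                                  sample_count=int(rng.integers(10, 1000)),
                                  label_class_count=int(rng.integers(1, 10)),
                                  client_id=i)
            for i in range(k)
        }
        split = int(rng.integers(1, k))
        asg = fl.GroupAssignment(groups=[list(range(split)), list(range(split, k))])
        stats = fl.compute_group_stats(asg, sigs)
        for m, group in enumerate(asg.groups):
            w = np.array(list(fl.combination_weights(group, stats, cfg,
                                                     group_index=m).values()))
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(w >= -1e-12)
        gw = fl.global_weights(stats, cfg)
        assert gw.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(gw >= -1e-12)


class TestAggregateParameters:
    def test_identical_models_fixed_point(self):
        m = scalar_model(3.3)
        out = fl.aggregate_parameters([m, m, m], [0.2, 0.3, 0.5])
        assert out.values[0] == pytest.approx(3.3, abs=1e-15)

    def test_scalar_arithmetic(self):
        out = fl.aggregate_parameters([scalar_model(0), scalar_model(4)],
                                      [0.25, 0.75])
        assert out.values[0] == pytest.approx(3.0, abs=1e-15)

    def test_degenerate_weights_select_one_model(self):
        a, b = scalar_model(1.5), scalar_model(9.0)
        out = fl.aggregate_parameters([a, b], [1.0, 0.0])
        assert out.values[0] == 1.5

    def test_convexity_bound(self):
        rng = np.random.default_rng(9)
        layout = [("w", (20,))]
        models = [ModelParameters(rng.standard_normal(20), layout) for _ in range(4)]
        w = rng.dirichlet(np.ones(4))
        out = fl.aggregate_parameters(models, w)
        stacked = np.stack([m.values for m in models])
        assert np.all(out.values <= stacked.max(axis=0) + 1e-12)
        assert np.all(out.values >= stacked.min(axis=0) - 1e-12)

    def test_layout_mismatch_raises(self):
        a = scalar_model(1.0)
        b = ModelParameters(np.zeros(2), [("v", (2,))])
        with pytest.raises(ValueError):
            fl.aggregate_parameters([a, b], [0.5, 0.5])


class TestProposedAggregation:
    def test_identical_models_fixed_point(self, signature_factory):
        asg, stats = make_stats(signature_factory, [[0, 1], [2]],
                                {0: (10, 1, 1.0), 1: (20, 2, 2.0), 2: (30, 3, 3.0)})
        asg = assign_heads(asg, {i: signature_factory(i, variance=float(i + 1))
                                 for i in range(3)})
        m = scalar_model(2.5)
        out, audit = fl.run_proposed_aggregation({0: m, 1: m, 2: m}, asg, stats,
                                                 fl.AggregationConfig())
        assert out.values[0] == pytest.approx(2.5, abs=1e-12)
        assert len(audit["groups"]) == 2
        assert audit["group_weights"][0] + audit["group_weights"][1] == \
            pytest.approx(1.0, abs=1e-9)

    def test_single_group_alpha_one_equals_fedavg(self, signature_factory):
        rng = np.random.default_rng(10)
        layout = [("w", (8,))]
        counts = [15, 35, 50]
        models = {i: ModelParameters(rng.standard_normal(8), layout)
                  for i in range(3)}
        asg, stats = make_stats(signature_factory, [[0, 1, 2]],
                                {i: (counts[i], 2, 1.0) for i in range(3)})
        cfg = fl.AggregationConfig(alpha=1.0, beta=0.0, gamma=0.0)
        proposed, _ = fl.run_proposed_aggregation(models, asg, stats, cfg)
        baseline = fl.fedavg_aggregate([models[i] for i in range(3)], counts)
        np.testing.assert_allclose(proposed.values, baseline.values, atol=1e-12)

    def test_client_order_invariance(self, signature_factory):
        rng = np.random.default_rng(11)
        layout = [("w", (4,))]
        models = {i: ModelParameters(rng.standard_normal(4), layout)
                  for i in range(4)}
        triples = {0: (10, 1, 1.0), 1: (20, 2, 0.5), 2: (15, 3, 2.0), 3: (25, 1, 1.5)}
        asg1, stats1 = make_stats(signature_factory, [[0, 1], [2, 3]], triples)
        asg2, stats2 = make_stats(signature_factory, [[1, 0], [3, 2]], triples)
        out1, _ = fl.run_proposed_aggregation(models, asg1, stats1,
                                              fl.AggregationConfig())
        out2, _ = fl.run_proposed_aggregation(models, asg2, stats2,
                                              fl.AggregationConfig())
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-12)


class TestFedAvg:
    def test_equal_counts_plain_mean(self):
        out = fl.fedavg_aggregate([scalar_model(1), scalar_model(3)], [10, 10])
        assert out.values[0] == pytest.approx(2.0, abs=1e-15)

    def test_count_weighting(self):
        out = fl.fedavg_aggregate([scalar_model(0), scalar_model(4)], [1, 3])
        assert out.values[0] == pytest.approx(3.0, abs=1e-15)

    def test_single_client(self):
        out = fl.fedavg_aggregate([scalar_model(7)], [5])
        assert out.values[0] == 7.0

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            fl.fedavg_aggregate([scalar_model(1)], [0])
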