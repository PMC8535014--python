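import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adnet.bayeslr import (
    FeatureMatrix,
    LabelVector,
    PriorVector,
    build_features,
    complex_priors,
    decision_scores,
    fit_logistic,
    posterior,
    roc_auc,
    run_integrated,
    sample_labels,
)
from adnet.graphio import ComplexCatalog, DiseaseCatalog, GeneNetwork


def _disease(focal: set[str], others: dict[str, set[str]] | None = None,
             total: int = 100) -> DiseaseCatalog:
    mapping = {"AD": set(focal)}
    mapping.update(others or {})
    return DiseaseCatalog(mapping, "AD", total)


class TestPriors:
    def test_complex_ratio(self):
        # complex {g, a, b}: a focal, b another disease -> A=1, B=2, P=1/2
        cat = ComplexCatalog({"c1": {"g", "a", "b"}})
        dis = _disease({"a"}, {"other": {"b"}})
        pr = complex_priors({"g", "a"}, cat, dis)
        assert pr.priors["g"] == pytest.approx(0.5)
        assert pr.priors["a"] == 1.0 and "a" in pr.known

    def test_fallback_c_over_d(self):
        focal = {f"K{i}" for i in range(859)}
        dis = _disease(focal, total=20000)
        pr = complex_priors({"g"}, ComplexCatalog({"c": {"x", "y"}}), dis)
        assert pr.priors["g"] == pytest.approx(859 / 20000)  # 0.04295

    def test_complex_without_disease_genes_falls_back(self):
        cat = ComplexCatalog({"c1": {"g", "x"}})
        dis = _disease({"a"}, total=50)
        pr = complex_priors({"g"}, cat, dis)
        assert pr.priors["g"] == pytest.approx(1 / 50)

    def test_multi_complex_union_pooling(self):
        cat = ComplexCatalog({"c1": {"g", "a"}, "c2": {"g", "b"}})
        dis = _disease({"a"}, {"other": {"b"}})
        pr = complex_priors({"g"}, cat, dis)
        assert pr.priors["g"] == pytest.approx(0.5)  # pooled union {g,a,b}
        pr_max = complex_priors({"g"}, cat, dis, combine="max")
        assert pr_max.priors["g"] == pytest.approx(1.0)  # best single complex

    def test_prior_bounds_validated(self):
        with pytest.raises(ValueError):
            PriorVector(priors={"g": 1.5}, known=set())


class TestLabels:
    def test_extreme_priors_deterministic(self):
        pr = PriorVector(priors={"a": 1.0, "b": 0.0}, known=set())
        for seed in range(5):
            lab = sample_labels(pr, seed)
            assert lab.labels == {"a": 1, "b": 0}

    def test_known_always_one(self):
        pr = PriorVector(priors={"k": 1.0, "u": 0.2}, known={"k"})
        assert all(sample_labels(pr, s).labels["k"] == 1 for s in range(10))

    def test_binomial_fraction(self):
        pr = PriorVector(priors={f"g{i}": 0.3 for i in range(10000)}, known=set())
        lab = sample_labels(pr, seed=123)
        frac = np.mean(list(lab.labels.values()))
        assert frac == pytest.approx(0.30, abs=0.01)


class TestFeatures:
    def test_isolated_node(self):
        net = GeneNetwork()
        net.add_node("A")
        F = build_features(net, LabelVector(labels={"A": 1}))
        assert list(F.rows[0]) == [1, 0, 0, 0, 0]

    def test_path_counts_distance_two(self):
        net = GeneNetwork.from_edges([("A", "B"), ("B", "C")])
        F = build_features(net, LabelVector(labels={"A": 1, "B": 1, "C": 0}))
        rows = dict(zip(F.genes, F.rows))
        # A: one label-1 direct neighbour (B), one label-0 node at distance 2 (C)
        assert list(rows["A"]) == [1, 1, 0, 0, 1]
        assert list(rows["C"]) == [1, 1, 0, 1, 0]
        assert list(rows["B"]) == [1, 1, 1, 0, 0]

    def test_complete_graph_has_no_second_order(self, triangle):
        F = build_features(triangle, LabelVector(labels={g: 1 for g in "ABC"}))
        assert (F.rows == [1, 2, 0, 0, 0]).all()

    def test_unlabeled_node_errors(self, triangle):
        with pytest.raises(ValueError, match="unlabeled"):
            build_features(triangle, LabelVector(labels={"A": 1}))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_direct_counts_sum_to_degree(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        nodes = [f"N{i}" for i in range(n)]
        net = GeneNetwork()
        for v in nodes:
            net.add_node(v)
        for u, v in itertools.combinations(nodes, 2):
            if rng.random() < 0.3:
                net.add_edge(u, v)
        lab = LabelVector(labels={v: int(rng.random() < 0.5) for v in nodes})
        F = build_features(net, lab)
        for g, row in zip(F.genes, F.rows):
            assert row[1] + row[2] == net.degree(g)


class TestLogisticFit:
    def test_intercept_only_bernoulli_mean(self):
        F = FeatureMatrix(genes=["a", "b"], rows=np.array([[1, 0, 0, 0, 0]] * 2))
        lab = LabelVector(labels={"a": 0, "b": 1})
        w = fit_logistic(F, lab)
        p = posterior(F, w)
        assert p["a"] == pytest.approx(0.5, abs=1e-4)

    def test_degenerate_labels_finite_with_ridge(self):
        F = FeatureMatrix(
            genes=["a", "b", "c"],
            rows=np.column_stack([np.ones(3), np.arange(3), np.zeros(3),
                                  np.zeros(3), np.zeros(3)]),
        )
        lab = LabelVector(labels={"a": 1, "b": 1, "c": 1})
        w = fit_logistic(F, lab, ridge=1e-3)
        assert np.all(np.isfinite(w.w))
        assert min(posterior(F, w).values()) > 0.9

    def test_objective_never_decreases(self):
        rng = np.random.default_rng(5)
        phi = np.column_stack([np.ones(200), rng.poisson(3, (200, 4))])
        x = rng.integers(0, 2, 200)
        F = FeatureMatrix(genes=[f"g{i}" for i in range(200)], rows=phi)
        lab = LabelVector(labels={f"g{i}": int(x[i]) for i in range(200)})
        w = fit_logistic(F, lab)
        diffs = np.diff(w.ll_path)
        assert (diffs >= -1e-9).all()
        assert w.converged

    def test_sigmoid_worked_value(self):
        F = FeatureMatrix(genes=["g"], rows=np.array([[1, 1, 0, 0, 0]]))
        from adnet.bayeslr import WeightVector

        w = WeightVector(w=np.array([1.0, 1, 0, 0, 0]), converged=True, iterations=0)
        assert posterior(F, w)["g"] == pytest.approx(0.8808, abs=1e-4)


class TestDecisionScores:
    def test_distinct_posteriors(self):
        res = decision_scores({"a": 0.9, "b": 0.5, "c": 0.1})
        assert res.scores == {"a": 1.0, "b": pytest.approx(2 / 3),
                              "c": pytest.approx(1 / 3)}
        assert res.n_scored == 3

    def test_all_equal_scores_one(self):
        res = decision_scores({"a": 0.4, "b": 0.4, "c": 0.4})
        assert set(res.scores.values()) == {1.0}

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.integers(1, 999), min_size=1, max_size=30, unique=True))
    def test_invariant_under_monotone_transform(self, ints):
        post = {f"g{i}": v / 1000.0 for i, v in enumerate(ints)}
        base = decision_scores(post).scores
        for transform in (lambda v: 2 * v + 1, np.exp, lambda v: v**3):
            again = decision_scores({g: float(transform(v)) for g, v in post.items()})
            assert again.scores == base


class TestRoc:
    def test_perfect_separation(self):
        scores = {"p1": 0.9, "p2": 0.8, "n1": 0.2, "n2": 0.1}
        curve = roc_auc(scores, {"p1", "p2"}, {"n1", "n2"})
        assert curve.auc == pytest.approx(1.0)
        assert tuple(curve.points[0]) == (0.0, 0.0)
        assert tuple(curve.points[-1]) == (1.0, 1.0)

    def test_constant_scores_give_half(self):
        scores = {g: 0.5 for g in "abcd"}
        assert roc_auc(scores, {"a", "b"}, {"c", "d"}).auc == pytest.approx(0.5)

    def test_pair_counting_worked_example(self):
        scores = {"p1": 0.9, "p2": 0.8, "n1": 0.85, "n2": 0.1}
        assert roc_auc(scores, {"p1", "p2"}, {"n1", "n2"}).auc == pytest.approx(0.75)

    def test_equals_mann_whitney_pair_count(self):
        rng = np.random.default_rng(9)
        pos = {f"p{i}": float(rng.choice([0.1, 0.3, 0.5, 0.7, 0.9]))
               for i in range(15)}
        neg = {f"n{i}": float(rng.choice([0.1, 0.3, 0.5, 0.7]))
               for i in range(20)}
        curve = roc_auc({**pos, **neg}, set(pos), set(neg))
        wins = ties = 0
        for sp in pos.values():
            for sn in neg.values():
                wins += sp > sn
                ties += sp == sn
        expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert curve.auc == pytest.approx(expected, abs=1e-12)

    def test_overlapping_controls_error(self):
        with pytest.raises(ValueError, match="overlap"):
            roc_auc({"a": 1.0, "b": 0.0}, {"a"}, {"a", "b"})

    def test_unscored_control_error(self):
        with pytest.raises(ValueError, match="unscored"):
            roc_auc({"a": 1.0}, {"a"}, {"zz"})


class TestIntegratedRun:
    @pytest.fixture()
    def small_problem(self):
        rng = np.random.default_rng(21)
        block1 = [f"D{i}" for i in range(12)]
        block2 = [f"N{i}" for i in range(12)]
        net = GeneNetwork()
        for group in (block1, block2):
            for u, v in itertools.combinations(group, 2):
                if rng.random() < 0.7:
                    net.add_edge(u, v)
        for u in block1:
            for v in block2:
                if rng.random() < 0.05:
                    net.add_edge(u, v)
        cat = ComplexCatalog({"c1": set(block1[:6]), "c2": set(block2[:4])})
        dis = DiseaseCatalog({"AD": set(block1[:4])}, "AD", 24)
        return net, cat, dis, block1

    def test_seeded_determinism(self, small_problem):
        net, cat, dis, _ = small_problem
        a = run_integrated(net, cat, dis, reps=5, seed=3)
        b = run_integrated(net, cat, dis, reps=5, seed=3)
        assert a.posteriors == b.posteriors and a.scores == b.scores

    def test_single_rep_matches_manual_chain(self, small_problem):
        net, cat, dis, _ = small_problem
        res = run_integrated(net, cat, dis, reps=1, seed=5)
        pr = complex_priors(net.nodes, cat, dis)
        rep_seed = int(np.random.default_rng(5).integers(0, 2**31 - 1, size=1)[0])
        # reproduce the label draw: sorted genes, one uniform each
        rng = np.random.default_rng(rep_seed)
        nodes = sorted(net.nodes)
        u = rng.uniform(size=len(nodes))
        labels = {
            g: 1 if g in pr.known else int(u[i] <= pr.priors[g])
            for i, g in enumerate(nodes)
        }
        lab = LabelVector(labels=labels)
        F = build_features(net, lab)
        w = fit_logistic(F, lab)
        manual = posterior(F, w)
        for g in nodes:
            assert res.posteriors[g] == pytest.approx(manual[g], abs=1e-9)

    def test_mean_posteriors_stabilise_with_reps(self, small_problem):
        # run-to-run spread of the averaged posteriors shrinks ~1/sqrt(reps)
        net, cat, dis, _ = small_problem

        def spread(reps):
            a = run_integrated(net, cat, dis, reps=reps, seed=101)
            b = run_integrated(net, cat, dis, reps=reps, seed=202)
            return float(
                np.mean([abs(a.posteriors[g] - b.posteriors[g]) for g in net.nodes])
            )

        coarse, fine = spread(50), spread(800)
        assert fine < coarse / 2
        assert fine < 0.012

    def test_disease_block_ranks_high(self, small_problem):
        net, cat, dis, block1 = small_problem
        res = run_integrated(net, cat, dis, reps=20, seed=7)
        top12 = sorted(res.scores, key=res.scores.get, reverse=True)[:12]
        assert len(set(top12) & set(block1)) >= 9
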