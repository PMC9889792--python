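"""Shapley engine: enumeration weights, the game-theoretic axioms
(efficiency, symmetry, dummy), kernel-estimator/oracle equivalence, and
the positional summaries built on top."""

import math

import numpy as np
import pytest

from promdds import shapley as sh
from promdds.dds import FeatureMatrix


def linear_model(w):
    w = np.asarray(w, dtype=float)
    return lambda X: np.asarray(X, dtype=float) @ w


class TestWeights:
    @pytest.mark.parametrize(
        "n,s,expected", [(3, 1, 1 / 6), (1, 0, 1.0), (4, 0, 1 / 4), (4, 3, 1 / 4)]
    )
    def test_enumeration_weight_values(self, n, s, expected):
        assert sh.eq2_weight(n, s) == pytest.approx(expected)

    @pytest.mark.parametrize("n", range(1, 11))
    def test_weights_sum_to_one_over_subsets(self, n):
        total = sum(sh.eq2_weight(n, s) * math.comb(n - 1, s) for s in range(n))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sh.eq2_weight(3, 3)

    def test_kernel_weight_value(self):
        assert sh.shapley_kernel_weight(4, 1) == pytest.approx(1 / 4)

    def test_kernel_weight_endpoints_rejected(self):
        with pytest.raises(ValueError):
            sh.shapley_kernel_weight(4, 0)


class TestMaskedModel:
    def test_full_and_empty_coalitions(self):
        f = linear_model([1, 2, 3])
        x, bg = np.array([1.0, 1, 1]), np.array([0.0, 0, 0])
        assert sh.masked_model(f, x, bg, np.ones(3)) == pytest.approx(6.0)
        assert sh.masked_model(f, x, bg, np.zeros(3)) == pytest.approx(0.0)

    def test_masking_identity_when_x_equals_background(self):
        f = linear_model([1, -2, 5])
        x = np.array([2.0, 3.0, -1.0])
        rng = np.random.default_rng(0)
        outs = {sh.masked_model(f, x, x, rng.integers(0, 2, 3)) for _ in range(10)}
        assert len(outs) == 1


class TestExactShapley:
    def test_additive_model_splits_exactly(self):
        f = linear_model([1, 2])
        ex = sh.exact_shapley(f, [1.0, 1.0], [0.0, 0.0])
        assert ex.phi == pytest.approx([1.0, 2.0])
        assert ex.base_value == pytest.approx(0.0)

    def test_symmetry_axiom(self):
        f = lambda X: X[:, 0] + X[:, 1]
        ex = sh.exact_shapley(f, [3.0, 3.0], [0.0, 0.0])
        assert ex.phi[0] == pytest.approx(ex.phi[1])

    def test_dummy_axiom(self):
        f = lambda X: X[:, 0] * 2.0  # feature 1 ignored
        ex = sh.exact_shapley(f, [1.0, 9.0], [0.0, 0.0])
        assert ex.phi[1] == pytest.approx(0.0, abs=1e-12)

    def test_efficiency_on_interaction_model(self):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(6, 2))
        f = lambda X: np.tanh(X @ W[:, 0]) * (X @ W[:, 1])
        ex = sh.exact_shapley(f, rng.normal(size=6), rng.normal(size=6))
        assert ex.efficiency_gap() < 1e-10

    def test_refuses_wide_inputs(self):
        f = linear_model(np.ones(20))
        with pytest.raises(ValueError, match="kernel_shap"):
            sh.exact_shapley(f, np.ones(20), np.zeros(20))


class TestKernelShap:
    @pytest.mark.parametrize("M", [5, 8, 10])
    def test_exhaustive_matches_exact(self, M):
        rng = np.random.default_rng(M)
        W = rng.normal(size=(M, 2))
        f = lambda X: np.sin(X @ W[:, 0]) + 0.2 * (X @ W[:, 1]) ** 2
        x, bg = rng.normal(size=M), rng.normal(size=M)
        exact = sh.exact_shapley(f, x, bg)
        kernel = sh.kernel_shap(f, x, bg, exhaustive=True)
        assert np.abs(exact.phi - kernel.phi).max() < 1e-6

    def test_sampled_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        f = linear_model(rng.normal(size=12))
        x, bg = rng.normal(size=12), rng.normal(size=12)
        a = sh.kernel_shap(f, x, bg, n_coalitions=300, seed=7)
        b = sh.kernel_shap(f, x, bg, n_coalitions=300, seed=7)
        assert np.array_equal(a.phi, b.phi)

    def test_sampled_efficiency_exact_by_constraint(self):
        rng = np.random.default_rng(3)
        f = lambda X: (X**2).sum(axis=1)
        x, bg = rng.normal(size=30), rng.normal(size=30)
        ks = sh.kernel_shap(f, x, bg, n_coalitions=200, seed=1)
        assert ks.efficiency_gap() < 1e-9

    def test_sampled_close_to_exact_on_linear_model(self):
        # additive models are recovered well even from few coalitions
        rng = np.random.default_rng(4)
        w = rng.normal(size=10)
        f = linear_model(w)
        x, bg = rng.normal(size=10), rng.normal(size=10)
        exact = sh.exact_shapley(f, x, bg)
        ks = sh.kernel_shap(f, x, bg, n_coalitions=2000, seed=5)
        assert np.abs(exact.phi - ks.phi).max() < 0.05 * max(1.0, np.abs(exact.phi).max())

    def test_too_few_coalitions_rejected(self):
        f = linear_model(np.ones(10))
        with pytest.raises(ValueError, match="n_coalitions"):
            sh.kernel_shap(f, np.ones(10), np.zeros(10), n_coalitions=5)


class TestExplainSample:
    def _pool(self, n=20, m=6, seed=0):
        rng = np.random.default_rng(seed)
        return FeatureMatrix(
            values=rng.normal(size=(n, m)),
            position_labels=np.arange(1, m + 1),
            ids=tuple(f"i{j}" for j in range(n)),
        )

    def test_full_pool_no_repeats(self):
        pool = self._pool()
        f = linear_model(np.ones(6))
        out = sh.explain_sample(f, pool, np.zeros(6), n_explain=20, n_coalitions=50, seed=0)
        assert sorted(e.instance_id for e in out) == sorted(pool.ids)

    def test_pool_too_small_rejected(self):
        pool = self._pool(n=5)
        with pytest.raises(ValueError, match="pool"):
            sh.explain_sample(linear_model(np.ones(6)), pool, np.zeros(6), n_explain=10)

    def test_same_seed_same_sample(self):
        pool = self._pool(n=30)
        f = linear_model(np.ones(6))
        a = sh.explain_sample(f, pool, np.zeros(6), n_explain=10, n_coalitions=50, seed=3)
        b = sh.explain_sample(f, pool, np.zeros(6), n_explain=10, n_coalitions=50, seed=3)
        assert [e.instance_id for e in a] == [e.instance_id for e in b]
        assert all(np.array_equal(x.phi, y.phi) for x, y in zip(a, b))


class TestSummaries:
    def _expl(self, phi, labels=None, iid="e0"):
        phi = np.asarray(phi, dtype=float)
        return sh.ShapExplanation(
            phi=phi, base_value=0.0, model_output=float(phi.sum()),
            instance_id=iid,
            position_labels=np.asarray(labels) if labels is not None else None,
        )

    def test_single_explanation_importance(self):
        e = self._expl([0.5, -2.0, 0.0], labels=[-3, -2, -1])
        gi = sh.global_importance([e], np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(gi.mean_abs_phi, [0.5, 2.0, 0.0])
        assert gi.ranking()[0] == -2

    def test_all_zero_phi(self):
        es = [self._expl([0, 0, 0], iid=f"e{i}") for i in range(3)]
        gi = sh.global_importance(es, np.zeros((3, 3)))
        assert np.allclose(gi.mean_abs_phi, 0.0)

    def test_topk_orders_by_abs_phi(self):
        e = self._expl([0.1, -0.9, 0.5], labels=[-27, -26, 3])
        top = sh.explain_instance_topk(e, k=3)
        assert top["position"].tolist() == [-26, 3, -27]

    def test_topk_single_nonzero(self):
        e = self._expl([0.0, 0.7, 0.0], labels=[-28, -27, -26])
        assert sh.explain_instance_topk(e, k=1)["position"].tolist() == [-27]

    def test_topk_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            sh.explain_instance_topk(self._expl([1.0, 2.0]), k=3)

    def test_dinucleotide_class_impact_classes(self):
        # sequence ATGC -> dinucs AT (AT-class), TG (mixed), GC (GC-class)
        e = self._expl([1.0, 5.0, -2.0])
        out = sh.dinucleotide_class_impact([e], ["ATGC"])
        d = dict(zip(out["class"], out["mean_phi"]))
        assert d["AT"] == pytest.approx(1.0)
        assert d["GC"] == pytest.approx(-2.0)
        assert d["mixed"] == pytest.approx(5.0)

    def test_dinucleotide_zero_phi(self):
        e = self._expl([0.0, 0.0, 0.0])
        out = sh.dinucleotide_class_impact([e], ["ATGC"])
        assert (out["mean_phi"] == 0).all()

    def test_dinucleotide_count_mismatch_rejected(self):
        e = self._expl([1.0, 2.0, 3.0])
        with pytest.raises(Exception):
            sh.dinucleotide_class_impact([e, e], ["ATGC"])
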