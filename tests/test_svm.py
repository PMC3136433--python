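"""PUK kernel and the SMO-solved SVM against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize

import cppscreen as cs
from cppscreen.errors import DegenerateLabels, DimensionError, EmptySubset
from cppscreen.svm import KernelParams, PukSvm, PukSvmResults, SVMConfig


def brute_force_dual(K, y, C):
    """Dense QP oracle: maximize sum(a) - 0.5 aᵀ(yyᵀ∘K)a on the box with
    the equality constraint, via SLSQP from several starts."""
    n = len(y)
    Q = np.outer(y, y) * K

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def neg_grad(a):
        return -(np.ones(n) - Q @ a)

    best = None
    for x0 in (np.zeros(n), np.full(n, C / 2), np.full(n, C * 0.9)):
        r = minimize(neg_obj, x0, jac=neg_grad, method="SLSQP",
                     bounds=[(0, C)] * n,
                     constraints={"type": "eq", "fun": lambda a: a @ y,
                                  "jac": lambda a: y.astype(float)},
                     options={"maxiter": 500, "ftol": 1e-14})
        if best is None or r.fun < best:
            best = r.fun
    return -best


class TestPukKernel:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=8)
            assert cs.puk_kernel(x, x, KernelParams()) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 6))
        p = KernelParams(omega=2.0, sigma=0.7)
        assert cs.puk_kernel(x, y, p) == pytest.approx(cs.puk_kernel(y, x, p))

    def test_closed_form_half_distance(self):
        # omega=1, sigma=1, ||x-y||=0.5: sqrt(2^1 - 1)=1, K=1/(1+1)=0.5
        x = np.array([0.0])
        y = np.array([0.5])
        assert cs.puk_kernel(x, y, KernelParams(1.0, 1.0)) == pytest.approx(0.5)

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionError):
            cs.puk_kernel(np.zeros(3), np.zeros(4), KernelParams())

    def test_gram_matches_pairwise_kernel(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 4))
        p = KernelParams(omega=3.0, sigma=0.5)
        G = cs.puk_gram(X, X, p)
        for i in range(6):
            for j in range(6):
                assert G[i, j] == pytest.approx(
                    cs.puk_kernel(X[i], X[j], p), abs=1e-12)

    @pytest.mark.parametrize("omega", [0.5, 1.0, 2.5])
    def test_gram_positive_semidefinite(self, omega):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(25, 10))
        G = cs.puk_gram(X, X, KernelParams(omega=omega, sigma=0.8))
        eig = np.linalg.eigvalsh((G + G.T) / 2)
        assert eig.min() >= -1e-8

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(omega=0.0)
        with pytest.raises(ValueError):
            KernelParams(sigma=-1.0)


class TestTraining:
    def test_separable_pair(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([-1, 1])
        res = PukSvm(X, y, normalize=False).fit()
        labels, _ = res.predict(X)
        assert labels.tolist() == [-1, 1]
        assert res.dual_coef.sum() == pytest.approx(0.0, abs=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabels):
            PukSvm(np.eye(3), np.array([1, 1, 1]))

    def test_empty_subset_rejected(self, cpp111, noncpp34):
        ds = cs.build_dataset(cs.Strategy.UNBALANCED, cpp111, noncpp34, seed=0)
        with pytest.raises(EmptySubset):
            PukSvm.from_dataset(ds, subset=[])
        with pytest.raises(EmptySubset):
            PukSvm.from_dataset(ds, subset=["no_such_feature"])

    @pytest.mark.parametrize("rep", range(20))
    def test_objective_matches_brute_force_qp(self, rep):
        """SMO dual objective equals a dense SLSQP solution on 6-point
        problems (1e-6 relative)."""
        rng = np.random.default_rng(100 + rep)
        X = rng.normal(size=(6, 3))
        y = np.array([1, 1, 1, -1, -1, -1])
        rng.shuffle(y)
        C = float(rng.choice([0.5, 1.0, 2.0]))
        cfg = SVMConfig(C=C, kkt_tolerance=1e-8)
        res = PukSvm(X, y, config=cfg, normalize=False).fit()
        K = cs.puk_gram(X, X, res.kernel)
        oracle = brute_force_dual(K, y, C)
        assert res.dual_objective() == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_duplicating_rows_leaves_decision_unchanged(self):
        # separable clusters with generous C: no alpha at the box bound,
        # so the duplicated problem has the same margin solution
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0.0, 0.1, size=(6, 3)),
                       rng.normal(1.5, 0.1, size=(6, 3))])
        y = np.array([-1] * 6 + [1] * 6)
        cfg = SVMConfig(C=10.0, kkt_tolerance=1e-6)
        base = PukSvm(X, y, config=cfg, normalize=False).fit()
        doubled = PukSvm(np.vstack([X, X]), np.concatenate([y, y]),
                         config=cfg, normalize=False).fit()
        assert base.alphas.max() < cfg.C - 1e-3
        probe = rng.uniform(-0.5, 2.0, size=(20, 3))
        f1 = base.decision_function(probe)
        f2 = doubled.decision_function(probe)
        assert np.allclose(f1, f2, atol=1e-4)

    def test_label_flip_negates_decision(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(size=(14, 5))
        y = np.where(rng.random(14) < 0.5, 1, -1)
        y[:2] = [1, -1]  # ensure both classes
        a = PukSvm(X, y, normalize=False).fit()
        b = PukSvm(X, -y, normalize=False).fit()
        probe = rng.uniform(size=(10, 5))
        assert np.allclose(a.decision_function(probe),
                           -b.decision_function(probe), atol=1e-6)

    def test_kkt_conditions_hold(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(size=(30, 4))
        y = np.where(X[:, 0] + 0.2 * rng.normal(size=30) > 0.5, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        model = PukSvm(X, y, normalize=False,
                       config=SVMConfig(kkt_tolerance=1e-3))
        res = model.fit()
        assert res.kkt_violation() <= 1e-3


class TestPredictionAndSerialization:
    def test_training_margin_on_separable_toy(self, charge_toy_dataset):
        X, y, _ = charge_toy_dataset
        res = PukSvm(X, y).fit()
        labels, f = res.predict(X)
        assert (labels == y).all()
        assert np.all(y * f > 0)

    def test_charge_ranking_on_toy_model(self, charge_toy_dataset):
        X, y, _ = charge_toy_dataset
        subset = ["net_charge", "positive_charge", "negative_charge"]
        res = PukSvm(X[subset], y).fit()
        strong = cs.parse_peptide("RRRRRRRRR", "r9")
        neutral = cs.parse_peptide("GGGGGGGGG", "g9")
        _, scores = res.predict_peptides([strong, neutral])
        assert scores[0] > scores[1]

    def test_serialization_round_trip(self, charge_toy_dataset, tmp_path):
        X, y, _ = charge_toy_dataset
        res = PukSvm(X, y).fit()
        path = tmp_path / "model.json"
        res.save(path)
        loaded = PukSvmResults.load(path)
        probe = X.to_numpy() + 0.1
        assert np.array_equal(res.decision_function(X),
                              loaded.decision_function(X.to_numpy()))
        assert np.array_equal(res.decision_function(probe),
                              loaded.decision_function(probe))

    def test_dimension_mismatch_on_predict(self, charge_toy_dataset):
        X, y, _ = charge_toy_dataset
        res = PukSvm(X, y).fit()
        with pytest.raises(DimensionError):
            res.decision_function(np.zeros((2, 3)))
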