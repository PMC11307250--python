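import dataclasses

import numpy as np
import pytest

import sfc_qsrr as sq
from sfc_qsrr.ann import (
    AnnConfig,
    TrainedModel,
    TrainingDivergedError,
    WeightVector,
    _sigmoid,
    extract_weights,
    gradients,
    predict,
    train,
)
from sfc_qsrr.workflow import CONVERGED_ANN, normalized_targets


def random_instance(rng, n=12, p=5):
    X = rng.uniform(-1, 1, (n, p))
    y = rng.uniform(0.05, 0.95, n)
    return X, y


class TestGradients:
    @pytest.mark.parametrize("arch", ["direct", "hidden"])
    def test_analytic_matches_central_differences(self, arch):
        rng = np.random.default_rng(42)
        for _ in range(5):
            X, y = random_instance(rng)
            if arch == "direct":
                params = {"w": rng.normal(0, 1, 5), "b": np.array(rng.normal())}
            else:
                params = {
                    "W1": rng.normal(0, 1, (5, 3)),
                    "b1": rng.normal(0, 1, 3),
                    "w2": rng.normal(0, 1, 3),
                    "b2": np.array(rng.normal()),
                }
            grads = gradients(params, arch, X, y)
            eps = 1e-6

            def loss(p):
                from sfc_qsrr.ann import _forward

                yhat, _ = _forward(p, arch, X)
                return float(np.mean((yhat - y) ** 2))

            for key, g in grads.items():
                g = np.atleast_1d(np.asarray(g, dtype=float))
                flat = np.atleast_1d(params[key]).astype(float)
                for idx in np.ndindex(*np.atleast_1d(params[key]).shape):
                    pp = {k: np.array(v, dtype=float) for k, v in params.items()}
                    pm = {k: np.array(v, dtype=float) for k, v in params.items()}
                    pp[key] = np.atleast_1d(pp[key])
                    pm[key] = np.atleast_1d(pm[key])
                    pp[key][idx] += eps
                    pm[key][idx] -= eps
                    pp[key] = pp[key].reshape(np.shape(params[key]))
                    pm[key] = pm[key].reshape(np.shape(params[key]))
                    fd = (loss(pp) - loss(pm)) / (2 * eps)
                    ga = np.asarray(g).reshape(np.atleast_1d(params[key]).shape)[idx]
                    # floor guards against central-difference roundoff on
                    # near-zero gradients (absolute agreement is ~1e-11 there)
                    denom = max(abs(fd), abs(ga), 1e-5)
                    assert abs(fd - ga) / denom < 1e-5


class TestTrain:
    def test_constant_target_learns_bias_only(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (30, 4))
        y = np.full(30, 0.5)
        model = train(X, y, AnnConfig(learning_rate=1.0, epochs=5000, init_scale=0.01))
        pred = predict(model, X)
        np.testing.assert_allclose(pred, 0.5, atol=1e-3)
        np.testing.assert_allclose(model.weights["w"], 0.0, atol=1e-3)

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(1)
        X, y = random_instance(rng, n=20, p=6)
        cfg = AnnConfig(seed=5)
        m1, m2 = train(X, y, cfg), train(X, y, cfg)
        np.testing.assert_array_equal(m1.weights["w"], m2.weights["w"])
        np.testing.assert_array_equal(m1.loss_trace, m2.loss_trace)

    def test_loss_trace_monotone_contract(self):
        rng = np.random.default_rng(2)
        X, y = random_instance(rng, n=25, p=4)
        model = train(X, y, AnnConfig(epochs=200))
        assert len(model.loss_trace) == 200
        assert not model.non_convergence

    def test_divergence_names_learning_rate(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, (10, 3))
        y = rng.uniform(0, 1, 10)
        with pytest.raises(TrainingDivergedError, match="learning_rate"):
            train(X, y, AnnConfig(learning_rate=float("inf"), epochs=200))

    def test_unnormalized_table_rejected(self, small_study):
        desc, _, _ = small_study
        with pytest.raises(ValueError, match="normalized"):
            train(desc, np.zeros(desc.shape[0]))

    def test_recovers_planted_weights_against_irls_oracle(self):
        """On noiseless data from the model's own link (n > p), gradient
        descent and a logistic-regression GLM fit by IRLS find the same
        weights, which match the planted ones."""
        import statsmodels.api as sm

        cfg = sq.SyntheticConfig(
            n_compounds=80,
            n_descriptors=15,
            n_informative=4,
            n_distinctive=8,
            n_null_groups=3,
            conditions=(("silica", "MeOH"),),
            elution_prob=1.0,
            noise_sd=0.0,
            seed=21,
        )
        desc, ret, truth = sq.generate_study(cfg)
        Xn = sq.normalize_by_max(desc).values
        sub = ret.select("silica", "MeOH", time_point="0M").set_index("compound_id")
        kp = sub.loc[list(truth.compound_ids), "k_prime"].to_numpy()
        y = kp / cfg.k_max  # exactly sigmoid(Xn @ w + b)
        model = train(
            Xn, y, dataclasses.replace(CONVERGED_ANN, epochs=50000, seed=1)
        )
        glm = sm.GLM(y, sm.add_constant(Xn), family=sm.families.Binomial()).fit()
        oracle_w = glm.params[1:]
        w_true = truth.baseline_weights[("silica", "MeOH")]
        assert np.corrcoef(model.weights["w"], oracle_w)[0, 1] >= 0.99
        assert np.corrcoef(model.weights["w"], w_true)[0, 1] >= 0.99

    def test_descriptor_scaling_absorbed_by_normalization(self, small_study):
        desc, ret, _ = small_study
        sub = ret.select("silica", "MeOH", time_point="0M", eluted_only=True)
        y = normalized_targets(sub["k_prime"].to_numpy(float))
        cfg = AnnConfig(epochs=300, seed=4)
        m1 = train(sq.normalize_by_max(desc).subset(sub["compound_id"]), y, cfg)
        scaled = sq.DescriptorTable(desc.data * 7.0)
        m2 = train(sq.normalize_by_max(scaled).subset(sub["compound_id"]), y, cfg)
        np.testing.assert_allclose(m1.weights["w"], m2.weights["w"], rtol=1e-10)


class TestPredict:
    def test_zero_weight_model_outputs_logistic_bias(self):
        model = TrainedModel(
            config=AnnConfig(),
            descriptor_names=("a", "b"),
            weights={"w": np.zeros(2), "b": np.array(0.7)},
            loss_trace=np.zeros(1),
        )
        X = np.random.default_rng(0).uniform(-1, 1, (6, 2))
        np.testing.assert_allclose(predict(model, X), _sigmoid(np.array(0.7)))

    def test_converged_noiseless_fit_mse(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, (40, 5))
        w = np.array([2.0, -1.0, 0.0, 0.5, 1.5])
        y = _sigmoid(X @ w + 0.3)
        model = train(X, y, AnnConfig(learning_rate=2.0, epochs=20000, init_scale=0.01))
        mse = float(np.mean((predict(model, X) - y) ** 2))
        assert mse < 1e-4

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        X, y = random_instance(rng, n=15, p=4)
        model = train(X, y, AnnConfig(epochs=100))
        perm = rng.permutation(15)
        np.testing.assert_allclose(predict(model, X[perm]), predict(model, X)[perm])

    def test_missing_descriptor_named(self, small_study):
        desc, ret, _ = small_study
        dn = sq.normalize_by_max(desc)
        sub = ret.select("silica", "MeOH", time_point="0M", eluted_only=True)
        y = normalized_targets(sub["k_prime"].to_numpy(float))
        model = train(dn, y, AnnConfig(epochs=10))
        crippled = sq.DescriptorTable(dn.data.drop(columns=["nAcid"]), normalized=True)
        with pytest.raises(ValueError, match="nAcid"):
            predict(model, crippled)


class TestExtractWeights:
    def test_direct_identity(self):
        model = TrainedModel(
            config=AnnConfig(),
            descriptor_names=("a", "b"),
            weights={"w": np.array([1.2, -0.3]), "b": np.array(0.0)},
            loss_trace=np.zeros(1),
        )
        np.testing.assert_array_equal(extract_weights(model).weights, [1.2, -0.3])

    def test_hidden_connection_weights_formula(self):
        model = TrainedModel(
            config=AnnConfig(architecture="hidden", hidden_size=1),
            descriptor_names=("a", "b"),
            weights={
                "W1": np.array([[2.0], [-1.0]]),
                "b1": np.zeros(1),
                "w2": np.array([0.5]),
                "b2": np.array(0.0),
            },
            loss_trace=np.zeros(1),
        )
        np.testing.assert_allclose(extract_weights(model).weights, [1.0, -0.5])

    def test_hidden_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        p, h = 6, 4
        W1, w2 = rng.normal(0, 1, (p, h)), rng.normal(0, 1, h)
        model = TrainedModel(
            config=AnnConfig(architecture="hidden", hidden_size=h),
            descriptor_names=tuple(f"d{i}" for i in range(p)),
            weights={"W1": W1, "b1": np.zeros(h), "w2": w2, "b2": np.array(0.0)},
            loss_trace=np.zeros(1),
        )
        scores = extract_weights(model).weights
        brute = np.array(
            [sum(W1[i, j] * w2[j] for j in range(h)) for i in range(p)]
        )
        np.testing.assert_allclose(scores, brute, rtol=1e-12)


def test_model_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    X, y = random_instance(rng, n=10, p=3)
    model = train(X, y, AnnConfig(epochs=20), condition=("silica", "MeOH", "0M"))
    p = tmp_path / "m.json"
    model.save(p)
    back = TrainedModel.load(p)
    np.testing.assert_array_equal(back.weights["w"], model.weights["w"])
    assert back.condition == ("silica", "MeOH", "0M")
    assert back.config == model.config
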