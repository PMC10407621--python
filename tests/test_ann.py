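import numpy as np
import pandas as pd
import pytest

from roqsar import ann
from roqsar.ann import AnnWeights, ScalerParams, TrainConfig
from roqsar.dataset import QsarDataset
from roqsar.exceptions import ScalingError, TrainingError


class TestScaler:
    def test_endpoints(self):
        params = ScalerParams.fit(np.array([[2.0], [10.0]]))
        assert ann.scale(np.array([[2.0]]), params)[0, 0] == -1.0
        assert ann.scale(np.array([[10.0]]), params)[0, 0] == 1.0

    def test_midpoint(self):
        params = ScalerParams.fit(np.array([[2.0], [10.0]]))
        assert ann.scale(np.array([[6.0]]), params)[0, 0] == 0.0

    def test_round_trip(self, rng):
        data = rng.standard_normal((100, 3)) * 10
        params = ScalerParams.fit(data)
        back = ann.unscale(ann.scale(data, params), params)
        assert np.abs(back - data).max() < 1e-12

    def test_degenerate_variable(self):
        with pytest.raises(ScalingError, match="degenerate"):
            ScalerParams.fit(np.array([[1.0, 2.0], [1.0, 3.0]]))

    def test_bad_target_range(self):
        with pytest.raises(ScalingError):
            ScalerParams.fit(np.array([[0.0], [1.0]]), r_min=1.0, r_max=-1.0)


class TestForward:
    def test_zero_weights(self):
        w = AnnWeights(W=np.zeros((4, 4)), b_hidden=np.zeros(4),
                       v=np.zeros(4), b_out=0.0)
        out = ann.forward(w, np.zeros((1, 4)))
        assert out[0] == 0.0
        hidden = ann.logsig(np.zeros(4))
        np.testing.assert_allclose(hidden, 0.5)

    def test_single_hidden_unit(self):
        w = AnnWeights(W=np.array([[1.0]]), b_hidden=np.zeros(1),
                       v=np.array([2.0]), b_out=0.0)
        assert ann.forward(w, np.array([[0.0]]))[0] == pytest.approx(1.0)

    def test_hand_computed_221(self):
        # 2-2-1 network with weights +-1: independent closed-form evaluation
        w = AnnWeights(W=np.array([[1.0, -1.0], [1.0, 1.0]]),
                       b_hidden=np.array([1.0, -1.0]),
                       v=np.array([1.0, -1.0]), b_out=0.5)
        x = np.array([0.3, -0.7])
        h1 = 1 / (1 + np.exp(-(0.3 + -0.7 + 1.0)))
        h2 = 1 / (1 + np.exp(-(-0.3 + -0.7 - 1.0)))
        expected = h1 - h2 + 0.5
        assert ann.forward(w, x[None, :])[0] == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonfinite(self):
        w = AnnWeights(W=np.zeros((2, 2)), b_hidden=np.zeros(2),
                       v=np.zeros(2), b_out=0.0)
        with pytest.raises(TrainingError):
            ann.forward(w, np.array([[np.nan, 0.0]]))


class TestTrainConfig:
    def test_eta_bound(self):
        with pytest.raises(TrainingError, match="eta"):
            TrainConfig(eta=0.5)

    def test_unknown_algorithm(self):
        with pytest.raises(TrainingError):
            TrainConfig(algorithm="adam")


def _network_dataset(n=200, seed=3, noise=0.0):
    """Response generated by a known 4-4-1 network."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 4))
    truth = AnnWeights(W=rng.uniform(-2, 2, (4, 4)),
                       b_hidden=rng.uniform(-1, 1, 4),
                       v=rng.uniform(-3, 3, 4), b_out=0.2)
    y = ann.forward(truth, X) * 20 + 50 + noise * rng.standard_normal(n)
    splits = np.array(["training"] * (n - 2 * (n // 7))
                      + ["test"] * (n // 7) + ["validation"] * (n // 7))
    idx = [f"s{i}" for i in range(n)]
    return QsarDataset(pd.DataFrame(X, columns=list("wxyz"), index=idx),
                       pd.Series(y, index=idx),
                       pd.Series(splits[rng.permutation(n)], index=idx))


class TestTrainLM:
    def test_noiseless_network_recovery(self):
        data = _network_dataset(n=200, seed=3, noise=0.0)
        result = ann.train(data, TrainConfig(seed=1))
        test = data.subset("test")
        pred = ann.predict(result, test.X.to_numpy())
        ss_res = ((test.y.to_numpy() - pred) ** 2).sum()
        ss_tot = ((test.y - test.y.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot >= 0.99
        assert result.epochs_run <= 1000

    def test_linear_response_subsumed(self):
        rng = np.random.default_rng(1)
        n = 150
        X = rng.standard_normal((n, 4))
        y = X[:, 0] * 10 + 50
        idx = [f"s{i}" for i in range(n)]
        splits = pd.Series(["training"] * 110 + ["test"] * 20 + ["validation"] * 20,
                           index=idx)
        data = QsarDataset(pd.DataFrame(X, columns=list("abcd"), index=idx),
                           pd.Series(y, index=idx), splits)
        result = ann.train(data, TrainConfig(seed=1))
        pred = ann.predict(result, X)
        ss_res = ((y - pred) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot >= 0.999

    def test_pure_noise_stops_by_validation(self):
        stopped_early = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 80
            X = rng.standard_normal((n, 4))
            y = rng.standard_normal(n)
            idx = [f"s{i}" for i in range(n)]
            splits = pd.Series(["training"] * 56 + ["test"] * 12
                               + ["validation"] * 12, index=idx)
            data = QsarDataset(pd.DataFrame(X, columns=list("abcd"), index=idx),
                               pd.Series(y, index=idx), splits)
            result = ann.train(data, TrainConfig(seed=seed, max_epochs=400))
            stopped_early += result.stop_reason != "max_epochs"
        assert stopped_early >= 16

    def test_training_mse_nonincreasing_on_accepted_steps(self):
        data = _network_dataset(n=120, seed=5, noise=1.0)
        result = ann.train(data, TrainConfig(seed=2, max_epochs=60))
        mse = result.history["train_mse"].to_numpy()
        assert np.all(np.diff(mse) <= 1e-12)

    def test_seeded_determinism(self):
        data = _network_dataset(n=100, seed=4, noise=1.0)
        r1 = ann.train(data, TrainConfig(seed=9, max_epochs=50))
        r2 = ann.train(data, TrainConfig(seed=9, max_epochs=50))
        pd.testing.assert_frame_equal(r1.history, r2.history)
        np.testing.assert_array_equal(r1.weights.flatten(), r2.weights.flatten())

    def test_missing_split_raises(self):
        data = _network_dataset(n=60, seed=2)
        no_val = QsarDataset(data.X, data.y,
                             data.splits.replace("validation", "training"))
        with pytest.raises(TrainingError, match="validation"):
            ann.train(no_val, TrainConfig(seed=1))

    def test_stop_reason_consistent(self):
        data = _network_dataset(n=100, seed=6, noise=2.0)
        result = ann.train(data, TrainConfig(seed=3, max_epochs=5))
        assert result.stop_reason in ("max_epochs", "validation", "gradient", "mu")
        if result.stop_reason == "max_epochs":
            assert result.epochs_run == 5


class TestTrainGradient:
    def test_single_sample_update_matches_delta_rule(self):
        # output-layer change of one gradient step must equal
        # eta * (t - o) * input for every output-layer connection
        cfg = TrainConfig(algorithm="gradient", eta=0.05, max_epochs=1, seed=11)
        w0 = ann._init_weights(cfg)
        x = np.array([0.4, -0.2, 0.1, 0.8])
        target = 0.7
        hidden = ann.logsig(x @ w0.W + w0.b_hidden)
        out = float(hidden @ w0.v + w0.b_out)
        w1 = ann.gradient_step(w0, x, target, eta=0.05)
        np.testing.assert_allclose(w1.v - w0.v, 0.05 * (target - out) * hidden,
                                   atol=1e-12)
        assert w1.b_out - w0.b_out == pytest.approx(0.05 * (target - out),
                                                    abs=1e-12)

    def test_step_descends_squared_error(self, rng):
        # finite-difference oracle: the update is -eta * dE/dtheta
        w0 = AnnWeights(W=rng.standard_normal((4, 4)),
                        b_hidden=rng.standard_normal(4),
                        v=rng.standard_normal(4), b_out=0.1)
        x = rng.standard_normal(4)
        target = 0.3
        w1 = ann.gradient_step(w0, x, target, eta=0.05)
        eps = 1e-6
        theta0, theta1 = w0.flatten(), w1.flatten()
        for j in range(theta0.size):
            tp = theta0.copy()
            tp[j] += eps
            wp = AnnWeights.from_flat(tp, 4, 4)
            loss0 = 0.5 * (target - ann.forward(w0, x[None, :])[0]) ** 2
            loss_p = 0.5 * (target - ann.forward(wp, x[None, :])[0]) ** 2
            grad_fd = (loss_p - loss0) / eps
            assert theta1[j] - theta0[j] == pytest.approx(-0.05 * grad_fd,
                                                          abs=1e-5)

    def test_gradient_mode_trains(self):
        data = _network_dataset(n=120, seed=8, noise=1.0)
        result = ann.train(data, TrainConfig(algorithm="gradient", eta=0.05,
                                             seed=1, max_epochs=200))
        pred = ann.predict(result, data.X.to_numpy())
        y = data.y.to_numpy()
        r2 = 1 - ((y - pred) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 > 0.5


TABLE_W_ROWS = np.array([
    [-1.0877, 1.3881, 0.0052, 0.9426],
    [1.8117, -1.3380, -1.8139, -2.1147],
    [3.6353, -0.7606, -1.5711, 3.9892],
    [2.2321, -2.9344, 2.5124, 3.6544],
])
TABLE_V = np.array([0.7219, -0.2206, 0.1505, 0.5867])


def _garson_oracle(W, v):
    """Naive loop implementation of the weight-partitioning importance."""
    n_in, n_hidden = W.shape
    q = np.zeros(n_in)
    for t in range(n_in):
        for n in range(n_hidden):
            denom = sum(abs(W[k, n]) for k in range(n_in))
            if denom > 0:
                q[t] += abs(W[t, n]) / denom * abs(v[n])
    return 100 * q / q.sum()


class TestGarson:
    def test_symmetric_two_inputs(self):
        w = AnnWeights(W=np.ones((2, 3)), b_hidden=np.zeros(3),
                       v=np.ones(3), b_out=0.0)
        np.testing.assert_allclose(ann.garson_importance(w), [50.0, 50.0])

    def test_dead_input_zero_share(self):
        W = np.ones((3, 2))
        W[2, :] = 0.0
        w = AnnWeights(W=W, b_hidden=np.zeros(2), v=np.ones(2), b_out=0.0)
        imp = ann.garson_importance(w)
        assert imp[2] == 0.0
        assert imp.sum() == pytest.approx(100.0)

    def test_matches_oracle_on_random_weights(self, rng):
        for _ in range(25):
            W = rng.standard_normal((4, 4))
            v = rng.standard_normal(4)
            w = AnnWeights(W=W, b_hidden=rng.standard_normal(4),
                           v=v, b_out=0.0)
            np.testing.assert_allclose(ann.garson_importance(w),
                                       _garson_oracle(W, v), atol=1e-10)

    def test_published_weights_max_share(self):
        w = AnnWeights(W=TABLE_W_ROWS.T, b_hidden=np.zeros(4),
                       v=TABLE_V, b_out=0.0)
        imp = ann.garson_importance(w)
        assert imp.sum() == pytest.approx(100.0, abs=1e-9)
        # inputs ordered (SIC1, R2e, EEig03d, ESpm14u): max share on ESpm14u
        assert imp.argmax() == 3
        # full published ordering: ESpm14u > R2e > SIC1 > EEig03d
        assert list(np.argsort(-imp)) == [3, 1, 0, 2]

    def test_invariant_to_v_rescaling_and_hidden_permutation(self, rng):
        W = rng.standard_normal((4, 4))
        v = rng.standard_normal(4)
        base = ann.garson_importance(
            AnnWeights(W=W, b_hidden=np.zeros(4), v=v, b_out=0.0))
        scaled = ann.garson_importance(
            AnnWeights(W=W, b_hidden=np.zeros(4), v=3.7 * v, b_out=0.0))
        np.testing.assert_allclose(scaled, base, atol=1e-10)
        perm = rng.permutation(4)
        permuted = ann.garson_importance(
            AnnWeights(W=W[:, perm], b_hidden=np.zeros(4), v=v[perm], b_out=0.0))
        np.testing.assert_allclose(permuted, base, atol=1e-10)


class TestEffectiveWeightTable:
    def test_structure(self):
        w = AnnWeights(W=TABLE_W_ROWS.T, b_hidden=np.zeros(4),
                       v=TABLE_V, b_out=0.0)
        table = ann.effective_weight_table(
            w, ["SIC1", "R2e", "EEig03d", "ESpm14u"])
        assert list(table.index) == ["H1", "H2", "H3", "H4",
                                     "Relative importance (%)"]
        assert list(table.columns) == ["SIC1", "R2e", "EEig03d", "ESpm14u",
                                       "hidden_to_out"]
        assert table.iloc[:4, :4].to_numpy() == pytest.approx(TABLE_W_ROWS)
        assert table.loc["Relative importance (%)"][:4].sum() == \
            pytest.approx(100.0)

    def test_echoes_input_weights(self):
        w = AnnWeights(W=TABLE_W_ROWS.T, b_hidden=np.zeros(4),
                       v=TABLE_V, b_out=0.0)
        table = ann.effective_weight_table(w)
        np.testing.assert_allclose(table.iloc[:4, -1], TABLE_V)

    def test_csv_round_trip(self, tmp_path):
        w = AnnWeights(W=TABLE_W_ROWS.T, b_hidden=np.zeros(4),
                       v=TABLE_V, b_out=0.0)
        table = ann.effective_weight_table(w)
        path = tmp_path / "ew.csv"
        table.to_csv(path, float_format="%.17g")
        back = pd.read_csv(path, index_col=0)
        np.testing.assert_allclose(back.iloc[:4].to_numpy(),
                                   table.iloc[:4].to_numpy())


class TestResultIO:
    def test_round_trip(self, small_dataset, tmp_path):
        result = ann.train(small_dataset, TrainConfig(seed=1, max_epochs=30))
        path = tmp_path / "model.json"
        ann.save_result(result, path)
        back = ann.load_result(path)
        np.testing.assert_array_equal(back.weights.flatten(),
                                      result.weights.flatten())
        X = small_dataset.X.to_numpy()
        np.testing.assert_allclose(ann.predict(back, X),
                                   ann.predict(result, X), atol=1e-12)
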