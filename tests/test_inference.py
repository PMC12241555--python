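import numpy as np
import pytest
from scipy import stats

from demosmc.demography import PriorBox
from demosmc.inference import (
    NetSpec,
    ReferenceTable,
    abc_model_choice,
    abc_parameters,
    bayes_factor,
    goodness_of_fit,
    train_network,
)
from demosmc.nn import MLP


@pytest.fixture(scope="module")
def separable_classifier():
    """Two-model toy with disjoint constant features."""
    rng = np.random.default_rng(0)
    n = 400
    x = np.vstack([np.full((n // 2, 6), 1.0), np.full((n // 2, 6), 9.0)])
    x += rng.normal(0, 0.01, x.shape)
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    order = rng.permutation(n)
    x, y = x[order], y[order]
    table = ReferenceTable(x, y, n_train=300, model_ids=("A", "B"))
    predictor = train_network(
        table, NetSpec(max_epochs=30, early_stop_patience=10), seed=1)
    return table, predictor


class TestNetSpec:
    def test_published_defaults(self):
        spec = NetSpec()
        assert spec.hidden == (256, 128, 64, 32)
        assert spec.dropout == 0.01
        assert spec.noise_sd == 0.05
        assert spec.learning_rate == 1e-3
        assert spec.lr_patience == 10
        assert spec.early_stop_patience == 100
        assert spec.batch_size == 32


class TestTrainNetwork:
    def test_softmax_sums_to_one(self, separable_classifier):
        _, predictor = separable_classifier
        rng = np.random.default_rng(5)
        probs = predictor.predict(rng.uniform(0, 10, (7, 6)))
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_separable_toy_accuracy(self, separable_classifier):
        table, predictor = separable_classifier
        x_val, y_val = table.validation_split()
        acc = (predictor.predict(x_val).argmax(axis=1) == y_val).mean()
        assert acc > 0.99

    def test_head_sizes(self):
        clf = MLP(999, 5, head="softmax")
        assert clf.weights[-1].shape[1] == 5
        reg = MLP(999, 24, head="linear")
        assert reg.weights[-1].shape[1] == 24

    def test_nonfinite_rejected(self):
        x = np.ones((20, 3))
        x[0, 0] = np.nan
        table = ReferenceTable(x, np.zeros(20, dtype=int), n_train=10,
                               model_ids=("A",))
        with pytest.raises(ValueError):
            train_network(table, NetSpec(max_epochs=2), seed=0)

    def test_training_log_records_best_epoch(self, separable_classifier):
        _, predictor = separable_classifier
        log = predictor.log
        assert 0 <= log.best_epoch < len(log.val_loss)
        assert log.best_val_loss == min(log.val_loss)

    def test_save_load_round_trip(self, separable_classifier, tmp_path):
        _, predictor = separable_classifier
        predictor.net.save(tmp_path / "net.npz")
        again = MLP.load(tmp_path / "net.npz")
        x = np.full((3, 6), 5.0)
        assert np.allclose(predictor.net.predict(x), again.predict(x))


class TestAbcModelChoice:
    def test_deep_inside_territory(self):
        rng = np.random.default_rng(2)
        preds = np.vstack([
            rng.normal([0.9, 0.1], 0.02, (50, 2)),
            rng.normal([0.1, 0.9], 0.02, (50, 2)),
        ])
        labels = np.r_[np.zeros(50), np.ones(50)].astype(int)
        post = abc_model_choice(preds, labels, preds[3], ("A", "B"),
                                tolerance=0.1)
        assert post.best_model() == "A"
        assert post.probability("A") == max(post.probabilities)

    def test_tolerance_one_balanced_uniform(self):
        preds = np.tile(np.eye(5), (10, 1))
        labels = np.tile(np.arange(5), 10)
        post = abc_model_choice(preds, labels, preds[0],
                                ("A", "O", "M", "AX", "OX"), tolerance=1.0)
        assert np.allclose(post.probabilities, 0.2)

    def test_brute_force_15_rows(self):
        rng = np.random.default_rng(9)
        preds = rng.uniform(0, 1, (15, 3))
        labels = rng.integers(0, 3, 15)
        obs = rng.uniform(0, 1, 3)
        tol = 0.4
        post = abc_model_choice(preds, labels, obs, ("A", "B", "C"),
                                tolerance=tol)
        # exhaustive oracle
        d = np.sqrt(((preds - obs) ** 2).sum(axis=1))
        keep = np.argsort(d)[: round(tol * 15)]
        freq = np.bincount(labels[keep], minlength=3) / len(keep)
        assert np.allclose(post.probabilities, freq)
        assert post.n_accepted == len(keep)

    def test_probabilities_simplex(self):
        rng = np.random.default_rng(1)
        preds = rng.uniform(0, 1, (40, 2))
        labels = rng.integers(0, 2, 40)
        post = abc_model_choice(preds, labels, preds[0], ("A", "B"),
                                tolerance=0.5)
        assert post.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            abc_model_choice(np.ones((5, 2)), np.zeros(5, dtype=int),
                             np.ones(2), ("A",), tolerance=0.0)


class TestBayesFactor:
    def test_arithmetic(self):
        from demosmc.inference import ModelPosterior
        post = ModelPosterior(("A", "O"), np.array([10 / 11, 1 / 11]), 11, 0.1)
        assert bayes_factor(post, "A", "O") == pytest.approx(10.0)

    def test_symmetric_is_one(self):
        from demosmc.inference import ModelPosterior
        post = ModelPosterior(("A", "O"), np.array([0.5, 0.5]), 10, 0.1)
        assert bayes_factor(post, "A", "O") == pytest.approx(1.0)

    def test_zero_denominator_inf(self):
        from demosmc.inference import ModelPosterior
        post = ModelPosterior(("A", "O"), np.array([1.0, 0.0]), 10, 0.1)
        with pytest.warns(UserWarning):
            assert bayes_factor(post, "A", "O") == np.inf


class TestGoodnessOfFit:
    def test_p_uniform_under_model(self):
        # over 200 repetitions, KS distance to uniform < 0.1
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            ref = rng.normal(0, 1, (150, 3))
            null = rng.normal(0, 1, (200, 3))
            obs = rng.normal(0, 1, 3)
            pvals.append(goodness_of_fit(ref, null, obs))
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1

    def test_null_median_gives_half(self):
        rng = np.random.default_rng(6)
        ref = rng.normal(0, 1, (300, 2))
        null = rng.normal(0, 1, (500, 2))
        # observed drawn from the same law should give p near 0.5 on average
        ps = [goodness_of_fit(ref, null, rng.normal(0, 1, 2))
              for _ in range(60)]
        assert abs(np.mean(ps) - 0.5) < 0.12

    def test_extreme_observed_small_p(self):
        rng = np.random.default_rng(8)
        ref = rng.normal(0, 1, (200, 4))
        null = rng.normal(0, 1, (200, 4))
        obs = np.full(4, 50.0)  # grossly out of support
        assert goodness_of_fit(ref, null, obs) < 0.05

    def test_small_null_warns(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning):
            goodness_of_fit(rng.normal(0, 1, (50, 2)),
                            rng.normal(0, 1, (20, 2)),
                            np.zeros(2))


class TestAbcParameters:
    def _identity_table(self, rng, n=1500, d=4):
        box = PriorBox(tuple("abcd"[:d]), np.zeros(d), np.ones(d))
        theta = rng.uniform(0, 1, (n, d))
        preds = theta + rng.normal(0, 0.01, theta.shape)
        return box, theta, preds

    def test_identity_toy_recovery(self):
        # enough rows + tight tolerance: median within 2% of the
        # observed prediction
        rng = np.random.default_rng(12)
        d = 3
        box = PriorBox(tuple("abc"), np.zeros(d), np.ones(d))
        theta = rng.uniform(0, 1, (8000, d))
        preds = theta + rng.normal(0, 0.01, theta.shape)
        obs = np.array([0.31, 0.72, 0.55])
        post = abc_parameters(preds, theta, obs, box.names, tolerance=0.01)
        assert np.all(np.abs(post.point_estimate - obs) < 0.02)

    def test_tolerance_one_returns_prior(self):
        rng = np.random.default_rng(11)
        box, theta, preds = self._identity_table(rng)
        post = abc_parameters(preds, theta, preds[0], box.names, tolerance=1.0)
        # credible interval spans ~ the prior box
        assert np.all(post.interval_low < 0.06)
        assert np.all(post.interval_high > 0.94)

    def test_point_inside_interval(self):
        rng = np.random.default_rng(13)
        box, theta, preds = self._identity_table(rng)
        post = abc_parameters(preds, theta, preds[5], box.names,
                              tolerance=0.1)
        assert np.all(post.interval_low <= post.point_estimate)
        assert np.all(post.point_estimate <= post.interval_high)

    def test_posterior_inside_prior_box(self):
        rng = np.random.default_rng(14)
        box, theta, preds = self._identity_table(rng)
        post = abc_parameters(preds, theta, preds[7], box.names,
                              tolerance=0.2, prior_box=box)
        assert box.contains(post.point_estimate)
        assert np.all(post.accepted >= box.lower - 1e-12)
        assert np.all(post.accepted <= box.upper + 1e-12)

    def test_multi_replicate_median(self):
        rng = np.random.default_rng(15)
        box, theta, preds = self._identity_table(rng)
        obs = np.array([[0.4, 0.4, 0.4, 0.4], [0.6, 0.6, 0.6, 0.6]])
        post = abc_parameters(preds, theta, obs, box.names, tolerance=0.05)
        assert np.all(np.abs(post.point_estimate - 0.5) < 0.12)


class TestParameterScaling:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(20)
        lo = rng.uniform(-5, 0, 8)
        hi = lo + rng.uniform(0.1, 10, 8)
        box = PriorBox(tuple(f"p{i}" for i in range(8)), lo, hi)
        for _ in range(20):
            v = rng.uniform(lo, hi)
            assert np.allclose(box.unscale(box.scale(v)), v, atol=1e-12)
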