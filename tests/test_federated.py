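"""FedAvg aggregation, the warm-restart scheduler, and local training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import planefed.federated as fed
from planefed.federated import (
    ClientState,
    FederationConfig,
    build_classifier,
    cosine_warm_restart_lr,
    fedavg,
    local_train,
    run_federation,
)
from planefed.nn import cross_entropy_loss, one_hot


def random_params(rng, names=("a.weight", "a.bias")):
    return {n: rng.standard_normal((3, 2) if "weight" in n else (2,)) for n in names}


class TestFedavg:
    def test_single_client_identity(self):
        p = random_params(np.random.default_rng(0))
        out = fedavg([(p, 17)])
        for k in p:
            np.testing.assert_array_equal(out[k], p[k])

    def test_opposite_params_cancel(self):
        p = random_params(np.random.default_rng(1))
        neg = {k: -v for k, v in p.items()}
        out = fedavg([(p, 5), (neg, 5)])
        for k in p:
            np.testing.assert_allclose(out[k], 0.0, atol=1e-15)

    def test_hand_computed_weighted_mean(self):
        ps = [({"w": np.array([v])}, n) for v, n in [(6.0, 1), (3.0, 2), (1.0, 3)]]
        assert fedavg(ps)["w"][0] == pytest.approx(2.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_clients=st.integers(1, 5))
    def test_matches_scalar_oracle(self, seed, n_clients):
        rng = np.random.default_rng(seed)
        updates = [
            (random_params(rng), int(rng.integers(1, 100))) for _ in range(n_clients)
        ]
        out = fedavg(updates)
        total = sum(n for _, n in updates)
        for key in updates[0][0]:
            flat = out[key].ravel()
            for i in range(flat.size):
                acc = 0.0
                for params, n in updates:
                    acc += (n / total) * params[key].ravel()[i]
                assert abs(flat[i] - acc) <= 1e-12 * max(1.0, abs(acc))

    def test_permutation_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        updates = [(random_params(rng), n) for n in (3, 7, 11)]
        base = fedavg(updates)
        perm = fedavg(updates[::-1])
        scaled = fedavg([(p, 10 * n) for p, n in updates])
        for k in base:
            np.testing.assert_allclose(perm[k], base[k], atol=1e-15)
            np.testing.assert_allclose(scaled[k], base[k], atol=1e-15)

    def test_shape_mismatch_rejected(self):
        a = {"w": np.zeros((2, 2))}
        b = {"w": np.zeros((3, 2))}
        with pytest.raises(ValueError):
            fedavg([(a, 1), (b, 1)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fedavg([])


class TestScheduler:
    def test_initial_learning_rate(self):
        assert cosine_warm_restart_lr(0, 20) == pytest.approx(0.05, rel=1e-12)

    def test_half_cycle_value(self):
        expected = 1e-5 + 0.5 * (0.05 - 1e-5)
        assert cosine_warm_restart_lr(10, 20) == pytest.approx(expected, rel=1e-12)

    def test_warm_restart_at_round_boundary(self):
        assert cosine_warm_restart_lr(20, 20) == pytest.approx(0.05, rel=1e-12)

    def test_periodicity_and_infimum(self):
        lrs = [cosine_warm_restart_lr(e, 20) for e in range(40)]
        np.testing.assert_allclose(lrs[:20], lrs[20:], rtol=1e-12)
        assert min(lrs) < 1e-5 + 0.01 * (0.05 - 1e-5)
        assert min(lrs) >= 1e-5

    def test_monotone_decay_within_cycle(self):
        lrs = [cosine_warm_restart_lr(e, 20) for e in range(20)]
        assert np.all(np.diff(lrs) < 0)


def tiny_client(n=40, size=32, seed=0, client_id="c0"):
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % 4
    # class-dependent mean brightness makes the task learnable
    pixels = np.clip(
        0.2 * labels[:, None, None] / 3.0
        + 0.4
        + 0.1 * rng.standard_normal((n, size, size)),
        0,
        1,
    )
    return ClientState(client_id, pixels, labels)


class TestLocalTrain:
    def test_zero_epochs_returns_global_params(self):
        client = tiny_client()
        cfg = FederationConfig(rounds=1, local_epochs=0, embedding_dim=8)
        init = build_classifier(8, 4, seed=0).get_params()
        out = local_train(client, init, cfg)
        for k in init:
            np.testing.assert_array_equal(out[k], init[k])

    def test_mixup_disabled_equals_plain_cross_entropy(self):
        # with alpha=0 targets are pure one-hot: the loss on any batch is
        # exactly the hand-rolled cross-entropy
        rng = np.random.default_rng(0)
        logits = rng.standard_normal((8, 4))
        labels = rng.integers(0, 4, 8)
        loss, _ = cross_entropy_loss(logits, one_hot(labels, 4))
        p = np.exp(logits - logits.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        manual = -np.log(p[np.arange(8), labels]).mean()
        assert loss == pytest.approx(manual, rel=1e-12)

    def test_training_reduces_loss(self):
        client = tiny_client(n=40)
        cfg = FederationConfig(
            rounds=1, local_epochs=5, embedding_dim=8, seed=1, mixup_alpha=0.0
        )
        init = build_classifier(8, 4, seed=1).get_params()

        def mean_loss(params):
            proba = fed.predict_proba(params, client.pixels, cfg)
            return -np.log(proba[np.arange(client.n_k), client.labels] + 1e-12).mean()

        out = local_train(client, init, cfg)
        assert mean_loss(out) < mean_loss(init)

    def test_deterministic_under_seed(self):
        client = tiny_client()
        cfg = FederationConfig(rounds=1, local_epochs=1, embedding_dim=8, seed=5)
        init = build_classifier(8, 4, seed=5).get_params()
        out1 = local_train(client, init, cfg, round_idx=0)
        out2 = local_train(client, init, cfg, round_idx=0)
        for k in out1:
            np.testing.assert_array_equal(out1[k], out2[k])

    def test_empty_client_rejected(self):
        with pytest.raises(ValueError):
            ClientState("x", np.zeros((0, 32, 32)), np.zeros(0, dtype=int))


class TestRunFederation:
    def test_single_client_equals_centralized_training_bitwise(self):
        client = tiny_client(n=40, seed=3)
        cfg = FederationConfig(rounds=2, local_epochs=2, embedding_dim=8, seed=9)
        init = build_classifier(8, 4, seed=9).get_params()
        fed_params, _ = run_federation([client], init, cfg, select_best=False)

        # centralized: same validation carve-out, then sequential local
        # training with no aggregation step at all
        train, _, _ = fed.validation_split(client, cfg)
        params = {k: v.copy() for k, v in init.items()}
        for rnd in range(cfg.rounds):
            params = local_train(train, params, cfg, round_idx=rnd)
        for k in params:
            np.testing.assert_array_equal(fed_params[k], params[k])

    def test_identical_clients_aggregate_to_client_params(self):
        c1 = tiny_client(n=24, seed=4, client_id="same")
        c2 = ClientState("same", c1.pixels.copy(), c1.labels.copy())
        cfg = FederationConfig(rounds=1, local_epochs=1, embedding_dim=8, seed=2)
        init = build_classifier(8, 4, seed=2).get_params()
        agg, _ = run_federation([c1, c2], init, cfg, select_best=False)
        solo, _ = run_federation([c1], init, cfg, select_best=False)
        for k in agg:
            np.testing.assert_allclose(agg[k], solo[k], atol=1e-12)

    def test_history_and_reproducibility(self):
        clients = [tiny_client(n=24, seed=6, client_id="a"), tiny_client(n=24, seed=7, client_id="b")]
        cfg = FederationConfig(rounds=3, local_epochs=1, embedding_dim=8, seed=3)
        p1, h1 = run_federation(clients, None, cfg)
        p2, h2 = run_federation(clients, None, cfg)
        assert len(h1) == 3 * 2
        assert set(h1.columns) == {"round", "client", "val_loss", "val_macro_f1"}
        for k in p1:
            np.testing.assert_array_equal(p1[k], p2[k])
        assert h1.equals(h2)

    def test_no_clients_rejected(self):
        with pytest.raises(ValueError):
            run_federation([], None, FederationConfig())
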