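"""Objective identities, gradient reversal, schedule and probes."""

import numpy as np
import pytest

from advbeat import nn
from advbeat.model import AdversarialModel, EncoderConfig
from advbeat.synthetic import generate_cohort
from advbeat.training import (
    PlateauSchedule,
    TrainConfig,
    adversarial_loss,
    evaluate_invariance_probe,
    split_validation,
    train,
)

TINY_CFG = EncoderConfig(stem_filters=4, block_filters=(4, 8, 8),
                         attention_reduction=4)


def _random_probs(rng, n, k):
    p = rng.uniform(0.05, 1.0, size=(n, k))
    return p / p.sum(axis=1, keepdims=True)


class TestAdversarialLoss:
    def test_total_identity_holds_exactly(self):
        rng = np.random.default_rng(0)
        cp, sp = _random_probs(rng, 16, 5), _random_probs(rng, 16, 7)
        y, s = rng.integers(0, 5, 16), rng.integers(0, 7, 16)
        for lam in (0.0, 0.005, 0.1, 1.0):
            b = adversarial_loss(cp, sp, y, s, lam)
            assert b.total == b.classifier_ce - lam * b.adversary_ce
            assert b.classifier_ce >= 0 and b.adversary_ce >= 0

    def test_lambda_zero_reduces_to_classifier_loss(self):
        rng = np.random.default_rng(1)
        b = adversarial_loss(_random_probs(rng, 8, 5), _random_probs(rng, 8, 3),
                             rng.integers(0, 5, 8), rng.integers(0, 3, 8), 0.0)
        assert b.total == b.classifier_ce

    def test_uniform_subject_probs_give_log_s(self):
        rng = np.random.default_rng(2)
        n, s_count = 10, 6
        sp = np.full((n, s_count), 1 / s_count)
        b = adversarial_loss(_random_probs(rng, n, 5), sp,
                             rng.integers(0, 5, n),
                             rng.integers(0, s_count, n), 0.4)
        assert b.adversary_ce == pytest.approx(np.log(s_count), rel=1e-12)
        assert b.total == pytest.approx(b.classifier_ce - 0.4 * np.log(s_count))

    def test_perfect_classifier_has_zero_ce_and_zero_prob_is_clamped(self):
        y = np.array([0, 1])
        perfect = np.eye(5)[y]
        sp = np.full((2, 3), 1 / 3)
        b = adversarial_loss(perfect, sp, y, np.array([0, 1]), 0.1)
        assert b.classifier_ce == pytest.approx(0.0, abs=1e-12)
        bad = np.zeros((1, 5))
        bad[0, 1] = 1.0
        b2 = adversarial_loss(bad, np.ones((1, 2)) / 2, np.array([0]),
                              np.array([0]), 0.0)
        assert np.isfinite(b2.classifier_ce)


class TestGradientReversal:
    def test_gradients_match_central_differences(self):
        """Directional derivatives of L_c - lam*L_a (encoder), L_c
        (classifier) and L_a (adversary) against the implemented
        backward pass on a small network."""
        m = AdversarialModel(n_subjects=3, cfg=TINY_CFG, seed=5)
        m.set_training(True)
        rng = np.random.default_rng(6)
        x = rng.normal(size=(4, 3, 128, 2))
        y, s = np.array([0, 1, 2, 1]), np.array([0, 1, 2, 0])
        lam = 0.37

        def losses():
            m.set_training(True)
            _, cl, al = m.forward(x, lam)
            return nn.softmax_cross_entropy(cl, y), nn.softmax_cross_entropy(al, s)

        lc, la = losses()
        (lc + la).backward()
        checks = [
            (m.encoder.conv1.weight, lambda c, a: c - lam * a),
            (m.encoder.blocks[1].conv2.weight, lambda c, a: c - lam * a),
            (m.encoder.attentions[0].channel.fc1.weight, lambda c, a: c - lam * a),
            (m.classifier_head.weight, lambda c, a: c),
            (m.adversary_head.weight, lambda c, a: a),
        ]
        rng2 = np.random.default_rng(7)
        eps = 1e-6
        for p, combine in checks:
            flat, g = p.data.reshape(-1), p.grad.reshape(-1)
            for k in rng2.choice(flat.size, size=3, replace=False):
                old = flat[k]
                flat[k] = old + eps
                lc1, la1 = losses()
                flat[k] = old - eps
                lc2, la2 = losses()
                flat[k] = old
                fd = (combine(lc1.data, la1.data)
                      - combine(lc2.data, la2.data)) / (2 * eps)
                assert abs(fd - g[k]) <= 1e-4 * max(abs(fd), abs(g[k]), 1e-3)

    def test_lambda_zero_matches_classifier_only_trajectory(self):
        """With lam=0 the encoder/classifier follow exactly the update
        path of a network trained without any adversary loss."""
        rng = np.random.default_rng(8)
        x = rng.normal(size=(24, 3, 128, 2))
        y = rng.integers(0, 3, 24)
        s = rng.integers(0, 2, 24)

        def run(with_adversary: bool):
            m = AdversarialModel(n_subjects=2, cfg=TINY_CFG, seed=9)
            opt = nn.Adam(m.parameters(), lr=1e-3)
            for step in range(6):
                m.set_training(True)
                opt.zero_grad()
                _, cl, al = m.forward(x, lambda_adv=0.0)
                loss = nn.softmax_cross_entropy(cl, y)
                if with_adversary:
                    loss = loss + nn.softmax_cross_entropy(al, s)
                loss.backward()
                opt.step()
            return m

        a, b = run(True), run(False)
        for pa, pb in zip(a.encoder.parameters() + a.classifier_head.parameters(),
                          b.encoder.parameters() + b.classifier_head.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
        # the adversary heads must differ (trained vs frozen)
        assert not np.array_equal(a.adversary_head.weight.data,
                                  b.adversary_head.weight.data)

    def test_adversary_step_decreases_its_loss_on_frozen_encoder(self):
        m = AdversarialModel(n_subjects=4, cfg=TINY_CFG, seed=10)
        m.set_training(False)  # freeze batch statistics
        rng = np.random.default_rng(11)
        x = rng.normal(size=(16, 3, 128, 2))
        s = rng.integers(0, 4, 16)
        h = m.encode(x)

        def la_value():
            logits = m.adversary_head(nn.Tensor(h))
            return nn.softmax_cross_entropy(logits, s)

        before = la_value()
        before.backward()
        for p in m.adversary_head.parameters():
            p.data -= 1e-3 * p.grad
            p.grad = None
        assert la_value().data < before.data


class TestSplitAndSchedule:
    def test_split_sizes_disjoint_exhaustive_reproducible(self):
        tr, va = split_validation(1000, 0.2, seed=3)
        assert len(tr) == 800 and len(va) == 200
        assert not set(tr) & set(va)
        assert sorted(np.concatenate([tr, va])) == list(range(1000))
        tr2, va2 = split_validation(1000, 0.2, seed=3)
        np.testing.assert_array_equal(tr, tr2)
        np.testing.assert_array_equal(va, va2)

    def test_zero_fraction_gives_empty_validation(self):
        tr, va = split_validation(50, 0.0, seed=0)
        assert len(va) == 0 and len(tr) == 50

    def test_plateau_schedule_drops_once_then_stops(self):
        sched = PlateauSchedule(lr_patience=10, stop_patience=20)
        assert sched.step(1.0) == (True, False, False)
        drops, stops = [], []
        for i in range(25):
            is_best, drop, stop = sched.step(1.0)  # flat plateau
            assert not is_best
            drops.append(drop)
            stops.append(stop)
            if stop:
                break
        assert drops.index(True) == 9  # 10th non-improving epoch
        assert sum(drops) == 1  # the reduction happens at most once
        assert stops.index(True) == 19  # stop at exactly 20
        # improvement resets the counter
        s2 = PlateauSchedule(2, 4)
        s2.step(1.0)
        s2.step(2.0)
        assert s2.step(0.5) == (True, False, False)
        assert s2.epochs_since_best == 0

    def test_learning_rate_never_increases_and_best_is_running_min(self):
        cohort = generate_cohort(4, 40, seed=4, n_test_subjects=2)
        cfg = TrainConfig(lambda_adv=0.005, max_epochs=4, batch_size=32,
                          seed=4)
        model, hist = train((cohort.train_x, cohort.train_y, cohort.train_s),
                            cfg, encoder_config=TINY_CFG)
        lrs = [e.learning_rate for e in hist.epochs]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        vals = [e.val_classifier_ce for e in hist.epochs]
        best = hist.best_epoch
        assert vals[best - 1] == min(vals)
        # the combined objective identity holds for every logged epoch
        for e in hist.epochs:
            assert e.train_total == pytest.approx(
                e.train_classifier_ce - cfg.lambda_adv * e.train_adversary_ce,
                abs=1e-12)


class TestTrainingRuns:
    def test_separable_toy_converges(self):
        """On an easy low-noise two-class cohort the classifier
        cross-entropy falls below 0.1 within 50 epochs."""
        cohort = generate_cohort(4, 80, seed=5, n_test_subjects=2,
                                 confound_strength=0.3,
                                 class_mix=(0.8, 0.2, 0.0))
        cfg = TrainConfig(lambda_adv=0.0, max_epochs=50, batch_size=16,
                          seed=5, val_fraction=0.2)
        model, hist = train((cohort.train_x, cohort.train_y, cohort.train_s),
                            cfg, encoder_config=TINY_CFG)
        assert min(e.train_classifier_ce for e in hist.epochs) < 0.1

    def test_fixed_seed_reproduces_history(self):
        cohort = generate_cohort(4, 30, seed=6, n_test_subjects=2)
        cfg = TrainConfig(lambda_adv=0.01, max_epochs=2, batch_size=32, seed=6)
        data = (cohort.train_x, cohort.train_y, cohort.train_s)
        _, h1 = train(data, cfg, encoder_config=TINY_CFG)
        _, h2 = train(data, cfg, encoder_config=TINY_CFG)
        assert [vars(a) for a in h1.epochs] == [vars(b) for b in h2.epochs]

    def test_alternating_scheme_runs(self):
        cohort = generate_cohort(4, 30, seed=7, n_test_subjects=2)
        cfg = TrainConfig(lambda_adv=0.01, max_epochs=1, batch_size=32,
                          seed=7, update_scheme="alternating")
        model, hist = train((cohort.train_x, cohort.train_y, cohort.train_s),
                            cfg, encoder_config=TINY_CFG)
        assert len(hist.epochs) == 1

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train((np.zeros((0, 3, 128, 2)), np.zeros(0), np.zeros(0)),
                  TrainConfig())


class TestInvarianceProbe:
    def test_constant_features_score_majority_frequency(self):
        feats = np.ones((200, 8))
        sids = np.array([1] * 150 + [2] * 50)
        acc = evaluate_invariance_probe(feats, sids, seed=0)
        counts = np.bincount(sids[split_validation(200, 0.5, 0)[1]])
        assert acc == pytest.approx(counts.max() / counts.sum())

    def test_one_hot_subject_features_score_perfectly(self):
        rng = np.random.default_rng(12)
        sids = rng.integers(1, 5, 300)
        feats = np.eye(5)[sids]
        assert evaluate_invariance_probe(feats, sids, seed=1) == 1.0

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            evaluate_invariance_probe(np.ones((10, 3)), np.ones(10, dtype=int))
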