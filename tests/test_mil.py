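"""MIL network contracts: gradients, attention pooling, checkpoint
selection, determinism and persistence."""

import numpy as np
import pytest

from slidemil import nn
from slidemil.mil import AttentionMILClassifier, _select_checkpoints

from conftest import untrained_mil


def _rand_bag(rng, k=12, size=16):
    return rng.random((k, size, size, 3), dtype=np.float32)


# -- analytic gradients -----------------------------------------------------


def test_backprop_matches_numeric_gradients():
    """Exact gradient check of the full CNN + gated-attention stack."""
    rng = np.random.default_rng(0)
    cnn = nn.TinyCNN(channels=(3, 4), dtype=np.float64)
    head = nn.GatedAttentionHead(4, 3, dtype=np.float64)
    p, q = cnn.init_params(rng), head.init_params(rng)
    x = rng.random((4, 8, 8, 3))

    def loss():
        feats, _ = cnn.forward(p, x)
        _, _, logit, _ = head.forward(q, feats)
        return nn.bce_with_logits(logit, 1.0)[0]

    feats, c1 = cnn.forward(p, x)
    _, _, logit, c2 = head.forward(q, feats)
    _, dlogit = nn.bce_with_logits(logit, 1.0)
    gh, dfeat = head.backward(q, dlogit, c2)
    gc, dx = cnn.backward(p, dfeat, c1, need_dx=True)

    eps = 1e-6
    for params, grads in ((q, gh), (p, gc)):
        for key, arr in params.items():
            flat = arr.reshape(-1)
            for i in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = np.asarray(grads[key]).reshape(-1)[i]
                assert num == pytest.approx(ana, abs=1e-7, rel=1e-4), key
    # input gradient (used by Grad-CAM machinery)
    xf = x.reshape(-1)
    for i in (0, 137, xf.size - 1):
        orig = xf[i]
        xf[i] = orig + eps
        lp = loss()
        xf[i] = orig - eps
        lm = loss()
        xf[i] = orig
        assert (lp - lm) / (2 * eps) == pytest.approx(
            dx.reshape(-1)[i], abs=1e-8, rel=1e-4
        )


# -- forward-pass contracts -------------------------------------------------


def test_attention_weights_normalized(mil_model):
    rng = np.random.default_rng(1)
    for _ in range(20):
        out = mil_model.forward_bag(_rand_bag(rng))
        assert out.weights.min() >= 0
        assert abs(out.weights.sum() - 1.0) < 1e-6
        assert 0.0 <= out.score <= 1.0


def test_forward_is_permutation_invariant(mil_model):
    rng = np.random.default_rng(2)
    for _ in range(50):
        bag = _rand_bag(rng)
        perm = rng.permutation(len(bag))
        out = mil_model.forward_bag(bag)
        out_p = mil_model.forward_bag(bag[perm])
        assert out_p.score == pytest.approx(out.score, abs=1e-5)
        assert np.allclose(out_p.weights, out.weights[perm], atol=1e-5)


def test_identical_instances_get_uniform_weights(mil_model):
    rng = np.random.default_rng(3)
    one = rng.random((1, 16, 16, 3), dtype=np.float32)
    bag = np.repeat(one, 10, axis=0)
    out = mil_model.forward_bag(bag)
    assert np.allclose(out.weights, 0.1, atol=1e-7)


def test_ensemble_mean_bounded_by_member_extremes(mil_model):
    rng = np.random.default_rng(4)
    for _ in range(100):
        bag = _rand_bag(rng, k=6)
        members = mil_model.member_scores(bag)
        ens = mil_model.ensemble_score(bag)
        assert members.min() - 1e-12 <= ens <= members.max() + 1e-12
        assert ens == pytest.approx(members.mean(), abs=1e-12)


def test_identical_checkpoints_give_member_score():
    clf = untrained_mil()
    clf.checkpoints_ = [clf.checkpoints_[0]] * 5
    rng = np.random.default_rng(5)
    bag = _rand_bag(rng)
    assert clf.ensemble_score(bag) == pytest.approx(
        clf.member_scores(bag)[0], abs=1e-12
    )


def test_bad_bag_shape_raises(mil_model):
    with pytest.raises(ValueError, match="bag"):
        mil_model.forward_bag(np.zeros((4, 16, 16)))


# -- checkpoint selection ---------------------------------------------------


def test_checkpoint_selection_prefers_pre_overfit_epochs():
    # loss falls for 8 epochs then rises for 6: overfit point at epoch 8
    loss = np.r_[np.linspace(1.0, 0.2, 8), np.linspace(0.25, 0.9, 6)]
    auc = np.r_[np.linspace(0.5, 0.9, 8), np.full(6, 0.99)]
    chosen, overfit = _select_checkpoints(loss, auc, 5, window=1, patience=3)
    assert overfit is not None and overfit <= 9
    assert all(e < overfit for e in chosen)
    assert len(chosen) == 5


def test_checkpoint_selection_ties_break_earlier():
    loss = np.linspace(1.0, 0.1, 10)          # never rises: no overfit point
    auc = np.full(10, 0.8)
    chosen, overfit = _select_checkpoints(loss, auc, 5, 3, 3)
    assert overfit is None
    assert chosen == [0, 1, 2, 3, 4]          # all AUCs tie -> earliest epochs


def test_checkpoint_selection_falls_back_when_overfit_too_early():
    loss = np.r_[[0.5], np.linspace(0.6, 1.5, 9)]   # rises from the start
    auc = np.linspace(0.5, 0.95, 10)
    chosen, _ = _select_checkpoints(loss, auc, 5, 1, 3)
    assert len(chosen) == 5                   # fewer than 5 pre-overfit epochs


# -- training ---------------------------------------------------------------


def _toy_pools(rng, n_slides=10, signal=0.25):
    pools, labels = [], []
    for i in range(n_slides):
        label = i % 2
        pool = rng.random((6, 16, 16, 3), dtype=np.float32) * 0.2 + 0.4
        if label:
            pool[:, :, :, 1] += signal
        pools.append(np.clip(pool, 0, 1))
        labels.append(label)
    return pools, np.array(labels)


def _fit_toy(seed=0, epochs=6):
    rng = np.random.default_rng(123)
    pools, y = _toy_pools(rng, 12)
    fpools, fy = _toy_pools(rng, 6)
    clf = AttentionMILClassifier(sample_count=8, conv_channels=(4, 8),
                                 epochs=epochs, random_state=seed)
    return clf.fit(pools, y, fpools, fy), pools


def test_training_learns_toy_signal_and_is_deterministic():
    clf1, pools = _fit_toy(seed=7)
    clf2, _ = _fit_toy(seed=7)
    assert clf1.checkpoint_epochs_ == clf2.checkpoint_epochs_
    s1 = clf1.predict_proba(pools)[:, 1]
    s2 = clf2.predict_proba(pools)[:, 1]
    assert np.allclose(s1, s2)
    assert len(clf1.checkpoints_) == 5
    # green-shifted (odd) slides must outscore the others
    assert s1[1::2].min() > s1[0::2].max()


def test_training_history_logged():
    clf, _ = _fit_toy()
    assert list(clf.history_.columns) == [
        "epoch", "train_loss", "finetune_loss", "finetune_auc"
    ]
    assert len(clf.history_) == clf.epochs


def test_single_class_finetune_rejected():
    rng = np.random.default_rng(0)
    pools, y = _toy_pools(rng, 8)
    fpools, _ = _toy_pools(rng, 4)
    clf = AttentionMILClassifier(sample_count=8)
    with pytest.raises(ValueError, match="finetune"):
        clf.fit(pools, y, fpools, np.ones(4))


def test_overlapping_patient_groups_rejected():
    rng = np.random.default_rng(0)
    pools, y = _toy_pools(rng, 8)
    fpools, fy = _toy_pools(rng, 4)
    clf = AttentionMILClassifier(sample_count=8)
    with pytest.raises(ValueError, match="share"):
        clf.fit(pools, y, fpools, fy,
                groups=["a", "b", "c", "d", "e", "f", "g", "h"],
                finetune_groups=["a", "x", "y", "z"])


def test_too_few_epochs_rejected():
    rng = np.random.default_rng(0)
    pools, y = _toy_pools(rng, 8)
    clf = AttentionMILClassifier(sample_count=8, epochs=3)
    with pytest.raises(ValueError, match="epochs"):
        clf.fit(pools, y, pools, y)


def test_unknown_backbone_rejected():
    rng = np.random.default_rng(0)
    pools, y = _toy_pools(rng, 8)
    clf = AttentionMILClassifier(sample_count=8,
                                 backbone="inception_v4_pretrained")
    with pytest.raises(ValueError, match="backbone"):
        clf.fit(pools, y, pools[:4], y[:4])


def test_save_load_roundtrip(tmp_path):
    clf, pools = _fit_toy()
    clf.save(tmp_path / "model")
    loaded = AttentionMILClassifier.load(tmp_path / "model")
    assert loaded.checkpoint_epochs_ == clf.checkpoint_epochs_
    assert np.allclose(loaded.predict_proba(pools)[:, 1],
                       clf.predict_proba(pools)[:, 1])
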