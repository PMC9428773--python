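"""Transfer head forward pass, training loop, and ensemble selection."""

import numpy as np
import pytest

from breathkit.classifier import (
    Ensemble,
    TrainingConfig,
    TransferHead,
    ensemble_predict,
    head_forward,
    load_ensemble,
    save_ensemble,
    select_ensemble,
    train_head,
)
from breathkit.embedding import EMBEDDING_DIM


def zero_head():
    return TransferHead(
        W1=np.zeros((EMBEDDING_DIM, 32)),
        b1=np.zeros(32),
        W2=np.zeros((32, 3)),
        b2=np.zeros(3),
    )


_CENTER_RNG = np.random.default_rng(12345)
_CENTERS = _CENTER_RNG.standard_normal((3, EMBEDDING_DIM))
_CENTERS *= 8.0 / np.linalg.norm(_CENTERS, axis=1, keepdims=True)


def gaussian_clusters(seed, n_per_class=100, noise=1.0):
    """Three well-separated Gaussian blobs around shared fixed centers."""
    rng = np.random.default_rng(seed)
    centers = _CENTERS
    X, Y = [], []
    for c in range(3):
        X.append(centers[c] + noise * rng.standard_normal((n_per_class, EMBEDDING_DIM)) / np.sqrt(EMBEDDING_DIM))
        y = np.zeros((n_per_class, 3))
        y[:, c] = 1.0
        Y.append(y)
    return np.vstack(X), np.vstack(Y)


def test_zero_parameters_give_uniform_probabilities():
    probs = head_forward(zero_head(), np.random.default_rng(0).standard_normal(EMBEDDING_DIM))
    assert probs.as_array() == pytest.approx([1 / 3, 1 / 3, 1 / 3])


def test_forward_is_valid_distribution():
    head = TransferHead.initialize(seed=5)
    rng = np.random.default_rng(1)
    for _ in range(5):
        p = head_forward(head, rng.standard_normal(EMBEDDING_DIM)).as_array()
        assert np.all(p >= 0) and np.all(p <= 1)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)


def test_forward_matches_hand_computed_toy():
    """Plant a 2-active-unit analogue and check the swish/softmax arithmetic."""
    head = zero_head()
    head.W1[0, 0] = 1.0
    head.W1[1, 1] = 2.0
    head.W2[0, 0] = 1.5
    head.W2[1, 1] = -0.5
    head.b2[:] = [0.1, 0.2, 0.3]
    e = np.zeros(EMBEDDING_DIM)
    e[0], e[1] = 1.0, -0.5
    # hand arithmetic
    z1 = np.array([1.0, -1.0])
    swish = z1 / (1 + np.exp(-z1))
    logits = np.array([0.1 + 1.5 * swish[0], 0.2 - 0.5 * swish[1], 0.3])
    expected = np.exp(logits) / np.exp(logits).sum()
    assert head_forward(head, e).as_array() == pytest.approx(expected, abs=1e-9)


def test_training_recovers_separable_clusters():
    Xtr, Ytr = gaussian_clusters(seed=0)
    Xva, Yva = gaussian_clusters(seed=1, n_per_class=40)
    Xte, Yte = gaussian_clusters(seed=2, n_per_class=40)
    head, hist = train_head((Xtr, Ytr), (Xva, Yva), TrainingConfig(max_epochs=60), init_seed=3)
    pred = np.array([np.argmax(head_forward(head, x).as_array()) for x in Xte])
    true = Yte.argmax(axis=1)
    recalls = [np.mean(pred[true == c] == c) for c in range(3)]
    assert np.mean(recalls) >= 0.95
    assert hist.best_epoch == int(np.argmin(hist.val_loss)) + 1


def test_training_is_seed_reproducible():
    Xtr, Ytr = gaussian_clusters(seed=0, n_per_class=30)
    Xva, Yva = gaussian_clusters(seed=1, n_per_class=10)
    cfg = TrainingConfig(max_epochs=5, shuffle_seed=9)
    h1, _ = train_head((Xtr, Ytr), (Xva, Yva), cfg, init_seed=4)
    h2, _ = train_head((Xtr, Ytr), (Xva, Yva), cfg, init_seed=4)
    assert np.array_equal(h1.W1, h2.W1) and np.array_equal(h1.W2, h2.W2)


def test_early_stopping_restores_first_epoch_on_degrading_validation():
    """A validation set contradicting the training labels makes validation
    loss grow; training must stop after `patience` bad epochs and return
    the weights of the best (first) epoch."""
    rng = np.random.default_rng(6)
    Xtr = rng.standard_normal((60, EMBEDDING_DIM))
    Ytr = np.eye(3)[rng.integers(0, 3, 60)]
    # validation labels anti-correlated with training: loss rises as the head fits
    Xva, Yva = Xtr[:30], np.roll(Ytr[:30], 1, axis=1)
    cfg = TrainingConfig(max_epochs=50, patience=3, learning_rate=0.05)
    head, hist = train_head((Xtr, Ytr), (Xva, Yva), cfg, init_seed=1)
    assert hist.stopped_epoch == hist.best_epoch + 3
    assert hist.val_loss[hist.best_epoch - 1] == min(hist.val_loss)


def test_patience_zero_stops_at_first_non_improving_epoch():
    rng = np.random.default_rng(7)
    Xtr = rng.standard_normal((30, EMBEDDING_DIM))
    Ytr = np.eye(3)[rng.integers(0, 3, 30)]
    Xva, Yva = Xtr[:10], np.roll(Ytr[:10], 1, axis=1)
    _, hist = train_head(
        (Xtr, Ytr), (Xva, Yva),
        TrainingConfig(max_epochs=50, patience=0, learning_rate=0.05), init_seed=1,
    )
    # stops as soon as one epoch fails to improve on the best
    first_bad = next(
        i + 1 for i in range(1, len(hist.val_loss))
        if hist.val_loss[i] >= min(hist.val_loss[:i])
    )
    assert hist.stopped_epoch == first_bad


def test_empty_training_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        train_head(
            (np.empty((0, EMBEDDING_DIM)), np.empty((0, 3))),
            (np.zeros((1, EMBEDDING_DIM)), np.eye(3)[:1]),
        )


def test_single_class_training_warns_but_runs():
    rng = np.random.default_rng(8)
    X = rng.standard_normal((10, EMBEDDING_DIM))
    Y = np.tile([1.0, 0.0, 0.0], (10, 1))
    with pytest.warns(UserWarning, match="single class"):
        train_head((X, Y), (X, Y), TrainingConfig(max_epochs=2))


@pytest.mark.parametrize(
    "losses, k, expected_indices",
    [
        ([0.5, 0.2, 0.9, 0.1, 0.3], 3, [3, 1, 4]),
        ([0.5, 0.2, 0.9], 1, [1]),
        ([0.2, 0.2, 0.5], 1, [0]),  # tie -> first candidate
    ],
)
def test_select_ensemble_lowest_losses_tie_to_first(losses, k, expected_indices):
    heads = [TransferHead.initialize(seed=i) for i in range(len(losses))]
    ens = select_ensemble(list(zip(heads, losses)), k=k)
    assert [h.init_seed for h in ens.heads] == expected_indices
    assert ens.val_losses == sorted(ens.val_losses)


def test_select_ensemble_requires_enough_candidates():
    with pytest.raises(ValueError):
        select_ensemble([(TransferHead.initialize(0), 0.1)], k=3)


def test_ensemble_predict_averages_members():
    heads = [TransferHead.initialize(seed=i) for i in range(3)]
    ens = Ensemble(heads=heads, val_losses=[0.1, 0.2, 0.3])
    e = np.random.default_rng(9).standard_normal(EMBEDDING_DIM)
    member = np.stack([head_forward(h, e).as_array() for h in heads])
    assert ensemble_predict(ens, e).as_array() == pytest.approx(member.mean(axis=0))


def test_ensemble_of_identical_heads_equals_single_head():
    head = TransferHead.initialize(seed=2)
    ens = Ensemble(heads=[head, head.copy()], val_losses=[0.1, 0.1])
    e = np.random.default_rng(10).standard_normal(EMBEDDING_DIM)
    assert ensemble_predict(ens, e).as_array() == pytest.approx(
        head_forward(head, e).as_array()
    )


def test_ensemble_save_load_roundtrip(tmp_path):
    heads = [TransferHead.initialize(seed=i) for i in range(3)]
    ens = Ensemble(heads=heads, val_losses=[0.1, 0.2, 0.3])
    save_ensemble(ens, tmp_path / "ens.npz", metadata={"backend_id": "surrogate"})
    loaded, meta = load_ensemble(tmp_path / "ens.npz")
    assert meta["backend_id"] == "surrogate"
    for a, b in zip(ens.heads, loaded.heads):
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.b2, b.b2)
    assert loaded.val_losses == ens.val_losses
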