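"""Transfer-learning classifier head and soft-voting ensemble.

The head is deliberately tiny: a dense 1024→32 layer with swish
activation (x·sigmoid(x)) followed by a 32→3 softmax over
(exhalation, inhalation, nonbreathing). It is trained with mini-batch
Adam on categorical cross-entropy, early stopping on validation loss
(patience 10, best weights restored), and no class balancing — the
dominant nonbreathing class is left dominant on purpose to discourage
breathing false positives in noisy environments.

Many candidate heads are trained from different seeded initializations
and the k with the lowest validation loss form a soft-voting ensemble
(equal weights; the class with the maximum summed probability wins).

Implementation is pure NumPy; weights persist as a portable ``.npz`` +
JSON metadata file so detection and evaluation never depend on a
training framework.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .embedding import EMBEDDING_DIM

HIDDEN_UNITS = 32
N_CLASSES = 3
CLASS_NAMES = ("exhalation", "inhalation", "nonbreathing")

__all__ = [
    "CLASS_NAMES",
    "ClassProbabilities",
    "TransferHead",
    "TrainingConfig",
    "TrainingHistory",
    "Ensemble",
    "head_forward",
    "train_head",
    "train_candidates",
    "select_ensemble",
    "ensemble_predict",
    "save_ensemble",
    "load_ensemble",
]


@dataclass(frozen=True)
class ClassProbabilities:
    """Softmax output over (exhalation, inhalation, nonbreathing)."""

    p_exhalation: float
    p_inhalation: float
    p_nonbreathing: float

    def __post_init__(self) -> None:
        vec = self.as_array()
        if np.any(vec < -1e-12) or np.any(vec > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.p_exhalation, self.p_inhalation, self.p_nonbreathing], dtype=np.float64
        )

    @classmethod
    def from_array(cls, vec: np.ndarray) -> "ClassProbabilities":
        return cls(float(vec[0]), float(vec[1]), float(vec[2]))


@dataclass
class TransferHead:
    """Dense(1024→32, swish) → Dense(32→3, softmax) weights."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    init_seed: int = 0

    def __post_init__(self) -> None:
        shapes = {
            "W1": (EMBEDDING_DIM, HIDDEN_UNITS),
            "b1": (HIDDEN_UNITS,),
            "W2": (HIDDEN_UNITS, N_CLASSES),
            "b2": (N_CLASSES,),
        }
        for name, expected in shapes.items():
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != expected:
                raise ValueError(f"{name} must have shape {expected}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    @classmethod
    def initialize(cls, seed: int) -> "TransferHead":
        """Seeded Glorot-uniform initialization, zero biases."""
        rng = np.random.default_rng(seed)
        lim1 = np.sqrt(6.0 / (EMBEDDING_DIM + HIDDEN_UNITS))
        lim2 = np.sqrt(6.0 / (HIDDEN_UNITS + N_CLASSES))
        return cls(
            W1=rng.uniform(-lim1, lim1, (EMBEDDING_DIM, HIDDEN_UNITS)),
            b1=np.zeros(HIDDEN_UNITS),
            W2=rng.uniform(-lim2, lim2, (HIDDEN_UNITS, N_CLASSES)),
            b2=np.zeros(N_CLASSES),
            init_seed=seed,
        )

    def copy(self) -> "TransferHead":
        return TransferHead(
            self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy(), self.init_seed
        )


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1  # 1-based epoch with minimum validation loss
    stopped_epoch: int = 0


@dataclass
class Ensemble:
    """k heads sorted by ascending validation loss; soft voting."""

    heads: list[TransferHead]
    val_losses: list[float]

    def __post_init__(self) -> None:
        if not self.heads:
            raise ValueError("ensemble must contain at least one head")
        if len(self.heads) != len(self.val_losses):
            raise ValueError("one validation loss per head required")
        if any(
            self.val_losses[i] > self.val_losses[i + 1]
            for i in range(len(self.val_losses) - 1)
        ):
            raise ValueError("heads must be sorted by ascending validation loss")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable


def _swish(x: np.ndarray) -> np.ndarray:
    return x * _sigmoid(x)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _forward_batch(head: TransferHead, X: np.ndarray) -> np.ndarray:
    hidden = _swish(X @ head.W1 + head.b1)
    return _softmax(hidden @ head.W2 + head.b2)


def head_forward(head: TransferHead, embedding: np.ndarray) -> ClassProbabilities:
    """softmax(W2ᵀ·swish(W1ᵀe + b1) + b2) for one embedding."""
    embedding = np.asarray(embedding, dtype=np.float64)
    if embedding.shape != (EMBEDDING_DIM,):
        raise ValueError(f"embedding must have length {EMBEDDING_DIM}")
    probs = _forward_batch(head, embedding[None, :])[0]
    return ClassProbabilities.from_array(probs / probs.sum())


def _cross_entropy(probs: np.ndarray, Y: np.ndarray) -> float:
    return float(-np.mean(np.sum(Y * np.log(np.clip(probs, 1e-12, None)), axis=1)))


def train_head(
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    cfg: TrainingConfig | None = None,
    init_seed: int = 0,
) -> tuple[TransferHead, TrainingHistory]:
    """Train one head with Adam + early stopping; returns best-epoch weights.

    ``train_set``/``val_set`` are (embeddings, one-hot labels) arrays of
    shape (n, 1024) and (n, 3). Training stops after ``cfg.patience``
    epochs without a new validation-loss minimum and the minimizing
    epoch's weights are restored. No class balancing is applied; a
    single-class training set is allowed but warned about.
    """
    cfg = cfg or TrainingConfig()
    X, Y = np.asarray(train_set[0], float), np.asarray(train_set[1], float)
    Xv, Yv = np.asarray(val_set[0], float), np.asarray(val_set[1], float)
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    if Xv.shape[0] == 0:
        raise ValueError("validation set is empty")
    if np.count_nonzero(Y.sum(axis=0)) == 1:
        warnings.warn("training set contains a single class", stacklevel=2)

    head = TransferHead.initialize(init_seed)
    params = [head.W1, head.b1, head.W2, head.b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    rng = np.random.default_rng(cfg.shuffle_seed)
    history = TrainingHistory()
    best_val = np.inf
    best_params = [p.copy() for p in params]
    epochs_since_best = 0
    step = 0

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(X.shape[0])
        epoch_losses = []
        for start in range(0, X.shape[0], cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            # forward
            z1 = xb @ params[0] + params[1]
            sig = _sigmoid(z1)
            h = z1 * sig
            probs = _softmax(h @ params[2] + params[3])
            epoch_losses.append(_cross_entropy(probs, yb) * len(idx))
            # backward (softmax + cross-entropy, then swish')
            n = len(idx)
            dlogits = (probs - yb) / n
            grads = [None] * 4
            grads[2] = h.T @ dlogits
            grads[3] = dlogits.sum(axis=0)
            dh = dlogits @ params[2].T
            dz1 = dh * (sig + z1 * sig * (1.0 - sig))
            grads[0] = xb.T @ dz1
            grads[1] = dz1.sum(axis=0)
            step += 1
            for i in range(4):
                m[i] = cfg.adam_beta1 * m[i] + (1 - cfg.adam_beta1) * grads[i]
                v[i] = cfg.adam_beta2 * v[i] + (1 - cfg.adam_beta2) * grads[i] ** 2
                m_hat = m[i] / (1 - cfg.adam_beta1**step)
                v_hat = v[i] / (1 - cfg.adam_beta2**step)
                params[i] -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + cfg.adam_eps)

        history.train_loss.append(sum(epoch_losses) / X.shape[0])
        current = TransferHead(*[p for p in params], init_seed=init_seed)
        val_loss = _cross_entropy(_forward_batch(current, Xv), Yv)
        history.val_loss.append(val_loss)
        history.stopped_epoch = epoch
        if val_loss < best_val:
            best_val = val_loss
            best_params = [p.copy() for p in params]
            history.best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= max(cfg.patience, 1):
                break

    best = TransferHead(*best_params, init_seed=init_seed)
    return best, history


def train_candidates(
    train_set, val_set, cfg: TrainingConfig | None = None, n_candidates: int = 20,
    base_seed: int = 0,
) -> list[tuple[TransferHead, float]]:
    """Train ``n_candidates`` heads from derived seeds; return (head, val_loss)."""
    cfg = cfg or TrainingConfig()
    out = []
    seeds = np.random.SeedSequence(base_seed).generate_state(2 * n_candidates) % (2**31)
    for i in range(n_candidates):
        run_cfg = replace(cfg, shuffle_seed=int(seeds[2 * i + 1]))
        head, hist = train_head(train_set, val_set, run_cfg, init_seed=int(seeds[2 * i]))
        out.append((head, float(min(hist.val_loss))))
    return out


def select_ensemble(
    candidates: list[tuple[TransferHead, float]], k: int = 3
) -> Ensemble:
    """Keep the k candidates with the lowest validation loss (ties: first wins)."""
    if len(candidates) < k:
        raise ValueError(f"need at least {k} candidates, got {len(candidates)}")
    order = sorted(range(len(candidates)), key=lambda i: (candidates[i][1], i))[:k]
    return Ensemble(
        heads=[candidates[i][0] for i in order],
        val_losses=[candidates[i][1] for i in order],
    )


def ensemble_predict(ens: Ensemble, embedding: np.ndarray) -> ClassProbabilities:
    """Equal-weight soft voting: mean of member probability vectors."""
    stacked = np.stack([head_forward(h, embedding).as_array() for h in ens.heads])
    mean = stacked.mean(axis=0)
    return ClassProbabilities.from_array(mean / mean.sum())


def ensemble_predict_batch(ens: Ensemble, X: np.ndarray) -> np.ndarray:
    """Vectorized soft voting over an (n, 1024) embedding matrix."""
    X = np.asarray(X, dtype=np.float64)
    stacked = np.stack([_forward_batch(h, X) for h in ens.heads])
    mean = stacked.mean(axis=0)
    return mean / mean.sum(axis=1, keepdims=True)


def save_ensemble(ens: Ensemble, path: str | Path, metadata: dict | None = None) -> None:
    """Persist an ensemble as shape-tagged arrays + JSON metadata (.npz)."""
    path = Path(path)
    arrays = {"val_losses": np.asarray(ens.val_losses)}
    for i, h in enumerate(ens.heads):
        arrays.update(
            {f"h{i}_W1": h.W1, f"h{i}_b1": h.b1, f"h{i}_W2": h.W2, f"h{i}_b2": h.b2}
        )
    meta = dict(metadata or {})
    meta.update(
        n_heads=len(ens.heads),
        init_seeds=[h.init_seed for h in ens.heads],
        class_names=list(CLASS_NAMES),
    )
    np.savez(path, **arrays)
    # .npz is a zip; tuck the JSON metadata in alongside the arrays
    with zipfile.ZipFile(path if path.suffix == ".npz" else path.with_suffix(".npz"), "a") as zf:
        zf.writestr("metadata.json", json.dumps(meta, indent=2))


def load_ensemble(path: str | Path) -> tuple[Ensemble, dict]:
    path = Path(path)
    with np.load(path) as data:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("metadata.json"))
        heads = [
            TransferHead(
                W1=data[f"h{i}_W1"],
                b1=data[f"h{i}_b1"],
                W2=data[f"h{i}_W2"],
                b2=data[f"h{i}_b2"],
                init_seed=int(meta["init_seeds"][i]),
            )
            for i in range(int(meta["n_heads"]))
        ]
        val_losses = [float(x) for x in data["val_losses"]]
    return Ensemble(heads=heads, val_losses=val_losses), meta
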