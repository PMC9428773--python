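"""Pluggable 1024-dimensional audio embeddings.

The classifier head consumes a fixed 1024-vector per 15,600-sample input.
Two backends satisfy that contract:

* ``SurrogateBackend`` (default) — a deterministic, dependency-free
  feature map: per-mel-band summary statistics of the log-mel patch
  (mean, standard deviation, maximum, mean absolute first difference →
  256 features) expanded to 1024 dimensions by a fixed seeded Gaussian
  random projection followed by tanh. It preserves the spectral contrasts
  the synthetic archetypes are built on, so the full train/detect/eval
  pipeline runs offline.
* ``YamnetBackend`` — an adapter to the pretrained audio-event network's
  published embedding output. It requires tensorflow and a model download
  and raises a clear error when either is missing; it never falls back
  silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .frontend import TILED_SAMPLES, log_mel

EMBEDDING_DIM = 1024
SURROGATE_DEFAULT_SEED = 20_220_901

__all__ = [
    "EMBEDDING_DIM",
    "Embedding",
    "EmbeddingBackend",
    "SurrogateBackend",
    "YamnetBackend",
    "embed",
    "get_backend",
]


@dataclass(frozen=True)
class Embedding:
    vector: np.ndarray
    backend_id: str

    def __post_init__(self) -> None:
        vector = np.asarray(self.vector, dtype=np.float64)
        if vector.shape != (EMBEDDING_DIM,):
            raise ValueError(f"embedding must have length {EMBEDDING_DIM}")
        if not np.all(np.isfinite(vector)):
            raise ValueError("embedding entries must be finite")
        object.__setattr__(self, "vector", vector)


class EmbeddingBackend(Protocol):
    name: str
    deterministic: bool

    def embed(self, waveform: np.ndarray) -> Embedding: ...


def _check_waveform(waveform: np.ndarray) -> np.ndarray:
    waveform = np.asarray(waveform, dtype=np.float64)
    if waveform.shape != (TILED_SAMPLES,):
        raise ValueError(
            f"backend input must be a tiled waveform of {TILED_SAMPLES} samples, "
            f"got shape {waveform.shape}"
        )
    return waveform


@dataclass
class SurrogateBackend:
    """Deterministic log-mel summary-statistic embedding."""

    seed: int = SURROGATE_DEFAULT_SEED
    name: str = "surrogate"
    deterministic: bool = True
    _projection: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        # 4 statistics x 64 bands -> 1024; scaled for unit-ish variance
        self._projection = rng.standard_normal((256, EMBEDDING_DIM)) / np.sqrt(256.0)

    def embed(self, waveform: np.ndarray) -> Embedding:
        waveform = _check_waveform(waveform)
        patch = log_mel(waveform).values  # (64, T)
        stats = np.concatenate(
            [
                patch.mean(axis=1),
                patch.std(axis=1),
                patch.max(axis=1),
                np.abs(np.diff(patch, axis=1)).mean(axis=1),
            ]
        )
        return Embedding(vector=np.tanh(stats @ self._projection), backend_id=self.name)


@dataclass
class YamnetBackend:
    """Adapter to the pretrained audio-event network's 1024-d embedding.

    ``model_path`` points at a locally downloaded saved model. The adapter
    feeds the raw 15,600-sample waveform and returns the network's
    embedding output averaged over its internal patches.
    """

    model_path: str | None = None
    name: str = "yamnet"
    deterministic: bool = True
    _model: object | None = field(default=None, init=False, repr=False)

    def _load(self):
        if self._model is None:
            try:
                import tensorflow as tf  # noqa: F401
                import tensorflow_hub as hub
            except ImportError as exc:
                raise RuntimeError(
                    "yamnet backend not installed: requires tensorflow and "
                    "tensorflow_hub plus a downloaded model "
                    "(pass model_path or use the surrogate backend)"
                ) from exc
            source = self.model_path or "https://tfhub.dev/google/yamnet/1"
            self._model = hub.load(source)
        return self._model

    def embed(self, waveform: np.ndarray) -> Embedding:
        waveform = _check_waveform(waveform)
        model = self._load()
        _scores, embeddings, _spec = model(waveform.astype(np.float32))
        vector = np.asarray(embeddings).mean(axis=0)
        return Embedding(vector=vector.astype(np.float64), backend_id=self.name)


def get_backend(name: str, **kwargs) -> EmbeddingBackend:
    if name == "surrogate":
        return SurrogateBackend(**kwargs)
    if name == "yamnet":
        return YamnetBackend(**kwargs)
    raise ValueError(f"unknown embedding backend: {name!r}")


def embed(waveform: np.ndarray, backend: EmbeddingBackend) -> Embedding:
    """Embed a 15,600-sample tiled waveform with the given backend."""
    return backend.embed(waveform)
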