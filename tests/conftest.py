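import numpy as np
import pytest

from breathkit.decision import BreathPhase
from breathkit.embedding import SurrogateBackend
from breathkit.frontend import tile_frame

PHASE_ORDER = [BreathPhase.EXHALATION, BreathPhase.INHALATION, BreathPhase.NONBREATHING]


@pytest.fixture(scope="session")
def surrogate():
    return SurrogateBackend()


@pytest.fixture(scope="session")
def embed_frames(surrogate):
    """Embed a list of Frames into an (n, 1024) matrix."""

    def _embed(frames):
        return np.stack([surrogate.embed(tile_frame(f)).vector for f in frames])

    return _embed


def one_hot(phases):
    Y = np.zeros((len(phases), 3))
    for i, p in enumerate(phases):
        Y[i, PHASE_ORDER.index(p)] = 1.0
    return Y
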