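import numpy as np
import pytest

from emonet import (
    CharacterRoster,
    EmotionNetwork,
    RaterMatrix,
    RaterMatrixSet,
)


@pytest.fixture
def roster():
    return CharacterRoster(("Vincent Vega", "Butch Coolidge", "Mia Wallace"))


@pytest.fixture
def small_set(roster):
    """3 raters x 2 emotions; judges agree perfectly on two cells, disagree
    wildly on one."""
    n = len(roster)
    emotions = ("fear", "joy")
    raters = ("r1", "r2", "r3")
    base = {
        "fear": np.array([[0, 7, 0], [0, 0, 0], [0, 4, 0]], dtype=float),
        "joy": np.array([[0, 0, 6], [0, 0, 0], [0, 0, 0]], dtype=float),
    }
    matrices = {}
    for rater in raters:
        for emotion in emotions:
            values = base[emotion].copy()
            if emotion == "fear" and rater == "r3":
                values[0, 1] = 1.0  # one dissenting judge on Vincent -> Butch
            matrices[(rater, emotion)] = RaterMatrix(
                rater_id=rater, emotion=emotion, roster=roster, values=values
            )
    return RaterMatrixSet(
        roster=roster, emotions=emotions, raters=raters, matrices=matrices
    )


def random_network(rng, n_nodes=None, p=0.3, allow_self_loops=True):
    """Random weighted digraph over a generic roster (test utility)."""
    if n_nodes is None:
        n_nodes = int(rng.integers(1, 20))
    names = tuple(f"N{i}" for i in range(n_nodes))
    roster = CharacterRoster(names)
    edges = {}
    for i in range(n_nodes):
        for j in range(n_nodes):
            if not allow_self_loops and i == j:
                continue
            if rng.random() < p:
                edges[(names[i], names[j])] = float(rng.uniform(0.5, 20.0))
    return EmotionNetwork(emotion="anger", roster=roster, edges=edges)
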