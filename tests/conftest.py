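import numpy as np
import pandas as pd
import pytest

from memdyn.montage import make_sphere_montage
from memdyn.synthetic import (
    BehaviorParams,
    BehaviorSession,
    TaskDesign,
    WordPool,
    generate_word_pool,
    simulate_behavior,
)


@pytest.fixture(scope="session")
def pool():
    return generate_word_pool(seed=11)


@pytest.fixture(scope="session")
def small_design():
    return TaskDesign(n_sessions=3, lists_per_session=5)


@pytest.fixture(scope="session")
def behavior(small_design, pool):
    return simulate_behavior(small_design, pool, BehaviorParams(), seed=7)


@pytest.fixture(scope="session")
def montage8():
    return make_sphere_montage(8)


@pytest.fixture(scope="session")
def montage64():
    return make_sphere_montage(64, n_periocular=4)


def make_session(presentation_words, recall_rows, participant="T", session=0):
    """Hand-build a one-or-more-list BehaviorSession.

    ``presentation_words``: dict list -> sequence of word ids (serial order).
    ``recall_rows``: list of (list, onset_s, word_id, response_type).
    """
    pres = []
    for li, words in presentation_words.items():
        for j, w in enumerate(words):
            pres.append((li, j + 1, int(w)))
    recalls = []
    counters: dict[int, int] = {}
    for li, onset, w, rtype in recall_rows:
        counters[li] = counters.get(li, 0) + 1
        recalls.append((li, counters[li], float(onset), int(w), rtype))
    return BehaviorSession(
        participant=participant,
        session=session,
        presentations=pd.DataFrame(
            pres, columns=["list", "serial_position", "word_id"]
        ),
        recalls=pd.DataFrame(
            recalls,
            columns=[
                "list", "output_position", "onset_time_s", "word_id",
                "response_type",
            ],
        ),
    )


def make_pool(embeddings):
    """WordPool with hand-chosen (already unit-norm) embeddings."""
    emb = np.asarray(embeddings, dtype=float)
    emb = emb / np.linalg.norm(emb, axis=1, keepdims=True)
    return WordPool(embeddings=emb, n_words=len(emb), seed=0)
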