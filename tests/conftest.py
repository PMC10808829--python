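import math

import numpy as np
import pandas as pd
import pytest

from sretlca import CohortSpec, default_word_bank
from sretlca.simulate import ENDORSE, REJECT
from sretlca.wordbank import NEGATIVE, POSITIVE


@pytest.fixture(scope="session")
def bank():
    return default_word_bank()


def flat_rt_model(K, mu=math.log(800.0), sigma=0.3):
    cell = {
        (NEGATIVE, ENDORSE): (mu, sigma),
        (NEGATIVE, REJECT): (mu, sigma),
        (POSITIVE, ENDORSE): (mu, sigma),
        (POSITIVE, REJECT): (mu, sigma),
    }
    return [dict(cell) for _ in range(K)]


def flat_recall_model(K, p_endorsed=0.3, p_other=0.1):
    cell = {
        (NEGATIVE, True): p_endorsed,
        (NEGATIVE, False): p_other,
        (POSITIVE, True): p_endorsed,
        (POSITIVE, False): p_other,
    }
    return [dict(cell) for _ in range(K)]


def make_spec(endorse_probs, weights=None, n=20, seed=0, group="clinical", **overrides):
    """Minimal valid CohortSpec around a given endorsement-probability matrix."""
    P = np.atleast_2d(np.asarray(endorse_probs, dtype=float))
    K = P.shape[0]
    weights = np.full(K, 1.0 / K) if weights is None else np.asarray(weights, float)
    fields = dict(
        group=group,
        n_participants=n,
        K_true=K,
        mixing_weights=weights,
        endorse_probs=P,
        rt_model=flat_rt_model(K),
        recall_model=flat_recall_model(K),
        ids_model=[(20.0, 8.0)] * K,
        deq_model=[((36.0, 6.0), (40.0, 7.0))] * K,
        diagnosis_model=[{"depression": 0.6, "anxiety": 0.4}] * K,
        seed=seed,
    )
    fields.update(overrides)
    return CohortSpec(**fields)


def block_probs_3class(J=90, hi=0.9, lo=0.1):
    """Three well-separated classes: high blocks on thirds of the words."""
    P = np.full((3, J), lo)
    third = J // 3
    P[0, :third] = hi
    P[1, third:2 * third] = hi
    P[2, 2 * third:] = hi
    return P


def participant_trials(responses, rts=None, pid=0):
    """Build a single participant's trial frame from a response mapping.

    ``responses``: dict word_id -> True (endorse) / False (reject).
    """
    word_ids = sorted(responses)
    if rts is None:
        rts = {w: 700.0 for w in word_ids}
    return pd.DataFrame(
        {
            "participant_id": pid,
            "word_id": word_ids,
            "response": [ENDORSE if responses[w] else REJECT for w in word_ids],
            "rt_ms": [float(rts[w]) for w in word_ids],
        }
    )
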