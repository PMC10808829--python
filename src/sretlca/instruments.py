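"""Questionnaire scoring and internal-consistency reliability.

Two self-report instruments are scored:

* IDS-SR-30 — 30 items rated 0-3 measuring depressive symptom severity.
  The total sums 28 of the 30 items: the appetite increase/decrease pair and
  the weight increase/decrease pair each contribute once, because the two
  members of a pair describe mutually exclusive symptom directions. The
  scored member of each pair is taken as the maximum of the two (the
  standard convention when exactly one applies). Totals range 0-84 and a
  total of 18 or more flags the respondent as symptomatic.

* RecDEQ — 19 items rated 1-7 yielding two plain sums: dependency
  (anaclitic, 9 items) and self-criticism (introjective, 10 items).

Reliability is Cronbach's alpha on raw (non-standardized) item scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError

IDS_SYMPTOMATIC_CUTOFF = 18

# 0-based item positions of the appetite and weight increase/decrease pairs,
# following the standard IDS-SR item order (items 11/12 and 13/14, 1-based).
DEFAULT_APPETITE_PAIR = (10, 11)
DEFAULT_WEIGHT_PAIR = (12, 13)

# Default RecDEQ scale map: 9 dependency items then 10 self-criticism items.
DEFAULT_DEQ_MAP = {
    "dependency": tuple(range(0, 9)),
    "self_criticism": tuple(range(9, 19)),
}


@dataclass(frozen=True)
class IdsScore:
    total: int
    symptomatic: bool


@dataclass(frozen=True)
class DeqScore:
    dependency: int
    self_criticism: int


def score_ids30(
    items,
    appetite_pair: tuple[int, int] = DEFAULT_APPETITE_PAIR,
    weight_pair: tuple[int, int] = DEFAULT_WEIGHT_PAIR,
) -> IdsScore:
    """Score a single IDS-SR-30 item vector.

    Parameters
    ----------
    items
        Sequence of 30 integers, each in {0, 1, 2, 3}.
    appetite_pair, weight_pair
        0-based positions of the increase/decrease item pairs; each pair
        contributes max(pair) to the total, so 28 items are summed.
    """
    arr = np.asarray(items)
    if arr.shape != (30,):
        raise DataError(f"score_ids30: expected 30 items, got shape {arr.shape}")
    bad = np.nonzero((arr < 0) | (arr > 3) | (arr != np.floor(arr)))[0]
    if bad.size:
        raise DataError(f"score_ids30: items out of range 0-3 at positions {bad.tolist()}")
    arr = arr.astype(int)
    pairs = set(appetite_pair) | set(weight_pair)
    if len(pairs) != 4:
        raise DataError("score_ids30: appetite/weight pair positions must be 4 distinct items")
    singles = [i for i in range(30) if i not in pairs]
    total = int(
        arr[singles].sum()
        + max(arr[appetite_pair[0]], arr[appetite_pair[1]])
        + max(arr[weight_pair[0]], arr[weight_pair[1]])
    )
    return IdsScore(total=total, symptomatic=total >= IDS_SYMPTOMATIC_CUTOFF)


def score_ids30_matrix(
    items: np.ndarray,
    appetite_pair: tuple[int, int] = DEFAULT_APPETITE_PAIR,
    weight_pair: tuple[int, int] = DEFAULT_WEIGHT_PAIR,
) -> np.ndarray:
    """Vectorized IDS totals for an n x 30 item matrix."""
    arr = np.asarray(items)
    if arr.ndim != 2 or arr.shape[1] != 30:
        raise DataError("score_ids30_matrix: expected an n x 30 matrix")
    if ((arr < 0) | (arr > 3)).any():
        raise DataError("score_ids30_matrix: items out of range 0-3")
    arr = arr.astype(int)
    pairs = set(appetite_pair) | set(weight_pair)
    singles = [i for i in range(30) if i not in pairs]
    return (
        arr[:, singles].sum(axis=1)
        + np.maximum(arr[:, appetite_pair[0]], arr[:, appetite_pair[1]])
        + np.maximum(arr[:, weight_pair[0]], arr[:, weight_pair[1]])
    )


def score_recdeq(items, scale_map: dict = None) -> DeqScore:
    """Score a 19-item RecDEQ vector into dependency and self-criticism sums."""
    arr = np.asarray(items)
    if arr.shape != (19,):
        raise DataError(f"score_recdeq: expected 19 items, got shape {arr.shape}")
    bad = np.nonzero((arr < 1) | (arr > 7) | (arr != np.floor(arr)))[0]
    if bad.size:
        raise DataError(f"score_recdeq: items out of range 1-7 at positions {bad.tolist()}")
    arr = arr.astype(int)
    scale_map = scale_map or DEFAULT_DEQ_MAP
    dep = scale_map["dependency"]
    crit = scale_map["self_criticism"]
    if len(dep) != 9 or len(crit) != 10 or set(dep) & set(crit):
        raise DataError("score_recdeq: scale map must assign 9 disjoint dependency and 10 self-criticism items")
    return DeqScore(dependency=int(arr[list(dep)].sum()), self_criticism=int(arr[list(crit)].sum()))


def cronbach_alpha(item_scores) -> float:
    """Cronbach's alpha for an n-respondents x k-items score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of the total),
    with sample variances (denominator n-1). Undefined when the total score
    has zero variance.
    """
    X = np.asarray(item_scores, dtype=float)
    if X.ndim != 2:
        raise DataError("cronbach_alpha: expected a 2-D matrix")
    n, k = X.shape
    if n < 2 or k < 2:
        raise DataError("cronbach_alpha: need at least 2 respondents and 2 items")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DataError("cronbach_alpha: total score has zero variance")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))
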