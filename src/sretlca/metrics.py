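"""Per-participant SRET feature extraction.

Three families of metrics are computed from trial-level SRET data:

* Endorsement counts and rates — the number of positive/negative words a
  participant endorsed; rates divide by the total number of words presented
  (all valences), which is the published definition. Per-valence rates
  (count over words of that valence) are exposed as auxiliary outputs.

* RT bias per valence —
  (mean RT of endorsement - mean RT of rejection) / mean RT over all trials.
  Missing when the participant has no endorsements or no rejections of that
  valence.

* Recall bias — share of correctly recalled words of each valence among all
  correctly recalled words, plus their difference (negative minus positive).
  Missing when nothing was recalled.

Missing features are NaN; downstream statistics drop missing cases listwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError
from .simulate import ENDORSE
from .wordbank import WordBank, NEGATIVE, POSITIVE


@dataclass
class SretFeatureVector:
    """All SRET-derived features for one participant."""

    participant_id: object
    n_pos_endorsed: int
    n_neg_endorsed: int
    pos_rate: float
    neg_rate: float
    pos_rate_valence: float        # auxiliary: count / words of that valence
    neg_rate_valence: float
    pos_rt_bias: float             # NaN when undefined
    neg_rt_bias: float
    pos_recall_bias: float
    neg_recall_bias: float
    recall_bias_diff: float        # negative minus positive recall bias
    endorsement_vector: np.ndarray


@dataclass
class EndorsementMatrix:
    """Binary participants x words endorsement matrix used as clustering input.

    Rows are sorted by participant id; columns follow word_id order.
    """

    X: np.ndarray
    participant_ids: np.ndarray
    word_ids: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def J(self) -> int:
        return self.X.shape[1]

    def to_frame(self, bank: WordBank = None) -> pd.DataFrame:
        cols = list(bank.text) if bank is not None else [str(w) for w in self.word_ids]
        frame = pd.DataFrame(self.X, columns=cols)
        frame.insert(0, "participant_id", self.participant_ids)
        return frame

    def write_csv(self, path, bank: WordBank = None) -> None:
        self.to_frame(bank).to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EndorsementMatrix":
        frame = frame.sort_values("participant_id").reset_index(drop=True)
        X = frame.drop(columns=["participant_id"]).to_numpy()
        if not np.isin(X, (0, 1)).all():
            raise DataError("EndorsementMatrix: entries must be 0/1 with no missing values")
        return cls(
            X=X.astype(np.int8),
            participant_ids=frame["participant_id"].to_numpy(),
            word_ids=np.arange(X.shape[1]),
        )

    @classmethod
    def read_csv(cls, path) -> "EndorsementMatrix":
        return cls.from_frame(pd.read_csv(path))


def _check_trials(trials: pd.DataFrame, bank: WordBank) -> pd.DataFrame:
    ids = trials["word_id"].to_numpy()
    unknown = np.setdiff1d(ids, bank.word_ids)
    if unknown.size:
        raise DataError(f"trials reference unknown word_ids {unknown.tolist()}")
    dup = trials["word_id"][trials["word_id"].duplicated()].unique()
    if dup.size:
        raise DataError(f"duplicate trials for word_ids {sorted(dup.tolist())}")
    return trials


def endorsement_features(trials: pd.DataFrame, bank: WordBank) -> dict:
    """Endorsement counts and rates for one participant's trials.

    Rates use the total number of words presented as denominator; the
    per-valence variants are returned alongside under ``*_rate_valence``.
    """
    trials = _check_trials(trials, bank)
    valence = bank.valence_of(trials["word_id"])
    endorsed = (trials["response"] == ENDORSE).to_numpy()
    n_total = len(trials)
    n_pos_presented = int((valence == POSITIVE).sum())
    n_neg_presented = int((valence == NEGATIVE).sum())
    n_pos = int((endorsed & (valence == POSITIVE)).sum())
    n_neg = int((endorsed & (valence == NEGATIVE)).sum())
    return {
        "n_pos_endorsed": n_pos,
        "n_neg_endorsed": n_neg,
        "pos_rate": n_pos / n_total if n_total else np.nan,
        "neg_rate": n_neg / n_total if n_total else np.nan,
        "pos_rate_valence": n_pos / n_pos_presented if n_pos_presented else np.nan,
        "neg_rate_valence": n_neg / n_neg_presented if n_neg_presented else np.nan,
    }


def rt_bias(trials: pd.DataFrame, valence: str, bank: WordBank) -> float:
    """Normalized endorse-minus-reject RT difference for one valence.

    Returns NaN when either the endorsement or rejection mean is undefined.
    """
    trials = _check_trials(trials, bank)
    rt = trials["rt_ms"].to_numpy(dtype=float)
    if (rt <= 0).any():
        bad = trials["word_id"][rt <= 0].tolist()
        raise DataError(f"non-positive rt_ms for word_ids {bad}")
    word_val = bank.valence_of(trials["word_id"])
    endorsed = (trials["response"] == ENDORSE).to_numpy()
    in_val = word_val == valence
    rt_endorse = rt[in_val & endorsed]
    rt_reject = rt[in_val & ~endorsed]
    if rt_endorse.size == 0 or rt_reject.size == 0:
        return np.nan
    return float((rt_endorse.mean() - rt_reject.mean()) / rt.mean())


def recall_bias(recalls: pd.DataFrame, bank: WordBank, endorsed_only: bool = False,
                trials: pd.DataFrame = None) -> dict:
    """Recall-bias ratios for one participant's correctly recalled words.

    ``pos_bias`` and ``neg_bias`` divide the recalled count of each valence
    by the total recalled; ``diff`` is neg_bias - pos_bias. All NaN when no
    words were recalled. With ``endorsed_only=True`` the ratios are computed
    over recalled words the participant also endorsed (an optional variant;
    requires ``trials``).
    """
    ids = recalls["word_id"].to_numpy()
    unknown = np.setdiff1d(ids, bank.word_ids)
    if unknown.size:
        raise DataError(f"recalled word_ids not in bank: {unknown.tolist()}")
    if endorsed_only:
        if trials is None:
            raise DataError("recall_bias: endorsed_only=True requires trials")
        endorsed_ids = trials.loc[trials["response"] == ENDORSE, "word_id"].to_numpy()
        ids = ids[np.isin(ids, endorsed_ids)]
    if ids.size == 0:
        return {"pos_recall_bias": np.nan, "neg_recall_bias": np.nan, "recall_bias_diff": np.nan}
    val = bank.valence_of(ids)
    pos = float((val == POSITIVE).mean())
    neg = float((val == NEGATIVE).mean())
    return {"pos_recall_bias": pos, "neg_recall_bias": neg, "recall_bias_diff": neg - pos}


def build_endorsement_matrix(trials: pd.DataFrame, bank: WordBank) -> EndorsementMatrix:
    """Pivot all participants' trials into the binary clustering input.

    Every participant must have exactly one trial per bank word; no
    imputation is performed.
    """
    pivot = trials.pivot_table(
        index="participant_id", columns="word_id",
        values="response", aggfunc="count",
    )
    if (pivot.to_numpy(na_value=0) > 1).any():
        raise DataError("duplicate participant x word trials in endorsement data")
    full = trials.assign(endorsed=(trials["response"] == ENDORSE).astype(np.int8)).pivot(
        index="participant_id", columns="word_id", values="endorsed"
    )
    full = full.reindex(columns=bank.word_ids)
    if full.isna().any().any():
        missing = full.index[full.isna().any(axis=1)].tolist()
        raise DataError(f"participants missing word trials (no imputation): {missing}")
    full = full.sort_index()
    return EndorsementMatrix(
        X=full.to_numpy(dtype=np.int8),
        participant_ids=full.index.to_numpy(),
        word_ids=np.asarray(bank.word_ids),
    )


def compute_features(trials: pd.DataFrame, recalls: pd.DataFrame, bank: WordBank,
                     endorsed_only_recall: bool = False) -> pd.DataFrame:
    """One row of SRET features per participant, sorted by participant id."""
    rows = []
    recall_groups = dict(tuple(recalls.groupby("participant_id"))) if len(recalls) else {}
    empty = recalls.iloc[0:0] if len(recalls) else pd.DataFrame({"participant_id": [], "word_id": []})
    for pid, part_trials in trials.groupby("participant_id"):
        feats = endorsement_features(part_trials, bank)
        part_recalls = recall_groups.get(pid, empty)
        rb = recall_bias(part_recalls, bank, endorsed_only=endorsed_only_recall,
                         trials=part_trials if endorsed_only_recall else None)
        rows.append(
            {
                "participant_id": pid,
                **feats,
                "pos_rt_bias": rt_bias(part_trials, POSITIVE, bank),
                "neg_rt_bias": rt_bias(part_trials, NEGATIVE, bank),
                **rb,
            }
        )
    return pd.DataFrame(rows).sort_values("participant_id").reset_index(drop=True)
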