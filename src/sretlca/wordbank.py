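"""Word bank for the self-referential encoding task.

A word bank is the list of valenced adjectives shown during the endorsement
phase. The default bank has 90 words: 48 negative and 42 positive, matching
the overlap set used for clustering. The published study's exact adjective
list lives in supplementary material that is not redistributed here, so the
default text labels are a synthetic stand-in: they include the top-endorsed
adjectives printed in the results plus generic valenced fillers. All
computations depend only on word ids and valence labels, never on the text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError

NEGATIVE = "negative"
POSITIVE = "positive"

_NEGATIVE_WORDS = [
    "awful", "coward", "inefficient", "abandoned", "stupid", "bad", "ugly",
    "cruel", "fretful", "unsparkling", "uncheery", "impractical",
    "high-strung", "timid", "shy", "worrying", "introverted", "nervous",
    "boring", "anxious", "quiet", "hurt", "loss", "meek", "upset", "ill",
    "accused", "unkind", "angry", "burdened", "victim", "tricky", "useless",
    "uncharitable", "unstable", "lonely", "helpless", "worthless", "gloomy",
    "irritable", "insecure", "moody", "weak", "careless", "hopeless",
    "bitter", "tense", "fearful",
]

_POSITIVE_WORDS = [
    "enthusiastic", "successful", "unnervous", "lively", "exciting",
    "winner", "happy", "cheerful", "nice", "relaxed", "secure", "unworrying",
    "self-confident", "at ease", "calm", "popular", "attractive", "well-off",
    "leader", "self-assured", "neighbourly", "lucky", "stable", "smart",
    "inquisitive", "friendly", "warm", "capable", "honest", "generous",
    "patient", "optimistic", "energetic", "confident", "reliable",
    "creative", "sociable", "brave", "kind", "thoughtful", "cheery",
    "steady",
]

assert len(_NEGATIVE_WORDS) == 48 and len(_POSITIVE_WORDS) == 42


@dataclass(frozen=True)
class WordBank:
    """Immutable table of (word_id, text, valence).

    Word ids are unique and contiguous from 0.
    """

    text: tuple[str, ...]
    valence: tuple[str, ...]
    _frame: pd.DataFrame = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if len(self.text) != len(self.valence):
            raise ConfigError("WordBank: text and valence must have equal length")
        bad = sorted(set(self.valence) - {NEGATIVE, POSITIVE})
        if bad:
            raise ConfigError(f"WordBank: invalid valence labels {bad}")
        frame = pd.DataFrame(
            {
                "word_id": np.arange(len(self.text), dtype=int),
                "text": list(self.text),
                "valence": list(self.valence),
            }
        )
        object.__setattr__(self, "_frame", frame)

    @property
    def n_words(self) -> int:
        return len(self.text)

    @property
    def word_ids(self) -> np.ndarray:
        return np.arange(self.n_words, dtype=int)

    @property
    def is_negative(self) -> np.ndarray:
        return np.asarray([v == NEGATIVE for v in self.valence])

    @property
    def is_positive(self) -> np.ndarray:
        return np.asarray([v == POSITIVE for v in self.valence])

    @property
    def n_negative(self) -> int:
        return int(self.is_negative.sum())

    @property
    def n_positive(self) -> int:
        return int(self.is_positive.sum())

    def valence_of(self, word_ids) -> np.ndarray:
        """Valence labels for an array of word ids."""
        ids = np.asarray(word_ids, dtype=int)
        if ids.size and (ids.min() < 0 or ids.max() >= self.n_words):
            raise ConfigError("WordBank.valence_of: word_id out of range")
        return np.asarray(self.valence, dtype=object)[ids]

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "WordBank":
        frame = frame.sort_values("word_id").reset_index(drop=True)
        ids = frame["word_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ConfigError("WordBank: word_ids must be unique and contiguous from 0")
        return cls(text=tuple(frame["text"]), valence=tuple(frame["valence"]))


def default_word_bank() -> WordBank:
    """The 90-word default bank: 48 negative followed by 42 positive words."""
    text = tuple(_NEGATIVE_WORDS + _POSITIVE_WORDS)
    valence = tuple([NEGATIVE] * 48 + [POSITIVE] * 42)
    return WordBank(text=text, valence=valence)
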