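"""Synthetic SRET cohort generator with known latent-class structure.

Each participant belongs to a latent class drawn from the mixing weights.
Conditional on the class, word endorsements are independent Bernoulli draws
with class-specific per-word probabilities; reaction times are log-normal
per (class, valence, response) cell; free recall is per-word Bernoulli with
probability depending on (valence, endorsed) and class; depressive-symptom
items, RecDEQ items, diagnosis and sex are drawn per class/group. A single
RNG stream seeded once produces the whole cohort, so one integer reproduces
it bit for bit.

``default_paperlike_spec`` builds two 5-class specifications (a clinical-like
and a non-clinical-like group) whose endorsement probabilities follow a
0.9/0.1 block structure per valence; the block widths are calibrated so each
class's expected positive/negative endorsement counts match the published
cluster means, giving the strong but realistic separation the recovery
properties assume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .instruments import score_ids30_matrix
from .wordbank import WordBank, default_word_bank, NEGATIVE, POSITIVE

ENDORSE = "endorse"
REJECT = "reject"

DIAGNOSIS_LABELS = ("anxiety", "depression", "adjustment", "bipolar", "ocd", "other")


@dataclass
class CohortSpec:
    """Full generative specification for one participant group."""

    group: str
    n_participants: int
    K_true: int
    mixing_weights: np.ndarray          # (K,)
    endorse_probs: np.ndarray           # (K, J) in [0, 1]
    rt_model: list                      # K dicts {(valence, response): (mu_log, sigma)}
    recall_model: list                  # K dicts {(valence, endorsed): prob}
    ids_model: list                     # K tuples (mean, sd) of the severity target
    deq_model: list                     # K tuples ((dep_mean, dep_sd), (crit_mean, crit_sd))
    diagnosis_model: list               # K dicts {label: prob}
    seed: int
    p_female: float = 0.5
    word_bank: WordBank = field(default_factory=default_word_bank)
    class_names: tuple = ()
    id_offset: int = 0

    def __post_init__(self) -> None:
        self.mixing_weights = np.asarray(self.mixing_weights, dtype=float)
        self.endorse_probs = np.asarray(self.endorse_probs, dtype=float)
        if not self.class_names:
            self.class_names = tuple(f"class{k}" for k in range(self.K_true))

    def validate(self) -> None:
        """Raise ConfigError naming the first offending field."""
        if self.n_participants <= 0:
            raise ConfigError("n_participants: must be a positive integer")
        if self.K_true <= 0:
            raise ConfigError("K_true: must be a positive integer")
        if self.mixing_weights.shape != (self.K_true,):
            raise ConfigError("mixing_weights: length must equal K_true")
        if (self.mixing_weights < 0).any():
            raise ConfigError("mixing_weights: entries must be non-negative")
        if abs(self.mixing_weights.sum() - 1.0) > 1e-12:
            raise ConfigError("mixing_weights: must sum to 1 within 1e-12")
        J = self.word_bank.n_words
        if self.endorse_probs.shape != (self.K_true, J):
            raise ConfigError("endorse_probs: shape must be (K_true, n_words)")
        if ((self.endorse_probs < 0) | (self.endorse_probs > 1)).any():
            raise ConfigError("endorse_probs: entries must lie in [0, 1]")
        if not 0 <= self.p_female <= 1:
            raise ConfigError("p_female: must lie in [0, 1]")
        for name, model, keys in (
            ("rt_model", self.rt_model, [(v, r) for v in (NEGATIVE, POSITIVE) for r in (ENDORSE, REJECT)]),
            ("recall_model", self.recall_model, [(v, e) for v in (NEGATIVE, POSITIVE) for e in (True, False)]),
        ):
            if len(model) != self.K_true:
                raise ConfigError(f"{name}: need one entry per class")
            for k, cell in enumerate(model):
                for key in keys:
                    if key not in cell:
                        raise ConfigError(f"{name}[{k}]: missing cell {key}")
        for k, cell in enumerate(self.rt_model):
            for key, (mu, sigma) in cell.items():
                if sigma < 0:
                    raise ConfigError(f"rt_model[{k}]{key}: sigma must be >= 0")
        for k, cell in enumerate(self.recall_model):
            for key, p in cell.items():
                if not 0 <= p <= 1:
                    raise ConfigError(f"recall_model[{k}]{key}: probability must lie in [0, 1]")
        for name, model in (("ids_model", self.ids_model), ("deq_model", self.deq_model)):
            if len(model) != self.K_true:
                raise ConfigError(f"{name}: need one entry per class")
        for k, (m, sd) in enumerate(self.ids_model):
            if sd < 0:
                raise ConfigError(f"ids_model[{k}]: sd must be >= 0")
        for k, ((dm, ds), (cm, cs)) in enumerate(self.deq_model):
            if ds < 0 or cs < 0:
                raise ConfigError(f"deq_model[{k}]: sds must be >= 0")
        if len(self.diagnosis_model) != self.K_true:
            raise ConfigError("diagnosis_model: need one entry per class")
        for k, dist in enumerate(self.diagnosis_model):
            probs = np.asarray(list(dist.values()), dtype=float)
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigError(f"diagnosis_model[{k}]: probabilities must be non-negative and sum to 1")


@dataclass
class Cohort:
    """Generated cohort: trial-level data plus participant metadata and truth."""

    trials: pd.DataFrame        # participant_id, word_id, response, rt_ms
    recalls: pd.DataFrame       # participant_id, word_id (correctly recalled)
    participants: pd.DataFrame  # participant_id, group, sex, diagnosis, latent_class, scores
    truth: pd.DataFrame         # participant_id, latent_class, class_name
    ids_items: pd.DataFrame     # participant_id + 30 item columns
    deq_items: pd.DataFrame     # participant_id + 19 item columns


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full cohort from ``spec``. Identical seed gives identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, J, K = spec.n_participants, spec.word_bank.n_words, spec.K_true
    val_idx = spec.word_bank.is_positive.astype(int)  # 0 = negative, 1 = positive
    valences = (NEGATIVE, POSITIVE)

    z = rng.choice(K, size=n, p=spec.mixing_weights)
    endorsed = rng.random((n, J)) < spec.endorse_probs[z]

    # Log-normal RTs per (class, valence, response) cell.
    mu_tab = np.empty((K, 2, 2))
    sd_tab = np.empty((K, 2, 2))
    for k in range(K):
        for vi, v in enumerate(valences):
            for ri, r in enumerate((REJECT, ENDORSE)):
                mu_tab[k, vi, ri], sd_tab[k, vi, ri] = spec.rt_model[k][(v, r)]
    resp_idx = endorsed.astype(int)
    mu = mu_tab[z[:, None], val_idx[None, :], resp_idx]
    sd = sd_tab[z[:, None], val_idx[None, :], resp_idx]
    rt_ms = np.exp(mu + sd * rng.standard_normal((n, J)))

    rec_tab = np.empty((K, 2, 2))
    for k in range(K):
        for vi, v in enumerate(valences):
            for ei, e in enumerate((False, True)):
                rec_tab[k, vi, ei] = spec.recall_model[k][(v, e)]
    recalled = rng.random((n, J)) < rec_tab[z[:, None], val_idx[None, :], resp_idx]

    sex = np.where(rng.random(n) < spec.p_female, "female", "male")

    ids_means = np.asarray([m for m, _ in spec.ids_model])
    ids_sds = np.asarray([s for _, s in spec.ids_model])
    severity = np.clip(rng.normal(ids_means[z], ids_sds[z]), 0.0, 84.0)
    ids_items = rng.binomial(3, (severity / 84.0)[:, None] * np.ones((1, 30)))
    ids_total = score_ids30_matrix(ids_items)

    dep_mean = np.asarray([d[0][0] for d in spec.deq_model])
    dep_sd = np.asarray([d[0][1] for d in spec.deq_model])
    crit_mean = np.asarray([d[1][0] for d in spec.deq_model])
    crit_sd = np.asarray([d[1][1] for d in spec.deq_model])
    dep_target = np.clip(rng.normal(dep_mean[z], dep_sd[z]), 9, 63)
    crit_target = np.clip(rng.normal(crit_mean[z], crit_sd[z]), 10, 70)
    dep_items = np.clip(
        np.rint(rng.normal((dep_target / 9.0)[:, None], 1.3, (n, 9))), 1, 7
    ).astype(int)
    crit_items = np.clip(
        np.rint(rng.normal((crit_target / 10.0)[:, None], 1.3, (n, 10))), 1, 7
    ).astype(int)
    deq_items = np.concatenate([dep_items, crit_items], axis=1)

    labels = list(spec.diagnosis_model[0].keys())
    diag_probs = np.asarray([[spec.diagnosis_model[k][lab] for lab in labels] for k in range(K)])
    cum = np.cumsum(diag_probs, axis=1)
    u = rng.random(n)
    diag_idx = (u[:, None] > cum[z]).sum(axis=1)
    diagnosis = np.asarray(labels, dtype=object)[diag_idx]

    pid = spec.id_offset + np.arange(n)
    trials = pd.DataFrame(
        {
            "participant_id": np.repeat(pid, J),
            "word_id": np.tile(np.arange(J), n),
            "response": np.where(endorsed.ravel(), ENDORSE, REJECT),
            "rt_ms": rt_ms.ravel(),
        }
    )
    rec_rows = np.nonzero(recalled)
    recalls = pd.DataFrame(
        {
            "participant_id": pid[rec_rows[0]],
            "word_id": rec_rows[1],
        }
    )
    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "group": spec.group,
            "sex": sex,
            "diagnosis": diagnosis,
            "latent_class": z,
            "ids_total": ids_total,
            "deq_dependency": dep_items.sum(axis=1),
            "deq_selfcriticism": crit_items.sum(axis=1),
        }
    )
    truth = pd.DataFrame(
        {
            "participant_id": pid,
            "latent_class": z,
            "class_name": np.asarray(spec.class_names, dtype=object)[z],
        }
    )
    ids_frame = pd.DataFrame(ids_items, columns=[f"ids_{i + 1:02d}" for i in range(30)])
    ids_frame.insert(0, "participant_id", pid)
    deq_frame = pd.DataFrame(deq_items, columns=[f"deq_{i + 1:02d}" for i in range(19)])
    deq_frame.insert(0, "participant_id", pid)
    return Cohort(trials, recalls, participants, truth, ids_frame, deq_frame)


def _block_probs(bank: WordBank, blocks, hi: float = 0.9, lo: float = 0.1) -> np.ndarray:
    """Per-class probabilities from (neg_slice, pos_slice) high-endorsement blocks."""
    neg_ids = np.nonzero(bank.is_negative)[0]
    pos_ids = np.nonzero(bank.is_positive)[0]
    P = np.full((len(blocks), bank.n_words), lo)
    for k, (neg_sl, pos_sl) in enumerate(blocks):
        P[k, neg_ids[neg_sl]] = hi
        P[k, pos_ids[pos_sl]] = hi
    return P


def _rt_cells(neg_bias: float, pos_bias: float, base: float = math.log(1500.0), sigma: float = 0.35) -> dict:
    """RT cells realizing approximate target RT-bias values via log-mean shifts."""
    return {
        (NEGATIVE, ENDORSE): (base + neg_bias / 2.0, sigma),
        (NEGATIVE, REJECT): (base - neg_bias / 2.0, sigma),
        (POSITIVE, ENDORSE): (base + pos_bias / 2.0, sigma),
        (POSITIVE, REJECT): (base - pos_bias / 2.0, sigma),
    }


def _recall_cells(neg_endorsed: float, pos_endorsed: float, base: float = 0.10) -> dict:
    return {
        (NEGATIVE, True): neg_endorsed,
        (NEGATIVE, False): base,
        (POSITIVE, True): pos_endorsed,
        (POSITIVE, False): base,
    }


_CLINICAL_CLASSES = ("neurotic", "extraverted", "anxious_to_please", "self_critical", "conscientious")
_NONCLINICAL_CLASSES = ("self_confident", "low_endorsement", "non_neurotic", "neurotic", "high_endorsement")

# High-endorsement blocks (slices into the valence-sorted word lists). Widths
# chosen so expected counts under 0.9/0.1 match the published cluster means.
_CLINICAL_BLOCKS = [
    (slice(0, 32), slice(0, 16)),    # neurotic:        ~30 neg, ~17 pos
    (slice(16, 32), slice(0, 24)),   # extraverted:     ~18 neg, ~23 pos
    (slice(0, 20), slice(30, 42)),   # anxious_to_please: ~21 neg, ~14 pos
    (slice(12, 40), slice(16, 22)),  # self_critical:   ~27 neg,  ~9 pos
    (slice(42, 48), slice(6, 22)),   # conscientious:   ~10 neg, ~17 pos
]
_NONCLINICAL_BLOCKS = [
    (slice(0, 2), slice(0, 40)),     # self_confident:   ~6 neg, ~36 pos
    (slice(2, 12), slice(0, 20)),    # low_endorsement: ~13 neg, ~20 pos
    (slice(12, 17), slice(10, 40)),  # non_neurotic:     ~9 neg, ~28 pos
    (slice(17, 46), slice(23, 40)),  # neurotic:        ~28 neg, ~18 pos
    (slice(20, 43), slice(0, 30)),   # high_endorsement: ~23 neg, ~28 pos
]

_CLINICAL_WEIGHTS = np.asarray([17, 24, 13, 49, 16], dtype=float) / 119.0
_NONCLINICAL_WEIGHTS = np.asarray([23, 21, 27, 21, 23], dtype=float) / 115.0

# (neg_rt_bias, pos_rt_bias) targets per class; published cells where printed,
# zero elsewhere.
_CLINICAL_RT = [(-0.10, 0.00), (0.00, -0.50), (0.00, 0.00), (-0.60, 0.15), (0.15, 0.00)]
_NONCLINICAL_RT = [(0.00, -0.45), (0.00, 0.00), (0.00, 0.00), (0.00, -0.10), (0.00, 0.00)]

_CLINICAL_RECALL = [(0.34, 0.26), (0.26, 0.34), (0.30, 0.30), (0.34, 0.24), (0.24, 0.32)]
_NONCLINICAL_RECALL = [(0.22, 0.36), (0.28, 0.30), (0.24, 0.34), (0.34, 0.26), (0.32, 0.32)]

_CLINICAL_IDS = [(37.4, 10.0), (28.0, 13.0), (27.0, 12.0), (32.7, 14.8), (20.0, 9.4)]
_NONCLINICAL_IDS = [(10.0, 9.0), (15.0, 11.0), (12.0, 10.0), (20.0, 13.0), (17.0, 12.0)]

_CLINICAL_DEQ = [
    ((40.0, 8.0), (48.8, 7.7)),
    ((40.0, 8.0), (42.0, 9.0)),
    ((42.0, 8.0), (44.0, 9.0)),
    ((40.0, 8.0), (47.7, 7.3)),
    ((40.0, 8.0), (38.7, 12.4)),
]
_NONCLINICAL_DEQ = [
    ((34.0, 8.0), (30.0, 9.0)),
    ((36.0, 8.0), (34.0, 9.0)),
    ((34.0, 8.0), (31.0, 9.0)),
    ((38.0, 8.0), (38.0, 9.0)),
    ((36.0, 8.0), (34.0, 9.0)),
]

# Per-class diagnosis distributions shaped like the published table: classes
# endorsing more negative words carry more depressive-disorder mass.
_CLINICAL_DIAG_COUNTS = [
    (4, 13, 1, 1, 1, 0),
    (4, 13, 6, 1, 0, 2),
    (2, 5, 5, 1, 1, 2),
    (9, 33, 6, 3, 3, 3),
    (4, 7, 3, 1, 1, 3),
]


def default_paperlike_spec(seed: int, group: str = "clinical", n_participants: int = None) -> CohortSpec:
    """Build the default 5-class specification for one group.

    ``group`` is ``"clinical"`` (n defaults to 119) or ``"nonclinical"``
    (n defaults to 115); ``n_participants`` overrides the group size while
    keeping the class structure (used for recovery experiments).
    """
    bank = default_word_bank()
    if group == "clinical":
        n = 119 if n_participants is None else n_participants
        diag = [
            {lab: c / sum(counts) for lab, c in zip(DIAGNOSIS_LABELS, counts)}
            for counts in _CLINICAL_DIAG_COUNTS
        ]
        return CohortSpec(
            group="clinical",
            n_participants=n,
            K_true=5,
            mixing_weights=_CLINICAL_WEIGHTS,
            endorse_probs=_block_probs(bank, _CLINICAL_BLOCKS),
            rt_model=[_rt_cells(nb, pb) for nb, pb in _CLINICAL_RT],
            recall_model=[_recall_cells(ne, pe) for ne, pe in _CLINICAL_RECALL],
            ids_model=_CLINICAL_IDS,
            deq_model=_CLINICAL_DEQ,
            diagnosis_model=diag,
            seed=seed,
            p_female=59.0 / 119.0,
            word_bank=bank,
            class_names=_CLINICAL_CLASSES,
            id_offset=0,
        )
    if group == "nonclinical":
        n = 115 if n_participants is None else n_participants
        diag = [{"none": 1.0} for _ in range(5)]
        return CohortSpec(
            group="nonclinical",
            n_participants=n,
            K_true=5,
            mixing_weights=_NONCLINICAL_WEIGHTS,
            endorse_probs=_block_probs(bank, _NONCLINICAL_BLOCKS),
            rt_model=[_rt_cells(nb, pb) for nb, pb in _NONCLINICAL_RT],
            recall_model=[_recall_cells(ne, pe) for ne, pe in _NONCLINICAL_RECALL],
            ids_model=_NONCLINICAL_IDS,
            deq_model=_NONCLINICAL_DEQ,
            diagnosis_model=diag,
            seed=seed,
            p_female=76.0 / 115.0,
            word_bank=bank,
            class_names=_NONCLINICAL_CLASSES,
            id_offset=1000,
        )
    raise ConfigError(f"group: unknown group {group!r} (expected 'clinical' or 'nonclinical')")


def well_separated_spec(seed: int, K: int = 3, n_participants: int = 150,
                        hi: float = 0.9, lo: float = 0.1) -> CohortSpec:
    """Benchmark spec with K equal classes on disjoint high-endorsement blocks.

    Classes endorse disjoint word-index blocks at ``hi`` and everything else
    at ``lo``, giving maximal, valence-agnostic separation. Used for
    recoverability and stability benchmarks where the class structure should
    be unambiguous.
    """
    bank = default_word_bank()
    J = bank.n_words
    P = np.full((K, J), lo)
    width = J // K
    for k in range(K):
        P[k, k * width:(k + 1) * width] = hi
    return CohortSpec(
        group="benchmark",
        n_participants=n_participants,
        K_true=K,
        mixing_weights=np.full(K, 1.0 / K),
        endorse_probs=P,
        rt_model=[_rt_cells(0.0, 0.0) for _ in range(K)],
        recall_model=[_recall_cells(0.3, 0.3) for _ in range(K)],
        ids_model=[(20.0, 8.0)] * K,
        deq_model=[((36.0, 6.0), (40.0, 7.0))] * K,
        diagnosis_model=[{"none": 1.0}] * K,
        seed=seed,
        word_bank=bank,
    )


def write_cohort(cohort: Cohort, out_dir, bank: WordBank = None) -> dict:
    """Write the cohort as UTF-8 comma-separated tables; returns path map."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bank = bank or default_word_bank()
    paths = {}
    for name, frame in (
        ("trials", cohort.trials),
        ("recalls", cohort.recalls),
        ("participants", cohort.participants),
        ("truth", cohort.truth),
        ("items_ids", cohort.ids_items),
        ("items_deq", cohort.deq_items),
        ("wordbank", bank.to_frame()),
    ):
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths
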