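"""Cluster profiling: top-endorsed words and cross-solution correspondence.

A cluster's profile is the per-word endorsement proportion among its
members. Words whose mean endorsement is at or above the upper quartile
(75th percentile, linear-interpolation quantile) of that cluster's word
means are its top-endorsed words, ranked by mean endorsement descending
with ties broken by the word's relative endorsement (its mean in the
cluster minus its mean among all other participants) and then word index.

Correspondence between two cluster solutions on the same participants is a
contingency table with composition percentages in both directions: the
share of each column cluster contributed by each row cluster, and the
distribution of each row cluster across column clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError
from .wordbank import WordBank


@dataclass
class ClusterProfile:
    """Per-cluster word endorsement summary."""

    cluster: int
    n_members: int
    word_means: np.ndarray
    threshold: float
    top_words: pd.DataFrame      # word_id, text, mean, relative, rank
    mean_endorsement_rate: float


def top_words(X, labels, bank: WordBank, quantile: float = 0.75) -> list[ClusterProfile]:
    """Profile every cluster of a labeling of the endorsement matrix.

    ``X`` is the binary matrix (or EndorsementMatrix); ``labels`` assigns a
    cluster to each row. Empty clusters are skipped with a warning.
    """
    Xarr = X.X if hasattr(X, "X") else np.asarray(X)
    labels = np.asarray(labels)
    profiles = []
    for k in range(int(labels.max()) + 1):
        members = labels == k
        if not members.any():
            warnings.warn(f"top_words: cluster {k} is empty, skipped")
            continue
        means = Xarr[members].mean(axis=0)
        others = ~members
        other_means = Xarr[others].mean(axis=0) if others.any() else np.zeros_like(means)
        relative = means - other_means
        threshold = float(np.quantile(means, quantile))   # linear interpolation
        is_top = means >= threshold
        ids = np.nonzero(is_top)[0]
        order = sorted(ids, key=lambda j: (-means[j], -relative[j], j))
        table = pd.DataFrame(
            {
                "word_id": order,
                "text": [bank.text[j] for j in order],
                "mean": [means[j] for j in order],
                "relative": [relative[j] for j in order],
                "rank": np.arange(1, len(order) + 1),
            }
        )
        profiles.append(
            ClusterProfile(
                cluster=k,
                n_members=int(members.sum()),
                word_means=means,
                threshold=threshold,
                top_words=table,
                mean_endorsement_rate=float(means.mean()),
            )
        )
    return profiles


@dataclass
class CorrespondenceTable:
    """Cross-tabulation of two labelings of the same participants."""

    counts: pd.DataFrame           # rows = labeling A clusters, cols = labeling B
    column_composition: pd.DataFrame  # % of each B cluster contributed by A clusters
    row_distribution: pd.DataFrame    # % of each A cluster across B clusters

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


def correspondence_table(labels_a: pd.Series, labels_b: pd.Series,
                         name_a: str = "a", name_b: str = "b") -> CorrespondenceTable:
    """Build the correspondence table between two labelings.

    Inputs are participant-id-indexed Series (or mappings); the ids must
    coincide exactly.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    orphans_a = a.index.difference(b.index)
    orphans_b = b.index.difference(a.index)
    if len(orphans_a) or len(orphans_b):
        raise DataError(
            "correspondence_table: participant ids do not align; "
            f"only-in-a={orphans_a.tolist()}, only-in-b={orphans_b.tolist()}"
        )
    b = b.loc[a.index]
    counts = pd.crosstab(a, b)
    counts.index.name = name_a
    counts.columns.name = name_b
    col_pct = counts / counts.sum(axis=0) * 100.0
    row_pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return CorrespondenceTable(
        counts=counts, column_composition=col_pct, row_distribution=row_pct,
    )
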