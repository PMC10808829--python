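"""Characterize clusters by their top-endorsed words.

A cluster's top words are those whose mean endorsement among members
reaches the upper quartile of the cluster's word means, ranked by mean and
then by how much more this cluster endorses them than everyone else.
"""

from sretlca import (
    build_endorsement_matrix, default_paperlike_spec, default_word_bank,
    generate_cohort, select_model, top_words,
)

bank = default_word_bank()
cohort = generate_cohort(default_paperlike_spec(seed=1, group="clinical"))
matrix = build_endorsement_matrix(cohort.trials, bank)
solution = select_model(matrix, "bic", seed=3)

for prof in top_words(matrix, solution.labels, bank):
    head = prof.top_words.head(7)
    words = ", ".join(f"{t} ({m:.2f})" for t, m in zip(head["text"], head["mean"]))
    print(f"cluster {prof.cluster} (n={prof.n_members}, "
          f"mean endorsement {prof.mean_endorsement_rate:.2f}): {words}")

# The printed proportion is the fraction of members endorsing the word; the
# word lists are what a thematic reading would label (e.g. a cluster whose
# top words are negative self-critical adjectives).
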