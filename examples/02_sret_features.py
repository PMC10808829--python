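"""Compute per-participant SRET metrics from trial-level data.

Endorsement counts/rates (denominator = all 90 words presented), RT biases
(endorse-minus-reject mean RT over the participant's overall mean RT, per
valence) and recall biases (share of each valence among correctly recalled
words).
"""

from sretlca import compute_features, default_paperlike_spec, default_word_bank, generate_cohort

cohort = generate_cohort(default_paperlike_spec(seed=1, group="clinical"))
features = compute_features(cohort.trials, cohort.recalls, default_word_bank())

cols = ["n_neg_endorsed", "n_pos_endorsed", "neg_rt_bias", "pos_rt_bias",
        "neg_recall_bias", "recall_bias_diff"]
print(features[cols].describe().round(3).loc[["mean", "std", "min", "max"]])

by_class = features.merge(cohort.truth, on="participant_id").groupby("class_name")
print("\nmean negative endorsements by latent class:")
print(by_class["n_neg_endorsed"].mean().round(1).sort_values(ascending=False))

# A negative RT bias means the participant endorses words of that valence
# faster than they reject them; recall_bias_diff > 0 means memory favours
# negative self-referential words.
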