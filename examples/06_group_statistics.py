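"""Cross-cluster and cross-group statistics.

One-way ANOVA with eta-squared and Tukey-Kramer HSD compare clusters on a
feature; the pooled t test, Yates chi-square and uniform multinomial test
cover group-level and diagnosis-frequency comparisons. The summary-input
entry points also reproduce published worked examples exactly.
"""

from sretlca import (
    build_endorsement_matrix, chi2_2x2, compute_features, default_paperlike_spec,
    default_word_bank, generate_cohort, multinomial_gof, one_way_anova,
    pooled_t_test, select_model, tukey_hsd,
)

cohort = generate_cohort(default_paperlike_spec(seed=1, group="clinical"))
bank = default_word_bank()
matrix = build_endorsement_matrix(cohort.trials, bank)
solution = select_model(matrix, "bic", seed=3)
features = compute_features(cohort.trials, cohort.recalls, bank)
features = features.set_index("participant_id").loc[matrix.participant_ids]

groups = [features["n_neg_endorsed"][solution.labels == k].to_numpy()
          for k in range(solution.model.K)]
res = one_way_anova(groups)
print(f"negative endorsement by cluster: F({res.df_between},{res.df_residual}) = "
      f"{res.F:.2f}, eta^2 = {res.eta_sq:.2f}, p = {res.p:.2g}")
biggest = max(tukey_hsd(groups), key=lambda p: abs(p.diff))
print(f"largest pairwise contrast: clusters {biggest.group_a} vs {biggest.group_b}: "
      f"diff = {biggest.diff:.1f}, 95% CI [{biggest.ci_low:.1f}, {biggest.ci_high:.1f}], "
      f"p_adj = {biggest.p_adj:.2g}")

# Worked examples on summary inputs (group sizes, means, SDs, counts):
t = pooled_t_test(14.56, 11.59, 115, 31.25, 13.90, 119)
print(f"\ngroup symptom comparison: t({t.df}) = {t.t:.2f}, d = {t.cohens_d:.2f}")
chi = chi2_2x2([[60, 59], [39, 76]])
print(f"sex by group (Yates): chi2 = {chi.chi2:.2f}, p = {chi.p:.3f}")
mult = multinomial_gof([13, 13, 5, 33, 7])
print(f"depressive diagnoses across 5 clusters: chi2({mult.df}) = {mult.chi2:.2f}")
# Large F with eta^2 near 0.6-0.9 says cluster membership explains most of
# the variance in negative endorsement, as expected when clustering was
# driven by the endorsement patterns themselves.
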