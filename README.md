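# sretlca

Latent-class subtyping of self-referential judgements.

In the Self-Referential Encoding Task (SRET), participants judge whether
valenced adjectives describe them (endorsement), complete a distractor, then
freely recall the adjectives. The pattern of endorsements is a window onto
the self-schema, and negatively biased self-schemas are central to cognitive
models of depression. `sretlca` clusters participants directly on their
binary word-endorsement vectors to find transdiagnostic subtypes — for
example self-critical, neurotic or self-confident profiles — and compares
the subtypes on symptoms, reaction-time and memory biases, and diagnoses.
It is aimed at researchers in computational psychiatry and personality who
work with SRET-style endorsement data.

## The model

Endorsements form an *n* × *J* binary matrix *X* (participants × words).
Each participant belongs to one of *K* latent classes with mixing
proportions π<sub>k</sub>; conditional on the class, the *J* endorsements
are independent Bernoulli draws with class-specific probabilities
p<sub>kj</sub>:

P(x<sub>i</sub>) = Σ<sub>k</sub> π<sub>k</sub> Π<sub>j</sub>
p<sub>kj</sub><sup>x<sub>ij</sub></sup> (1 − p<sub>kj</sub>)<sup>1 − x<sub>ij</sub></sup>

The unrestricted model has ν = (K − 1) + K·J free parameters and is fitted
by EM with multiple seeded restarts. The number of classes is chosen over
the Bezdek range (2 up to the smallest integer above ∛n) by the lowest of
BIC = −2ℓ + ν ln n, ICL = BIC + 2·entropy of the posterior memberships, or
NEC = entropy / (ℓ<sub>K</sub> − ℓ<sub>1</sub>). Solution quality and
stability are assessed with the Davies–Bouldin and Calinski–Harabasz
indices and by refitting under perturbed initialization seeds, matching
cluster centers across seeds by optimal assignment on Pearson correlations
(a matched pair with r ≥ 0.7 counts as stable).

Around the clustering core the package provides: SRET feature extraction
(endorsement rates, RT biases, recall biases), IDS-SR-30 and RecDEQ
questionnaire scoring with Cronbach's α, top-word cluster profiling,
correspondence tables between cluster solutions, and the statistics suite
(one-way ANOVA with η², Tukey–Kramer HSD, pooled t tests with Cohen's d,
Yates χ², uniform multinomial goodness of fit). Because SRET study data are
rarely deposited, a synthetic cohort generator with known latent-class
structure makes every stage testable end to end.

## Worked example

```python
from sretlca import (
    default_paperlike_spec, generate_cohort, default_word_bank,
    build_endorsement_matrix, fit_range, kmax_bezdek,
)

cohort = generate_cohort(default_paperlike_spec(seed=1, group="clinical"))
matrix = build_endorsement_matrix(cohort.trials, default_word_bank())
solutions = fit_range(matrix, seed=3, kmin=2, kmax=kmax_bezdek(matrix.n))
for K in sorted(k for k in solutions if k >= 2):
    s = solutions[K]
    print(K, round(s.model.loglik, 1), round(s.criteria["bic"], 1))
```

prints

```
2 -5021.9 10908.8
3 -4368.4 10036.8
4 -3842.0 9418.8
5 -3523.9 9217.5
```

BIC keeps falling to K = 5, the number of classes the generator planted:
the synthetic clinical cohort of 119 participants is correctly resolved
into its five endorsement subtypes. `examples/` contains one short script
per capability (simulation, features, model selection, stability, profiles,
statistics), each printing the numbers it computes and what they mean, and
the `sretlca` command-line tool exposes the same stages as shell verbs
(`simulate`, `metrics`, `cluster`, `stability`, `profile`, `stats`, `run`).

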