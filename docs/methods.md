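# Methods

## The latent-class model

Participants' endorsement vectors are modelled as a finite mixture of
multivariate Bernoulli distributions (a latent class model). For an n × J
binary matrix X, class k has mixing proportion pi_k and per-word
endorsement probabilities p_kj; words are conditionally independent given
the class. The unrestricted parameterization is used throughout, with
nu = (K − 1) + K·J free parameters. Parsimonious constrained variants
(shared dispersion across words or classes) exist in the mixture-modelling
literature; they are deliberately out of scope because the unrestricted
model subsumes them for binary data and the reported criterion values of
constrained fits cannot be distinguished without knowing the variant.

### Fitting

EM from random responsibilities (rows drawn from a symmetric Dirichlet(1)),
best of 10 restarts per fit, every restart stream spawned deterministically
from the user seed via `numpy.random.SeedSequence`. Convergence is declared
when the relative log-likelihood change falls below 1e-8 or after 500
iterations. Estimated probabilities are clamped to [1e-6, 1 − 1e-6] so the
log-likelihood stays finite on degenerate columns. The log-likelihood is
asserted non-decreasing at every ordinary EM step; when a component's
responsibility mass falls below 1/(10n) it is re-initialized once (which
may legitimately lower the log-likelihood, so the monotonicity guard resets
at that point), and a restart whose component collapses twice is marked
failed and excluded. K = 1 is fitted in closed form (column means).

MAP labels break ties toward the lowest cluster index (the behaviour of
argmax on equal posteriors).

### Model selection

Candidates run over the Bezdek range: K from 2 to the smallest integer
strictly greater than the cube root of n (119 → 5, 234 → 7; when the cube
root is an integer c the bound is c + 1, so 8 → 3). Criteria, all
lower-is-better:

- BIC = −2·loglik + nu·ln(n)
- ICL = BIC + 2·H, with H = Σ −t_ik log t_ik the assignment entropy
- NEC = H / (loglik_K − loglik_1), with NEC(1) ≡ 1 by convention and +inf
  (with a warning) when the K-class fit does not improve on one class.

Ties between K values break toward the smaller K. All three criteria are
computed from one shared set of fits per seed, so a stability study costs
one K-sweep per seed rather than one per criterion.

## Validation and stability

Davies–Bouldin and Calinski–Harabasz are computed on the raw 0/1 vectors
with Euclidean geometry — the indices' standard definitions — and both
accept model centroids: for mixture solutions the natural cluster center is
the probability row p_k (the responsibility-weighted mean), which is what
the stability study uses. When centroids are omitted they default to
per-cluster member means, in which case both indices agree with their
scikit-learn counterparts (verified in tests). Degenerate geometry maps to
+inf sentinels: coincident centroids for DBI, zero within-cluster scatter
for CHI.

The perturbation study refits the full selection procedure for each seed in
a list (default 1–30) and reports the per-criterion mean and SD of the
selected K, criterion value, log-likelihood, DBI and CHI. Cluster centers
of each seed's selected solution are matched against a representative-seed
reference (default seed 3) by optimal one-to-one assignment (Hungarian
algorithm) on the matrix of Pearson correlations between probability rows;
a matched pair is stable when r ≥ 0.7. Reference-versus-each matching was
chosen over all-pairs matching: it is what a reader of a per-seed stability
table needs and scales linearly in the number of seeds. Constant centroid
rows have undefined correlation and are treated as unmatchable (never
stable).

## SRET metrics

- Endorsement rate divides the per-valence endorsement count by the total
  number of words presented (all valences), which is the published
  definition; per-valence rates (count over words of that valence) are also
  exposed under separate names because cluster descriptions often use them.
- RT bias per valence = (mean endorse RT − mean reject RT) / mean RT over
  all endorsement-phase trials of the participant. "All trial types" is
  read as both valences and both responses. The bias is therefore invariant
  to rescaling a participant's RTs. It is missing when the participant has
  no endorsements or no rejections of that valence.
- Recall bias divides correctly recalled words of each valence by all
  correctly recalled words; the difference is negative minus positive. An
  endorsed-only variant (ratios over recalled-and-endorsed words) is
  available behind a flag but is not the default definition.
- Missing features are NaN and all downstream tests drop missing cases
  listwise, which mirrors the varying error degrees of freedom seen in
  per-feature analyses of real cohorts.
- No RT outlier trimming is applied.

## Questionnaire scoring

IDS-SR-30 totals sum 28 of 30 items: the appetite and weight
increase/decrease pairs each contribute the maximum of their two members,
realizing the convention that exactly one direction applies per
respondent; whether a given study zeroed the unused member or took the
maximum is usually unstated, and the maximum is adopted as the
deterministic choice (pair positions are configurable, defaulting to the
standard item order 11/12 and 13/14). Totals range 0–84 with the
symptomatic cut-off at ≥ 18. RecDEQ is two plain sums (9 dependency items,
10 self-criticism items, each 1–7). Cronbach's alpha uses raw
(non-standardized) item scores with sample variances.

## Cluster profiles and correspondence

Top-endorsed words of a cluster are those with mean endorsement at or
above the 75th percentile of the cluster's word means. The quantile uses
linear interpolation between order statistics (the common default); the
boundary is inclusive. Ranking is by mean descending, then by relative
endorsement (the word's mean in the cluster minus its mean among all other
participants), then word index. Correspondence between two labelings of
the same participants is a contingency table with composition percentages
in both directions; counts are authoritative and percentages are derived
from them.

## Statistics suite

One-way fixed-effects ANOVA with eta-squared = SS_between / SS_total;
Tukey–Kramer HSD for unequal group sizes with confidence half-width
q(1−α, K, df)·sqrt(MSE/2·(1/n_a + 1/n_b)) and adjusted p from the
studentized-range distribution (no normal approximation; cross-checked
against statsmodels to 1e-6 on random datasets). The pooled two-sample t
test uses df = n1 + n2 − 2 and Cohen's d with the pooled SD and no
small-sample correction. The 2×2 chi-square applies the Yates continuity
correction by default. The "multinomial test" of diagnosis frequencies is
the chi-square goodness of fit of per-cluster counts against uniform
expected proportions — this definition reproduces published worked
examples exactly and its type-I error at alpha 0.05 is calibrated (within
[0.04, 0.06] over 10,000 null simulations in the test suite). Exact
adjusted p values are always reported; significance thresholds are left to
the caller.

## Synthetic cohort generator

The generator exists because SRET study data are rarely deposited; it
emulates the data-generating structure the analysis assumes, with known
ground truth. Per participant: a latent class from the mixing weights,
Bernoulli endorsements from the class's probability row, log-normal RTs
per (class, valence, response) cell, per-word Bernoulli recall with
probability depending on (valence, endorsed) and class, IDS-SR-30 item
vectors drawn from a class-specific severity target and passed through the
real scorer, RecDEQ items likewise, and sex/diagnosis from class- and
group-specific categorical distributions. One RNG stream seeded once
generates the whole cohort, so a single integer reproduces it bit for bit.

Default specifications model a clinical-like group (n = 119) and a
non-clinical-like group (n = 115), each with five classes. Endorsement
probabilities follow a 0.9/0.1 block structure: each class endorses
class-specific blocks of negative and positive word indices at 0.9 and
everything else at 0.1, with block widths calibrated so the expected
per-class positive/negative endorsement counts match published cluster
means (e.g. the clinical "neurotic"-like class expects ≈30 negative and
≈17 positive endorsements). Mixing weights are proportional to published
cluster sizes. RT-bias targets and symptom-score means use published
per-cluster values where available and neutral values elsewhere; diagnosis
distributions place more depressive-disorder mass in negative-endorsing
classes. A separate `well_separated_spec` builds K equal classes on
disjoint blocks for benchmark experiments where the class structure should
be unambiguous.

What the generator does **not** emulate: item-level word semantics (words
within a block are exchangeable), correlations between RT, recall and
symptoms beyond what class membership induces, response omissions, and the
overlapping soft cluster boundaries of real cohorts (real endorsement
probabilities are mid-range more often than 0.1/0.9). Passing recovery
tests therefore show that the pipeline is correct and well calibrated
under its own assumptions, not that real SRET cohorts contain five crisp
classes.

## Problem sizes and numerical choices

Recovery experiments use n = 300 with the default clinical-like structure
(selected K, adjusted Rand index ≥ 0.8, RMSE of recovered probabilities
≤ 0.05 after optimal centroid matching); stability experiments use n = 150
well-separated 3-class cohorts over 10 seeds. These sizes give stable,
quickly reproducible results while staying in the regime of the motivating
study (hundreds of participants, 90 words). The EM grid-search oracle in
the tests enumerates (pi, P) at resolution 0.05 for K = 2 on matrices with
up to 8 rows and 2 columns, which is exhaustive yet fast; larger J adds
nothing to the check while growing exponentially.

## Known limitations

- Only the unrestricted Bernoulli parameterization is provided; reported
  criterion values from constrained mixture variants are not comparable.
- The thematic labelling of clusters (mapping top words onto personality
  or psychodynamic constructs) is human interpretation; the package emits
  the ranked word lists that feed it and stops there.
- NEC is reported but is the least stable criterion under seed
  perturbation, consistent with its behaviour on real cohorts; BIC is the
  default.
- Covariate-adjusted analyses (age, gender) are out of scope beyond group
  descriptives.
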