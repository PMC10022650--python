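# Methods

This note documents the models implemented in `lsspanel`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducibility.

## Document scaling

The scaling model is latent semantic scaling: a truncated SVD of the raw
documents × terms count matrix, term polarities as signed mean cosine
similarity to seed terms, and document scores as frequency-weighted mean
term polarity, standardized to the fitting corpus.

Choices that were genuinely open and how they were resolved:

- **Word vectors.** Term vectors are rows of the term-side singular matrix
  *V* multiplied elementwise by the singular values, the standard
  latent-semantic-analysis convention; `sv_weighting="none"` is available
  as a sensitivity option. Cosine similarity is scale-invariant per vector,
  so the weighting matters only through the relative emphasis of
  dimensions.
- **Embedding dimension.** Default 200, intended for corpora with ~10⁵–10⁶
  documents and 10⁴+ terms, where a few hundred dimensions capture coarse
  semantics rather than topical detail. Synthetic studies in the test suite
  use k = 30–50, matched to their smaller vocabularies (150–500 terms); the
  dimension is clipped with a warning when it exceeds min(n_docs, n_terms).
- **Determinism.** The randomized SVD solver is seeded, and each singular
  vector's sign is fixed by making its largest-magnitude term loading
  positive. This makes fits bit-reproducible and row-permutation invariant.
- **Seed polarity encoding.** Seed terms carry +1 (worse) or −1 (better)
  and enter a single signed average. This makes "higher score = more
  distress" hold by construction and makes swapping the two seed sets negate
  every polarity and every standardized score exactly — a symmetry the test
  suite asserts bitwise.
- **Standardization.** Population SD over the scored documents of the
  fitting corpus. Center and scale are stored in the model, and held-out
  documents are standardized with the fitting corpus's constants, never
  their own.
- **Degenerate inputs.** Zero-norm word vectors get cosine 0 (logged).
  Documents with no in-vocabulary token are unscored (NaN) and excluded
  from standardization and from all downstream analyses; they are counted
  in the reported coverage fraction. A corpus whose raw scores have zero
  variance is rejected rather than silently producing infinities.
- **No term weighting.** The SVD is taken of raw counts; tf-idf or similar
  reweighting is deliberately not applied by default.

## Corpus construction

Exclusion rules (retweets, language, link-only posts, inactive users, date
window) are independent toggles; each excluded document is charged to the
first rule it fails, and the report records the inactivity threshold used.
"Inactive user" is operationalised as fewer than `min_docs_per_user`
(default 10) documents in the analysis window; "link-only" means no token
remains after removing URL tokens (matched by scheme prefix). Vocabulary
pruning drops terms occurring fewer than `min_term_count` (default 5) times
corpus-wide, because very rare terms have unstable singular-vector
coordinates. Documents left with zero in-vocabulary tokens keep their DTM
row so document identity is preserved end to end.

The default tokenizer lowercases, splits on whitespace/punctuation, and
keeps URLs, hashtags, mentions and emojis as single tokens (emojis are
scored like words). It is a pluggable callable: morphological analyzers for
languages without whitespace segmentation can be passed in.

## Coder validation

Three labels per document aggregate to −2…+2 by the unanimous/majority
rule; the implementation is cross-checked against an exhaustive enumeration
of all 27 ordered label triples. Category summaries use the normal
approximation mean ± 1.96·SD/√n for the 95% CI; with n = 1 the CI is
reported as undefined rather than zero-width. The correlation between the
scales is the plain Pearson product-moment coefficient.

## Panel estimation

The weekly model is estimated on individual documents, not user-week
aggregates. The three fixed-effect factors (user, week-of-year,
day-of-week) are absorbed by alternating-projection demeaning of the
outcome and the treatment-week dummies, iterated to a 1e−12 relative
tolerance; the weekly coefficients then come from OLS on the demeaned
design (Frisch–Waugh), which is numerically identical to the explicit-dummy
regression — the test suite verifies coefficients and standard errors
against a hand-built dummy-variable OLS and against statsmodels' clustered
OLS to 1e−8.

- **Clustered variance.** CR1: the cluster-sum sandwich scaled by
  G/(G−1) · (N−1)/(N−K), with K counting all parameters of the equivalent
  dummy regression including the absorbed effects, so the small-sample
  correction matches the explicit regression exactly. CIs use the normal
  critical value 1.96.
- **Week convention.** Weeks are consecutive 7-day blocks from January 1
  (week 1 = Jan 1–7). This convention reproduces the calendar weeks of the
  2020 reference events (school closure week 9, state of emergency weeks
  14–21, the two celebrity-suicide reports in weeks 29 and 39) from their
  dates. Block 53 (days 365–366) is a partial week with no matched
  counterpart and is excluded from estimation.
- **Collinearity.** No year effect is included (it would be collinear with
  the full set of treatment-week dummies). Treatment dummies that are fully
  absorbed by the fixed effects are dropped with a warning and their weeks
  reported absent. The reference-category choice for absorbed effects is
  irrelevant to the weekly coefficients; shift-invariance tests assert this.
- **Stratified runs.** Subgroup fits re-estimate the full model within each
  subgroup. Participants recorded as `other/NA` on the stratifying variable
  (sex, employment) are omitted from that stratification only.

Whether clustered CIs should use normal or t critical values with few
clusters is a genuine choice; normal critical values were chosen and CI
calibration is verified empirically (see below) rather than assumed.

## Descriptive trajectories

Baseline deviations subtract each user's baseline-year mean score; users
with no scored baseline document are dropped and counted. The smoother is a
local-linear (loess) regression: at each grid point the nearest 5% of
points (configurable) receive tricube weights and a weighted line is
evaluated at the point; the pointwise 95% band uses the local WLS
prediction variance with the local residual variance, assuming independent
errors. Smoothing is applied to the pooled deviations, not per user, and is
evaluated on a daily grid. Weekly aggregation reports per-week means and
counts, outer-joined to user-supplied exogenous weekly series, with Pearson
correlations over the overlapping weeks.

## Synthetic data generator

The generator emulates a two-year (real 2019/2020 calendars, including the
leap day) panel of users whose word choice is tilted by a latent distress
state:

> d = γ_i + week-of-year effect + day-of-week effect +
> δ(week)·(treatment year) + N(0, noise_sd²) per document,
> P(token = w | d) ∝ base_freq_w · exp(tilt · d · θ_w),

with planted term polarities θ_w ~ N(0, polarity_sd²), Zipf base
frequencies, user baselines γ_i ~ N(0, baseline_sd²), and a weekly effect
profile that ramps over weeks 9–21 peaking at 0.2 in week 14 of the
treatment year. Seed words are the 8 highest- and 8 lowest-θ terms,
mirroring an 8+8 seed lexicon. Coders threshold d at ±0.5 and mislabel to
an adjacent category with probability 0.15. Attribute marginals approximate
a 560-person survey sample (57.5% female, 62.5% low income, 31% PHQ-9 ≥ 10,
30% any suicidal ideation, 49% lonely). Everything is a deterministic
function of one seed.

Default study conditions: 200 users, 500 terms, Poisson(2) documents per
user-week over both years (~42k documents), Poisson(12) tokens per
document.

**Variance budget.** The seasonal and day-effect SDs (0.5 and 0.1) were set
by a variance-budget argument: the standardized document score has unit
variance by construction, and its regression slope on d is approximately
1/√(Var(d) + sampling noise), with Var(d) = baseline² + week² + day² +
noise² ≈ 0.76 and the finite-document sampling term ≈ 1/11. Keeping this
total near 1 makes one unit of latent distress map to about one
standardized-score unit, so planted weekly effects are recovered on their
own scale — empirically the fitted slope is 0.99–1.09 across seeds and the
mean recovered week-14 effect over replications is within 0.01–0.02 of the
planted 0.2.

**What the generator does not emulate** — and hence what passing tests do
not show about real corpora: natural-language structure (tokens are
abstract symbols; there is no syntax, topicality, sarcasm or code-switching),
polysemy and seed-word ambiguity, retweets/links/multilingual noise (the
filter rules are tested on constructed cases instead), attrition and
deletion of posts, measurement drift between the survey date and the
observation window, and any confounding between attributes and posting
behaviour. Recovery results on the generator demonstrate correctness of the
estimation machinery under the model's own assumptions, not validity of
LSS on real text.

## Problem sizes used in the checks

The test suite exercises the full pipeline at two scales chosen for quick,
well-powered checks: a 40-user/150-term study for contract and symmetry
tests, and the default 200-user/500-term study (20 replications) for
parameter recovery. Monotonicity of category means is checked with
annotations over the whole corpus rather than an 800-document subsample, so
the extreme (unanimous) categories are estimated precisely. CI calibration
uses 100 replications of a 30-user, 8-week panel drawn directly from the
linear fixed-effects model; observed coverage is ~95%.

## Known limitations

- The loess bands assume independent errors; serially correlated documents
  by the same user make them anticonservative.
- CR1 with normal critical values can undercover with very few clusters
  (< ~20 participants); a t correction is not implemented.
- The alternating-projection absorber assumes the three-factor design is
  connected; pathological designs (a user posting in only one week) can
  slow convergence, which is warned about rather than silently accepted.
- The default tokenizer is whitespace/punctuation based and is not a
  substitute for proper morphological analysis of unsegmented languages.
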