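# lsspanel

Semisupervised surveillance of emotional distress from short social-media
posts, and panel estimation of how distress evolved week by week during a
crisis year relative to a baseline year.

The package is aimed at computational social scientists and infodemiology
researchers who have (a) a stream of short documents written by known
authors over time and (b) author-level survey measures (depression
screening, loneliness, income, employment), and who want to track the
psychological state of author subgroups at weekly resolution without large
annotated training sets.

## Method

**Latent semantic scaling (LSS).** Given a documents × terms count matrix
*D*, a truncated rank-*k* SVD *D ≈ UΣVᵀ* yields a word vector *v_f* for
every term *f* (row *f* of *V*, scaled by the singular values). A small seed
lexicon *S* splits into "worse" (distress, polarity *p_s* = +1) and
"better" (well-being, *p_s* = −1) terms, and every term receives a polarity

> *g_f* = (1/|S|) Σ_{s∈S} *p_s* · cos(*v_f*, *v_s*),

its signed mean cosine similarity to the seed words. A document with
in-vocabulary term frequencies *h_f* (total *N*) is scored
(Σ_f *g_f h_f*) / *N*; scores are recentered to the corpus mean and rescaled
by the corpus SD, so they distribute around 0 with SD 1 and higher values
mean more distress. Documents with no in-vocabulary token are left unscored,
not imputed.

**Validation against human coders.** Three coders label each sampled
document good/neutral/bad; labels aggregate to a −2…+2 scale (±2 unanimous,
±1 two-of-three, 0 otherwise). Category-wise mean LSS scores and the Pearson
correlation between the two scales quantify agreement.

**Two-way fixed-effects panel.** With *LSS_{i,t}* the score of a document
by individual *i* at time *t*:

> *LSS_{i,t}* = Σ_τ *δ_τ* *w_τ* + *γ_i* + (week-of-year FE) + (day-of-week FE) + *ε_{i,t}*,

where *w_τ* indicates week *τ* of the treatment year. Each *δ_τ* is the
deviation of that week from the matched baseline-year week, net of stable
individual differences and calendar seasonality. Standard errors are
clustered by individual (CR1). Weeks are consecutive 7-day blocks from
January 1, so e.g. 2020-04-07 falls in week 14.

Because real survey-linked corpora are private, the package ships a
synthetic-data generator with known ground truth (planted word polarities,
user baselines, a weekly event profile peaking at 0.2 in week 14, simulated
coders) on which the whole pipeline is exercised and validated.

## Worked example

```python
from lsspanel import (SyntheticConfig, generate_corpus, build_dtm, fit_lss,
                      LSSConfig, score_corpus, build_panel, fit_weekly_fe)

study = generate_corpus(SyntheticConfig(random_seed=1))  # 200 users, 500 terms
dtm = build_dtm(study.documents, min_term_count=5)
model = fit_lss(dtm, study.truth.seed_lexicon(),
                LSSConfig(embedding_dim=50, random_seed=1))
print(f"{len(study.documents)} documents, vocabulary {len(dtm.vocabulary)}, "
      f"scoring coverage {model.coverage_:.4f}")

meta = study.latent[["doc_id", "user_id"]].assign(timestamp=study.latent["date"])
scores = score_corpus(model, dtm, doc_meta=meta)
panel = build_panel(scores, study.attributes, baseline_year=2019, treatment_year=2020)
effects = fit_weekly_fe(panel)
print(effects[effects.week.isin([9, 14, 21, 30])].round(3).to_string(index=False))
```

prints

```
41703 documents, vocabulary 500, scoring coverage 1.0000
 week  delta    se  ci_low  ci_high  n_obs  n_clusters
    9 -0.046 0.046  -0.136    0.044    424         200
   14  0.176 0.041   0.095    0.256    378         200
   21  0.025 0.042  -0.059    0.108    428         200
   30 -0.022 0.043  -0.106    0.061    412         200
```

The generator plants a weekly distress ramp over weeks 9–21 peaking at 0.2
in week 14 of 2020: the week-14 estimate (0.176, 95% CI 0.095–0.256) picks
it up, while weeks without a planted effect stay near zero. `model.polarity_`
holds the estimated per-term polarities, which can be compared with the
planted `study.truth.theta`.

A command-line interface mirrors the same stages (`lsspanel simulate`,
`lsspanel corpus build`, `lsspanel lss fit/score`, `lsspanel validate`,
`lsspanel panel fit`, `lsspanel trajectory`); see `lsspanel --help`.
A Japanese emotional-distress seed lexicon is packaged
(`load_seed_lexicon("ja")`) along with an English toy lexicon for
experimentation.

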