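"""Synthetic two-year document panel with known ground truth.

Real survey-linked social-media corpora are private, so every pipeline stage
is exercised on a generated panel whose data-generating process mirrors the
assumptions of the analysis: each user has a latent distress state composed
of a personal baseline, calendar (week-of-year and day-of-week) effects, a
treatment-year weekly event profile, and document-level noise; word choice
is tilted exponentially along a planted word-polarity axis, which is exactly
the structure latent semantic scaling presupposes.  Three noisy coders are
simulated by thresholding the latent state.

Everything is fully determined by ``random_seed``.

The latent state and the standardized document score live on comparable
scales by construction: with the default variance budget (baseline SD 0.5,
seasonal SD 0.5, day SD 0.1, document noise SD 0.5, ~12 tokens per
document) the total variance of a document's expected score is close to 1,
so a planted weekly effect of 0.2 on the latent scale reappears as roughly
0.2 standardized-score units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import Document
from .lss import SeedLexicon
from .panel import assign_week_index

__all__ = [
    "SyntheticConfig",
    "TrueParameters",
    "SyntheticData",
    "default_delta_profile",
    "generate_truth",
    "generate_documents",
    "generate_attributes",
    "generate_annotations",
    "generate_exogenous",
    "generate_corpus",
    "generate_linear_panel",
    "write_dataset",
]


def default_delta_profile(peak: float = 0.2) -> dict[int, float]:
    """Treatment-year weekly effects: a ramp over weeks 9-21 peaking at
    ``peak`` in week 14 (zero elsewhere)."""
    profile = {}
    for w in range(9, 15):
        profile[w] = peak * (w - 8) / 6
    for w in range(15, 22):
        profile[w] = peak * (22 - w) / 8
    return profile


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults define the standard study conditions.

    ``tilt`` couples the latent distress state d to word choice: token
    sampling probability ∝ base_freq_w * exp(tilt * d * theta_w).
    ``group_effects`` optionally multiplies the weekly effect profile per
    derived subgroup, e.g. ``{"depressive": {True: 1.5, False: 0.5}}``.
    """

    random_seed: int = 0
    n_users: int = 200
    vocab_size: int = 500
    n_weeks_per_year: int = 52
    docs_per_user_week: float = 2.0
    tokens_per_doc: float = 12.0
    polarity_sd: float = 1.0
    tilt: float = 1.0
    baseline_sd: float = 0.5
    week_effect_sd: float = 0.5
    day_effect_sd: float = 0.1
    noise_sd: float = 0.5
    delta_profile: dict[int, float] = field(default_factory=default_delta_profile)
    annotator_noise: float = 0.15
    annotation_threshold: float = 0.5
    n_seeds_per_side: int = 8
    zipf_exponent: float = 1.0
    baseline_year: int = 2019
    treatment_year: int = 2020
    news_tracks_delta: bool = True
    group_effects: dict[str, dict] | None = None

    def __post_init__(self) -> None:
        for name in ("polarity_sd", "baseline_sd", "week_effect_sd", "day_effect_sd",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tilt < 0:
            raise ValueError("tilt must be >= 0")
        if not 0 <= self.annotator_noise <= 1:
            raise ValueError("annotator_noise must be a probability")


@dataclass
class TrueParameters:
    """Planted ground truth the pipeline is asked to recover."""

    theta: pd.Series            # term -> true polarity
    gamma: pd.Series            # user -> baseline distress
    delta: dict[int, float]     # treatment-year week -> effect
    base_freq: pd.Series        # term -> baseline sampling weight (sums to 1)
    day_effects: np.ndarray     # (7,) Monday..Sunday offsets
    week_of_year_effects: np.ndarray  # (54,) indexed by week 1..53
    seed_worse: list[str]
    seed_better: list[str]

    def seed_lexicon(self) -> SeedLexicon:
        return SeedLexicon.from_sets(self.seed_worse, self.seed_better)


def generate_truth(config: SyntheticConfig) -> TrueParameters:
    """Draw word polarities, seed words, user baselines and calendar effects."""
    rng = np.random.default_rng(config.random_seed)
    if config.vocab_size < 2 * config.n_seeds_per_side:
        raise ValueError("vocabulary too small for seed selection")
    terms = [f"w{i:03d}" for i in range(config.vocab_size)]
    theta = pd.Series(rng.normal(0.0, config.polarity_sd, config.vocab_size), index=terms)

    order = np.argsort(theta.to_numpy(), kind="stable")
    seed_better = [terms[i] for i in order[: config.n_seeds_per_side]]
    seed_worse = [terms[i] for i in order[-config.n_seeds_per_side:]]

    ranks = np.arange(1, config.vocab_size + 1, dtype=float)
    freq = ranks ** (-config.zipf_exponent)
    base_freq = pd.Series(freq / freq.sum(), index=terms)

    users = [f"u{i:03d}" for i in range(config.n_users)]
    gamma = pd.Series(rng.normal(0.0, config.baseline_sd, config.n_users), index=users)
    week_eff = np.zeros(54)
    week_eff[1:54] = rng.normal(0.0, config.week_effect_sd, 53)
    day_eff = rng.normal(0.0, config.day_effect_sd, 7)
    return TrueParameters(
        theta=theta,
        gamma=gamma,
        delta=dict(config.delta_profile),
        base_freq=base_freq,
        day_effects=day_eff,
        week_of_year_effects=week_eff,
        seed_worse=seed_worse,
        seed_better=seed_better,
    )


def _year_dates(year: int) -> list[date]:
    d0 = date(year, 1, 1)
    n = (date(year + 1, 1, 1) - d0).days
    return [d0 + timedelta(days=i) for i in range(n)]


def generate_documents(
    truth: TrueParameters,
    config: SyntheticConfig,
    delta_multiplier: pd.Series | None = None,
) -> tuple[list[Document], pd.DataFrame]:
    """Sample the two-year document stream.

    Returns the documents plus a hidden per-document table with the true
    latent state d (used by annotation generation and recovery checks).
    Document counts per user-day are Poisson(docs_per_user_week / 7) over
    every calendar day of both years; token counts are Poisson(mean, min 1);
    token identities are multinomial with probabilities tilted by d.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.random_seed, 1]))
    users = list(truth.gamma.index)
    theta = truth.theta.to_numpy()
    terms = np.asarray(truth.theta.index)
    log_base = np.log(truth.base_freq.to_numpy())

    days = _year_dates(config.baseline_year) + _year_dates(config.treatment_year)
    day_info = pd.DataFrame({"date": pd.to_datetime(days)})
    day_info["year"] = day_info["date"].dt.year
    day_info["week"] = assign_week_index(day_info["date"])
    day_info["dow"] = day_info["date"].dt.dayofweek

    if delta_multiplier is None:
        mult = np.ones(len(users))
    else:
        mult = delta_multiplier.reindex(users).fillna(1.0).to_numpy()

    # documents per (user, day)
    n_days = len(days)
    counts = rng.poisson(config.docs_per_user_week / 7.0, size=(len(users), n_days))
    user_idx = np.repeat(np.arange(len(users)), counts.sum(axis=1))
    day_idx = np.concatenate(
        [np.repeat(np.arange(n_days), counts[u]) for u in range(len(users))]
    )
    n_docs = len(user_idx)

    week = day_info["week"].to_numpy()[day_idx]
    year = day_info["year"].to_numpy()[day_idx]
    dow = day_info["dow"].to_numpy()[day_idx]
    delta_vec = np.zeros(n_docs)
    is_treat = year == config.treatment_year
    for w, eff in truth.delta.items():
        delta_vec[is_treat & (week == w)] = eff
    d = (
        truth.gamma.to_numpy()[user_idx]
        + truth.week_of_year_effects[week]
        + truth.day_effects[dow]
        + delta_vec * mult[user_idx]
        + rng.normal(0.0, config.noise_sd, n_docs)
    )

    n_tokens = np.maximum(rng.poisson(config.tokens_per_doc, n_docs), 1)

    documents: list[Document] = []
    latent_rows = []
    dates_np = [ts.to_pydatetime() for ts in day_info["date"]]
    chunk = 4096
    for start in range(0, n_docs, chunk):
        stop = min(start + chunk, n_docs)
        logits = log_base[None, :] + config.tilt * d[start:stop, None] * theta[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        for i in range(start, stop):
            cnt = rng.multinomial(n_tokens[i], probs[i - start])
            nz = np.nonzero(cnt)[0]
            tokens = list(np.repeat(terms[nz], cnt[nz]))
            doc_id = f"d{i:06d}"
            documents.append(
                Document(
                    doc_id=doc_id,
                    user_id=users[user_idx[i]],
                    timestamp=dates_np[day_idx[i]],
                    tokens=tokens,
                    is_retweet=False,
                    language="ja",
                    link_only=False,
                )
            )
            latent_rows.append((doc_id, users[user_idx[i]], d[i]))
    latent = pd.DataFrame(latent_rows, columns=["doc_id", "user_id", "d"])
    latent["date"] = pd.to_datetime([dates_np[j] for j in day_idx])
    latent["year"] = year
    latent["week_index"] = week
    latent["day_of_week"] = dow
    return documents, latent


# Target marginals mirror a 560-person survey sample: ~57.5% female, 62.5%
# household income below JPY 6M, ~31% PHQ-9 >= 10, ~30% any suicidal
# ideation, ~49% lonely.
_SEX_P = {"female": 0.575 * 557 / 560, "male": 0.425 * 557 / 560, "other/NA": 3 / 560}
_AGE_P = {"18-29": 0.148, "30-39": 0.407, "40-49": 0.445}
_EMP_BASE = {"parttime_temp_unemployed": 0.318, "permanent": 0.538,
             "not_in_labor_force": 0.144}
_EMP_P = {**{k: v * 547 / 560 for k, v in _EMP_BASE.items()}, "other/NA": 13 / 560}


def generate_attributes(config: SyntheticConfig, truth: TrueParameters) -> pd.DataFrame:
    """Sample participant attributes approximating the survey marginals.

    PHQ-9 totals come from a rounded, clipped normal (mean 7, SD 6) so about
    31% clear the >=10 cut-off; suicidal ideation is a noisy threshold of
    the same latent severity (~30% positive) and populates PHQ-9 item 9;
    loneliness totals (3-9) put ~50% at the >=6 cut-off.  When
    ``group_effects`` targets a psychological subgroup, the PHQ-9 latent
    severity is correlated (rho = 0.6) with the user's baseline distress so
    the flagged group genuinely is more distressed at baseline.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.random_seed, 2]))
    users = list(truth.gamma.index)
    n = len(users)

    def _cat(p: dict[str, float]) -> np.ndarray:
        keys = list(p)
        probs = np.asarray(list(p.values()), dtype=float)
        probs = probs / probs.sum()
        return rng.choice(keys, size=n, p=probs)

    z = rng.normal(size=n)
    wants_psych = bool(config.group_effects) and bool(
        {"depressive", "suicidal", "lonely"} & set(config.group_effects or {})
    )
    if wants_psych and config.baseline_sd > 0:
        g = truth.gamma.to_numpy()
        gz = (g - g.mean()) / g.std()
        z = 0.6 * gz + np.sqrt(1 - 0.6**2) * rng.normal(size=n)

    severity = 7.0 + 6.0 * z
    phq9 = np.clip(np.round(severity), 0, 27).astype(int)
    suicidal = severity + rng.normal(0.0, 3.0, n) >= 10.48
    item9 = np.where(
        suicidal,
        rng.choice(["several_days", "more_than_half", "nearly_every_day"],
                   size=n, p=[0.6, 0.25, 0.15]),
        "not_at_all",
    )
    lonely_total = np.clip(np.round(5.5 + 1.8 * rng.normal(size=n)), 3, 9).astype(int)

    attrs = pd.DataFrame(
        {
            "user_id": users,
            "sex": _cat(_SEX_P),
            "age_group": _cat(_AGE_P),
            "income_group": _cat({"below_6M": 0.625, "at_least_6M": 0.375}),
            "employment": _cat(_EMP_P),
            "phq9_total": phq9,
            "phq9_item9": item9,
            "loneliness_total": lonely_total,
        }
    )
    return attrs


def generate_annotations(
    latent: pd.DataFrame,
    config: SyntheticConfig,
    n_docs: int | None = 800,
) -> pd.DataFrame:
    """Simulate three independent coders on a random document subset.

    Each coder's base label thresholds the latent state d at
    ±annotation_threshold (bad above, good below, neutral between), then
    flips to an adjacent category with probability ``annotator_noise``
    (neutral flips up or down with equal probability).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.random_seed, 3]))
    df = latent
    if n_docs is not None and n_docs < len(df):
        pick = rng.choice(len(df), size=n_docs, replace=False)
        df = df.iloc[np.sort(pick)]
    d = df["d"].to_numpy()
    thr = config.annotation_threshold
    base = np.where(d > thr, 2, np.where(d < -thr, 0, 1))  # 0=good,1=neutral,2=bad
    labels = {}
    names = np.array(["good", "neutral", "bad"])
    for coder in (1, 2, 3):
        lab = base.copy()
        flip = rng.random(len(lab)) < config.annotator_noise
        direction = np.where(rng.random(len(lab)) < 0.5, -1, 1)
        # edge categories have a single neighbour
        step = np.where(lab == 2, -1, np.where(lab == 0, 1, direction))
        lab = np.where(flip, lab + step, lab)
        labels[f"coder{coder}"] = names[lab]
    out = pd.DataFrame({"doc_id": df["doc_id"].to_numpy(), **labels})
    return out


def generate_exogenous(
    truth: TrueParameters, config: SyntheticConfig
) -> dict[str, pd.DataFrame]:
    """Weekly news and case-count series for the treatment year.

    With ``news_tracks_delta`` on, the news intensity follows the planted
    weekly effect profile (plus Poisson noise), emulating media coverage
    that co-moves with distress; the case-count series is an independent
    epidemic-like wave either way.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.random_seed, 4]))
    weeks = np.arange(1, config.n_weeks_per_year + 1)
    delta = np.array([truth.delta.get(int(w), 0.0) for w in weeks])
    if config.news_tracks_delta:
        intensity = 100.0 + 2000.0 * np.maximum(delta, 0.0)
    else:
        intensity = np.full(len(weeks), 100.0)
    news = rng.poisson(intensity)
    wave = 3000.0 * np.exp(-0.5 * ((weeks - 30) / 8.0) ** 2) + 50.0
    cases = rng.poisson(wave)
    return {
        "news_count": pd.DataFrame({"week": weeks, "news_count": news}),
        "case_count": pd.DataFrame({"week": weeks, "case_count": cases}),
    }


@dataclass
class SyntheticData:
    """Bundle of one generated study: inputs plus hidden ground truth."""

    config: SyntheticConfig
    truth: TrueParameters
    documents: list[Document]
    latent: pd.DataFrame
    attributes: pd.DataFrame
    annotations: pd.DataFrame
    exogenous: dict[str, pd.DataFrame]


def _delta_multiplier(attrs: pd.DataFrame, config: SyntheticConfig) -> pd.Series | None:
    if not config.group_effects:
        return None
    from .panel import categorize_participant

    labeled = categorize_participant(attrs)
    mult = np.ones(len(labeled))
    for field_name, mapping in config.group_effects.items():
        col = labeled[field_name]
        for value, m in mapping.items():
            mult = np.where(col.to_numpy() == value, float(m) * mult, mult)
    return pd.Series(mult, index=labeled["user_id"])


def generate_corpus(config: SyntheticConfig | None = None) -> SyntheticData:
    """Generate a full synthetic study (truth, documents, attributes,
    annotations, exogenous series) from one seed."""
    config = config or SyntheticConfig()
    truth = generate_truth(config)
    attributes = generate_attributes(config, truth)
    mult = _delta_multiplier(attributes, config)
    documents, latent = generate_documents(truth, config, delta_multiplier=mult)
    annotations = generate_annotations(latent, config)
    exogenous = generate_exogenous(truth, config)
    return SyntheticData(config, truth, documents, latent, attributes, annotations,
                         exogenous)


def generate_linear_panel(
    n_users: int = 30,
    weeks: int = 8,
    docs_per_cell: int = 3,
    delta: dict[int, float] | None = None,
    baseline_sd: float = 0.5,
    week_effect_sd: float = 0.3,
    day_effect_sd: float = 0.1,
    noise_sd: float = 0.5,
    baseline_year: int = 2019,
    treatment_year: int = 2020,
    random_seed: int = 0,
) -> pd.DataFrame:
    """Panel of document scores drawn directly from the linear fixed-effects
    model (no text step): score = gamma_i + week effect + day effect +
    delta_w (treatment year) + noise.  Used to study the estimator itself.
    """
    rng = np.random.default_rng(random_seed)
    delta = delta if delta is not None else {}
    gamma = rng.normal(0, baseline_sd, n_users)
    week_eff = rng.normal(0, week_effect_sd, weeks + 1)
    day_eff = rng.normal(0, day_effect_sd, 7)
    rows = []
    doc = 0
    for year in (baseline_year, treatment_year):
        start = date(year, 1, 1)
        for u in range(n_users):
            for w in range(1, weeks + 1):
                for j in range(docs_per_cell):
                    day = start + timedelta(days=(w - 1) * 7 + int(rng.integers(0, 7)))
                    dow = day.weekday()
                    score = gamma[u] + week_eff[w] + day_eff[dow] + rng.normal(0, noise_sd)
                    if year == treatment_year:
                        score += delta.get(w, 0.0)
                    rows.append(
                        (f"u{u:03d}", f"d{doc:06d}", pd.Timestamp(day), year, w, dow, score)
                    )
                    doc += 1
    panel = pd.DataFrame(
        rows,
        columns=["user_id", "doc_id", "date", "year", "week_index", "day_of_week",
                 "lss_score"],
    )
    panel.attrs["baseline_year"] = baseline_year
    panel.attrs["treatment_year"] = treatment_year
    return panel


def write_dataset(data: SyntheticData, directory: str | Path) -> None:
    """Write the generated study to disk in the pipeline's input formats."""
    from .corpus import write_documents_jsonl

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_documents_jsonl(data.documents, directory / "docs.jsonl")
    data.attributes.to_csv(directory / "survey.csv", index=False)
    data.annotations.to_csv(directory / "annotations.csv", index=False)
    for name, table in data.exogenous.items():
        table.to_csv(directory / f"{name}.csv", index=False)
    truth_dir = directory / "truth"
    truth_dir.mkdir(exist_ok=True)
    data.truth.theta.rename("theta").to_csv(truth_dir / "theta.csv", index_label="term")
    data.truth.gamma.rename("gamma").to_csv(truth_dir / "gamma.csv", index_label="user_id")
    pd.Series(data.truth.delta, name="delta").to_csv(truth_dir / "delta.csv",
                                                     index_label="week")
    data.latent.to_csv(truth_dir / "latent.csv", index=False)
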