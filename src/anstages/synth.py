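"""Synthetic-cohort generator.

The study's real data (Twitter timelines of users across anorexia-nervosa
recovery stages) are private, so this module generates cohorts with the
statistical structure the downstream analyses assume:

* five user groups (AN, treatment, recovered, focused control, random
  control) with group-specific circadian tweet-rate profiles — the AN-like
  groups post relatively more during the night slots;
* group-specific lexicon-category emission rates (first-person singular,
  negative emotion and AN vocabulary elevated for AN users);
* per-user topic-interest distributions drawn from group-level Dirichlet
  parameters, expressed through topic-term filler tokens in tweets, likes
  and biographies;
* homophilous directed follow edges (AN / focused-control polarization);
* an emotion-mixture split of the AN group into precontemplation-like and
  contemplation-like subpopulations (positivity-dominant vs
  negativity-dominant, with distinct mean polarity);
* noisy multi-annotator label matrices driven by a confusion matrix.

Tweet times follow a thinned homogeneous Poisson process: the expected
count for a day is ``base_rate`` modulated by the day-of-week weight, and
within a day counts are spread over the eight 3-hour slots proportionally
to the group's slot multipliers.  The filler vocabulary is disjoint from
every lexicon phrase, so measured category rates equal emission rates in
expectation.

Determinism: one seed in the config; per-user randomness is derived by
stable hashing of (seed, user id, purpose) so that adding users does not
perturb existing ones.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import GROUPS, Cohort, Lexicon, PictureFeatures, Tweet, User

log = logging.getLogger(__name__)

STAGES = ("precontemplation", "contemplation")


def substream(seed: int, *keys) -> np.random.Generator:
    """Independent RNG derived by stable hashing of (seed, keys)."""
    h = hashlib.blake2b(repr((int(seed),) + keys).encode(), digest_size=8)
    return np.random.default_rng(int.from_bytes(h.digest(), "big") >> 1)


def _utc_epoch(y: int, m: int, d: int) -> int:
    return int(datetime(y, m, d, tzinfo=timezone.utc).timestamp())


@dataclass
class EmotionMixture:
    """One stage subpopulation: emotion emission-rate overrides plus the
    mean/sd of the per-tweet polarity distribution and its mixture weight."""

    rates: dict[str, float]
    polarity_mean: float
    polarity_sd: float = 0.05
    weight: float = 0.5


@dataclass
class CohortConfig:
    group_sizes: dict[str, int]
    date_range: tuple[int, int]
    base_rate: float
    slot_multipliers: dict[str, Sequence[float]]
    weekday_weights: dict[str, Sequence[float]]
    category_rates: dict[str, dict[str, float]]
    topic_concentration: dict[str, dict[str, float]]
    homophily: dict[str, dict[str, float]]
    out_degree_mean: float
    emotion_mixtures: dict[str, EmotionMixture]
    annotator_confusion: dict[str, dict[str, float]]
    seed: int
    # generation details beyond the core statistical structure
    lexicons: list[Lexicon] = field(default_factory=list)
    topic_terms: dict[str, list[str]] = field(default_factory=dict)
    filler_vocab: list[str] = field(default_factory=list)
    topic_token_rate: float = 0.35
    tweet_len_mean: float = 11.0
    bio_len: int = 12
    likes_mean: float = 10.0
    polarity_by_group: dict[str, tuple[float, float]] = field(default_factory=dict)
    with_pictures: bool = True
    with_demographics: bool = True

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group_sizes[{g}]: negative size {n}")
        if self.date_range[0] >= self.date_range[1]:
            raise ValueError("date_range: start must precede end")
        if self.base_rate < 0:
            raise ValueError("base_rate: must be >= 0")
        for g, mult in self.slot_multipliers.items():
            if len(mult) != 8:
                raise ValueError(f"slot_multipliers[{g}]: need exactly 8 values")
            if any(m < 0 for m in mult):
                raise ValueError(f"slot_multipliers[{g}]: negative multiplier")
        for g, w in self.weekday_weights.items():
            if len(w) != 7 or any(x < 0 for x in w):
                raise ValueError(f"weekday_weights[{g}]: need 7 non-negative values")
        known_cats = {c for lex in self.lexicons for c in lex.categories}
        for g, rates in self.category_rates.items():
            for c, r in rates.items():
                if not 0 <= r <= 1:
                    raise ValueError(f"category_rates[{g}][{c}]: {r} not in [0,1]")
                if known_cats and c not in known_cats:
                    raise ValueError(f"category_rates[{g}]: unknown category {c!r}")
            if sum(rates.values()) > 1:
                raise ValueError(f"category_rates[{g}]: emission probabilities sum > 1")
        for g, row in self.homophily.items():
            if any(v < 0 for v in row.values()):
                raise ValueError(f"homophily[{g}]: negative weight")
        if self.out_degree_mean < 0:
            raise ValueError("out_degree_mean: must be >= 0")
        total_w = sum(m.weight for m in self.emotion_mixtures.values())
        if self.emotion_mixtures and abs(total_w - 1) > 1e-9:
            raise ValueError("emotion_mixtures: mixture weights must sum to 1")
        for true_lab, row in self.annotator_confusion.items():
            s = sum(row.values())
            if abs(s - 1) > 1e-9:
                raise ValueError(f"annotator_confusion[{true_lab}]: row sums to {s}, not 1")
            if any(not 0 <= p <= 1 for p in row.values()):
                raise ValueError(f"annotator_confusion[{true_lab}]: probability out of [0,1]")


# ---------------------------------------------------------------------------
# Elementary samplers

def sample_tweet_times(n_days: int, daily_rate: float,
                       slot_multipliers: Sequence[float],
                       weekday_weights: Sequence[float],
                       rng: np.random.Generator,
                       start: int = 0) -> list[int]:
    """Thinned-Poisson tweet times over ``n_days`` starting at UTC epoch
    ``start``.  Expected count per slot is proportional to
    slot multiplier x weekday weight; the weekly mean daily count is
    ``daily_rate``."""
    mult = np.asarray(slot_multipliers, dtype=float)
    wk = np.asarray(weekday_weights, dtype=float)
    if daily_rate == 0 or n_days == 0:
        return []
    if mult.sum() == 0:
        raise ValueError("slot_multipliers: all zero with positive daily_rate")
    if wk.sum() == 0:
        raise ValueError("weekday_weights: all zero with positive daily_rate")
    slot_p = mult / mult.sum()
    day_scale = 7.0 * wk / wk.sum()
    out: list[int] = []
    day0 = start // 86400
    offset = start % 86400
    for day in range(n_days):
        dow = (day0 + day + 3) % 7  # epoch day 0 (1970-01-01) was a Thursday
        n = rng.poisson(daily_rate * day_scale[dow])
        if n == 0:
            continue
        slots = rng.choice(8, size=n, p=slot_p)
        within = rng.integers(0, 3 * 3600, size=n)
        out.extend(int(start - offset + day * 86400 + s * 3 * 3600 + w)
                   for s, w in zip(slots, within))
    out.sort()
    return out


def sample_tokens(length: int, category_rates: Mapping[str, float],
                  lexicons: Iterable[Lexicon], filler_vocab: Sequence[str],
                  rng: np.random.Generator,
                  filler_sampler=None) -> list[str]:
    """Token stream of the stated length.  Each position independently emits
    a phrase of category ``c`` with probability ``rate(c)`` (multi-token
    phrases consume their length), otherwise a filler token."""
    phrase_lists: dict[str, list[tuple[str, ...]]] = {}
    for lex in lexicons:
        for cat, phrases in lex.categories.items():
            phrase_lists.setdefault(cat, []).extend(sorted(phrases))
    cats = sorted(category_rates)
    for c in cats:
        if c not in phrase_lists:
            raise ValueError(f"category_rates: unknown category {c!r}")
    rates = np.array([category_rates[c] for c in cats], dtype=float)
    cum = np.cumsum(rates)
    out: list[str] = []
    while len(out) < length:
        r = rng.random()
        idx = int(np.searchsorted(cum, r, side="right")) if cats else len(cats)
        if idx < len(cats):
            choices = phrase_lists[cats[idx]]
            out.extend(choices[rng.integers(len(choices))])
        elif filler_sampler is not None:
            out.append(filler_sampler(rng))
        else:
            out.append(filler_vocab[rng.integers(len(filler_vocab))])
    return out[:length]


def sample_follow_edges(users_by_group: Mapping[str, Sequence[str]],
                        homophily: Mapping[str, Mapping[str, float]],
                        out_degree_mean: float,
                        rng: np.random.Generator) -> list[tuple[str, str]]:
    """Directed follow edges: per-user out-degree ~ Poisson(mean), target
    group chosen proportionally to the homophily row, target user uniform
    within the group.  Self-loops and duplicates dropped."""
    groups = sorted(users_by_group)
    n_total = sum(len(users_by_group[g]) for g in groups)
    edges: list[tuple[str, str]] = []
    for g in groups:
        row = np.array([homophily.get(g, {}).get(h, 0.0) for h in groups], dtype=float)
        if row.sum() == 0:
            raise ValueError(f"homophily[{g}]: row all zero")
        p = row / row.sum()
        for uid in users_by_group[g]:
            d = rng.poisson(out_degree_mean)
            if d == 0:
                continue
            if n_total <= 1:
                log.warning("sample_follow_edges: single-user cohort, no edges for %s", uid)
                continue
            seen: set[str] = set()
            tg = rng.choice(len(groups), size=d, p=p)
            for gi in tg:
                pool = users_by_group[groups[gi]]
                if not pool:
                    continue
                target = pool[rng.integers(len(pool))]
                if target != uid and target not in seen:
                    seen.add(target)
                    edges.append((uid, target))
    return edges


def sample_annotations(true_labels: Sequence[str],
                       confusion: Mapping[str, Mapping[str, float]],
                       n_annotators: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Items x annotators label matrix; each cell drawn independently from
    the confusion row of the item's true label."""
    if n_annotators < 2:
        raise ValueError("n_annotators: must be >= 2")
    label_space = sorted({lab for row in confusion.values() for lab in row})
    rows = []
    for lab in true_labels:
        if lab not in confusion:
            raise ValueError(f"true_labels: label {lab!r} absent from confusion matrix")
        p = np.array([confusion[lab].get(a, 0.0) for a in label_space], dtype=float)
        p = p / p.sum()
        rows.append([label_space[i] for i in rng.choice(len(label_space), size=n_annotators, p=p)])
    return np.array(rows, dtype=object)


# ---------------------------------------------------------------------------
# Default study conditions (desk-scale cohort)

def default_lexicons() -> list[Lexicon]:
    """Small demonstration lexicons mirroring the analysis's feature
    families: linguistic dimensions, eight basic emotions plus
    positive/negative, personal concerns, and anorexia-related vocabulary.
    These are synthetic stand-ins, not any proprietary dictionary."""
    linguistic = Lexicon.from_phrases("linguistic", {
        "first_person_singular": ["yo", "mi", "me", "mis", "conmigo", "mio", "mia"],
        "negation": ["no", "nunca", "jamas", "nada", "ni", "tampoco"],
        "article": ["el", "la", "los", "las", "un", "una", "unos", "unas"],
    })
    emolex = Lexicon.from_phrases("emolex", {
        "anger": ["rabia", "odio", "ira", "furia", "enfado"],
        "anticipation": ["esperar", "pronto", "plan", "futuro", "meta"],
        "disgust": ["asco", "repulsion", "nausea", "horrible"],
        "fear": ["miedo", "terror", "panico", "ansiedad", "temor"],
        "joy": ["feliz", "alegria", "sonrisa", "contenta", "reir"],
        "sadness": ["triste", "llorar", "pena", "dolor", "vacio", "sola"],
        "surprise": ["sorpresa", "increible", "inesperado", "asombro"],
        "trust": ["confianza", "apoyo", "amiga", "seguro", "fiel"],
        "positive": ["bien", "bueno", "amor", "gracias", "bonito", "mejor", "fuerza"],
        "negative": ["mal", "malo", "culpa", "fracaso", "peor", "sufrir", "gorda"],
    })
    concerns = Lexicon.from_phrases("concerns", {
        "body": ["cuerpo", "piernas", "cintura", "huesos", "piel", "espejo"],
        "ingest": ["comer", "comida", "calorias", "ayuno", "cena", "dieta"],
        "health": ["salud", "doctor", "hospital", "terapia", "medico"],
        "death": ["muerte", "morir", "desaparecer", "fin"],
        "work": ["trabajo", "oficina", "jefe", "empresa", "reunion"],
        "leisure": ["cine", "fiesta", "viaje", "juego", "playa"],
    })
    an_vocab = Lexicon.from_phrases("an_vocab", {
        "an_vocab": ["proana", "promia", "mi anorexia", "perder peso", "imc",
                     "sibutramina", "ana y mia", "peso objetivo", "kcal", "thinspo"],
    })
    return [linguistic, emolex, concerns, an_vocab]


def default_topic_terms(n_terms: int = 8) -> dict[str, list[str]]:
    topics = [
        "pain", "eating", "violence", "suffering", "health", "communication",
        "business", "work_topic", "internet", "sports", "music", "reading",
        "weddings", "friends", "family", "love", "fashion", "movies",
        "school", "travel", "animals", "cooking", "politics", "art",
        "science", "nature", "shopping", "technology", "childhood", "night",
    ]
    return {t: [f"{t}_term{i}" for i in range(n_terms)] for t in topics}


def _night_slot_profile(night: float) -> list[float]:
    """Slot multipliers with the two 00:00-06:00 slots at weight ``night``
    and the remaining six sharing the rest; the minimum adjacent pair is the
    night pair, so the asymptotic STTR is 2 x night / total."""
    rest = (1.0 - 2 * night) / 6.0
    return [night, night, rest, rest, rest, rest, rest, rest]


def default_config(seed: int = 0, scale: float = 1.0) -> CohortConfig:
    """Desk-scale defaults reproducing the structure of the study cohort:
    group proportions, night-posting ordering (AN > random control >
    focused control), elevated first-person/negative/AN vocabulary for the
    AN group, topic-interest tilts per group, AN/focused-control follow
    polarization, and a 2:1 precontemplation:contemplation emotion split."""
    sizes = {"AN": 40, "treatment": 8, "recovered": 6,
             "focused_control": 60, "random_control": 48}
    sizes = {g: max(2, int(round(n * scale))) for g, n in sizes.items()}
    lexicons = default_lexicons()
    topic_terms = default_topic_terms()
    base = {
        "first_person_singular": 0.055, "negation": 0.020, "article": 0.055,
        "anger": 0.006, "anticipation": 0.008, "disgust": 0.005, "fear": 0.006,
        "joy": 0.012, "sadness": 0.009, "surprise": 0.005, "trust": 0.008,
        "positive": 0.026, "negative": 0.015,
        "body": 0.004, "ingest": 0.005, "health": 0.006, "death": 0.002,
        "work": 0.008, "leisure": 0.009, "an_vocab": 0.0005,
    }

    def rates(**over) -> dict[str, float]:
        r = dict(base)
        r.update(over)
        return r

    category_rates = {
        "AN": rates(first_person_singular=0.090, negation=0.032, article=0.042,
                    anger=0.011, disgust=0.010, fear=0.013, joy=0.008,
                    sadness=0.020, positive=0.020, negative=0.034,
                    body=0.014, ingest=0.017, health=0.011, death=0.007,
                    work=0.003, leisure=0.004, an_vocab=0.014),
        "treatment": rates(first_person_singular=0.080, negation=0.026,
                           joy=0.013, sadness=0.014, positive=0.028, negative=0.024,
                           body=0.009, ingest=0.009, health=0.016, death=0.004,
                           an_vocab=0.008),
        "recovered": rates(first_person_singular=0.072, negation=0.022,
                           joy=0.015, sadness=0.010, positive=0.032, negative=0.018,
                           body=0.007, ingest=0.007, health=0.012, an_vocab=0.004),
        "focused_control": rates(first_person_singular=0.030, negation=0.014,
                                 article=0.070, joy=0.010, sadness=0.007,
                                 positive=0.030, negative=0.013,
                                 body=0.007, ingest=0.008, health=0.014,
                                 work=0.013, leisure=0.010, an_vocab=0.006),
        "random_control": rates(work=0.011, leisure=0.012),
    }

    def alphas(**tilt) -> dict[str, float]:
        a = {t: 1.0 for t in topic_terms}
        for t in ("friends", "family", "love", "music"):
            a[t] = 3.0
        a.update(tilt)
        return a

    topic_concentration = {
        "AN": alphas(pain=8, eating=8, violence=6, suffering=7, night=4, fashion=3),
        "treatment": alphas(eating=5, reading=5, music=6, sports=5, health=4),
        "recovered": alphas(sports=6, weddings=5, music=6, travel=4),
        "focused_control": alphas(health=8, communication=7, business=7,
                                  work_topic=6, internet=6, sports=5),
        "random_control": alphas(movies=5, sports=4, internet=4, music=5),
    }

    def hrow(own: str, **cross) -> dict[str, float]:
        row = {g: 0.03 for g in GROUPS}
        row[own] = 0.85
        row.update(cross)
        return row

    homophily = {
        "AN": hrow("AN", treatment=0.05, recovered=0.03, focused_control=0.01),
        "treatment": hrow("treatment", AN=0.06, recovered=0.05, focused_control=0.04),
        "recovered": hrow("recovered", treatment=0.05, focused_control=0.05, AN=0.02),
        "focused_control": hrow("focused_control", AN=0.01, random_control=0.04),
        "random_control": hrow("random_control", focused_control=0.04),
    }

    emotion_mixtures = {
        "precontemplation": EmotionMixture(
            rates={"joy": 0.016, "sadness": 0.012, "positive": 0.034, "negative": 0.016,
                   "anticipation": 0.012, "trust": 0.010},
            polarity_mean=0.19, polarity_sd=0.04, weight=2 / 3),
        "contemplation": EmotionMixture(
            rates={"joy": 0.006, "sadness": 0.026, "positive": 0.014, "negative": 0.040,
                   "fear": 0.016, "disgust": 0.012},
            polarity_mean=0.17, polarity_sd=0.04, weight=1 / 3),
    }

    # diagonals calibrated analytically so the expected Light kappa of
    # five independent annotators is ~0.48 — the moderate-agreement regime
    # this kind of clinical labeling task exhibits
    annotator_confusion = {
        "AN": {"AN": 0.84, "focused_control": 0.08, "doubtful": 0.08},
        "focused_control": {"AN": 0.08, "focused_control": 0.84, "doubtful": 0.08},
        "doubtful": {"AN": 0.18, "focused_control": 0.18, "doubtful": 0.64},
    }

    return CohortConfig(
        group_sizes=sizes,
        date_range=(_utc_epoch(2017, 12, 21), _utc_epoch(2018, 12, 21)),
        base_rate=1.0,
        slot_multipliers={
            "AN": _night_slot_profile(0.025),
            "treatment": _night_slot_profile(0.022),
            "recovered": _night_slot_profile(0.021),
            "focused_control": _night_slot_profile(0.015),
            "random_control": _night_slot_profile(0.020),
        },
        weekday_weights={
            "AN": [1, 1, 1, 1, 1, 1.1, 1.1],
            "treatment": [1, 1, 1, 1, 1, 1, 1],
            "recovered": [1, 1, 1, 1, 1, 1, 1],
            "focused_control": [1.1, 1.1, 1.1, 1.1, 1.1, 0.7, 0.7],
            "random_control": [1, 1, 1, 1, 1, 1.05, 1.05],
        },
        category_rates=category_rates,
        topic_concentration=topic_concentration,
        homophily=homophily,
        out_degree_mean=25.0,
        emotion_mixtures=emotion_mixtures,
        annotator_confusion=annotator_confusion,
        seed=seed,
        lexicons=lexicons,
        topic_terms=topic_terms,
        filler_vocab=[f"w{i:04d}" for i in range(400)],
        polarity_by_group={
            "AN": (0.18, 0.05), "treatment": (0.22, 0.05), "recovered": (0.25, 0.05),
            "focused_control": (0.24, 0.05), "random_control": (0.22, 0.05),
        },
    )


# ---------------------------------------------------------------------------
# Cohort assembly

def _topic_filler(theta: np.ndarray, topics: list[str],
                  topic_terms: Mapping[str, list[str]],
                  filler_vocab: Sequence[str], topic_token_rate: float):
    def sampler(rng: np.random.Generator) -> str:
        if topics and rng.random() < topic_token_rate:
            t = topics[rng.choice(len(topics), p=theta)]
            terms = topic_terms[t]
            return terms[rng.integers(len(terms))]
        return filler_vocab[rng.integers(len(filler_vocab))]
    return sampler


def _sample_picture(group: str, rng: np.random.Generator) -> PictureFeatures:
    objects_pool = ["person", "text_logo", "food", "flower", "animal",
                    "building", "screen", "drawing", "sky", "mirror"]
    p_obj = {"focused_control": [.2, .5, .15, .1, .1, .3, .25, .1, .1, .05],
             "random_control": [.4, .3, .15, .15, .2, .15, .15, .1, .15, .05]}
    probs = p_obj.get(group, [.45, .1, .2, .15, .15, .05, .05, .2, .1, .15])
    objects = [o for o, p in zip(objects_pool, probs) if rng.random() < p]
    has_text = rng.random() < (0.55 if group in ("focused_control", "random_control") else 0.2)
    has_faces = rng.random() < (0.35 if group == "focused_control" else 0.6)
    emotion_scores = None
    if has_faces:
        emos = ["happy", "sad", "neutral", "angry", "surprised"]
        tilt = {"AN": [1.5, 3.0, 2.0, 1.0, 0.5],
                "treatment": [2.5, 1.5, 2.0, 0.7, 0.6]}.get(group, [3.5, 0.8, 2.0, 0.5, 0.7])
        raw = rng.dirichlet(tilt)
        emotion_scores = {e: float(v) for e, v in zip(emos, raw)}
    return PictureFeatures(objects=objects, has_text=has_text, has_faces=has_faces,
                           is_grayscale=rng.random() < 0.15,
                           is_lighter=rng.random() < 0.5,
                           emotion_scores=emotion_scores)


def _sample_demo_scores(group: str, rng: np.random.Generator) -> dict[str, float]:
    org_mean = {"focused_control": 0.55, "random_control": 0.15}.get(group, 0.05)
    org = float(np.clip(rng.normal(org_mean, 0.18), 0, 1))
    female_bias = {"AN": 0.80, "treatment": 0.78, "recovered": 0.75}.get(group, 0.5)
    female = float(np.clip(rng.normal(female_bias, 0.15), 0, 1))
    male = float(np.clip(rng.normal(1 - female_bias, 0.15), 0, 1))
    age_keys = ["age_le18", "age_19_29", "age_30_39", "age_ge40"]
    age_tilt = {"AN": [3, 4, 1, 0.5], "treatment": [2, 4, 1.5, 0.7],
                "recovered": [1, 4, 2, 1]}.get(group, [1, 2, 2, 2])
    ages = rng.dirichlet(age_tilt)
    scores = {"male": male, "female": female, "organization": org}
    scores.update({k: float(v) for k, v in zip(age_keys, ages)})
    return scores


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort per the config; deterministic for a
    fixed seed.  Users carry their true group (and, for AN users, the true
    stage subpopulation as generator ground truth)."""
    config.validate()
    cohort = Cohort(date_range=config.date_range)
    n_days = int((config.date_range[1] - config.date_range[0]) // 86400)
    topics = sorted(config.topic_terms)
    mixtures = sorted(config.emotion_mixtures)
    mix_w = np.array([config.emotion_mixtures[m].weight for m in mixtures], dtype=float)
    users_by_group: dict[str, list[str]] = {}
    for group in sorted(config.group_sizes):
        users_by_group[group] = []
        for i in range(config.group_sizes[group]):
            uid = f"{group}_{i:04d}"
            users_by_group[group].append(uid)
            rng_t = substream(config.seed, uid, "times")
            times = sample_tweet_times(
                n_days, config.base_rate, config.slot_multipliers[group],
                config.weekday_weights[group], rng_t, start=config.date_range[0])
            rng_x = substream(config.seed, uid, "text")
            cat_rates = dict(config.category_rates.get(group, {}))
            true_stage = None
            pol_mean, pol_sd = config.polarity_by_group.get(group, (0.5, 0.05))
            if group == "AN" and mixtures:
                true_stage = mixtures[rng_x.choice(len(mixtures), p=mix_w / mix_w.sum())]
                mix = config.emotion_mixtures[true_stage]
                cat_rates.update(mix.rates)
                pol_mean, pol_sd = mix.polarity_mean, mix.polarity_sd
            if topics:
                alpha = np.array([config.topic_concentration[group][t] for t in topics])
                theta = rng_x.dirichlet(alpha)
            else:
                theta = np.array([])
            filler = _topic_filler(theta, topics, config.topic_terms,
                                   config.filler_vocab, config.topic_token_rate)
            tweets = []
            for j, ts in enumerate(times):
                length = int(rng_x.poisson(config.tweet_len_mean)) + 1
                toks = sample_tokens(length, cat_rates, config.lexicons,
                                     config.filler_vocab, rng_x, filler_sampler=filler)
                tweets.append(Tweet(
                    tweet_id=f"{uid}_t{j:05d}", author_id=uid, created_at=ts,
                    text=" ".join(toks), tokens=toks,
                    polarity=float(np.clip(rng_x.normal(pol_mean, pol_sd), 0, 1))))
            rng_l = substream(config.seed, uid, "likes")
            liked = []
            for j in range(int(rng_l.poisson(config.likes_mean))):
                length = int(rng_l.poisson(config.tweet_len_mean)) + 1
                toks = sample_tokens(length, cat_rates, config.lexicons,
                                     config.filler_vocab, rng_l, filler_sampler=filler)
                liked.append(Tweet(tweet_id=f"{uid}_l{j:05d}", author_id="external",
                                   created_at=config.date_range[0], text=" ".join(toks),
                                   tokens=toks))
            bio = sample_tokens(config.bio_len, cat_rates, config.lexicons,
                                config.filler_vocab, rng_x, filler_sampler=filler)
            rng_p = substream(config.seed, uid, "profile")
            cohort.add(User(
                user_id=uid, group=group, tweets=tweets, liked=liked,
                bio_tokens=bio,
                picture=_sample_picture(group, rng_p) if config.with_pictures else None,
                demo_scores=_sample_demo_scores(group, rng_p) if config.with_demographics else None,
                true_stage=true_stage))
    rng_e = substream(config.seed, "edges")
    edges = sample_follow_edges(users_by_group, config.homophily,
                                config.out_degree_mean, rng_e)
    for src, dst in edges:
        cohort.users[src].followee_ids.append(dst)
    return cohort
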