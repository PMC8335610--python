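"""Lexicon-based text features.

Each user's tweets are concatenated (in chronological order, separated by a
sentinel so that no phrase can span a tweet boundary) and every lexicon
category is scored as the number of phrase matches normalized by the total
token count.  Matching is longest-first (trigram before bigram before
unigram) and non-overlapping within a category, so nested n-grams are not
double counted; a token may still feed several categories, following the
word-count convention of psycholinguistic dictionaries.  Emotion lexicons
(eight basic emotions plus positive/negative) are scored the same way, one
category at a time.  Median tweet length (in tokens) and the median of the
per-tweet polarity scores complete the per-user feature battery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import Cohort, Lexicon, User

#: sentinel inserted between tweets during concatenation; never a real token
SENTINEL = "\x00"

EMOTIONS = ("anger", "anticipation", "disgust", "fear",
            "joy", "sadness", "surprise", "trust")


def concat_tokens(user: User) -> list[str]:
    """All tweet tokens in chronological order, sentinel-separated."""
    out: list[str] = []
    for i, tweet in enumerate(user.tweets):
        if i:
            out.append(SENTINEL)
        out.extend(tweet.ensure_tokens())
    return out


def count_matches(tokens: Sequence[str], phrases: set[tuple[str, ...]]) -> int:
    """Longest-first, non-overlapping phrase matches in a token stream."""
    lengths = sorted({len(p) for p in phrases}, reverse=True)
    n = len(tokens)
    i = 0
    matches = 0
    while i < n:
        if tokens[i] == SENTINEL:
            i += 1
            continue
        for length in lengths:
            if i + length <= n and tuple(tokens[i:i + length]) in phrases:
                matches += 1
                i += length
                break
        else:
            i += 1
    return matches


def category_rate(tokens: Sequence[str], phrases: set[tuple[str, ...]]) -> float:
    """Matches per token; sentinels excluded from the denominator; 0 for an
    empty token list."""
    denom = sum(1 for t in tokens if t != SENTINEL)
    if denom == 0:
        return 0.0
    return count_matches(tokens, phrases) / denom


def emolex_profile(tokens: Sequence[str], emotion_lexicon: Lexicon) -> dict[str, float]:
    """Per-emotion rates (plus positive/negative if present).  A word listed
    under several emotions counts toward each; within one emotion matching
    is non-overlapping."""
    return {cat: category_rate(tokens, phrases)
            for cat, phrases in emotion_lexicon.categories.items()}


def polarity_median(scores: Sequence[float]) -> float:
    """Median per-tweet polarity; NaN (missing, not zero) for no scores."""
    if len(scores) == 0:
        return math.nan
    return float(np.median(np.asarray(scores, dtype=float)))


def standin_polarity(tokens: Sequence[str], emotion_lexicon: Lexicon) -> float:
    """Lexicon-ratio sentiment score p/(p+n) in [0, 1]; 0.5 when the text
    matches neither polarity list.  A transparent stand-in for an external
    sentiment model."""
    p = count_matches(tokens, emotion_lexicon.categories["positive"])
    n = count_matches(tokens, emotion_lexicon.categories["negative"])
    if p + n == 0:
        return 0.5
    return p / (p + n)


@dataclass
class UserTextFeatures:
    rates: dict[str, float]
    median_tweet_length: float
    polarity_median: float
    token_total: int


def user_text_features(user: User, lexicons: Iterable[Lexicon],
                       polarity_lexicon: Lexicon | None = None) -> UserTextFeatures:
    tokens = concat_tokens(user)
    token_total = sum(1 for t in tokens if t != SENTINEL)
    rates: dict[str, float] = {}
    for lex in lexicons:
        for cat, phrases in lex.categories.items():
            rates[cat] = category_rate(tokens, phrases)
    lengths = [len(t.ensure_tokens()) for t in user.tweets]
    med_len = float(np.median(lengths)) if lengths else math.nan
    pols = [t.polarity for t in user.tweets if t.polarity is not None]
    if pols:
        pol = polarity_median(pols)
    elif polarity_lexicon is not None and user.tweets:
        pol = polarity_median([standin_polarity(t.ensure_tokens(), polarity_lexicon)
                               for t in user.tweets])
    else:
        pol = math.nan
    return UserTextFeatures(rates, med_len, pol, token_total)


def build_feature_table(cohort: Cohort, lexicons: Iterable[Lexicon],
                        polarity_lexicon: Lexicon | None = None) -> pd.DataFrame:
    """One row per user: every category rate, median tweet length, polarity
    median and total token count.  Zero-token users get zero rates and
    missing length/polarity."""
    lexicons = list(lexicons)
    rows = {}
    for uid, user in cohort.users.items():
        f = user_text_features(user, lexicons, polarity_lexicon)
        row = dict(f.rates)
        row["median_tweet_length"] = f.median_tweet_length
        row["polarity_median"] = f.polarity_median
        row["token_total"] = f.token_total
        rows[uid] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("user_id")
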