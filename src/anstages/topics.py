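"""Topic-interest profiling and hierarchical aggregation.

Per-text topic score is the fraction of tokens belonging to the topic's
term set (a normalized term-membership count).  A user's own
profile averages per-text scores over three sampled pools: their own tweets
(capped), tweets they liked (capped) and biographies of sampled followees.
Followee profiles use a three-level aggregation: mean over texts per
followee, median over a user's followees, median over the group's users.
Group profiles are per-topic medians, reported at an optional display scale
(the study multiplied medians by 1000 for readability).  Profiles are
compared by Spearman rank correlation over the shared topic set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .corpus import Cohort, User
from .synth import substream

log = logging.getLogger(__name__)


@dataclass
class SamplingPlan:
    own_tweets_cap: int = 500
    liked_cap: int = 200
    followee_bios_cap: int = 200
    followees_per_user_cap: int = 25
    users_per_group_cap: int = 25
    # per-followee text pools in the followee-level analysis
    followee_own_tweets_cap: int = 200
    followee_liked_cap: int = 200
    followee_bio_sample: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("own_tweets_cap", "liked_cap", "followee_bios_cap",
                     "followees_per_user_cap", "users_per_group_cap",
                     "followee_own_tweets_cap", "followee_liked_cap",
                     "followee_bio_sample"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name}: must be >= 0")


@dataclass
class TopicProfile:
    level: str  # text | user | followee | group
    scores: dict[str, float] = field(default_factory=dict)
    display_scale: float = 1.0
    missing: bool = False

    def display(self) -> dict[str, float]:
        return {t: s * self.display_scale for t, s in self.scores.items()}


def topic_score(tokens: Sequence[str], topic_terms: set[str] | frozenset[str]) -> float:
    """Fraction of tokens inside the topic term set; 0 for empty text."""
    if not topic_terms:
        raise ValueError("topic_terms: empty topic set")
    if not tokens:
        return 0.0
    return sum(1 for t in tokens if t in topic_terms) / len(tokens)


def _cap(items: list, cap: int, rng: np.random.Generator) -> list:
    if len(items) <= cap:
        return list(items)
    idx = rng.choice(len(items), size=cap, replace=False)
    return [items[i] for i in sorted(idx)]


def _score_texts(texts: Iterable[Sequence[str]],
                 topics: Mapping[str, set[str]]) -> dict[str, float] | None:
    texts = [list(t) for t in texts]
    if not texts:
        return None
    return {name: float(np.mean([topic_score(toks, terms) for toks in texts]))
            for name, terms in topics.items()}


def _user_text_pools(user: User, cohort: Cohort, topics: Mapping[str, set[str]],
                     plan: SamplingPlan, own_cap: int, liked_cap: int,
                     bios_cap: int) -> list[list[str]]:
    rng = substream(plan.seed, "topics", user.user_id)
    texts: list[list[str]] = []
    texts += [t.ensure_tokens() for t in _cap(user.tweets, own_cap, rng)]
    texts += [t.ensure_tokens() for t in _cap(user.liked, liked_cap, rng)]
    followees = [cohort.users[f] for f in user.followee_ids if f in cohort.users]
    texts += [f.bio_tokens for f in _cap(followees, bios_cap, rng) if f.bio_tokens]
    return texts


def user_interest_profile(user: User, cohort: Cohort,
                          topics: Mapping[str, set[str]],
                          plan: SamplingPlan) -> TopicProfile:
    """Per-topic unweighted mean of per-text scores over the user's sampled
    own tweets, liked tweets and followee biographies."""
    texts = _user_text_pools(user, cohort, topics, plan,
                             plan.own_tweets_cap, plan.liked_cap,
                             plan.followee_bios_cap)
    scores = _score_texts(texts, topics)
    if scores is None:
        return TopicProfile("user", {t: math.nan for t in topics}, missing=True)
    return TopicProfile("user", scores)


def group_profile(profiles: Iterable[TopicProfile],
                  display_scale: float = 1.0) -> TopicProfile:
    """Per-topic median across non-missing user profiles."""
    profiles = [p for p in profiles if not p.missing]
    if not profiles:
        raise ValueError("group_profile: all user profiles missing")
    topics = profiles[0].scores.keys()
    scores = {t: float(np.median([p.scores[t] for p in profiles])) for t in topics}
    return TopicProfile("group", scores, display_scale=display_scale)


def followee_group_profile(group_users: Sequence[User], cohort: Cohort,
                           topics: Mapping[str, set[str]],
                           plan: SamplingPlan,
                           display_scale: float = 1.0) -> TopicProfile:
    """Three-level aggregation of followee interests: mean over texts per
    followee, median over a user's followees, median over the group's
    sampled users.  Users with zero resolvable followees are excluded from
    the outer median."""
    rng = substream(plan.seed, "topics", "followee_group")
    users = _cap(sorted(group_users, key=lambda u: u.user_id),
                 plan.users_per_group_cap, rng)
    user_scores: list[dict[str, float]] = []
    for user in users:
        followees = [cohort.users[f] for f in user.followee_ids if f in cohort.users]
        followees = _cap(followees, plan.followees_per_user_cap,
                         substream(plan.seed, "topics", "fsel", user.user_id))
        per_followee: list[dict[str, float]] = []
        for fw in followees:
            texts = _user_text_pools(fw, cohort, topics, plan,
                                     plan.followee_own_tweets_cap,
                                     plan.followee_liked_cap,
                                     plan.followee_bio_sample)
            s = _score_texts(texts, topics)
            if s is not None:
                per_followee.append(s)
        if not per_followee:
            log.info("followee_group_profile: user %s has no scorable followees",
                     user.user_id)
            continue
        user_scores.append({t: float(np.median([s[t] for s in per_followee]))
                            for t in topics})
    if not user_scores:
        raise ValueError("followee_group_profile: no user had scorable followees")
    scores = {t: float(np.median([s[t] for s in user_scores])) for t in topics}
    return TopicProfile("followee", scores, display_scale=display_scale)


def profile_spearman(a: TopicProfile, b: TopicProfile) -> float:
    """Spearman rank correlation between two profiles over the shared topic
    set (average ranks on ties); NaN for constant profiles."""
    if set(a.scores) != set(b.scores):
        raise ValueError("profiles cover different topic sets")
    topics = sorted(a.scores)
    if len(topics) < 3:
        raise ValueError("need at least 3 topics")
    x = np.array([a.scores[t] for t in topics])
    y = np.array([b.scores[t] for t in topics])
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("profile_spearman: constant profile, correlation undefined")
        return math.nan
    return float(sps.spearmanr(x, y).statistic)


def top_topics(profile: TopicProfile, n: int = 20) -> list[tuple[str, float]]:
    """Top-n topics by descending score (ties broken lexicographically),
    values on the profile's display scale."""
    if profile.missing:
        raise ValueError("profile is missing")
    ranked = sorted(profile.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(t, s * profile.display_scale) for t, s in ranked[:n]]
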