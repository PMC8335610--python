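"""Decision rules over externally supplied profile-picture and demographic
scores.

The gender/age scores come from an external multimodal classifier and the
picture features from external vision models; this module only applies the
study's decision rules: the organization label requires a score strictly
above 0.70 *and* strictly above both gender scores; organizations
short-circuit to the organization age group; picture objects form a boolean
bag restricted to objects seen in at least five users' pictures; users with
faces get the argmax emotion; group-level summaries are ratios of users.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .corpus import User

log = logging.getLogger(__name__)

AGE_KEYS = ("age_le18", "age_19_29", "age_30_39", "age_ge40")


@dataclass
class DemographicAssignment:
    gender: str  # male | female | organization
    age_group: str  # age_le18 | age_19_29 | age_30_39 | age_ge40 | organization

    def __post_init__(self) -> None:
        if (self.gender == "organization") != (self.age_group == "organization"):
            raise ValueError("organization gender and age group must co-occur")


def assign_gender_org(scores: Mapping[str, float], org_threshold: float = 0.70) -> str:
    """Organization iff its score is strictly over the threshold and
    strictly higher than both gender scores; otherwise the larger of the
    male/female scores.  An exact male/female tie is an error (degenerate
    upstream scores)."""
    for k in ("male", "female", "organization"):
        if k not in scores:
            raise ValueError(f"scores: missing {k!r}")
    org, male, female = scores["organization"], scores["male"], scores["female"]
    if org > org_threshold and org > male and org > female:
        return "organization"
    if male == female:
        raise ValueError("male/female scores exactly tied; resolve manually")
    return "male" if male > female else "female"


def assign_age(scores: Mapping[str, float], gender: str) -> str:
    """Argmax age range; organizations short-circuit to the organization
    age group.  Ties resolve to the lowest range (logged)."""
    if gender == "organization":
        return "organization"
    missing = [k for k in AGE_KEYS if k not in scores]
    if missing:
        raise ValueError(f"scores: missing {missing}")
    best = max(scores[k] for k in AGE_KEYS)
    winners = [k for k in AGE_KEYS if scores[k] == best]
    if len(winners) > 1:
        log.info("assign_age: tie among %s, taking lowest range", winners)
    return winners[0]


def assign_demographics(scores: Mapping[str, float],
                        org_threshold: float = 0.70) -> DemographicAssignment:
    gender = assign_gender_org(scores, org_threshold)
    return DemographicAssignment(gender, assign_age(scores, gender))


def object_bow(users: Iterable[User], min_images: int = 5) -> pd.DataFrame:
    """Boolean object bag over profile pictures, restricted to objects
    appearing in at least ``min_images`` distinct users' pictures."""
    users = [u for u in users if u.picture is not None]
    support: dict[str, int] = {}
    for u in users:
        for obj in set(o.lower() for o in u.picture.objects):
            support[obj] = support.get(obj, 0) + 1
    vocab = sorted(o for o, c in support.items() if c >= min_images)
    rows = {u.user_id: {o: (o in {x.lower() for x in u.picture.objects})
                        for o in vocab}
            for u in users}
    return pd.DataFrame.from_dict(rows, orient="index", dtype=bool) \
        .reindex(columns=vocab).rename_axis("user_id")


def dominant_emotion(picture) -> str | None:
    """Argmax emotion for pictures with faces; None otherwise.  Ties
    resolve lexicographically (logged)."""
    if picture is None or not picture.has_faces or not picture.emotion_scores:
        return None
    best = max(picture.emotion_scores.values())
    winners = sorted(e for e, v in picture.emotion_scores.items() if v == best)
    if len(winners) > 1:
        log.info("dominant_emotion: tie among %s", winners)
    return winners[0]


def group_user_ratios(values: Mapping[str, str | bool | None],
                      groups: Mapping[str, str]) -> pd.DataFrame:
    """Per group and feature value, the fraction of the group's users with
    that value; users with a missing value are excluded, so categorical
    ratios over present users sum to 1."""
    df = pd.DataFrame({"value": pd.Series(dict(values)),
                       "group": pd.Series(dict(groups))}).dropna(subset=["group"])
    out: dict[str, dict] = {}
    for g, sub in df.groupby("group"):
        present = sub["value"].dropna()
        if len(sub) == 0:
            raise ValueError(f"group {g}: empty")
        counts = present.value_counts()
        out[g] = {str(v): c / len(present) for v, c in counts.items()} if len(present) else {}
    return pd.DataFrame.from_dict(out, orient="index").fillna(0.0).rename_axis("group")
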