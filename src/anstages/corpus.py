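"""Core data model: users, tweets, lexicons, text scrubbing, tokenization,
cohort-inclusion filters and plain-text I/O.

The cohort is a set of users, each carrying their own tweets (retweets are
never part of a cohort), liked tweets, a tokenized biography, followee ids
and optionally externally supplied picture/demographic scores.  All text
passes through :func:`scrub_text` (anonymization tags) before
:func:`tokenize`; every module downstream shares this tokenizer.

Storage is deliberately plain text: JSON Lines for users/tweets/likes, a
two-column TSV edge list for the follow graph, TSV lexicons
(``category<TAB>phrase``).
"""

from __future__ import annotations

import json
import logging
import math
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger(__name__)

GROUPS = ("AN", "treatment", "recovered", "focused_control", "random_control")
#: groups plus the sentinel for network nodes without a seed label
GROUPS_EXT = GROUPS + ("unlabeled",)

# Protected generic tags survive tokenization as single tokens.
TAGS = ("<user>", "<url>", "<email>", "<number>", "<money>", "<hashtag>", "<emoticon>")

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_EMAIL_RE = re.compile(r"\b[\w.+-]+@[\w-]+\.[\w.-]+\b")
_MENTION_RE = re.compile(r"@\w+")
_NUMBER_RE = re.compile(r"(?<![\w<])\d+(?:[.,]\d+)*(?![\w>])")
_TAG_RE = "|".join(re.escape(t) for t in TAGS)
_TOKEN_RE = re.compile(rf"(?:{_TAG_RE})|\w+", re.UNICODE)


def scrub_text(text: str) -> str:
    """Replace personal identifiers with generic tags.

    @-mentions become ``<user>``, URLs ``<url>``, e-mail addresses
    ``<email>`` and standalone numbers ``<number>``.  The function is
    idempotent: tags themselves are never re-matched.
    """
    text = _URL_RE.sub("<url>", text)
    text = _EMAIL_RE.sub("<email>", text)
    text = _MENTION_RE.sub("<user>", text)
    text = _NUMBER_RE.sub("<number>", text)
    return text


def tokenize(text: str) -> list[str]:
    """Lowercase and split on whitespace/punctuation.

    Generic tags are kept as single tokens; the hashtag mark is stripped
    and the word kept (``#proana`` -> ``proana``).
    """
    return _TOKEN_RE.findall(text.lower())


def fold_accents(token: str) -> str:
    """Strip combining accents (``anorexía`` -> ``anorexia``)."""
    return "".join(
        c for c in unicodedata.normalize("NFKD", token) if not unicodedata.combining(c)
    )


@dataclass
class Tweet:
    tweet_id: str
    author_id: str
    created_at: int  # UTC epoch seconds
    text: str
    tokens: list[str] = field(default_factory=list)
    polarity: float | None = None  # externally supplied sentiment in [0, 1]

    def ensure_tokens(self) -> list[str]:
        if not self.tokens and self.text:
            self.tokens = tokenize(scrub_text(self.text))
        return self.tokens


@dataclass
class PictureFeatures:
    """Boolean/score features of a profile picture, supplied externally."""

    objects: list[str] = field(default_factory=list)
    has_text: bool = False
    has_faces: bool = False
    is_grayscale: bool = False
    is_lighter: bool = False
    emotion_scores: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.emotion_scores is not None and not self.has_faces:
            raise ValueError("emotion_scores present but has_faces is False")


@dataclass
class User:
    user_id: str
    group: str = "unlabeled"
    tweets: list[Tweet] = field(default_factory=list)
    liked: list[Tweet] = field(default_factory=list)
    bio_tokens: list[str] = field(default_factory=list)
    followee_ids: list[str] = field(default_factory=list)
    picture: PictureFeatures | None = None
    demo_scores: dict[str, float] | None = None
    true_stage: str | None = None  # generator ground truth, never used by analyses

    def __post_init__(self) -> None:
        if self.group not in GROUPS_EXT:
            raise ValueError(f"group: unknown group {self.group!r}")
        self.tweets.sort(key=lambda t: t.created_at)
        self.followee_ids = [f for f in self.followee_ids if f != self.user_id]

    def timestamps(self) -> list[int]:
        return [t.created_at for t in self.tweets]


@dataclass
class Cohort:
    users: dict[str, User] = field(default_factory=dict)
    date_range: tuple[int, int] | None = None

    def add(self, user: User) -> None:
        if user.user_id in self.users:
            raise ValueError(f"user_id: duplicate {user.user_id!r}")
        self.users[user.user_id] = user

    def __len__(self) -> int:
        return len(self.users)

    def by_group(self, group: str) -> list[User]:
        return [u for u in self.users.values() if u.group == group]

    def edges(self) -> list[tuple[str, str]]:
        """Directed follower -> followee pairs, deduplicated, order-stable."""
        out: list[tuple[str, str]] = []
        seen: set[tuple[str, str]] = set()
        for u in self.users.values():
            for f in u.followee_ids:
                e = (u.user_id, f)
                if e not in seen:
                    seen.add(e)
                    out.append(e)
        return out


@dataclass
class Lexicon:
    """Named category -> set of phrases, each phrase a tuple of 1-3 tokens."""

    name: str
    categories: dict[str, set[tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat, phrases in self.categories.items():
            for p in phrases:
                if not 1 <= len(p) <= 3:
                    raise ValueError(f"categories[{cat}]: phrase length {len(p)} not in 1-3")
            if not phrases:
                log.warning("lexicon %s: category %s is empty", self.name, cat)

    @classmethod
    def from_phrases(cls, name: str, categories: dict[str, Iterable[str]]) -> "Lexicon":
        return cls(
            name,
            {c: {tuple(tokenize(p)) for p in ps} for c, ps in categories.items()},
        )


# ---------------------------------------------------------------------------
# Cohort-inclusion filters

def filter_cohort(cohort: Cohort, min_period_tweets: int = 5) -> Cohort:
    """Drop users with fewer than ``min_period_tweets`` own tweets inside the
    cohort date range (users below the activity floor are uninformative)."""
    lo, hi = cohort.date_range if cohort.date_range else (-math.inf, math.inf)
    kept: dict[str, User] = {}
    removed = 0
    for uid, u in cohort.users.items():
        n = sum(1 for t in u.tweets if lo <= t.created_at <= hi)
        if n >= min_period_tweets:
            kept[uid] = u
        else:
            removed += 1
    log.info("filter_cohort: kept %d users, removed %d", len(kept), removed)
    return Cohort(users=kept, date_range=cohort.date_range)


def _contains_phrase(tokens: Sequence[str], phrases: set[tuple[str, ...]],
                     accent_fold: bool) -> bool:
    toks = [fold_accents(t) for t in tokens] if accent_fold else list(tokens)
    n = len(toks)
    for length in (1, 2, 3):
        for i in range(n - length + 1):
            if tuple(toks[i:i + length]) in phrases:
                return True
    return False


def keyword_tweet_filter(users: Iterable[User], keyword_phrases: Iterable[str],
                         min_matches: int = 3, accent_fold: bool = True) -> list[User]:
    """Keep users with at least ``min_matches`` *distinct* tweets each
    containing at least one keyword phrase (contiguous token match).

    Matching is case-normalized (the tokenizer lowercases) and, by default,
    accent-insensitive.
    """
    phrase_set = {tuple(tokenize(p)) for p in keyword_phrases}
    phrase_set = {p for p in phrase_set if p}
    if not phrase_set:
        raise ValueError("keyword_phrases: empty phrase set")
    if accent_fold:
        phrase_set = {tuple(fold_accents(t) for t in p) for p in phrase_set}
    kept = []
    for u in users:
        hits = sum(
            1 for t in u.tweets if _contains_phrase(t.ensure_tokens(), phrase_set, accent_fold)
        )
        if hits >= min_matches:
            kept.append(u)
    return kept


# ---------------------------------------------------------------------------
# Plain-text I/O

def _tweet_to_rec(t: Tweet) -> dict:
    rec = {"tweet_id": t.tweet_id, "author_id": t.author_id,
           "created_at": t.created_at, "text": t.text}
    if t.polarity is not None:
        rec["polarity"] = t.polarity
    return rec


def _tweet_from_rec(rec: dict) -> Tweet:
    return Tweet(rec["tweet_id"], rec["author_id"], int(rec["created_at"]),
                 rec["text"], polarity=rec.get("polarity"))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as JSON Lines (users, tweets, likes) plus a TSV edge
    list under directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "users.jsonl", "w") as fh:
        if cohort.date_range is not None:
            fh.write(json.dumps({"_meta": "date_range",
                                 "lo": cohort.date_range[0],
                                 "hi": cohort.date_range[1]}) + "\n")
        for u in cohort.users.values():
            rec: dict = {"user_id": u.user_id, "group": u.group,
                         "bio_tokens": u.bio_tokens}
            if u.true_stage is not None:
                rec["true_stage"] = u.true_stage
            if u.demo_scores is not None:
                rec["demo_scores"] = u.demo_scores
            if u.picture is not None:
                rec["picture"] = {
                    "objects": u.picture.objects, "has_text": u.picture.has_text,
                    "has_faces": u.picture.has_faces,
                    "is_grayscale": u.picture.is_grayscale,
                    "is_lighter": u.picture.is_lighter,
                    "emotion_scores": u.picture.emotion_scores,
                }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    with open(path / "tweets.jsonl", "w") as fh:
        for u in cohort.users.values():
            for t in u.tweets:
                fh.write(json.dumps(_tweet_to_rec(t), sort_keys=True) + "\n")
    with open(path / "likes.jsonl", "w") as fh:
        for u in cohort.users.values():
            for t in u.liked:
                rec = _tweet_to_rec(t)
                rec["liked_by"] = u.user_id
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
    with open(path / "edges.tsv", "w") as fh:
        for u in cohort.users.values():
            for f in u.followee_ids:
                fh.write(f"{u.user_id}\t{f}\n")


def _jsonl_records(fpath: Path) -> Iterable[tuple[int, dict]]:
    with open(fpath) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                yield lineno, json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{fpath.name}: malformed record at line {lineno}") from exc


def read_cohort(path: str | Path) -> Cohort:
    """Inverse of :func:`write_cohort`; ``read(write(c))`` is structurally
    equal to ``c``."""
    path = Path(path)
    cohort = Cohort()
    for lineno, rec in _jsonl_records(path / "users.jsonl"):
        if rec.get("_meta") == "date_range":
            cohort.date_range = (int(rec["lo"]), int(rec["hi"]))
            continue
        try:
            pic = None
            if "picture" in rec:
                p = rec["picture"]
                pic = PictureFeatures(
                    objects=p["objects"], has_text=p["has_text"],
                    has_faces=p["has_faces"], is_grayscale=p["is_grayscale"],
                    is_lighter=p["is_lighter"], emotion_scores=p["emotion_scores"],
                )
            cohort.add(User(
                user_id=rec["user_id"], group=rec["group"],
                bio_tokens=rec.get("bio_tokens", []),
                demo_scores=rec.get("demo_scores"),
                true_stage=rec.get("true_stage"),
                picture=pic,
            ))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"users.jsonl: malformed record at line {lineno}: {exc}") from exc
    tweets_f = path / "tweets.jsonl"
    if tweets_f.exists():
        for lineno, rec in _jsonl_records(tweets_f):
            try:
                t = _tweet_from_rec(rec)
            except KeyError as exc:
                raise ValueError(f"tweets.jsonl: malformed record at line {lineno}") from exc
            if t.author_id in cohort.users:
                cohort.users[t.author_id].tweets.append(t)
    likes_f = path / "likes.jsonl"
    if likes_f.exists():
        for lineno, rec in _jsonl_records(likes_f):
            uid = rec.get("liked_by")
            if uid in cohort.users:
                cohort.users[uid].liked.append(_tweet_from_rec(rec))
    edges_f = path / "edges.tsv"
    if edges_f.exists():
        with open(edges_f) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"edges.tsv: malformed record at line {lineno}")
                src, dst = parts
                if src in cohort.users and dst not in cohort.users[src].followee_ids:
                    if dst != src:
                        cohort.users[src].followee_ids.append(dst)
    for u in cohort.users.values():
        u.tweets.sort(key=lambda t: t.created_at)
    return cohort


def read_lexicon(path: str | Path, name: str | None = None) -> Lexicon:
    """Read a ``category<TAB>phrase`` TSV lexicon."""
    path = Path(path)
    cats: dict[str, set[tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path.name}: malformed record at line {lineno}")
            cat, phrase = parts
            cats.setdefault(cat, set()).add(tuple(tokenize(phrase)))
    return Lexicon(name or path.stem, cats)


def write_lexicon(lex: Lexicon, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cat in sorted(lex.categories):
            for phrase in sorted(lex.categories[cat]):
                fh.write(f"{cat}\t{' '.join(phrase)}\n")
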