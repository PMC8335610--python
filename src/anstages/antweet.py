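"""Bag-of-words classifier for anorexia-related tweets.

Pipeline: tweet preprocessing (anonymization tags, money/hashtag/emoticon
tags, stop-word removal) -> tf-idf over (1-3)-gram terms -> centered PCA to
at most 300 components -> L2 logistic regression.  Cross-validation is
stratified 10-fold with the vectorizer and PCA refit inside each fold, so
the reported precision/recall/F1 for the anorexia-related class carry no
transform leakage.  The classifier posterior for a tweet is its score in
[0, 1]; the per-user feature used in group comparisons is the median score
over all the user's tweets.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .corpus import scrub_text, tokenize

log = logging.getLogger(__name__)

POSITIVE_CLASS = "anorexia_related"
NEGATIVE_CLASS = "control"

#: Spanish function-word core plus the bare minimum of English ones; the
#: list is a declared, overridable default.
STOP_WORDS = frozenset("""
de la que el en y a los del se las por un para con no una su al lo como mas
pero sus le ya o este si porque esta entre cuando muy sin sobre tambien me
hasta hay donde quien desde todo nos durante todos uno les ni contra otros
ese eso ante ellos e esto mi antes algunos que unos yo otro otras otra el
tanto esa estos mucho quienes nada muchos cual poco ella estar estas algunas
algo nosotros tu te ti
the a an and or of to in for on at is are was be
""".split())

_MONEY_RE = re.compile(r"(?:[$€£]\s?\d[\d.,]*|\d[\d.,]*\s?(?:[$€£]|euros?|pesos?|dolares?))")
_HASHTAG_RE = re.compile(r"#(\w+)")
_EMOTICON_RE = re.compile(r"""(?x)
    (?<![\w])
    (?: [:;=8xX] ['-]? [)(\[\]DPpOo3*/\\|] | <3 | [)(\[\]DPpOo] ['-]? [:;=8] )
    (?![\w])
""")


def preprocess_tweet(text: str, stop_words: frozenset[str] = STOP_WORDS) -> list[str]:
    """Scrub + tokenize with money/hashtag/emoticon tags and stop-word
    removal; idempotent on its own (re-joined) output."""
    text = _MONEY_RE.sub(" <money> ", text)
    text = _EMOTICON_RE.sub(" <emoticon> ", text)
    text = _HASHTAG_RE.sub(r" <hashtag> \1", text)
    toks = tokenize(scrub_text(text))
    return [t for t in toks if t not in stop_words]


@dataclass
class TweetScoreModel:
    vectorizer: TfidfVectorizer
    pca: PCA
    clf: LogisticRegression
    cv_metrics: dict[str, float] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.pca.n_components_


def _make_steps(n_components: int, seed: int):
    vec = TfidfVectorizer(ngram_range=(1, 3), tokenizer=str.split,
                          preprocessor=None, lowercase=False, token_pattern=None)
    # randomized solver with few power iterations: the projection feeds a
    # linear classifier, so basis precision beyond this is immaterial
    pca = PCA(n_components=n_components, random_state=seed,
              svd_solver="randomized", iterated_power=2)
    # L2-regularized logistic regression, default strength
    clf = LogisticRegression(C=1.0, max_iter=1000, random_state=seed)
    return vec, pca, clf


def _fit_steps(texts: list[str], y: np.ndarray, n_components: int, seed: int):
    vec, pca, clf = _make_steps(n_components, seed)
    x = vec.fit_transform(texts)
    k = min(n_components, x.shape[1], x.shape[0] - 1)
    pca.set_params(n_components=k)
    z = pca.fit_transform(np.asarray(x.todense()))
    clf.fit(z, y)
    return vec, pca, clf


def _prf(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def fit(tweets: Sequence[str], labels: Sequence[str], folds: int = 10,
        seed: int = 0, n_components: int = 300,
        preprocessed: bool = False, cv: bool = True) -> TweetScoreModel:
    """Fit the scorer and report fold-wise cross-validated precision,
    recall and F1 for the anorexia-related class.

    ``tweets`` are raw texts unless ``preprocessed``; labels are
    ``anorexia_related`` / ``control``.  Folds are reduced with a warning
    when a class has fewer members than ``folds``.
    """
    labset = set(labels)
    if labset != {POSITIVE_CLASS, NEGATIVE_CLASS}:
        if len(labset) < 2:
            raise ValueError("both classes must be present")
        raise ValueError(f"unknown labels {labset}")
    texts = list(tweets) if preprocessed else [" ".join(preprocess_tweet(t)) for t in tweets]
    y = np.array([1 if lab == POSITIVE_CLASS else 0 for lab in labels])
    min_class = int(min(np.sum(y), np.sum(1 - y)))
    if min_class < folds:
        log.warning("fit: reducing folds from %d to %d", folds, max(2, min_class))
        folds = max(2, min_class)
    cv_metrics: dict[str, float] = {}
    if cv:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        metrics = []
        texts_arr = np.array(texts, dtype=object)
        for train, test in skf.split(texts_arr, y):
            vec, pca, clf = _fit_steps(list(texts_arr[train]), y[train], n_components, seed)
            z = pca.transform(np.asarray(vec.transform(list(texts_arr[test])).todense()))
            metrics.append(_prf(y[test], clf.predict(z)))
        prec, rec, f1 = (float(np.mean([m[i] for m in metrics])) for i in range(3))
        cv_metrics = {"precision": prec, "recall": rec, "f1": f1}
    vec, pca, clf = _fit_steps(texts, y, n_components, seed)
    return TweetScoreModel(vec, pca, clf, cv_metrics=cv_metrics)


def score_tweet(model: TweetScoreModel, text: str,
                preprocessed: bool = False) -> float:
    """Posterior probability of the anorexia-related class.  An empty token
    list after preprocessing scores via the intercept alone (flagged)."""
    toks = text.split() if preprocessed else preprocess_tweet(text)
    if not toks:
        log.warning("score_tweet: empty token list, intercept-only score")
        return float(1.0 / (1.0 + math.exp(-model.clf.intercept_[0])))
    z = model.pca.transform(np.asarray(model.vectorizer.transform([" ".join(toks)]).todense()))
    return float(model.clf.predict_proba(z)[0, 1])


def score_tweets(model: TweetScoreModel, texts: Sequence[str],
                 preprocessed: bool = False) -> np.ndarray:
    """Vectorized scoring (empty texts handled as in :func:`score_tweet`)."""
    toks = [t.split() if preprocessed else preprocess_tweet(t) for t in texts]
    out = np.empty(len(toks))
    nonempty = [i for i, t in enumerate(toks) if t]
    chunk = 2048  # keep the densified tf-idf block small
    for lo in range(0, len(nonempty), chunk):
        idx = nonempty[lo:lo + chunk]
        batch = [" ".join(toks[i]) for i in idx]
        z = model.pca.transform(np.asarray(model.vectorizer.transform(batch).todense()))
        out[idx] = model.clf.predict_proba(z)[:, 1]
    for i in range(len(toks)):
        if not toks[i]:
            out[i] = 1.0 / (1.0 + math.exp(-model.clf.intercept_[0]))
    return out


def user_median_score(model: TweetScoreModel, user) -> float:
    """Median classifier score over all the user's tweets; NaN for a user
    with no tweets."""
    if not user.tweets:
        return math.nan
    scores = score_tweets(model, [t.text for t in user.tweets])
    return float(np.median(scores))
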