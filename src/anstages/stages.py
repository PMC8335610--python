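"""Stage-of-change clustering within the AN group.

Users likely at the earliest stages of behaviour change (precontemplation:
denial of the problem; contemplation: awareness without action) are
separated by k-means (k = 2) over the eight basic-emotion rates plus the
median polarity score, z-standardized.  There is no annotated ground truth
for the stages, so the clusters are labeled by a rule: the cluster whose
median (positivity - negativity) is higher is the precontemplation
cluster (ties broken by higher median polarity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .lexfeat import EMOTIONS
from .stats import mann_whitney

log = logging.getLogger(__name__)

DEFAULT_FEATURES = EMOTIONS + ("positive", "negative", "polarity_median")


@dataclass
class StageClusterResult:
    assignments: pd.Series  # user_id -> cluster id in {0, 1}
    stage_labels: dict[int, str]  # cluster id -> stage name
    features: pd.DataFrame  # the (complete-case) feature matrix clustered


def cluster_stages(features: pd.DataFrame, seed: int = 0,
                   feature_set=DEFAULT_FEATURES, n_init: int = 50) -> pd.Series:
    """k = 2 k-means over z-standardized features; k-means++ with
    ``n_init`` restarts under a fixed seed.  Constant features are dropped
    with a warning; users with any missing feature are excluded."""
    x = features[list(feature_set)].dropna()
    if len(x) < 2:
        raise ValueError("need at least 2 users with complete features")
    keep = [c for c in x.columns if x[c].nunique() > 1]
    for c in x.columns.difference(keep):
        log.warning("cluster_stages: dropping constant feature %s", c)
    z = (x[keep] - x[keep].mean()) / x[keep].std(ddof=0)
    km = KMeans(n_clusters=2, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    return pd.Series(labels, index=x.index, name="cluster")


def label_clusters(assignments: pd.Series, features: pd.DataFrame,
                   pos_col: str = "positive", neg_col: str = "negative",
                   polarity_col: str = "polarity_median") -> dict[int, str]:
    """Cluster with higher median (positivity - negativity) is
    precontemplation; ties fall back to higher median polarity; an exact
    tie on both criteria is an error requiring manual resolution."""
    ids = sorted(assignments.unique())
    if len(ids) != 2:
        raise ValueError("expected exactly two clusters")
    gap = {}
    pol = {}
    for cid in ids:
        sub = features.loc[assignments.index[assignments == cid]]
        gap[cid] = float((sub[pos_col] - sub[neg_col]).median())
        pol[cid] = float(sub[polarity_col].median())
    a, b = ids
    if gap[a] != gap[b]:
        pre = a if gap[a] > gap[b] else b
    elif pol[a] != pol[b]:
        pre = a if pol[a] > pol[b] else b
    else:
        raise ValueError("exact tie on positivity gap and polarity; resolve manually")
    return {pre: "precontemplation", (b if pre == a else a): "contemplation"}


def run_stage_clustering(features: pd.DataFrame, seed: int = 0,
                         feature_set=DEFAULT_FEATURES) -> StageClusterResult:
    x = features[list(feature_set)].dropna()
    assignments = cluster_stages(features, seed=seed, feature_set=feature_set)
    labels = label_clusters(assignments, x)
    return StageClusterResult(assignments, labels, x)


def cluster_report(result: StageClusterResult,
                   display_scale: float = 1.0) -> pd.DataFrame:
    """Per-feature medians for each stage cluster and the two-sided
    Mann–Whitney p-value between clusters; cluster sizes in the column
    names.  Medians reported on the raw scale times ``display_scale``."""
    feats = result.features
    rows = []
    stage_of = {cid: name for cid, name in result.stage_labels.items()}
    members = {name: result.assignments.index[result.assignments == cid]
               for cid, name in stage_of.items()}
    for col in feats.columns:
        a = feats.loc[members["precontemplation"], col].to_numpy()
        b = feats.loc[members["contemplation"], col].to_numpy()
        _, p = mann_whitney(a, b)
        rows.append({
            "feature": col,
            f"median_precontemplation_n{len(a)}": float(np.median(a)) * display_scale,
            f"median_contemplation_n{len(b)}": float(np.median(b)) * display_scale,
            "mwu_p": p,
        })
    return pd.DataFrame(rows).set_index("feature")
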