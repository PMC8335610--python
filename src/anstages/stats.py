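"""Nonparametric group-comparison harness and annotation agreement.

The comparison workflow mirrors the study: a Kruskal–Wallis screen across
all groups at alpha = .05, then pairwise Mann–Whitney U tests for the five
pairs of interest on features passing the screen.  Boolean features use a
pooled two-sided two-proportion z test (z^2 equals the 2x2 chi-square
statistic without continuity correction).  Significance tiers are the usual
.05 / .01 / .001 marks on raw p-values (no multiple-testing correction by
default, with an optional Benjamini–Hochberg flag).

Annotation utilities: consensus labelling (a label wins an item when at
least ``min_agree`` annotators agree, otherwise a fallback label) and the
Light kappa — the mean of pairwise Cohen kappas over all annotator pairs,
appropriate when every annotator rated every item.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

#: the five group pairs compared throughout the study's tables
DEFAULT_PAIRS = (
    ("AN", "treatment"),
    ("AN", "recovered"),
    ("AN", "random_control"),
    ("AN", "focused_control"),
    ("random_control", "focused_control"),
)

TIERS = ((0.001, "<.001"), (0.01, "<.01"), (0.05, "<.05"))


def significance_tier(p: float) -> str:
    if math.isnan(p):
        return "na"
    for cutoff, mark in TIERS:
        if p < cutoff:
            return mark
    return "ns"


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p-value.  Returns
    (0, 1) when every value is identical (no evidence of any difference)."""
    clean = [np.asarray([v for v in g if not math.isnan(v)], dtype=float)
             for g in groups]
    clean = [g for g in clean if len(g)]
    if len(clean) < 2:
        raise ValueError("need >= 2 groups with at least one value each")
    pooled = np.concatenate(clean)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*clean)
    return float(h), float(p)


def _exact_mwu_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney by full enumeration of all splits of
    the pooled sample (handles ties); feasible for both n <= 8."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)
    us = []
    for comb in itertools.combinations(range(n + m), n):
        u = float(ranks[list(comb)].sum() - n * (n + 1) / 2)
        us.append(u)
    us = np.asarray(us)
    mean_u = n * m / 2
    dev = abs(u_obs - mean_u)
    p = float(np.mean(np.abs(us - mean_u) >= dev - 1e-12))
    return u_obs, min(1.0, p)


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann–Whitney U.  Exact enumeration when both samples have
    at most ``exact_max_n`` observations; otherwise the normal
    approximation with tie and continuity correction."""
    a = np.asarray([v for v in a if not math.isnan(v)], dtype=float)
    b = np.asarray([v for v in b if not math.isnan(v)], dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples need at least one non-missing value")
    if len(a) <= exact_max_n and len(b) <= exact_max_n:
        return _exact_mwu_p(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def proportion_ztest(successes_a: int, n_a: int,
                     successes_b: int, n_b: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z test, two-sided.  z^2 equals the
    2x2 chi-square statistic without continuity correction.  A degenerate
    pooled proportion (0 or 1) yields (nan, 1.0) with a warning."""
    if n_a < 1 or n_b < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0 <= successes_a <= n_a and 0 <= successes_b <= n_b):
        raise ValueError("successes out of range")
    p_pool = (successes_a + successes_b) / (n_a + n_b)
    if p_pool in (0.0, 1.0):
        log.warning("proportion_ztest: degenerate pooled proportion %.0f", p_pool)
        return math.nan, 1.0
    se = math.sqrt(p_pool * (1 - p_pool) * (1 / n_a + 1 / n_b))
    z = (successes_a / n_a - successes_b / n_b) / se
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class ComparisonRow:
    feature: str
    kind: str  # numeric | boolean
    group_stats: dict[str, float]  # medians (numeric) or user ratios (boolean)
    kw_h: float = math.nan
    kw_p: float = math.nan
    pair_p: dict[tuple[str, str], float] = field(default_factory=dict)
    pair_tier: dict[tuple[str, str], str] = field(default_factory=dict)


def compare_table(feature_table: pd.DataFrame, groups: Mapping[str, str] | pd.Series,
                  pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
                  boolean_columns: Sequence[str] = (),
                  kw_screen: bool = True, kw_alpha: float = 0.05,
                  bh_correct: bool = False) -> list[ComparisonRow]:
    """The study's comparison battery over a per-user feature table.

    Numeric columns: Kruskal–Wallis screen across all groups present, then
    pairwise Mann–Whitney for the requested pairs (only if the screen
    passes, unless ``kw_screen`` is off).  Boolean columns: per-group user
    ratios and pairwise two-proportion z tests.  Missing values are dropped
    per feature and group.
    """
    groups = pd.Series(groups)
    group_names = sorted(groups.unique())
    for a, b in pairs:
        if a not in group_names or b not in group_names:
            raise ValueError(f"pair ({a}, {b}): unknown group")
    members = {g: groups.index[groups == g] for g in group_names}
    boolean_set = set(boolean_columns)
    rows: list[ComparisonRow] = []
    for col in feature_table.columns:
        series = feature_table[col]
        if col in boolean_set:
            vals = {g: series.reindex(members[g]).dropna().astype(bool)
                    for g in group_names}
            row = ComparisonRow(
                feature=col, kind="boolean",
                group_stats={g: (float(v.mean()) if len(v) else math.nan)
                             for g, v in vals.items()})
            for pair in pairs:
                a, b = vals[pair[0]], vals[pair[1]]
                if len(a) == 0 or len(b) == 0:
                    row.pair_p[pair] = math.nan
                else:
                    _, p = proportion_ztest(int(a.sum()), len(a), int(b.sum()), len(b))
                    row.pair_p[pair] = p
        else:
            vals = {g: series.reindex(members[g]).dropna().astype(float)
                    for g in group_names}
            usable = [v.to_numpy() for v in vals.values() if len(v)]
            row = ComparisonRow(
                feature=col, kind="numeric",
                group_stats={g: (float(v.median()) if len(v) else math.nan)
                             for g, v in vals.items()})
            if len(usable) >= 2:
                row.kw_h, row.kw_p = kruskal_wallis(usable)
            if (not kw_screen) or (not math.isnan(row.kw_p) and row.kw_p < kw_alpha):
                for pair in pairs:
                    a, b = vals[pair[0]], vals[pair[1]]
                    if len(a) == 0 or len(b) == 0:
                        log.info("compare_table: %s pair %s has an empty sample", col, pair)
                        row.pair_p[pair] = math.nan
                    else:
                        _, p = mann_whitney(a, b)
                        row.pair_p[pair] = p
        rows.append(row)
    if bh_correct:
        flat = [(r, pair) for r in rows for pair in r.pair_p
                if not math.isnan(r.pair_p[pair])]
        ps = np.array([r.pair_p[pair] for r, pair in flat])
        if len(ps):
            order = np.argsort(ps)
            adj = np.empty_like(ps)
            m = len(ps)
            running = 1.0
            for rank_i in range(m - 1, -1, -1):
                idx = order[rank_i]
                running = min(running, ps[idx] * m / (rank_i + 1))
                adj[idx] = running
            for (r, pair), q in zip(flat, adj):
                r.pair_p[pair] = float(q)
    for r in rows:
        r.pair_tier = {pair: significance_tier(p) for pair, p in r.pair_p.items()}
    return rows


def comparison_frame(rows: Sequence[ComparisonRow]) -> pd.DataFrame:
    """Flatten ComparisonRows into the study's table layout: per-group
    medians/ratios, the KW p, and one p-value + tier column per pair."""
    recs = []
    for r in rows:
        rec: dict = {"feature": r.feature, "kind": r.kind, "kw_h": r.kw_h,
                     "kw_p": r.kw_p}
        for g, v in r.group_stats.items():
            rec[f"median_{g}"] = v
        for pair, p in r.pair_p.items():
            key = f"{pair[0]}_vs_{pair[1]}"
            rec[f"p_{key}"] = p
            rec[f"tier_{key}"] = r.pair_tier[pair]
        recs.append(rec)
    return pd.DataFrame(recs).set_index("feature")


# ---------------------------------------------------------------------------
# Annotation agreement

def cohen_kappa(labels_i: Sequence, labels_j: Sequence) -> float:
    """Cohen's kappa with chance agreement from marginal label
    frequencies.  Degenerate case (both annotators constant): 1 under
    perfect agreement, else 0."""
    if len(labels_i) != len(labels_j) or len(labels_i) == 0:
        raise ValueError("label vectors must be nonempty and equal length")
    a = np.asarray(labels_i, dtype=object)
    b = np.asarray(labels_j, dtype=object)
    n = len(a)
    p_o = float(np.mean(a == b))
    cats = sorted(set(a) | set(b), key=str)
    p_e = sum((np.mean(a == c)) * (np.mean(b == c)) for c in cats)
    if abs(1 - p_e) < 1e-12:
        log.warning("cohen_kappa: degenerate marginals (p_e = 1)")
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1 - p_e))


@dataclass
class AgreementResult:
    pairwise_kappas: dict[tuple[int, int], float]
    light_kappa: float


def light_kappa(matrix) -> AgreementResult:
    """Light's kappa: the mean of Cohen kappas over all annotator pairs.
    Requires a complete items x annotators matrix."""
    m = np.asarray(matrix, dtype=object)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("matrix: need items x >=2 annotators")
    if any(v is None for v in m.ravel()):
        raise ValueError("matrix: missing cells")
    pairs = {}
    for i, j in itertools.combinations(range(m.shape[1]), 2):
        pairs[(i, j)] = cohen_kappa(m[:, i], m[:, j])
    return AgreementResult(pairs, float(np.mean(list(pairs.values()))))


def consensus_label(matrix, min_agree: int = 3, fallback: str = "doubtful") -> list:
    """Per item, the label reaching at least ``min_agree`` votes; items
    without such a label get the fallback."""
    m = np.asarray(matrix, dtype=object)
    if m.ndim != 2 or m.shape[1] < min_agree:
        raise ValueError(f"matrix: need >= {min_agree} annotators")
    out = []
    for row in m:
        counts: dict = {}
        for lab in row:
            counts[lab] = counts.get(lab, 0) + 1
        winners = [lab for lab, c in counts.items() if c >= min_agree]
        if len(winners) > 1:
            raise RuntimeError("consensus_label: two labels reached quorum")
        out.append(winners[0] if winners else fallback)
    return out
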