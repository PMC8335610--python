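"""Synthetic-cohort generator: determinism, calibration, validity."""

import math

import numpy as np
import pytest

from anstages.behavior import slot_counts, sttr, week_ratios
from anstages.corpus import Lexicon
from anstages.stats import light_kappa
from anstages.synth import (
    CohortConfig, default_config, generate_cohort, sample_annotations,
    sample_follow_edges, sample_tokens, sample_tweet_times, substream,
)


def _serialize(cohort, tmp_path, name):
    from anstages.corpus import write_cohort
    d = tmp_path / name
    write_cohort(cohort, d)
    return b"".join(sorted((p.name.encode() + p.read_bytes())
                           for p in d.iterdir()))


class TestGenerateCohort:
    def test_empty_sizes_give_empty_cohort(self):
        cfg = default_config(seed=0)
        cfg.group_sizes = {g: 0 for g in cfg.group_sizes}
        c = generate_cohort(cfg)
        assert len(c) == 0 and c.edges() == []

    def test_byte_identical_under_same_seed(self, tmp_path):
        a = generate_cohort(default_config(seed=11, scale=0.1))
        b = generate_cohort(default_config(seed=11, scale=0.1))
        assert _serialize(a, tmp_path, "a") == _serialize(b, tmp_path, "b")

    def test_seed_changes_cohort(self, tmp_path):
        a = generate_cohort(default_config(seed=11, scale=0.1))
        b = generate_cohort(default_config(seed=12, scale=0.1))
        assert _serialize(a, tmp_path, "a") != _serialize(b, tmp_path, "b")

    def test_adding_users_preserves_existing(self):
        small = default_config(seed=3, scale=0.1)
        big = default_config(seed=3, scale=0.1)
        big.group_sizes = dict(big.group_sizes)
        big.group_sizes["AN"] += 3
        ca, cb = generate_cohort(small), generate_cohort(big)
        shared = set(ca.users)
        for uid in shared:
            assert [t.text for t in cb.users[uid].tweets] == \
                [t.text for t in ca.users[uid].tweets]

    def test_timestamps_inside_date_range(self, small_cohort):
        lo, hi = small_cohort.date_range
        for u in small_cohort.users.values():
            assert all(lo <= t.created_at < hi for t in u.tweets)

    def test_edges_reference_existing_users(self, small_cohort):
        for src, dst in small_cohort.edges():
            assert src in small_cohort.users and dst in small_cohort.users

    def test_night_multiplier_ordering_recovered_downstream(self):
        """AN-like slot profile (weaker sleep suppression) yields higher
        median STTR than control-like, measured by the brute-force
        statistic on generated streams."""
        cfg = default_config(seed=5)
        cfg.group_sizes = {"AN": 60, "random_control": 60}
        cfg.slot_multipliers = {"AN": [0.1, 0.1] + [1.0] * 6,
                                "random_control": [0.5, 0.5] + [1.0] * 6}
        cfg.with_pictures = cfg.with_demographics = False
        cfg.topic_terms, cfg.topic_concentration = {}, {}
        c = generate_cohort(cfg)
        med = {}
        for g in ("AN", "random_control"):
            med[g] = np.median([sttr(slot_counts(u.timestamps()))
                                for u in c.by_group(g)])
        # 0.5-multiplier night slots give the *larger* sleep-pair share
        assert med["random_control"] > med["AN"]

    def test_invalid_config_names_field(self):
        cfg = default_config(seed=0)
        cfg.slot_multipliers = dict(cfg.slot_multipliers)
        cfg.slot_multipliers["AN"] = [1.0] * 7
        with pytest.raises(ValueError, match="slot_multipliers"):
            generate_cohort(cfg)
        cfg = default_config(seed=0)
        cfg.annotator_confusion = {"AN": {"AN": 0.5, "doubtful": 0.4}}
        with pytest.raises(ValueError, match="annotator_confusion"):
            cfg.validate()


class TestTweetTimes:
    def test_zero_rate_empty(self, rng):
        assert sample_tweet_times(30, 0.0, [1] * 8, [1] * 7, rng) == []

    def test_sorted_output(self, rng):
        ts = sample_tweet_times(60, 5.0, [1] * 8, [1] * 7, rng)
        assert ts == sorted(ts)

    def test_uniform_slots_within_binomial_bound(self, rng):
        ts = sample_tweet_times(100, 100.0, [1] * 8, [1] * 7, rng)
        counts = slot_counts(ts)
        n = counts.T
        sigma = math.sqrt(n * (1 / 8) * (7 / 8))
        for c in counts.t:
            assert abs(c - n / 8) < 4 * sigma

    def test_weekend_only_weights(self, rng):
        ts = sample_tweet_times(70, 3.0, [1] * 8, [0, 0, 0, 0, 0, 1, 1], rng)
        assert week_ratios(ts) == (0.0, 1.0)

    def test_all_zero_multipliers_error(self, rng):
        with pytest.raises(ValueError, match="slot_multipliers"):
            sample_tweet_times(10, 1.0, [0] * 8, [1] * 7, rng)


class TestTokens:
    LEX = [Lexicon.from_phrases("l", {"uni": ["qq"], "bi": ["rr ss"]})]
    FILLER = [f"w{i}" for i in range(20)]

    def test_zero_rates_only_filler(self, rng):
        toks = sample_tokens(100, {}, self.LEX, self.FILLER, rng)
        assert set(toks) <= set(self.FILLER)

    def test_rate_one_unigram(self, rng):
        toks = sample_tokens(50, {"uni": 1.0}, self.LEX, self.FILLER, rng)
        assert toks == ["qq"] * 50

    def test_stated_length(self, rng):
        assert len(sample_tokens(101, {"bi": 0.5}, self.LEX, self.FILLER, rng)) == 101

    def test_unknown_category_error(self, rng):
        with pytest.raises(ValueError, match="unknown category"):
            sample_tokens(10, {"nope": 0.1}, self.LEX, self.FILLER, rng)


class TestFollowEdges:
    def test_identity_homophily_within_group(self, rng):
        ubg = {"a": [f"a{i}" for i in range(30)], "b": [f"b{i}" for i in range(30)]}
        hom = {"a": {"a": 1.0, "b": 0.0}, "b": {"a": 0.0, "b": 1.0}}
        edges = sample_follow_edges(ubg, hom, 5.0, rng)
        assert edges
        assert all(src[0] == dst[0] for src, dst in edges)

    def test_zero_degree_no_edges(self, rng):
        ubg = {"a": ["a1", "a2"]}
        assert sample_follow_edges(ubg, {"a": {"a": 1.0}}, 0.0, rng) == []

    def test_no_self_loops_no_duplicates(self, rng):
        ubg = {"a": [f"a{i}" for i in range(10)]}
        edges = sample_follow_edges(ubg, {"a": {"a": 1.0}}, 8.0, rng)
        assert len(edges) == len(set(edges))
        assert all(s != d for s, d in edges)

    def test_homophily_fraction_within_bound(self, rng):
        groups = ["g1", "g2", "g3", "g4"]
        ubg = {g: [f"{g}_{i}" for i in range(50)] for g in groups}
        hom = {g: {h: (0.95 if h == g else 0.05 / 3) for h in groups}
               for g in groups}
        edges = sample_follow_edges(ubg, hom, 10.0, rng)
        frac = np.mean([s.split("_")[0] == d.split("_")[0] for s, d in edges])
        n = len(edges)
        sigma = math.sqrt(0.95 * 0.05 / n)
        assert abs(frac - 0.95) < 4 * sigma + 0.01  # dedup slightly favors cross


class TestAnnotations:
    def test_identity_confusion_perfect_agreement(self, rng):
        conf = {"x": {"x": 1.0, "y": 0.0}, "y": {"y": 1.0, "x": 0.0}}
        m = sample_annotations(["x", "y"] * 20, conf, 5, rng)
        assert m.shape == (40, 5)
        assert light_kappa(m).light_kappa == 1.0

    def test_two_annotators_allowed_one_rejected(self, rng):
        conf = {"x": {"x": 1.0}}
        assert sample_annotations(["x"], conf, 2, rng).shape == (1, 2)
        with pytest.raises(ValueError, match="n_annotators"):
            sample_annotations(["x"], conf, 1, rng)

    def test_unknown_label_error(self, rng):
        with pytest.raises(ValueError, match="true_labels"):
            sample_annotations(["zz"], {"x": {"x": 1.0}}, 3, rng)


def test_substream_stability():
    a = substream(1, "u", "times").integers(0, 1000, 5)
    b = substream(1, "u", "times").integers(0, 1000, 5)
    c = substream(1, "u", "text").integers(0, 1000, 5)
    assert (a == b).all() and not (a == c).all()
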