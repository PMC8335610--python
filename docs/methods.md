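# Methods

## Scope and data model

The package analyses a cohort of social-media users split into five groups
— AN (precontemplation/contemplation stages of the transtheoretical
model), treatment, recovered, focused control (AN vocabulary without signs
of the disorder) and random control. A user carries their own tweets
(retweets excluded), liked tweets, a tokenized biography, followee ids and
optionally externally supplied picture and demographic scores. Timestamps
are UTC epoch seconds with no timezone metadata: user location is treated
as unknown throughout, which is why the circadian statistic is built to be
rotation-invariant. Text passes one shared scrubber (mentions, URLs,
e-mails and standalone numbers replaced by generic tags — numbers are
tagged rather than deleted so token counts are preserved) and one shared
tokenizer (lowercased unicode word characters; tags protected; hashtag
mark stripped). Keyword matching is case-normalized and accent-folded by
default (configurable), since source texts are Spanish-like.

Storage is plain text: JSON Lines for users/tweets/likes, a two-column
TSV edge list, TSV lexicons (`category<TAB>phrase`, phrases of 1–3
tokens), CSV feature tables.

Cohort-inclusion rules: users with fewer than 5 own tweets inside the
observation window are dropped; the keyword filter keeps users with at
least 3 *distinct* tweets containing a keyword phrase. Both thresholds are
parameters; both filters are monotone in their thresholds.

## Behavioral statistics

Eight fixed 3-hour slots anchored at 00:00 UTC (the anchor is immaterial:
STTR is invariant under cyclic rotation, asserted in tests). STTR is the
minimum over the eight cyclically adjacent slot-pair sums divided by the
total count; the first and last slots are treated as continuous. The
analytic range is [0, 0.25]: the eight pair sums total 2T, so their
minimum is at most T/4, with equality exactly when all pair sums are
equal; the test suite checks this exhaustively on small count vectors.
"Pair of continuous time slots" is read as the eight cyclically adjacent
pairs only (a 6-hour sleep window), not all 28 pairs. Weekday/weekend uses
UTC day-of-week; quarters are calendar-month blocks (Dec–Feb, Mar–May,
Jun–Aug, Sep–Nov); the inter-tweet gap is the median of successive
differences of the sorted timestamps. Users failing a statistic's
precondition (T=0, or T<2 for gaps) yield missing values, never zeros;
downstream tests drop missing values per feature and group.

## Lexicon features

Per user, tweets are concatenated in chronological order with a sentinel
token between tweets so no phrase can span a tweet boundary (cross-tweet
matches are artifacts). Matching is longest-first (3→2→1 tokens) and
non-overlapping within a category, preventing double counting of nested
n-grams; a token may feed several categories (the convention of
psycholinguistic word-count dictionaries), and within the emotion lexicon
a word listed under several emotions counts toward each. The denominator
is the total token count including generic tags, excluding sentinels.
Median tweet length is in tokens; polarity is the median of per-tweet
scores in [0,1] — supplied externally when available, otherwise via a
transparent stand-in scorer p/(p+n) over positive/negative lexicon
matches (0.5 when no match). The shipped lexicons are small synthetic
demonstrations of the feature families, not any proprietary dictionary;
the module is lexicon-agnostic.

## Topic profiles

Per-text topic score = fraction of tokens in the topic's term set
(normalized, so text length cancels). A user's own profile is the
unweighted mean of per-text scores over three pooled samples (own tweets
capped at 500, liked tweets at 200, followee biographies at 200; caps
seeded). Group profiles are per-topic medians, displayed ×1000 where
tables would otherwise show leading zeros. Followee profiles follow the
literal three-level reading: *mean* over a followee's texts, *median*
over a user's followees (≤25 followees of ≤25 users per group), *median*
over users; users with no scorable followees are excluded from the outer
median and logged. Spearman ρ uses average ranks on ties; profile
rankings break ties lexicographically for reproducible tables. No
translation step exists: synthetic lexicons are language-neutral.

## Follow network

The graph is directed (follower → followee), capped at 100 sampled
out-edges per user. Validation groups: level 1 = seed labels; level 2
assigns an unlabeled node the strict-plurality group among its level-1
in-neighbors; level 3 repeats using only level-2 assignments (synchronous
update; plurality ties leave the node unassigned; a node keeps its
earliest level). Strict plurality was chosen over absolute majority for
"mostly followed by"; both are simple variants of the same two-pass scan.
Louvain community detection, modularity, k-core (iterative peeling on the
undirected projection) and PageRank (damping 0.85, dangling mass
redistributed uniformly) operate on the undirected projection where the
quantity requires it; diameter and average path length are computed on
the largest weakly connected component, since they are infinite on
disconnected graphs (logged). Average degree is directed edges per node.
Polarization between two groups' assigned regions is summarized as the
cross-edge fraction.

## Statistical harness

Numeric features: Kruskal–Wallis (tie-corrected, χ² p) screens at α=.05;
features passing the screen get pairwise two-sided Mann–Whitney U tests
for five default pairs (AN–treatment, AN–recovered, AN–random,
AN–focused, random–focused). When both samples have ≤8 observations the
MWU p-value is computed by exhaustive enumeration of all splits of the
pooled sample (ties included); otherwise the normal approximation with
tie and continuity correction is used. Boolean features use the
pooled-variance two-proportion z-test; z² equals the 2×2 χ² statistic
without continuity correction (asserted to 1e-9). Raw p-values are
reported with .05/.01/.001 tiers and no multiple-testing correction by
default, matching the reporting style of this literature; a
Benjamini–Hochberg option exists but is off by default. Agreement: Cohen
κ from marginal frequencies (degenerate identical-constant annotators
give κ=1 under perfect agreement, else 0, flagged); Light κ is the mean
over all annotator pairs, appropriate when every annotator rates every
item; consensus labeling requires a quorum (default 3 of 5) and falls
back to "doubtful".

## AN-tweet scorer

Preprocessing adds money/hashtag/emoticon tags on top of the scrubber and
removes stop words (a declared, overridable list: a Spanish function-word
core plus minimal English). The model is tf-idf over (1–3)-gram terms →
centered PCA to min(300, features, fold size−1) components → L2 logistic
regression (C=1). The vectorizer and PCA are refit inside each stratified
CV fold, so reported precision/recall/F1 for the anorexia-related class
carry no transform leakage; whole-set transform fitting would bias the
metrics upward. The PCA uses the randomized solver with few power
iterations — the projection feeds a linear classifier, so basis precision
beyond that is immaterial. An empty token list after preprocessing is
scored through the intercept alone and flagged. Duplicating a tweet's
tokens does not monotonically move its score (tf-idf renormalizes); this
is a documented non-property. The per-user feature is the median score
over all the user's tweets.

## Stage clustering

k-means with k=2 (fixed; no model selection) over the eight emotion rates
plus median polarity, z-standardized because rates and polarity live on
different scales; k-means++ with 50 restarts under a fixed seed; constant
features dropped with a warning. The cluster whose median
(positive − negative) rate is higher is labeled precontemplation (the
stage characterized by positivity about the weight-loss process); ties
fall back to higher median polarity; an exact double tie is an error
demanding manual resolution. The report gives per-cluster medians (raw
[0,1] scale, with an optional display scale) and between-cluster
Mann–Whitney p-values.

## Profile rules

Organization label iff the organization score is strictly over 0.70 and
strictly above both gender scores; otherwise argmax(male, female), with
an exact gender tie raised as an error (it signals degenerate upstream
scores). Organizations short-circuit to the organization age group;
otherwise argmax over four age ranges, ties resolving to the lowest range
(logged). Picture objects form a boolean bag restricted to objects
appearing in ≥5 distinct users' pictures (one picture per user); the
vocabulary is monotone decreasing in that support threshold. Users with
faces get the argmax emotion (lexicographic on ties, logged). Group
summaries are ratios of users; categorical ratios over users with a
present value sum to 1. All external model scores (demographics, picture
features) are inputs — never computed here.

## The synthetic generator

The generator defines the study conditions; every downstream property is
measured against its known parameters.

* **Sizes.** Default 162 users (AN 40, treatment 8, recovered 6, focused
  control 60, random control 48) over one year at ~1 tweet/day — the real
  cohort's group proportions at roughly a quarter of its user count and
  tweet volume, chosen so the full pipeline runs in minutes on one CPU.
* **Tweet times.** Thinned homogeneous Poisson: a day's expected count is
  the base rate modulated by day-of-week weight; within a day, counts
  spread over the eight slots proportionally to group slot multipliers.
  Night-slot multipliers (0.025/0.022/0.021/0.015/0.020 for
  AN/treatment/recovered/focused/random against 0.158 for day slots) put
  the asymptotic STTR at 0.050/0.044/0.042/0.030/0.040 — the ordering and
  magnitudes of the study's headline behavioral finding.
* **Text.** Each token position independently emits a lexicon-category
  phrase with the group's (or, for AN users, the stage mixture's) emission
  probability, otherwise a filler token: with probability 0.35 a term of a
  topic drawn from the user's Dirichlet interest vector, else a neutral
  filler word. The filler vocabulary is disjoint from every lexicon
  phrase, so measured category rates equal emission rates in expectation
  (verified by 4σ binomial bounds at 10⁴ tokens). Multi-token phrases
  consume their length.
* **Stages.** AN users split 2:1 into precontemplation/contemplation
  mixtures: positivity-dominant (positive 0.034 vs negative 0.016,
  polarity mean 0.19) vs negativity-dominant (0.014 vs 0.040, polarity
  0.17), mirroring the published cluster contrast.
* **Follow edges.** Out-degree Poisson(25); target group proportional to
  a homophily row (0.85 within group; AN↔focused control 0.01, encoding
  the observed polarization); target user uniform; duplicates dropped
  rather than resampled (negligible at these densities).
* **Annotations.** Per-item labels drawn from a confusion row of the true
  label. The diagonals (0.84 AN/focused, 0.64 doubtful) were calibrated
  analytically — closed-form p_o/p_e over the 2:2:1 label mix — so the
  expected Light κ of five independent annotators is ≈0.48, the moderate
  agreement this kind of clinical labeling exhibits.
* **Determinism.** One config seed; per-user streams derived by stable
  hashing of (seed, user id, purpose), so adding users leaves existing
  users' data unchanged. Identical config + seed gives byte-identical
  serialized cohorts.
* **Topic-recovery conditions.** Shared-interest groups use one
  concentrated geometric weight profile (α = 60·w, w ∝ 0.96^i over 200
  topics), making 200 topic ranks estimable from ~1,500 tokens/user.
  Unrelated-interest groups have disjoint *dominant* supports (10 topics
  each at 60% mass) over a shared diffuse background: full 100/100
  disjoint supports would force a strongly negative rank correlation by
  construction (what is top in one group is bottom or tied in the other),
  whereas disjoint dominant interests over background noise give the
  near-zero correlation that "independent rankings" implies.

What the generator does **not** emulate: natural language (tokens are
draws, not sentences, so no syntax-sensitive feature can be studied),
bursty or sessionized posting (inter-tweet gaps are exponential within
slots), follower-count heavy tails, images (picture features are sampled
flags/scores directly), and annotator-specific biases (all annotators
share one confusion matrix). Passing tests therefore demonstrate that the
*statistics and decision rules* behave as specified and recover known
generating structure — not that the pipeline's findings would transfer to
any real population.

## Numerical choices and degenerate inputs

Missing values are NaN and propagate to pairwise-dropped tests, never
silently zero. Kruskal–Wallis on all-identical values returns (0, 1)
rather than erroring. The degenerate pooled proportion (0 or 1) in the
z-test reports p=1 with a warning. Spearman on a constant profile is NaN
with a warning. Ranking ties break lexicographically; k-means and Louvain
are seeded; every sampling cap uses a seeded substream. Problem sizes in
the tests and the acceptance script (e.g. 2,000 null simulations for
type-I calibration, 700-node propagation graphs, 2,000 tweets/class for
the scorer) were chosen as the smallest sizes at which the measured
quantities are stable to well within the asserted tolerances.

## Known limitations

The exact Mann–Whitney enumeration is O(C(n+m, n)) and only engaged when
both samples have ≤8 observations. Louvain community ids are stable only
per seed. The scorer's CV metrics depend on corpus separability by
construction; on realistic overlapping vocabularies the same pipeline
reports substantially lower F1 (the cohort-corpus figure in the
acceptance output) — both are reported. The deep-learning variants of the
published system (CNN text classifier, image models, pretrained
embeddings) are out of scope; external model outputs are modeled as
supplied scores.
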