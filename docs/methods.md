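# Methods

## Scope and data model

The package analyzes a corpus of tweets posted by a fixed roster of media
outlets, each record carrying: an opaque unique id, account handle,
UTC timestamp (calendar-date precision is all the analyses need; finer is
accepted), text, a set of canonical hashtag tokens (lowercase, no `#`),
like and retweet counts, a BCP-47 language code, and three curation
booleans. `relevant` stands in for a manual topical-relevance
adjudication step; `hashtag_only` and `picture_only` mark low-content
tweets. The canonical file dialect is JSON-lines (tweets have optional
and set-valued fields); a flat CSV importer with a fixed header is
provided for convenience. Hashtags are canonicalized on read and unioned
with any `#token` patterns found in the text, for robustness to exporters
that put tags in either place.

## Category assignment and filtering

Eight food-group categories are defined by a closed mapping of 17 hashtag
tokens (e.g. `olive_oil` = {oliveoil, extravirginoliveoil}). Matching is
exact-token only — `nutsandbolts` does not match `nuts` — because the
category scheme is a closed curated list, not a topic model. A tweet
belongs to every category whose token set intersects its hashtags; with
the default generator this is always exactly one category, which is what
makes per-category counts additive to the corpus totals. When a corpus
does contain multi-category tweets, each matching category row counts the
tweet, while corpus-level totals count it once; percentages then sum to
more than 100 and are reported as-is.

Filtering applies, in a fixed documented order (account whitelist → date
window → language → ≥1 category → relevant → not hashtag-only → not
picture-only), with each removed record attributed to its *first* failing
criterion. The fixed order makes the audit reproducible; the retained set
itself is order-independent. Filtering is idempotent. Defaults encode
the study window: 2009-01-01..2019-12-31, English, all curation filters
on, no account whitelist (supply one to enforce an outlet roster).

## Engagement summaries and odds ratios

Per category: tweet count, percentage of the grand (distinct-tweet)
total, like/retweet totals, and per-tweet ratios likes/tweets and
retweets/tweets. A category with zero tweets reports absent (not zero)
ratios. Reports round half-away-from-zero to one decimal (ratios,
percentages) or two decimals (odds ratios and CI bounds); unrounded
values are kept internally.

The engagement "odds" of a category is its per-tweet event rate — likes
(or retweets) divided by tweets — and the odds ratio of category *vs*
reference is the ratio of these rates:

    OR = (events_a / trials_a) / (events_b / trials_b)

with the log-scale Wald interval exp(ln OR ± z·sqrt(1/a + 1/b + 1/c +
1/d)), a = events_a, b = trials_a, c = events_b, d = trials_b, z the
standard-normal quantile of the confidence level (1.96 at the default
0.95). Two deliberate departures from textbook odds-ratio practice:

- the event counts may exceed the trial counts (a tweet can draw many
  likes), so this is a rate ratio, not a probability odds ratio, and no
  2×2 table or non-event cell exists;
- a zero anywhere is a hard error in the scalar function (the variance
  term is undefined) and a skip-with-notice in the panel builder. No
  continuity correction is applied by default, because a silent +0.5
  would change reported values.

The statistic satisfies OR(a,b)·OR(b,a) = 1 with reciprocal-reflected
intervals, and the CI is symmetric about ln OR on the log scale; both are
enforced as property tests at 1e-12.

## Sentiment

Tokenization: lowercase, drop URLs and @-mentions, strip `#` so hashtags
score as plain words, split on non-word characters. Lexicon terms are
AFINN-style integer valences in [−5, +5]; multi-word entries are matched
greedily (longest span first) and consume their tokens. The per-tweet
score is the affine map

    scaled = clamp(50 + 10 · mean(matched valences), 0, 100)

which is linear, symmetric about the neutral 50, and spans the valence
range exactly; this specific map is this package's choice — the 0–100
scale itself is standard in hashtag-analytics tools but its internals are
not published. Tweets with no matched terms score 50 and are included in
category means (excluding them would leave lexicon-sparse categories
undefined). Category score = unweighted mean of per-tweet scores; bands:
very negative [0–20], negative (20–40], neutral (40–60], positive
(60–80], very positive (80–100], with boundaries falling into the lower
band above 20. Negating every lexicon valence maps s → 100 − s
(antisymmetry property test). Limitations: no negation or
valence-shifter handling, no emoji, no context sensitivity.

## Potential reach

Reach of a category = sum of follower counts over the *distinct* accounts
with at least one tweet in it, follower counts taken from a snapshot
table keyed by handle (a per-tweet `followers_at_post` field, if present,
is ignored here: reach is a single additive total over the study period).
An account missing from the table is a hard error naming the handle.
Reach is monotone under added tweets and subadditive over category unions.
Real outlet follower counts are not bundled; reach is exercised on
synthetic follower tables.

## Temporal aggregation and seasonality

Grids are bin × category count matrices with explicit zero cells, for
three binnings: calendar years, month-of-year (pooling years), and
custom inclusive year-ranges (default: 2009–2011, then 2012–2013,
2014–2015, 2016–2017, 2018–2019). Proportions divide each cell by the
grid's grand total.

Monthly seasonality uses the tie-corrected Kruskal–Wallis H test:
H = [12/(N(N+1))]·Σ R²ⱼ/nⱼ − 3(N+1), divided by 1 − Σ(t³−t)/(N³−N),
referred to χ² with k−1 df. The observation unit is the per-(month,
year) pooled total of the measure, zero-filled over the corpus's year
span — 12 groups × one observation per year — the simplest unit
consistent with a month-wise scatter of yearly values; a flag switches to
per-(month, year, category) observations. The χ² approximation is used
regardless of group size, and an all-identical pooled sample returns
H = 0, p = 1 (the tie correction is degenerate there). The
implementation delegates to `scipy.stats.kruskal`; the test suite checks
it against an independent brute-force midrank implementation to 1e-10 and
against a hand-worked three-group example (H = 7.2).

## Synthetic corpus generator

The generator defines the study conditions for all end-to-end tests. Its
defaults are the published per-category margins (1608 tweets, 123,363
likes, 48,946 retweets across the eight categories), dates uniform over
2009-01-01..2019-12-31, 25 synthetic outlet accounts, English, neutral
(50) sentiment targets for every category except red wine (65). Choices
that matter:

- **Exact margins, not expectations.** Each category's like and retweet
  totals are split across its tweets by a symmetric Dirichlet-multinomial
  composition (concentration 1, giving heterogeneous per-tweet counts),
  so the summary table over a generated corpus equals the configured
  margins as an identity and the published result table becomes a
  deterministic test surface at any seed.
- **One hashtag per tweet** by default (disjoint categories, matching the
  additive structure of the published table); `multi_category_rate`
  injects overlapping tweets to stress-test category accounting.
- **Sentiment by construction.** Tweet text is two words from a bundled
  mini-lexicon whose mean valence maps exactly to the category's target
  score, plus neutral filler and the category hashtag. Targets are hit
  per tweet, not just on average.
- **One seed.** All randomness flows through a single
  `numpy.random.default_rng(seed)`; identical configs produce
  byte-identical JSONL. The synthetic follower table (log-normal around
  3M followers, the scale of major-outlet audiences) derives from the
  same seed.

What passing tests on this corpus show: the accounting, statistics and
report surfaces are correct on data with the published margins. What
they do not show: behavior on real tweet language (the sentiment scores
of real corpora depend on the lexicon supplied), on corpora where
categories overlap heavily, or on the real outlets' follower counts —
published reach figures are not reproducible without those counts and are
out of scope.

## Numerical conventions and degenerate inputs

Rounding is half-away-from-zero via `decimal`. Empty corpora are legal
everywhere downstream of ingestion (all-zero summaries with absent
ratios, all-zero grids); an empty *category* is skipped or reported
absent rather than zero-filled where a ratio would be undefined. The
seasonality test requires ≥2 calendar years; proportions require a
nonzero grand total; the odds ratio requires strictly positive counts.
Problem sizes throughout tests and the acceptance script are the study's
own (a 1608-tweet corpus), which runs in seconds.
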