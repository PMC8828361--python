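# Methods

## Source-credibility labelling

All analyses key on a domain catalog mapping *registered* domains to a
factual-reliability class (`conspiracy`, `questionable`, `reliable`) and a
five-point political bias (`left`, `left_center`, `least`, `right_center`,
`right`), the taxonomy used by source-credibility services such as Media
Bias/Fact Check. URLs are reduced to their registered domain with a
public-suffix-aware reducer (so `news.bbc.co.uk` → `bbc.co.uk`), carrying
a curated list of common second-level country registries; matching against
the catalog is exact on the registered domain, never substring, which keeps
`cdc.gov` distinct from look-alike hosts. Unparseable URLs degrade to
"no match" rather than raising mid-stream. URL unshortening is assumed to
have happened upstream (expanded URLs in the records).

A tweet belongs to the **misinformation subset** when at least one of its
URLs resolves to a conspiracy or questionable domain. This is an
engagement proxy — it flags exposure to unreliable *sources*, not the
falsity of any individual claim.

## Narrative tagging

Narratives are keyword filters over case-folded, punctuation-split tokens.
A plain keyword matches a whole token or its naive plural (`mask` tags
`masks`); a trailing `*` matches a token prefix (`social distanc*` tags
"social distancing"); multi-word patterns must match consecutive tokens.
Token-boundary matching is the default because raw substring search would
tag "protest" for the keyword "test"; a `substring=True` mode reproduces
platform-style substring semantics for comparability. The built-in specs
are the three recurring COVID-era misinformation narratives:
hydroxychloroquine/alternative medicine (`hcq`, `hydroxychloroquine`),
US officials and agencies (`fauci`, `brix`, `cdc`), and prevention
measures (`mask`, `vaccine`, `social distanc*`, `test`). A tweet may carry
several tags; per-user tags are the union over the user's tweets.

Volume curves bin by UTC day or ISO week (Monday-anchored) and smooth with
a *trailing* moving average (defaults: 7 days, 7 weeks); the first
`window−1` entries average the available prefix, and interior empty bins
count zero.

## Temporal bigram clustering

Bigrams are consecutive token pairs after stop-word removal; the stop-word
list is pinned in the package so token streams are reproducible. Each of
the overall top-n bigrams (default 50,000; at synthetic scale a few dozen)
gets a weekly series of its count divided by the week's total bigram-token
count — totals over *all* bigrams, not just the retained ones.

The shape-clustering stage is a deliberately simple, fully reproducible
stand-in for specialised social-media shape-clustering algorithms whose
internals are published elsewhere; it keeps the same interface and
behavior contract (window length W = 21 days, K = 11 clusters by default):

1. **Burst filter** — a bigram survives only if its best contiguous window
   of W days (≈ 3 ISO weeks) holds at least `burst_fraction` (default 0.5,
   a majority-of-mass reading of "trending for at most three weeks") of
   its total normalized mass. This removes perennial phrases that dominate
   every week. The decision is scale-invariant.
2. **Z-normalization** of survivors, then **k-means** (seeded, n_init=10,
   ≤ 200 iterations). Euclidean distance on z-scored rows is a monotone
   transform of 1 − Pearson correlation, so this clusters by curve shape,
   not amplitude.
3. Clusters are reported ordered by the peak week of their mean shape.

Topic models are latent Dirichlet allocation fits over the same token
stream; the topic count is chosen from a candidate list by the highest
mean per-topic UMass coherence (log document co-occurrence ratios over
each topic's top 10 terms). UMass was chosen because it is computed from
the corpus itself and needs no external reference corpus.

## User profiles

A user's lean is the argmax of their per-bias catalogued-share counts,
counting both originals and retweets (a retweet republishes the URL).
Exact ties — including ≥ 3-way ties — are broken uniformly at random from
a single seeded generator; the generator is consulted *only* on ties, so
perturbing any count removes the randomness. Users are classified only
when they shared strictly more than `min_urls` URLs (default 5, i.e. ≥ 6);
URLs resolving to uncatalogued domains count toward this threshold but not
toward bias counts (`cataloged_only=True` flips this). A single
conspiracy/questionable share sets the misinformation-engagement flag,
which is monotone under adding tweets.

## Retweet network

Edges run retweeted → retweeter (information flow) with weight = retweet
count per ordered pair, so "prominent" accounts — those widely retweeted —
have high out-degree; prominence ranking uses *distinct* retweeters
(unweighted out-degree) with ties broken by user id. The graph is
restricted to retweets made by misinformation-engaged users; any retweet
by such a user counts, whether or not that retweet itself carried an
unreliable URL. Bot pruning removes nodes that tweet at or above a rate
threshold (default: the 95th percentile of per-user original-tweet counts;
"tweet frequently" is otherwise undefined) *and* are never retweeted. The
k-core (default k = 100 at full scale; far smaller on synthetic data) is
computed on the undirected simplification with distinct-neighbor degrees —
the standard unweighted definition.

## Co-sharing density

For each domain group (conspiracy, questionable, and a random baseline
sampled uniformly from all shared domains excluding the unreliable lists —
the exclusion makes the baseline a genuine control), two domains are
linked when at least one user shared both, weighted by the number of such
users (share multiplicity does not matter). Density statistics:

- **average clustering coefficient** — mean local coefficient on the
  binarized graph over *all* nodes (degree < 2 contributes 0);
- **average link weight** — total edge weight divided by n(n−1)/2, i.e.
  averaged over all possible pairs with absent links counting zero. The
  all-pairs denominator is what lets a sparse baseline group approach
  zero; an existing-edges-only variant sits behind a flag.

Both are reported relative to the random group (baseline ≡ 1). At
synthetic scale the baseline's absolute clustering is a small-count
quantity (a handful of users forming triangles), so ratio estimates should
be pooled over replicate streams — the acceptance checks average absolute
metrics over four streams before taking ratios.

## Trend model

Daily per-group URL counts (each URL occurrence counts once, missing days
zero-filled) feed an OLS fit of `V_group ~ t·β₁ + V_random·β₂`, with the
intercept off by default to match the model as written (a flag adds one,
since the notation may elide it). The day index starts at 0 on the first
observed day. Inference is classical: t-distribution with n − p degrees of
freedom, 95% CIs. Constant or collinear regressors raise errors naming the
offender. Note that when the baseline covariate is itself a noisy count,
the no-intercept model absorbs level differences imperfectly
(errors-in-variables); the estimator is validated by Monte Carlo where the
data-generating process conditions on the *observed* baseline, which is
the regression's own contract.

## Synthetic stream generator

The generator emulates the statistical structure the pipeline assumes, at
desk scale, with a single global RNG seeded once (identical config ⇒
byte-identical JSONL). Defaults define the reference conditions:

- **Population**: 300 users over 120 days, ~1 original tweet/user/day
  (Poisson), latent lean right with probability `lean_mix` = 0.5; bots
  (default 0) tweet at 12× the base rate and are never retweet targets.
- **Domain universe**: 40 catalogued domains per group (conspiracy,
  questionable, reliable-left, reliable-right; unreliable outlets also
  carry an alternating left/right bias) plus 12,000 uncatalogued
  background domains standing in for the web's long tail. The long tail is
  deliberately much larger than any group: that is what makes a random
  sample of shared domains a sparse co-sharing baseline, as observed on
  real platforms where unreliable lists number hundreds against millions
  of shared domains.
- **Sharing**: each original tweet carries 0–2 URLs; a URL is unreliable
  with probability `misinfo_propensity` (0.3), otherwise a catalogued
  partisan outlet with probability `political_share` (0.4), otherwise
  background. Every catalogued URL matches the sharer's lean with
  probability `fidelity` (0.8) — making per-user lean recovery an exact
  binomial-majority problem.
- **Trends**: `trend_slope_*` plants that many extra unreliable URLs per
  day (Poisson around a linearly growing mean). Planted-trend tweets are
  excluded from the retweet pool so re-sharing does not amplify the slope
  beyond its nominal value.
- **Retweets**: 30% of user-events from day 1 onward; the target author
  matches the retweeter's lean with probability `retweet_homophily` (0.8);
  targets are sampled from previous days' originals, so retweets never
  chain and always reference earlier tweets.
- **Bursts**: each configured topic injects tweets containing its
  signature bigrams at a Gaussian-bump daily rate (amplitude 30/day at the
  peak by default). Background text is drawn from a small fixed
  vocabulary; a fraction of tweets (15%) also carries a narrative phrase
  so narrative tagging has signal.
- Timestamps are day-granular with uniform within-day jitter; the
  analysis only uses daily/weekly bins.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: natural language (texts are vocabulary samples),
follower structure, heavy-tailed user activity and virality cascades,
coordinated campaigns, deletion/suspension dynamics, or non-English
content. Tests demonstrate that the pipeline recovers planted structure
correctly, not that the structure exists in any particular real corpus.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately small scale: streams
of 1k–65k tweets, 40-domain groups, k-means on dozens of series,
Monte-Carlo batteries of 50–500 replicates. These sizes were chosen so the
statistical checks (CI coverage in [90%, 99%], type-I error 0.05 ± 0.02,
purity ≥ 0.9, density ratios > 5) are well-powered while the full suite
stays fast. Determinism everywhere flows from explicit seeds; frequency
ties (top-n bigram selection, hashtag ranking, prominence ranking) break
lexicographically so outputs are stable across platforms. Degenerate
inputs (empty streams, empty groups, constant regressors, k exceeding
survivors) raise informative errors rather than returning silent zeros.

## Known limitations

- The shape-clustering stand-in shares the interface and intent of
  specialised shape-clustering methods but not their internals; at full
  scale cluster boundaries may differ.
- The bot-pruning rule is the published heuristic only (high volume, never
  retweeted); it is not a bot classifier.
- Headline corpus-level magnitudes from billion-tweet studies (absolute
  subset sizes, absolute co-share densities, absolute trend slopes) are
  scale-dependent and are not reproduced at desk scale; the package
  reproduces the *arithmetic* of published summary tables and the
  *behavior* of each estimator under planted conditions.
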