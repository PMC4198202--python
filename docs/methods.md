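# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and what the validation does and does not show.

## Emotion taxonomy and distant supervision

Sentiment is a closed four-class set — anger, joy, sadness, disgust — with
a fixed canonical order (anger < joy < sadness < disgust) used for every
deterministic tie-break. The taxonomy reflects what emoticon usage on
Chinese microblogs supports: classes like fear or surprise do not gather
enough consistent emoticon votes to train on.

Training labels come from the users themselves: an emoticon→emotion map
(default inventory: 95 emoticon tokens) labels any tweet whose mapped
emoticons name exactly one emotion. Tweets whose emoticons conflict are
discarded — the crowdsourced label is ambiguous — and emoticon tokens are
stripped from the feature sequence before training so the label cannot
leak into the features. Only about 5% of posts carry an emoticon, which
is exactly why the classifier exists: it extends the crowdsourced labels
to the other 95%.

## Classifier

Multinomial naive Bayes over word tokens. Class conditionals use add-one
(Laplace) smoothing, `P(w|c) = (count(w,c)+1) / (total(c)+|V|)`, which
normalizes to exactly 1 over the trained vocabulary. Design choices where
the method description is open:

* **Prior estimator.** `P(c)` is the training document frequency
  `doc_count(c)/N`.
* **Out-of-vocabulary words** at inference use count 0 with the *trained*
  `|V|`; the vocabulary never grows at inference. This is the simplest
  reading consistent with the smoothing formula.
* **Ties** in the posterior argmax break by canonical class order, making
  classification deterministic.
* **Incremental learning.** The model is a set of integer count tables,
  so updating with a labeled batch is exact: `train(A).update(B)` equals
  `train(A ∪ B)` table-for-table, and updates commute.
* **Tokenization** is pluggable and defaults to pre-tokenized input
  (synthetic corpora emit token lists); word segmentation for real
  Chinese text is out of scope.
* Retweeted (duplicated) text is not deduplicated before training.

Classification is computed in log space; a batched variant caches
per-word log conditionals (identical argmax, used by the pipeline).

## Interaction network

Each retweet or mention event between two distinct users adds one count
to their unordered pair; direction is ignored because the tie definition
is symmetric. Users must pass an activity filter — strictly more than
`min_rate` tweets/day averaged over the window, default 0.5/day, i.e.
more than one tweet every two days — and a pair becomes an edge only when
its count reaches the threshold `n` (default 5; the threshold is a
scale/strength trade-off, and node/edge counts are monotone non-increasing
in it). Edge weight is the total event count. Mentions repeated within
one tweet count once per occurrence as provided.

Hop-`h` pair collection runs a BFS from every node (cutoff `h`) and emits
*both* orientations of each unordered pair, so the pair statistic is
invariant to which endpoint is called source. Local clustering is
`2|E_v|/(k_v(k_v−1))` with the convention that degree-0/1 nodes have
clustering 0.

## Correlation estimators

Pearson uses population standard deviations; Spearman assigns average
ranks and uses the rank-difference closed form `1 − 6Σd²/(N(N²−1))` when
both sequences are tie-free, otherwise the Pearson correlation of the
rank vectors (the two coincide without ties). Both raise a
degenerate-sequence error on constant input rather than returning NaN;
callers (sweeps, strata) treat that as a missing cell.

Bootstrap: each repetition draws one index sequence of length N uniformly
with replacement and applies it to both sequences, keeping pairs intact;
the estimate is the mean and standard deviation over non-degenerate
resamples, with degenerate resamples dropped and counted (not imputed),
which keeps the estimator well defined on short sequences. B defaults to
1000 and is configurable; tests and the acceptance script use B in
100–300, where the bootstrap mean is already stable to well under 0.01
at the sequence lengths involved.

Neighborhood comparison: a node's neighborhood vector sums *raw class
counts* over neighbors before normalizing, so prolific neighbors carry
proportionally more weight than averaging fractions would give them.
Degree strata and clustering bins require `min_group` (default 10) nodes;
smaller strata import noise and produce larger errors and are omitted.
Clustering bins are half-open `[i·w, (i+1)·w)` with the last bin closed.

The emotion vector of a user keeps emoticon labels where they exist and
uses the classifier only for the remaining tweets; users with zero tweets
are excluded upstream.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions used throughout the
tests and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| `n_users` | 500 | network size (tests scale 100–1000) |
| `graph_model` | small-world (k=8, p=0.1) | interaction backbone; PA (m=2–3) used where degree spread matters, max degrees ~30 |
| `dirichlet_alpha` | 1.0 | base mixture concentration (uniform simplex) |
| `assortativity_rho` | 0.6 | neighborhood-mixing weight in [0,1] |
| `smoothing_rounds` | 3 | rounds of `v_i ← (1−ρ)v_i + ρ·mean(neighbors)` |
| `tweets_per_user` | 200 (Poisson mean) | over `window_days`=180 → everyone passes the activity filter; `low_activity_fraction` injects filtered users |
| `tokens_per_tweet` | 8 (Poisson mean) | tweet length |
| `emoticon_prob` | 0.05 | fraction of tweets carrying one emoticon |
| `vocab_size_per_emotion` | 60 | per-class inventory |
| `vocab_overlap` | 0.2 | fraction of each inventory shared by all classes |
| `interaction_mean` | 6 | shifted-geometric per-edge event total, so thresholds n=1..10 prune progressively |
| `weight_similarity_coupling` | 0 (off) | scales an edge's event mean by 1 + coupling × mixture similarity |

The assortativity mechanism — smoothing Dirichlet mixtures toward
neighborhood means — is a modeling invention, not a claim about how
affective similarity arises on a real platform. It was chosen because it
offers a single interpretable knob ρ whose induced cross-edge correlation
is monotone in ρ and decays with hop distance, which is precisely what
parameter-recovery tests need. Degree-dependent correlation growth arises
statistically: a larger neighborhood aggregates more tweets, so its
vector is less noisy; with noise-free true mixtures the diffusion process
itself does not favor hubs, so the degree-trend validation uses measured
(finite-sample) vectors, mirroring how the quantity is defined on real
data.

Not emulated: realistic (Chinese) text, diurnal or bursty timing
(timestamps are uniform integer epoch seconds over the window),
follower-graph semantics, event-driven emotion dynamics, and the
asymmetric per-emotion correlation profile seen on real platforms (the
generator treats the four classes symmetrically). Passing tests therefore
demonstrate estimator correctness and end-to-end parameter recovery under
a controlled model — not that any particular real-world emotion is more
assortative than another.

## Numerical and engineering choices

* Pearson output is clipped to [−1, 1] to absorb last-bit float drift.
* Mixtures are renormalized after smoothing; simplex deviation stays
  below 1e−9 at every round.
* Determinism: one global seed fans out to per-stage child seeds via
  stage-name hashing (CRC32), so stages are reproducible in isolation and
  a full rerun is byte-identical. All stochastic code uses
  `numpy.random.Generator`; iteration orders are explicitly sorted
  wherever they influence output files.
* Shifted-geometric interaction totals are drawn as `Geometric(1/mean)`
  (support ≥ 1).
* The corpus generator guarantees a ≥90% giant component by bounded
  regeneration with perturbed seeds; failure after 20 attempts is a
  generation error.
* Malformed tweet lines are skipped with a warning; more than 10%
  malformed lines aborts (the file is probably not a tweet stream).

## Validation problem sizes

Unit and acceptance tests run at n_users 100–1000, 40–200 tweets/user,
bootstrap B 100–300, 3–5 seeds per trend assertion; the full suite
completes in well under a minute on one CPU. Trend assertions on
seed-averaged quantities allow a fixed 0.01 slack for sampling noise.
The classifier hold-out check uses 10,000 training and 2,000 test tweets
on a zero-overlap vocabulary.

## Known limitations

* The smoothing mechanism conflates homophily and contagion; the package
  measures correlation, not causation, and no temporal lead–lag analysis
  is attempted.
* Correlation magnitudes on synthetic corpora are functions of ρ and the
  tweet sample size and are not calibrated to any real platform's values.
* The Spearman rank-difference form is only used tie-free; heavily tied
  fraction data silently takes the Pearson-of-ranks route, which is the
  standard tie-robust definition but can differ from naive applications
  of the closed form.
* `threshold_sweep` recomputes BFS per threshold; for very large graphs
  an incremental approach would be preferable.
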