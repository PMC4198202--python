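# emocorr

Emotion assortativity on microblog interaction networks.

On Twitter-like platforms (Weibo in particular), connected users tend to
share affective states — and different emotions are not equally "social":
anger, for instance, can be far more strongly correlated across ties than
sadness. `emocorr` is a reusable pipeline for measuring that effect. It
covers the whole chain:

1. **Distant-supervision sentiment classification.** Tweets that carry an
   emoticon are labeled by an emoticon→emotion map over four classes
   (*anger*, *joy*, *sadness*, *disgust*) — the users crowdsource their own
   labels. A multinomial naive Bayes classifier with Laplace smoothing,

   P(w | c) = (count(w, c) + 1) / (total(c) + |V|),

   is trained on the labeled posts and classifies the roughly 95% of posts
   without emoticons, by the prior-weighted argmax
   argmax_c log P(c) + Σᵢ log P(wᵢ | c). The count tables support exact
   incremental updates.

2. **Interaction network.** Follow links are not social ties; an edge
   requires repeated interaction. Every retweet or mention event between
   two users adds one count to their pair; pairs with at least *n* events
   between two *active* users (strictly more than one tweet every two days
   over the window) become weighted undirected edges.

3. **Correlation analysis.** Each user's *emotion vector* e = (e_anger,
   e_joy, e_sadness, e_disgust) holds their per-class tweet fractions. For
   every ordered user pair at shortest-path distance *h*, the source
   fractions form a sequence X_m and the target fractions Y_m; association
   is measured by Pearson's r or Spearman's ρ (rank-difference form
   1 − 6Σd²/(N(N²−1)) when tie-free). Errors come from bootstrap
   resampling of the paired index range (mean ± sd over B resamples), and
   a shuffle null (permuting Y) gives the no-association baseline.
   Stratified variants correlate a node against its neighborhood's
   count-summed vector, grouped by degree or by binned local clustering
   coefficient (2|Eᵢ|/(kᵢ(kᵢ−1)), zero below degree 2), and a threshold
   sweep re-extracts the network at rising tie strength *n*.

4. **Synthetic corpora with known ground truth.** Real corpora of this
   kind are huge and access-restricted, so the `synth` module generates
   Weibo-like data: a small-world / preferential-attachment / random
   backbone, per-user Dirichlet emotion mixtures made assortative by a
   single knob ρ (neighborhood mixture smoothing), tweet emission with
   per-emotion vocabularies, 5% emoticon coverage, and shifted-geometric
   per-edge interaction counts. Every downstream claim is validated
   against this ground truth.

Intended users: computational social scientists studying sentiment
homophily/contagion, and anyone needing a tested reference implementation
of emoticon-bootstrapped classification plus network-stratified
correlation statistics.

## Worked example

```sh
emocorr run-all --out demo_run --seed 7 -n 3 --bootstrap-reps 200
```

runs the full pipeline in synthetic mode (500 users, ρ = 0.6, 200
tweets/user over 180 days, 5% emoticon coverage) and prints stage counts:

```
INFO:emocorr:corpus: 99891 tweets
INFO:emocorr:train: 4910 labeled tweets, |V|=204
INFO:emocorr:network: 500 active users -> 499 nodes / 1404 edges at n=3
INFO:emocorr:vectors: 499 users, 99687 tweets classified
INFO:emocorr:correlate: 12 estimates
run complete: demo_run
```

`demo_run/correlations.csv` then holds the hop-stratified estimates, e.g.

```
stratum_type,stratum_value,emotion,method,r_mean,r_std,n_pairs,n_degenerate
hop,1,anger,pearson,0.597340559291,0.0128495740165,2808,0
hop,2,anger,pearson,0.358865058175,0.0110948115249,6670,0
hop,3,anger,pearson,0.111454436575,0.00802576886711,15320,0
...
```

Read: at one hop, a user's anger fraction and their neighbors' anger
fractions correlate at r ≈ 0.60 ± 0.01 over 2,808 ordered pairs; the
correlation decays to ≈ 0.36 at two hops and ≈ 0.11 at three — the
assortativity the generator planted (ρ = 0.6), recovered end-to-end
through classification, network construction and correlation.

The same stages are available individually (`emocorr generate`, `train`,
`classify`, `build-network`, `sweep`) and as library functions
(`emocorr.pearson`, `emocorr.bootstrap_corr`,
`emocorr.pairwise_correlation`, `emocorr.degree_stratified`, ...).

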