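"""Pairwise emotion correlation across social ties.

A user's sentiment status is an emotion vector: the fractions of their
tweets classified into each of the four classes.  For a hop distance
``h``, all ordered user pairs at shortest-path distance ``h`` are
collected; the source users' fractions for one emotion form a sequence X
and the target users' fractions form Y, and their association is measured
with the Pearson product-moment correlation

    r = sum((x_i - mean(X)) (y_i - mean(Y))) / (N sigma_X sigma_Y)

(population standard deviations) or with the Spearman rank correlation,
which for tie-free data is 1 - 6 sum(d_i^2) / (N (N^2 - 1)) with d_i the
rank difference of the i-th pair, and in general is the Pearson
correlation of average ranks.

Uncertainty is estimated by bootstrap: an index sequence of length N is
drawn uniformly with replacement, the same indices are applied to X and Y,
and the correlation of the resampled pair is computed; over B repetitions
this yields an averaged correlation and a standard deviation (the error).
A shuffle null (permuting Y) gives the no-association baseline.

Stratified variants measure the correlation between a node's own vector
and its neighborhood's aggregate vector, grouped by node degree or by
binned local clustering coefficient, and a threshold sweep re-extracts the
network at increasing tie-strength thresholds ``n``.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .classify import EmoticonMap, NaiveBayesModel, label_by_emoticon, strip_emoticons
from .emotions import EMOTION_NAMES, EMOTIONS, N_EMOTIONS, Emotion
from .errors import (
    ConfigurationError,
    DegenerateSequenceError,
    EmocorrError,
    InsufficientDataError,
)
from .network import ActivityFilterSpec, active_users, build_graph, count_interactions, hop_pairs, local_clustering
from .records import Tweet


@dataclass(frozen=True)
class EmotionVector:
    """Per-user fractions of tweets in each emotion class."""

    fractions: tuple[float, float, float, float]
    tweet_count: int

    def __post_init__(self) -> None:
        if self.tweet_count < 1:
            raise EmocorrError("emotion vector requires >= 1 classified tweet")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise EmocorrError("emotion fractions must sum to 1")

    def __getitem__(self, emotion: Emotion) -> float:
        return self.fractions[int(emotion)]

    @classmethod
    def from_counts(cls, counts: Sequence[float]) -> "EmotionVector":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise EmocorrError("emotion vector requires >= 1 classified tweet")
        return cls(tuple(counts / total), int(round(total)))


@dataclass(frozen=True)
class CorrelationEstimate:
    """Bootstrap-averaged correlation for one (stratum, emotion, method)."""

    emotion: Emotion
    stratum_type: str  # "hop" | "degree" | "clustering" | "threshold"
    stratum_value: float
    method: str  # "pearson" | "spearman"
    r_mean: float
    r_std: float
    n_pairs: int
    n_degenerate: int
    b: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r_mean <= 1.0 + 1e-12:
            raise EmocorrError("r_mean outside [-1, 1]")
        if self.r_std < 0:
            raise EmocorrError("r_std must be non-negative")


# ---------------------------------------------------------------------------
# classification of a user's tweets into an emotion vector


def emotion_counts(
    tweets: Sequence[Tweet], model: NaiveBayesModel, emap: EmoticonMap
) -> np.ndarray:
    """Integer class counts over one user's tweets.

    Tweets with an unambiguous emoticon keep that crowdsourced label; all
    others are classified by the trained model (emoticon tokens stripped
    from features first).
    """
    if not tweets:
        raise EmocorrError("user has zero tweets; filter upstream")
    counts = np.zeros(N_EMOTIONS, dtype=np.int64)
    to_classify: list[tuple[str, ...]] = []
    for t in tweets:
        label = label_by_emoticon(t, emap)
        if label is not None:
            counts[int(label)] += 1
        else:
            to_classify.append(strip_emoticons(t.tokens, emap))
    for label in model.classify_many(to_classify):
        counts[int(label)] += 1
    return counts


def emotion_vector(
    tweets: Sequence[Tweet], model: NaiveBayesModel, emap: EmoticonMap
) -> EmotionVector:
    """Classify one user's tweets and return their fraction vector."""
    return EmotionVector.from_counts(emotion_counts(tweets, model, emap))


def dominant_emotion(vector: EmotionVector) -> Emotion:
    """The class with the maximum tweet fraction; ties break canonically."""
    best = EMOTIONS[0]
    for c in EMOTIONS[1:]:
        if vector[c] > vector[best]:
            best = c
    return best


# ---------------------------------------------------------------------------
# correlation primitives


def _as_pair(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise EmocorrError("X and Y must be 1-d sequences of equal length")
    if x.size < 2:
        raise InsufficientDataError("need at least 2 pairs")
    return x, y


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation (population sigmas).

    Raises :class:`DegenerateSequenceError` if either sequence is constant.
    """
    x, y = _as_pair(x, y)
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        raise DegenerateSequenceError("constant sequence: correlation undefined")
    r = float((x - x.mean()) @ (y - y.mean()) / (x.size * sx * sy))
    return max(-1.0, min(1.0, r))


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Tie-free inputs use the rank-difference form 1 - 6 sum(d^2)/(N(N^2-1));
    with ties the Pearson correlation of the rank sequences is returned
    (identical when no ties exist).
    """
    x, y = _as_pair(x, y)
    rx = rankdata(x)
    ry = rankdata(y)
    n = x.size
    tie_free = np.unique(x).size == n and np.unique(y).size == n
    if tie_free:
        d = rx - ry
        return float(1.0 - 6.0 * (d @ d) / (n * (n * n - 1)))
    return pearson(rx, ry)


_METHODS = {"pearson": pearson, "spearman": spearman}


def _corr_fn(method: str):
    try:
        return _METHODS[method]
    except KeyError:
        raise ConfigurationError(
            f"unknown method {method!r}; expected one of {sorted(_METHODS)}"
        ) from None


def bootstrap_corr(
    x: Sequence[float],
    y: Sequence[float],
    b: int = 1000,
    seed: int | np.random.Generator = 0,
    method: str = "pearson",
) -> tuple[float, float, int]:
    """Bootstrap mean and standard deviation of the correlation.

    Each repetition draws one index sequence of length N uniformly with
    replacement and applies it to both X and Y (pairs stay paired).
    Degenerate resamples — where a resampled sequence is constant — are
    dropped and counted.  Returns ``(r_mean, r_std, n_degenerate)``.
    """
    x, y = _as_pair(x, y)
    if b < 1:
        raise ConfigurationError("bootstrap repetitions must be >= 1")
    fn = _corr_fn(method)
    rng = np.random.default_rng(seed)
    n = x.size
    rs: list[float] = []
    n_degenerate = 0
    for _ in range(b):
        k = rng.integers(0, n, size=n)
        try:
            rs.append(fn(x[k], y[k]))
        except DegenerateSequenceError:
            n_degenerate += 1
    if not rs:
        raise DegenerateSequenceError("all bootstrap resamples degenerate")
    arr = np.asarray(rs)
    return float(arr.mean()), float(arr.std()), n_degenerate


def shuffle_null(
    x: Sequence[float],
    y: Sequence[float],
    seed: int | np.random.Generator = 0,
    method: str = "pearson",
) -> float:
    """Correlation of X against a uniform random permutation of Y.

    Breaking the pairing estimates the no-association baseline against
    which the observed correlation is judged.
    """
    x, y = _as_pair(x, y)
    rng = np.random.default_rng(seed)
    return _corr_fn(method)(x, rng.permutation(y))


# ---------------------------------------------------------------------------
# pair sequences over the network


def hop_sequences(
    graph: nx.Graph,
    vectors: Mapping,
    h: int,
    emotion: Emotion,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Source/target fraction sequences over all ordered pairs at distance h."""
    pairs = hop_pairs(graph, h)
    pairs = [(s, t) for s, t in pairs if s in vectors and t in vectors]
    if len(pairs) < 2:
        raise InsufficientDataError(f"fewer than 2 pairs at hop distance {h}")
    xs = np.array([vectors[s][emotion] for s, _ in pairs])
    ys = np.array([vectors[t][emotion] for _, t in pairs])
    return xs, ys, len(pairs)


def pairwise_correlation(
    graph: nx.Graph,
    vectors: Mapping,
    h: int,
    emotion: Emotion,
    method: str = "pearson",
    b: int = 1000,
    seed: int | np.random.Generator = 0,
) -> CorrelationEstimate:
    """Bootstrap correlation of an emotion's fractions across pairs at hop h."""
    xs, ys, n_pairs = hop_sequences(graph, vectors, h, emotion)
    r_mean, r_std, n_deg = bootstrap_corr(xs, ys, b=b, seed=seed, method=method)
    return CorrelationEstimate(
        emotion=emotion,
        stratum_type="hop",
        stratum_value=float(h),
        method=method,
        r_mean=r_mean,
        r_std=r_std,
        n_pairs=n_pairs,
        n_degenerate=n_deg,
        b=b,
    )


# ---------------------------------------------------------------------------
# node-vs-neighborhood correlation, stratified


def neighborhood_vector(graph: nx.Graph, v, counts: Mapping) -> EmotionVector:
    """Aggregate emotion vector of v's neighborhood.

    Raw class counts are summed over all neighbors (so prolific neighbors
    weigh more than an average of fractions would allow) and normalized.
    """
    if v not in graph:
        raise EmocorrError(f"node {v!r} not in graph")
    neighbors = [u for u in graph.neighbors(v) if u in counts]
    if not neighbors:
        raise EmocorrError(f"node {v!r} has no neighbor with tweet counts")
    total = np.zeros(N_EMOTIONS, dtype=float)
    for u in neighbors:
        total += np.asarray(counts[u], dtype=float)
    return EmotionVector.from_counts(total)


def _node_neighborhood_estimate(
    nodes: Sequence,
    stratum_type: str,
    stratum_value: float,
    graph: nx.Graph,
    vectors: Mapping,
    counts: Mapping,
    emotion: Emotion,
    method: str,
    b: int,
    seed,
) -> CorrelationEstimate:
    xs = np.array([vectors[v][emotion] for v in nodes])
    ys = np.array([neighborhood_vector(graph, v, counts)[emotion] for v in nodes])
    r_mean, r_std, n_deg = bootstrap_corr(xs, ys, b=b, seed=seed, method=method)
    return CorrelationEstimate(
        emotion=emotion,
        stratum_type=stratum_type,
        stratum_value=stratum_value,
        method=method,
        r_mean=r_mean,
        r_std=r_std,
        n_pairs=len(nodes),
        n_degenerate=n_deg,
        b=b,
    )


def degree_stratified(
    graph: nx.Graph,
    vectors: Mapping,
    counts: Mapping,
    emotion: Emotion,
    method: str = "pearson",
    b: int = 1000,
    min_group: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[CorrelationEstimate]:
    """Node-vs-neighborhood correlation grouped by node degree.

    Degrees with fewer than ``min_group`` eligible nodes are omitted (small
    strata import noise and produce larger errors).  Returns estimates in
    increasing degree order; empty if no group qualifies.
    """
    rng = np.random.default_rng(seed)
    by_degree: dict[int, list] = {}
    for v in sorted(graph.nodes):
        if v in vectors and graph.degree(v) >= 1:
            by_degree.setdefault(graph.degree(v), []).append(v)
    out: list[CorrelationEstimate] = []
    for k in sorted(by_degree):
        nodes = by_degree[k]
        if len(nodes) < min_group:
            continue
        out.append(
            _node_neighborhood_estimate(
                nodes, "degree", float(k), graph, vectors, counts, emotion,
                method, b, rng,
            )
        )
    return out


def clustering_binned(
    graph: nx.Graph,
    vectors: Mapping,
    counts: Mapping,
    emotion: Emotion,
    bin_width: float = 0.1,
    method: str = "pearson",
    b: int = 1000,
    min_group: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[CorrelationEstimate]:
    """Node-vs-neighborhood correlation with nodes linearly binned by local
    clustering coefficient.

    Bins are half-open ``[i*w, (i+1)*w)`` over [0, 1], the last bin closed
    so clustering 1.0 belongs to the top bin.  The stratum value reported
    is the bin's left edge.
    """
    if not 0.0 < bin_width <= 1.0:
        raise ConfigurationError("bin_width must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_bins = int(np.ceil(1.0 / bin_width))
    by_bin: dict[int, list] = {}
    for v in sorted(graph.nodes):
        if v in vectors and graph.degree(v) >= 1:
            c = local_clustering(graph, v)
            idx = min(int(c / bin_width), n_bins - 1)
            by_bin.setdefault(idx, []).append(v)
    out: list[CorrelationEstimate] = []
    for idx in sorted(by_bin):
        nodes = by_bin[idx]
        if len(nodes) < min_group:
            continue
        out.append(
            _node_neighborhood_estimate(
                nodes, "clustering", round(idx * bin_width, 12), graph, vectors,
                counts, emotion, method, b, rng,
            )
        )
    return out


# ---------------------------------------------------------------------------
# tie-strength threshold sweep


def threshold_sweep(
    tweets: Sequence[Tweet],
    vectors: Mapping,
    n_values: Sequence[int],
    h_values: Sequence[int],
    emotions: Iterable[Emotion] = EMOTIONS,
    method: str = "pearson",
    b: int = 1000,
    seed: int | np.random.Generator = 0,
    activity: ActivityFilterSpec | None = None,
) -> list[CorrelationEstimate]:
    """Re-extract the interaction network at each threshold n and recompute
    the hop-stratified correlations.

    Returns a long-format list of estimates with stratum_type
    ``"threshold_h{h}"`` and stratum value ``n``.  Cells with insufficient
    data or constant sequences are skipped (missing rows, not fatal).
    """
    if not n_values:
        raise ConfigurationError("n_values must be non-empty")
    rng = np.random.default_rng(seed)
    pair_counts = count_interactions(tweets)
    if activity is None:
        active = {t.user_id for t in tweets}
    else:
        active = active_users(tweets, activity)
    out: list[CorrelationEstimate] = []
    for n in n_values:
        g = build_graph(pair_counts, active, n)
        for h in h_values:
            for emotion in emotions:
                try:
                    est = pairwise_correlation(
                        g, vectors, h, emotion, method=method, b=b, seed=rng
                    )
                except (InsufficientDataError, DegenerateSequenceError):
                    continue
                out.append(
                    CorrelationEstimate(
                        emotion=est.emotion,
                        stratum_type=f"threshold_h{h}",
                        stratum_value=float(n),
                        method=est.method,
                        r_mean=est.r_mean,
                        r_std=est.r_std,
                        n_pairs=est.n_pairs,
                        n_degenerate=est.n_degenerate,
                        b=est.b,
                    )
                )
    return out
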