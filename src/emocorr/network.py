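"""Interaction-network construction and structural statistics.

Follow links on microblog platforms are a poor proxy for social ties; an
edge here instead requires repeated interaction.  Every retweet or mention
event between two users contributes one count to their unordered pair; a
pair becomes an edge only when its total count reaches the interaction
threshold ``n``, and the edge weight is that total.  Occasional users are
excluded first by an activity filter (strictly more than ``min_rate``
tweets per day on average over the observation window; the default 0.5/day
is "more than one tweet every two days").

The module also exposes the structural quantities the correlation analysis
stratifies on: ordered user pairs at exact shortest-path distance ``h``,
and the local clustering coefficient (zero for degree < 2).
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable
from dataclasses import dataclass

import networkx as nx

from .errors import ConfigurationError, EmocorrError
from .records import Tweet

PairCounts = dict[tuple[str, str], int]


@dataclass(frozen=True)
class ActivityFilterSpec:
    """Activity filter: keep users posting more than ``min_rate`` tweets/day
    on average over a ``window_days`` observation window."""

    window_days: int
    min_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.window_days < 1:
            raise ConfigurationError("window_days must be positive")
        if self.min_rate <= 0:
            raise ConfigurationError("min_rate must be > 0")

    @property
    def min_tweets(self) -> float:
        return self.min_rate * self.window_days


def _pair(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def count_interactions(tweets: Iterable[Tweet]) -> PairCounts:
    """Aggregate retweet/mention events into unordered-pair counts.

    Each retweet source and each entry in a tweet's mention list adds one
    count to the (author, target) pair, direction-blind.  Self-interactions
    are ignored.  Repeated mentions of the same user in one tweet count
    once per occurrence, as provided.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for t in tweets:
        if t.retweet_of is not None and t.retweet_of != t.user_id:
            counts[_pair(t.user_id, t.retweet_of)] += 1
        for m in t.mentions:
            if m != t.user_id:
                counts[_pair(t.user_id, m)] += 1
    return dict(counts)


def active_users(tweets: Iterable[Tweet], spec: ActivityFilterSpec) -> set[str]:
    """Users whose tweet count strictly exceeds min_rate * window_days."""
    per_user: Counter[str] = Counter(t.user_id for t in tweets)
    threshold = spec.min_tweets
    return {u for u, n in per_user.items() if n > threshold}


def build_graph(pair_counts: PairCounts, active: set[str], n: int) -> nx.Graph:
    """Threshold the pair counts into an undirected weighted graph.

    Keeps pairs with count >= ``n`` whose endpoints are both active; users
    left without any qualifying link are omitted entirely.  The threshold
    is recorded as graph attribute ``interaction_threshold``.
    """
    if n < 1:
        raise ConfigurationError(f"interaction threshold must be >= 1, got {n}")
    g = nx.Graph(interaction_threshold=n)
    for (u, v), c in sorted(pair_counts.items()):
        if c >= n and u in active and v in active:
            g.add_edge(u, v, weight=c)
    return g


def hop_pairs(graph: nx.Graph, h: int) -> list[tuple]:
    """All ordered (source, target) pairs at shortest-path distance exactly ``h``.

    Both orientations of each unordered pair are returned so pair statistics
    built from them are symmetric in source/target.  Pairs in different
    components are unreachable and never appear.
    """
    if h < 1:
        raise ConfigurationError(f"hop distance must be >= 1, got {h}")
    pairs: list[tuple] = []
    for s in sorted(graph.nodes):
        dists = nx.single_source_shortest_path_length(graph, s, cutoff=h)
        pairs.extend((s, t) for t, d in sorted(dists.items()) if d == h)
    return pairs


def local_clustering(graph: nx.Graph, v) -> float:
    """Local clustering coefficient 2|E_v| / (k_v (k_v - 1)).

    ``E_v`` is the set of ties among v's neighbors and ``k_v`` its degree;
    nodes with degree < 2 get clustering 0 by convention.
    """
    if v not in graph:
        raise EmocorrError(f"node {v!r} not in graph")
    neighbors = list(graph.neighbors(v))
    k = len(neighbors)
    if k < 2:
        return 0.0
    ties = 0
    nset = set(neighbors)
    for i, a in enumerate(neighbors):
        ties += sum(1 for b in graph.neighbors(a) if b in nset and b > a)
    return 2.0 * ties / (k * (k - 1))


def write_edge_list(graph: nx.Graph, path) -> None:
    """3-column tab-separated edge list u, v, weight with u < v."""
    lines = ["user_a\tuser_b\tweight"]
    for u, v, w in sorted(
        (min(u, v), max(u, v), d["weight"]) for u, v, d in graph.edges(data=True)
    ):
        lines.append(f"{u}\t{v}\t{w}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
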