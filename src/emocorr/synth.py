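"""Synthetic microblog corpus generator with tunable emotion assortativity.

Real microblog corpora with interaction metadata are large and access
restricted, so every downstream stage here is exercised on generated data
with known ground truth.  The generator emulates:

* an interaction backbone — small-world, preferential-attachment or
  Erdos-Renyi random graph with tunable degree and clustering;
* per-user emotion mixtures over the four classes, made assortative by
  ``smoothing_rounds`` rounds of neighborhood mixing
  ``v_i <- (1 - rho) v_i + rho mean(v_j, j ~ i)`` applied to symmetric
  Dirichlet base mixtures.  ``rho`` is the single assortativity knob: 0
  leaves mixtures independent, values near 1 drive neighbors together, and
  the induced cross-edge correlation decays with hop distance;
* tweet emission: each user posts a Poisson number of tweets spread
  uniformly over the observation window; each tweet's latent emotion is
  drawn from the user's mixture and its tokens from that emotion's word
  distribution (per-emotion vocabularies with configurable overlap);
* emoticon sparsity: only a small fraction of tweets (default 5%, matching
  the roughly 95% of real posts that carry none) include an emoticon, drawn
  from the latent emotion's emoticon set;
* per-edge retweet/mention events with shifted-geometric totals, so the
  tie-strength threshold prunes edges progressively; the event-count mean
  can optionally be coupled to endpoint mixture similarity.

Fixed seed and config reproduce the corpus bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .classify import default_emoticon_map, emoticons_for
from .emotions import EMOTION_NAMES, EMOTIONS, N_EMOTIONS, Emotion
from .errors import ConfigurationError, GenerationError
from .records import Tweet

GRAPH_MODELS = ("small-world", "preferential-attachment", "random")

_DEFAULT_GRAPH_PARAMS = {
    "small-world": {"k": 8, "p": 0.1},
    "preferential-attachment": {"m": 3},
    "random": {"p": 0.02},
}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from a global seed."""
    return (zlib.crc32(stage.encode()) ^ (seed * 2654435761)) % (2**31)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic corpus; defaults are the study conditions.

    ``tweets_per_user`` is a Poisson mean (default 200 over a 180-day
    window so every user passes the default activity filter);
    ``low_activity_fraction`` turns a share of users into occasional
    posters (mean scaled by ``low_activity_factor``) to exercise the
    filter.  ``interaction_mean`` sets the shifted-geometric mean of
    per-edge retweet/mention totals; ``weight_similarity_coupling`` scales
    that mean by ``1 + coupling * similarity`` of the endpoints' mixtures.
    """

    n_users: int = 500
    graph_model: str = "small-world"
    graph_params: dict = field(default_factory=dict)
    assortativity_rho: float = 0.6
    smoothing_rounds: int = 3
    dirichlet_alpha: float = 1.0
    tweets_per_user: float = 200.0
    low_activity_fraction: float = 0.0
    low_activity_factor: float = 0.2
    tokens_per_tweet: float = 8.0
    window_days: int = 180
    emoticon_prob: float = 0.05
    n_emoticons: int = 95
    vocab_size_per_emotion: int = 60
    vocab_overlap: float = 0.2
    interaction_mean: float = 6.0
    weight_similarity_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_users < 4:
            raise ConfigurationError("n_users must be >= 4")
        if self.graph_model not in GRAPH_MODELS:
            raise ConfigurationError(
                f"unknown graph_model {self.graph_model!r}; "
                f"expected one of {GRAPH_MODELS}"
            )
        for name in ("assortativity_rho", "emoticon_prob", "vocab_overlap",
                     "low_activity_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.smoothing_rounds < 0:
            raise ConfigurationError("smoothing_rounds must be >= 0")
        if self.dirichlet_alpha <= 0:
            raise ConfigurationError("dirichlet_alpha must be > 0")
        if self.tweets_per_user <= 0 or self.tokens_per_tweet <= 0:
            raise ConfigurationError("tweet/token rates must be > 0")
        if self.window_days < 1:
            raise ConfigurationError("window_days must be >= 1")
        if self.vocab_size_per_emotion < 1:
            raise ConfigurationError("vocab_size_per_emotion must be >= 1")
        if self.interaction_mean < 1:
            raise ConfigurationError("interaction_mean must be >= 1")
        if self.weight_similarity_coupling < 0:
            raise ConfigurationError("weight_similarity_coupling must be >= 0")

    def effective_graph_params(self) -> dict:
        params = dict(_DEFAULT_GRAPH_PARAMS[self.graph_model])
        params.update(self.graph_params)
        return params

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)


@dataclass
class GroundTruth:
    """Oracle for parameter recovery: true per-user mixtures, the dominant
    emotion each implies, and the realized interaction backbone."""

    mixtures: dict[int, np.ndarray]
    graph: nx.Graph

    def dominant(self, node: int) -> Emotion:
        mix = self.mixtures[node]
        return EMOTIONS[int(np.argmax(mix))]  # argmax: first max wins, canonical

    def mixture_matrix(self) -> np.ndarray:
        return np.stack([self.mixtures[v] for v in sorted(self.mixtures)])


# ---------------------------------------------------------------------------


def generate_network(config: GeneratorConfig) -> nx.Graph:
    """Realize the interaction backbone; nodes are 0..n_users-1.

    Regenerates with perturbed seeds until the giant component covers at
    least 90% of nodes (bounded retries), so hop statistics are computed on
    one dominant component.
    """
    params = config.effective_graph_params()
    n = config.n_users
    base = stage_seed(config.seed, "network")
    for attempt in range(20):
        seed = (base + attempt) % (2**31)
        try:
            if config.graph_model == "small-world":
                g = nx.watts_strogatz_graph(n, params["k"], params["p"], seed=seed)
            elif config.graph_model == "preferential-attachment":
                g = nx.barabasi_albert_graph(n, params["m"], seed=seed)
            else:
                g = nx.gnp_random_graph(n, params["p"], seed=seed)
        except (nx.NetworkXError, KeyError, ValueError) as exc:
            raise ConfigurationError(
                f"invalid graph_params {params} for {config.graph_model}: {exc}"
            ) from exc
        giant = max(nx.connected_components(g), key=len) if g.number_of_edges() else set()
        if len(giant) >= 0.9 * n:
            return g
    raise GenerationError(
        f"could not realize a 90% giant component for {config.graph_model} "
        f"with params {params} after 20 attempts"
    )


def assign_emotions(graph: nx.Graph, config: GeneratorConfig) -> GroundTruth:
    """Draw base mixtures and smooth them toward neighborhood means.

    Base mixtures are symmetric Dirichlet(alpha).  Each of the S smoothing
    rounds replaces every mixture by the convex combination
    (1 - rho) * own + rho * neighborhood mean (synchronous update), which
    preserves the simplex exactly.  Isolated nodes keep their base mixture.
    """
    rng = np.random.default_rng(stage_seed(config.seed, "emotions"))
    nodes = sorted(graph.nodes)
    mix = rng.dirichlet(np.full(N_EMOTIONS, config.dirichlet_alpha), size=len(nodes))
    index = {v: i for i, v in enumerate(nodes)}
    rho = config.assortativity_rho
    for _ in range(config.smoothing_rounds):
        if rho == 0.0:
            break
        new = mix.copy()
        for v in nodes:
            nbrs = [index[u] for u in graph.neighbors(v)]
            if nbrs:
                new[index[v]] = (1.0 - rho) * mix[index[v]] + rho * mix[nbrs].mean(axis=0)
        mix = new
    mix = mix / mix.sum(axis=1, keepdims=True)  # renormalize fp drift
    return GroundTruth(
        mixtures={v: mix[index[v]] for v in nodes},
        graph=graph,
    )


def _build_vocabularies(config: GeneratorConfig) -> list[list[str]]:
    """Per-emotion token inventories with a shared (uninformative) pool.

    A fraction ``vocab_overlap`` of each emotion's inventory is drawn from
    a pool common to all four classes; the remainder is class-unique.
    """
    size = config.vocab_size_per_emotion
    n_shared = int(round(config.vocab_overlap * size))
    shared = [f"w_shared_{i:04d}" for i in range(n_shared)]
    vocabs = []
    for emo in EMOTIONS:
        unique = [f"w_{emo.label}_{i:04d}" for i in range(size - n_shared)]
        vocabs.append(shared + unique)
    return vocabs


def generate_tweets(
    graph: nx.Graph, truth: GroundTruth, config: GeneratorConfig
) -> tuple[list[Tweet], dict[str, Emotion]]:
    """Emit the tweet stream and the latent per-tweet emotion labels.

    Returns ``(tweets, latent)`` where ``latent`` maps tweet_id to the true
    emotion each tweet was drawn from (the oracle used by classifier
    evaluation; it is not part of the corpus files).
    """
    rng = np.random.default_rng(stage_seed(config.seed, "tweets"))
    nodes = sorted(graph.nodes)
    missing = [v for v in nodes if v not in truth.mixtures]
    if missing:
        raise ConfigurationError(f"ground truth missing mixtures for {missing[:5]}")
    vocabs = _build_vocabularies(config)
    emap = default_emoticon_map(config.n_emoticons)
    emo_sets = [emoticons_for(emap, e) for e in EMOTIONS]
    window_seconds = config.window_days * 86400

    low = rng.random(len(nodes)) < config.low_activity_fraction
    records: list[dict] = []
    latent: dict[str, Emotion] = {}
    per_user: dict[str, list[int]] = {}
    for i, v in enumerate(nodes):
        mean = config.tweets_per_user * (config.low_activity_factor if low[i] else 1.0)
        n_tweets = max(1, int(rng.poisson(mean)))
        times = np.sort(rng.integers(0, window_seconds, size=n_tweets))
        emotions = rng.choice(N_EMOTIONS, size=n_tweets, p=truth.mixtures[v])
        uid = str(v)
        user_idx: list[int] = []
        for j in range(n_tweets):
            emo = int(emotions[j])
            length = max(1, int(rng.poisson(config.tokens_per_tweet)))
            tokens = [vocabs[emo][t] for t in rng.integers(0, len(vocabs[emo]), length)]
            emoticons: list[str] = []
            if rng.random() < config.emoticon_prob:
                emoticons.append(emo_sets[emo][int(rng.integers(len(emo_sets[emo])))])
            tid = f"t{v}_{j}"
            user_idx.append(len(records))
            records.append(
                {
                    "tweet_id": tid,
                    "user_id": uid,
                    "timestamp": int(times[j]),
                    "tokens": tokens,
                    "emoticons": emoticons,
                    "retweet_of": None,
                    "mentions": [],
                }
            )
            latent[tid] = EMOTIONS[emo]
        per_user[uid] = user_idx

    # Per-edge interaction events: totals are shifted-geometric; with
    # similarity coupling, similar endpoints interact more, so high
    # thresholds select assortative edges.
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        mean = config.interaction_mean
        if config.weight_similarity_coupling > 0:
            sim = 1.0 - 0.5 * float(
                np.abs(truth.mixtures[u] - truth.mixtures[v]).sum()
            )
            mean = mean * (1.0 + config.weight_similarity_coupling * sim)
        total = int(rng.geometric(1.0 / mean))
        for _ in range(total):
            actor, target = (u, v) if rng.random() < 0.5 else (v, u)
            idx = per_user[str(actor)][int(rng.integers(len(per_user[str(actor)])))]
            rec = records[idx]
            if rng.random() < 0.5 and rec["retweet_of"] is None:
                rec["retweet_of"] = str(target)
            else:
                rec["mentions"].append(str(target))

    tweets = [
        Tweet(
            tweet_id=r["tweet_id"],
            user_id=r["user_id"],
            timestamp=r["timestamp"],
            tokens=tuple(r["tokens"]),
            emoticons=tuple(r["emoticons"]),
            retweet_of=r["retweet_of"],
            mentions=tuple(r["mentions"]),
        )
        for r in records
    ]
    return tweets, latent


def generate_corpus(config: GeneratorConfig, out_dir: str | Path) -> dict:
    """Orchestrate network, mixtures and tweets; write the corpus to disk.

    Writes ``tweets.jsonl`` (line-delimited records), ``ground_truth.tsv``
    (per-user mixtures and dominant emotion), ``true_network.tsv`` (the
    realized backbone) and ``manifest.json`` (config echo, seed, counts).
    Returns the manifest dict.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise GenerationError(f"cannot create output directory {out}: {exc}") from exc

    graph = generate_network(config)
    truth = assign_emotions(graph, config)
    tweets, _latent = generate_tweets(graph, truth, config)

    tweet_path = out / "tweets.jsonl"
    with tweet_path.open("w") as fh:
        for t in tweets:
            fh.write(t.to_json() + "\n")

    gt_lines = ["user_id\t" + "\t".join(f"p_{n}" for n in EMOTION_NAMES)
                + "\tdominant_emotion"]
    for v in sorted(truth.mixtures):
        mix = truth.mixtures[v]
        gt_lines.append(
            str(v) + "\t" + "\t".join(f"{p:.10f}" for p in mix)
            + "\t" + truth.dominant(v).label
        )
    (out / "ground_truth.tsv").write_text("\n".join(gt_lines) + "\n")

    net_lines = ["user_a\tuser_b"]
    net_lines += [f"{u}\t{v}" for u, v in sorted(tuple(sorted(e)) for e in graph.edges)]
    (out / "true_network.tsv").write_text("\n".join(net_lines) + "\n")

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_users": config.n_users,
        "n_tweets": len(tweets),
        "n_edges": graph.number_of_edges(),
        "n_emoticon_tweets": sum(1 for t in tweets if t.emoticons),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
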