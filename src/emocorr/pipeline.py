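"""End-to-end orchestration: corpus -> labels -> classifier -> network ->
emotion vectors -> hop-stratified correlations.

A single global seed is fanned out to per-stage child seeds (stage-name
hashing) so stages are individually reproducible, and rerunning with the
same configuration reproduces every output file bit-identically.  Stage
boundaries log record counts: the activity filter and the interaction
threshold silently shrink the cohort, and the counts are the audit trail.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as eio
from .classify import (
    NaiveBayesModel,
    build_training_corpus,
    default_emoticon_map,
    load_emoticon_map,
    save_emoticon_map,
)
from .correlate import (
    CorrelationEstimate,
    EmotionVector,
    dominant_emotion,
    emotion_counts,
    pairwise_correlation,
)
from .emotions import EMOTION_NAMES, EMOTIONS
from .errors import DegenerateSequenceError, EmocorrError, InsufficientDataError
from .network import (
    ActivityFilterSpec,
    active_users,
    build_graph,
    count_interactions,
    write_edge_list,
)
from .records import Tweet
from .synth import GeneratorConfig, generate_corpus, stage_seed

logger = logging.getLogger("emocorr")


@dataclass
class PipelineConfig:
    """Configuration for a full run.

    In synthetic mode (``tweets_path`` unset) a corpus is generated into
    the output directory first; otherwise tweets are read from
    ``tweets_path`` and the emoticon map from ``emoticon_map_path`` (the
    default inventory is used when unset).
    """

    out_dir: str = "emocorr_run"
    tweets_path: str | None = None
    emoticon_map_path: str | None = None
    # network params
    min_interactions: int = 5
    window_days: int = 180
    min_rate: float = 0.5
    # correlation params
    hops: tuple[int, ...] = (1, 2, 3)
    bootstrap_reps: int = 1000
    method: str = "pearson"
    bin_width: float = 0.1
    min_group: int = 10
    # synthetic mode
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", {})
        cfg = cls(**raw)
        if gen:
            cfg.generator = GeneratorConfig(**gen)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hops"] = list(self.hops)
        return d


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write all artifacts into the run directory.

    Returns the run directory path.  Any stage failure aborts with the
    stage name in the message.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    # -- stage: corpus ----------------------------------------------------
    if config.tweets_path is None:
        gen_cfg = dataclasses.replace(
            config.generator,
            seed=stage_seed(config.seed, "generate"),
            window_days=config.window_days,
        )
        corpus_manifest = generate_corpus(gen_cfg, out / "corpus")
        tweets = eio.read_tweets(out / "corpus" / "tweets.jsonl")
        manifest["stages"]["generate"] = {
            "n_tweets": corpus_manifest["n_tweets"],
            "n_users": corpus_manifest["n_users"],
        }
        emap = default_emoticon_map(gen_cfg.n_emoticons)
    else:
        if not Path(config.tweets_path).exists():
            raise EmocorrError(f"stage read: tweets path not found: {config.tweets_path}")
        tweets = eio.read_tweets(config.tweets_path)
        emap = (
            load_emoticon_map(config.emoticon_map_path)
            if config.emoticon_map_path
            else default_emoticon_map()
        )
        manifest["stages"]["read"] = {"n_tweets": len(tweets)}
    logger.info("corpus: %d tweets", len(tweets))
    save_emoticon_map(emap, out / "emoticon_map.tsv")

    # -- stage: label + train --------------------------------------------
    try:
        labeled = build_training_corpus(tweets, emap)
        model = NaiveBayesModel.train(labeled)
    except EmocorrError as exc:
        raise EmocorrError(f"stage train: {exc}") from exc
    model.save(out / "nb_model.tsv")
    manifest["stages"]["train"] = {
        "n_labeled": len(labeled),
        "vocabulary_size": len(model.vocabulary),
        "doc_counts": {c.label: model.doc_counts[c] for c in EMOTIONS},
    }
    logger.info("train: %d labeled tweets, |V|=%d", len(labeled), len(model.vocabulary))

    # -- stage: network ---------------------------------------------------
    pair_counts = count_interactions(tweets)
    spec = ActivityFilterSpec(window_days=config.window_days, min_rate=config.min_rate)
    active = active_users(tweets, spec)
    graph = build_graph(pair_counts, active, config.min_interactions)
    write_edge_list(graph, out / "edges.tsv")
    manifest["stages"]["network"] = {
        "n_interacting_pairs": len(pair_counts),
        "n_active_users": len(active),
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
    }
    logger.info(
        "network: %d active users -> %d nodes / %d edges at n=%d",
        len(active), graph.number_of_nodes(), graph.number_of_edges(),
        config.min_interactions,
    )

    # -- stage: emotion vectors ------------------------------------------
    by_user: dict[str, list[Tweet]] = defaultdict(list)
    for t in tweets:
        by_user[t.user_id].append(t)
    counts = {}
    vectors = {}
    n_emoticon_labeled = 0
    for u in sorted(graph.nodes):
        user_tweets = by_user.get(u, [])
        if not user_tweets:
            continue
        c = emotion_counts(user_tweets, model, emap)
        counts[u] = c
        vectors[u] = EmotionVector.from_counts(c)
    vec_lines = [
        "user_id\t" + "\t".join(f"e_{n}" for n in EMOTION_NAMES)
        + "\ttweet_count\tdominant_emotion"
    ]
    for u in sorted(vectors):
        v = vectors[u]
        vec_lines.append(
            u + "\t" + "\t".join(f"{p:.10f}" for p in v.fractions)
            + f"\t{v.tweet_count}\t{dominant_emotion(v).label}"
        )
    (out / "vectors.tsv").write_text("\n".join(vec_lines) + "\n")
    n_classified = sum(v.tweet_count for v in vectors.values())
    manifest["stages"]["vectors"] = {
        "n_users_with_vectors": len(vectors),
        "n_classified_tweets": n_classified,
    }
    logger.info("vectors: %d users, %d tweets classified", len(vectors), n_classified)

    # -- stage: correlations ---------------------------------------------
    estimates: list[CorrelationEstimate] = []
    corr_seed = stage_seed(config.seed, "correlate")
    for h in config.hops:
        for emotion in EMOTIONS:
            try:
                estimates.append(
                    pairwise_correlation(
                        graph, vectors, h, emotion,
                        method=config.method, b=config.bootstrap_reps,
                        seed=stage_seed(corr_seed, f"h{h}_{emotion.label}"),
                    )
                )
            except (InsufficientDataError, DegenerateSequenceError) as exc:
                logger.warning("correlate: h=%d %s skipped (%s)", h, emotion.label, exc)
    eio.write_results(estimates, out / "correlations.csv")
    manifest["stages"]["correlate"] = {"n_estimates": len(estimates)}
    logger.info("correlate: %d estimates", len(estimates))

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return out
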