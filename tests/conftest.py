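import numpy as np
import pytest

from emocorr import (
    EmotionVector,
    GeneratorConfig,
    NaiveBayesModel,
    Tweet,
    assign_emotions,
    generate_network,
    generate_tweets,
)
from emocorr.emotions import Emotion


def tweet(uid="u1", tokens=(), emoticons=(), retweet_of=None, mentions=(),
          tid=None, ts=0):
    return Tweet(
        tweet_id=tid or f"{uid}_{ts}",
        user_id=uid,
        timestamp=ts,
        tokens=tuple(tokens),
        emoticons=tuple(emoticons),
        retweet_of=retweet_of,
        mentions=tuple(mentions),
    )


@pytest.fixture(scope="session")
def tiny_model():
    """Hand-checkable corpus: {("a b", joy), ("a", joy), ("c", anger)}."""
    return NaiveBayesModel.train(
        [(("a", "b"), Emotion.JOY), (("a",), Emotion.JOY), (("c",), Emotion.ANGER)]
    )


@pytest.fixture(scope="session")
def small_corpus():
    """One shared synthetic corpus (300 users, default conditions)."""
    cfg = GeneratorConfig(n_users=300, tweets_per_user=80.0, emoticon_prob=0.05,
                          seed=42)
    graph = generate_network(cfg)
    truth = assign_emotions(graph, cfg)
    tweets, latent = generate_tweets(graph, truth, cfg)
    return cfg, graph, truth, tweets, latent


def truth_vectors(truth):
    """True mixtures wrapped as emotion vectors (oracle labels, infinite-sample
    limit)."""
    return {
        v: EmotionVector(tuple(m), 1) for v, m in truth.mixtures.items()
    }
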