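"""Emoticon distant supervision and a four-class multinomial naive Bayes
classifier with Laplace smoothing.

Users annotate their own posts when they attach an emoticon; an
emoticon-to-emotion map turns those posts into a labeled training corpus
without any manual annotation of text.  A multinomial naive Bayes model is
trained on the labeled posts and classifies the large emoticon-free
remainder.  Word conditionals use add-one (Laplace) smoothing

    P(w | c) = (count(w, c) + 1) / (total(c) + |V|)

where ``count(w, c)`` is the number of occurrences of word ``w`` in
class-``c`` training tweets, ``total(c)`` the class token total and ``V``
the trained vocabulary.  Classification is the prior-weighted argmax in
log space.  The model supports exact incremental updates: adding a batch
of labeled tweets yields the same count tables as retraining on the union.
"""

from __future__ import annotations

import math
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

from .emotions import EMOTIONS, Emotion, emotion_from_name
from .errors import ConfigurationError, NoLabelableTweetsError
from .records import Tweet

# An emoticon map assigns each emoticon token exactly one emotion.
EmoticonMap = Mapping[str, Emotion]

#: Default emoticon inventory size: the most popular emoticons on the
#: platform, manually mapped to the four classes.
DEFAULT_N_EMOTICONS = 95


def default_emoticon_map(n_emoticons: int = DEFAULT_N_EMOTICONS) -> dict[str, Emotion]:
    """Synthetic emoticon inventory: tokens ``E1..E{n}`` assigned to the four
    emotions round-robin, standing in for a manually annotated map."""
    if n_emoticons < len(EMOTIONS):
        raise ConfigurationError("need at least one emoticon per emotion")
    return {f"E{i + 1}": EMOTIONS[i % len(EMOTIONS)] for i in range(n_emoticons)}


def emoticons_for(emap: EmoticonMap, emotion: Emotion) -> tuple[str, ...]:
    """All emoticon tokens mapped to ``emotion``, in map order."""
    return tuple(tok for tok, emo in emap.items() if emo is emotion)


def load_emoticon_map(path: str | Path) -> dict[str, Emotion]:
    """Read a 2-column tab-separated file: emoticon_token<TAB>emotion_name."""
    emap: dict[str, Emotion] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConfigurationError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
            )
        tok, name = parts
        if tok in emap:
            raise ConfigurationError(f"{path}:{lineno}: duplicate emoticon {tok!r}")
        emap[tok] = emotion_from_name(name)
    return emap


def save_emoticon_map(emap: EmoticonMap, path: str | Path) -> None:
    lines = [f"{tok}\t{emo.label}" for tok, emo in emap.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def label_by_emoticon(tweet: Tweet, emap: EmoticonMap) -> Emotion | None:
    """Distant-supervision label for one tweet.

    Returns the emotion if the tweet's emoticons map to exactly one distinct
    emotion; returns ``None`` when no emoticon is mapped or when mapped
    emoticons conflict (such tweets are excluded from training).
    """
    found: set[Emotion] = set()
    for tok in tweet.emoticons:
        emo = emap.get(tok)
        if emo is not None:
            found.add(emo)
            if len(found) > 1:
                return None
    if len(found) == 1:
        return next(iter(found))
    return None


def strip_emoticons(tokens: Iterable[str], emap: EmoticonMap) -> tuple[str, ...]:
    """Drop any token that is a mapped emoticon (label-leak hygiene)."""
    return tuple(t for t in tokens if t not in emap)


def build_training_corpus(
    tweets: Iterable[Tweet], emap: EmoticonMap
) -> list[tuple[tuple[str, ...], Emotion]]:
    """Extract the emoticon-labelable tweets as (tokens, label) pairs.

    Emoticon tokens are removed from the token sequence so labels cannot
    leak into features.  Raises :class:`NoLabelableTweetsError` if nothing
    is labelable.
    """
    if not emap:
        raise ConfigurationError("emoticon map is empty")
    labeled: list[tuple[tuple[str, ...], Emotion]] = []
    for tweet in tweets:
        label = label_by_emoticon(tweet, emap)
        if label is not None:
            labeled.append((strip_emoticons(tweet.tokens, emap), label))
    if not labeled:
        raise NoLabelableTweetsError("no labelable tweets in corpus")
    return labeled


@dataclass
class NaiveBayesModel:
    """Count tables of a trained multinomial naive Bayes model.

    ``counts[c][w]`` is the number of times word ``w`` appeared in training
    tweets of class ``c``; ``token_totals[c]`` the class token total;
    ``doc_counts[c]`` the number of training tweets per class.  The class
    prior is the training document frequency ``doc_counts[c] / n_docs``.
    """

    counts: dict[Emotion, Counter] = field(
        default_factory=lambda: {e: Counter() for e in EMOTIONS}
    )
    doc_counts: dict[Emotion, int] = field(
        default_factory=lambda: {e: 0 for e in EMOTIONS}
    )
    token_totals: dict[Emotion, int] = field(
        default_factory=lambda: {e: 0 for e in EMOTIONS}
    )
    vocabulary: set[str] = field(default_factory=set)

    @property
    def n_docs(self) -> int:
        return sum(self.doc_counts.values())

    @classmethod
    def train(cls, labeled: Sequence[tuple[tuple[str, ...], Emotion]]) -> "NaiveBayesModel":
        """Fit the count tables from (tokens, label) pairs.

        At least two classes must be present; a single-class corpus is
        degenerate (every input would get the same label).
        """
        if not labeled:
            raise NoLabelableTweetsError("empty training set")
        model = cls()
        model.update(labeled)
        if sum(1 for c in EMOTIONS if model.doc_counts[c] > 0) < 2:
            raise ConfigurationError(
                "training corpus covers a single class; classifier degenerate"
            )
        return model

    def update(
        self, labeled: Sequence[tuple[tuple[str, ...], Emotion]]
    ) -> "NaiveBayesModel":
        """Add a labeled batch to the count tables (incremental learning).

        Exactly equivalent to retraining on the union: counts are additive
        integers.  Returns ``self`` for chaining.
        """
        for tokens, label in labeled:
            self.doc_counts[label] += 1
            self.counts[label].update(tokens)
            self.token_totals[label] += len(tokens)
            self.vocabulary.update(tokens)
        return self

    def copy(self) -> "NaiveBayesModel":
        return NaiveBayesModel(
            counts={c: Counter(self.counts[c]) for c in EMOTIONS},
            doc_counts=dict(self.doc_counts),
            token_totals=dict(self.token_totals),
            vocabulary=set(self.vocabulary),
        )

    def word_prob(self, word: str, emotion: Emotion) -> float:
        """Laplace-smoothed class conditional (count(w,c)+1)/(total(c)+|V|).

        Out-of-vocabulary words use count 0 with the trained vocabulary
        size; the vocabulary does not grow at inference time.
        """
        return (self.counts[emotion][word] + 1) / (
            self.token_totals[emotion] + len(self.vocabulary)
        )

    def prior(self, emotion: Emotion) -> float:
        return self.doc_counts[emotion] / self.n_docs

    def classify(self, tokens: Iterable[str]) -> Emotion:
        """Prior-weighted argmax over classes, computed in log space.

        Classes absent from training (zero prior) are excluded.  Ties break
        by canonical emotion order (anger < joy < sadness < disgust).  An
        empty token sequence reduces to the prior argmax.
        """
        tokens = list(tokens)
        n_docs = self.n_docs
        vsize = len(self.vocabulary)
        best: Emotion | None = None
        best_score = -math.inf
        for c in EMOTIONS:
            if self.doc_counts[c] == 0:
                continue
            cnt = self.counts[c]
            denom = math.log(self.token_totals[c] + vsize)
            score = math.log(self.doc_counts[c] / n_docs)
            for w in tokens:
                score += math.log(cnt[w] + 1) - denom
            if score > best_score:  # strict: first (canonical) class wins ties
                best, best_score = c, score
        if best is None:
            raise ConfigurationError("model has no training documents")
        return best

    def classify_many(self, token_seqs: Iterable[Sequence[str]]) -> list[Emotion]:
        """Classify a batch, caching per-word log conditionals across tweets."""
        n_docs = self.n_docs
        vsize = len(self.vocabulary)
        classes = [c for c in EMOTIONS if self.doc_counts[c] > 0]
        if not classes:
            raise ConfigurationError("model has no training documents")
        log_prior = {c: math.log(self.doc_counts[c] / n_docs) for c in classes}
        log_denom = {c: math.log(self.token_totals[c] + vsize) for c in classes}
        cache: dict[str, list[float]] = {}
        log = math.log
        out: list[Emotion] = []
        for tokens in token_seqs:
            scores = [log_prior[c] for c in classes]
            for w in tokens:
                contrib = cache.get(w)
                if contrib is None:
                    contrib = [
                        log(self.counts[c][w] + 1) - log_denom[c] for c in classes
                    ]
                    cache[w] = contrib
                for i, v in enumerate(contrib):
                    scores[i] += v
            best_i = 0
            for i in range(1, len(classes)):
                if scores[i] > scores[best_i]:
                    best_i = i
            out.append(classes[best_i])
        return out

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Flat tabular dump: header lines with per-class doc counts, then
        one ``word<TAB>class<TAB>count`` row per nonzero cell.  Vocabulary
        words unseen in any class are preserved via sentinel rows."""
        out: list[str] = []
        for c in EMOTIONS:
            out.append(f"#doc_count\t{c.label}\t{self.doc_counts[c]}")
        for w in sorted(self.vocabulary):
            wrote = False
            for c in EMOTIONS:
                n = self.counts[c][w]
                if n:
                    out.append(f"{w}\t{c.label}\t{n}")
                    wrote = True
            if not wrote:
                out.append(f"{w}\t-\t0")
        Path(path).write_text("\n".join(out) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "NaiveBayesModel":
        model = cls()
        for line in Path(path).read_text().splitlines():
            if not line:
                continue
            if line.startswith("#doc_count\t"):
                _, name, n = line.split("\t")
                model.doc_counts[emotion_from_name(name)] = int(n)
                continue
            w, name, n = line.split("\t")
            model.vocabulary.add(w)
            if name != "-":
                c = emotion_from_name(name)
                model.counts[c][w] = int(n)
                model.token_totals[c] += int(n)
        return model
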