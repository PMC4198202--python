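"""The four-class emotion taxonomy used throughout the package.

Microblog sentiment is categorized into anger, joy, sadness and disgust.
The enum order is the canonical order used for deterministic tie-breaking
everywhere (classification argmax, dominant emotion).
"""

from __future__ import annotations

from enum import IntEnum


class Emotion(IntEnum):
    """Closed four-class emotion set with a stable canonical ordering."""

    ANGER = 0
    JOY = 1
    SADNESS = 2
    DISGUST = 3

    @property
    def label(self) -> str:
        return self.name.lower()


EMOTIONS: tuple[Emotion, ...] = tuple(Emotion)
EMOTION_NAMES: tuple[str, ...] = tuple(e.label for e in EMOTIONS)
N_EMOTIONS = len(EMOTIONS)

_BY_NAME = {e.label: e for e in EMOTIONS}


def emotion_from_name(name: str) -> Emotion:
    """Look up an emotion by its lowercase name.

    Raises ``KeyError`` with the list of valid names on a miss.
    """
    try:
        return _BY_NAME[name.strip().lower()]
    except KeyError:
        raise KeyError(
            f"unknown emotion {name!r}; expected one of {EMOTION_NAMES}"
        ) from None
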