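"""The tweet record: one microblog post with author, time, content and
interaction targets (retweet source and mentioned users)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Tweet:
    """One microblog post.

    ``tokens`` is the pre-segmented word sequence (emoticons excluded);
    ``emoticons`` lists the emoticon tokens attached to the post;
    ``retweet_of`` names the user whose post was retweeted, if any;
    ``mentions`` lists mentioned users, one entry per occurrence.
    """

    tweet_id: str
    user_id: str
    timestamp: int
    tokens: tuple[str, ...] = ()
    emoticons: tuple[str, ...] = ()
    retweet_of: str | None = None
    mentions: tuple[str, ...] = ()

    def to_json(self) -> str:
        """Serialize to a single compact JSON line with a fixed key order."""
        return json.dumps(
            {
                "tweet_id": self.tweet_id,
                "user_id": self.user_id,
                "timestamp": self.timestamp,
                "tokens": list(self.tokens),
                "emoticons": list(self.emoticons),
                "retweet_of": self.retweet_of,
                "mentions": list(self.mentions),
            },
            ensure_ascii=False,
            separators=(",", ":"),
        )

    @classmethod
    def from_json(cls, line: str) -> "Tweet":
        obj = json.loads(line)
        if not isinstance(obj, dict):
            raise ValueError("tweet record is not a JSON object")
        tweet = cls(
            tweet_id=str(obj["tweet_id"]),
            user_id=str(obj["user_id"]),
            timestamp=int(obj["timestamp"]),
            tokens=tuple(str(t) for t in obj.get("tokens", [])),
            emoticons=tuple(str(t) for t in obj.get("emoticons", [])),
            retweet_of=(None if obj.get("retweet_of") is None
                        else str(obj["retweet_of"])),
            mentions=tuple(str(t) for t in obj.get("mentions", [])),
        )
        return tweet
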