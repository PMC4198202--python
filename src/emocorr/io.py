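"""Readers and writers for tweet streams and result tables."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .correlate import CorrelationEstimate
from .emotions import emotion_from_name
from .errors import EmocorrError
from .records import Tweet

logger = logging.getLogger("emocorr")

RESULT_COLUMNS = [
    "stratum_type",
    "stratum_value",
    "emotion",
    "method",
    "r_mean",
    "r_std",
    "n_pairs",
    "n_degenerate",
]


def read_tweets(path: str | Path, max_malformed_frac: float = 0.1) -> list[Tweet]:
    """Read line-delimited tweet records, skipping malformed lines.

    Each skipped line is logged; if more than ``max_malformed_frac`` of
    non-empty lines fail to parse the file is likely the wrong format and
    a fatal error is raised.
    """
    path = Path(path)
    if not path.exists():
        raise EmocorrError(f"tweets file not found: {path}")
    tweets: list[Tweet] = []
    n_bad = 0
    n_lines = 0
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        n_lines += 1
        try:
            tweets.append(Tweet.from_json(line))
        except (ValueError, KeyError, TypeError) as exc:
            n_bad += 1
            logger.warning("%s:%d: malformed tweet record skipped (%s)", path, lineno, exc)
    if n_lines == 0:
        logger.warning("%s: empty tweet file", path)
    elif n_bad / n_lines > max_malformed_frac:
        raise EmocorrError(
            f"{path}: {n_bad}/{n_lines} lines malformed; wrong file format?"
        )
    if n_bad:
        logger.warning("%s: skipped %d of %d malformed lines", path, n_bad, n_lines)
    return tweets


def write_tweets(tweets, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in tweets:
            fh.write(t.to_json() + "\n")


def results_frame(estimates: list[CorrelationEstimate]) -> pd.DataFrame:
    """Long-format results table, deterministically sorted."""
    rows = [
        {
            "stratum_type": e.stratum_type,
            "stratum_value": e.stratum_value,
            "emotion": e.emotion.label,
            "method": e.method,
            "r_mean": e.r_mean,
            "r_std": e.r_std,
            "n_pairs": e.n_pairs,
            "n_degenerate": e.n_degenerate,
        }
        for e in estimates
    ]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["stratum_type", "stratum_value", "emotion", "method"]
        ).reset_index(drop=True)
    return df


def write_results(estimates: list[CorrelationEstimate], path: str | Path) -> None:
    """Write estimates as CSV with stable column and row order."""
    try:
        results_frame(estimates).to_csv(path, index=False, float_format="%.12g")
    except OSError as exc:
        raise EmocorrError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
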