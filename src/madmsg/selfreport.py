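"""Scoring of crowdsourced self-report message-evaluation constructs.

Participants in the crowdsourced arm each rate one message on four
multi-item constructs: receptivity (9 items, 1-7), engagement (3 items,
1-7), positive attitude (9 semantic-differential items, 1-7) and negative
emotion (frightened / anxious / nervous / worried; 4 items, 1-4).  A
participant's construct score is the mean of the construct's items; the
per-message attribute entering the decision matrix is the mean of those
scores across participants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConstructScale:
    """Item count and response bounds for one self-report construct."""

    n_items: int
    lo: float
    hi: float


#: The four constructs measured in the crowdsourced arm.
CONSTRUCTS: Mapping[str, ConstructScale] = {
    "receptivity": ConstructScale(9, 1, 7),
    "engagement": ConstructScale(3, 1, 7),
    "positive_attitude": ConstructScale(9, 1, 7),
    "negative_emotion": ConstructScale(4, 1, 4),
}


@dataclass(frozen=True)
class ItemResponseSet:
    """One participant's item responses to one construct for one message.

    The item list must be complete (the construct's full item count) and
    every response must lie within the construct's scale bounds; records
    failing either check are rejected rather than prorated.
    """

    participant_id: str
    message_id: str
    construct: str
    item_scores: tuple = field(default=())

    def __post_init__(self):
        if self.construct not in CONSTRUCTS:
            raise DataValidationError(
                f"unknown construct {self.construct!r}; expected one of "
                f"{sorted(CONSTRUCTS)}"
            )
        scale = CONSTRUCTS[self.construct]
        scores = tuple(float(s) for s in self.item_scores)
        object.__setattr__(self, "item_scores", scores)
        if len(scores) != scale.n_items:
            raise DataValidationError(
                f"{self.construct} requires {scale.n_items} items, got "
                f"{len(scores)} (participant {self.participant_id}, "
                f"message {self.message_id})"
            )
        for s in scores:
            if not (scale.lo <= s <= scale.hi):
                raise DataValidationError(
                    f"item score {s} outside [{scale.lo}, {scale.hi}] for "
                    f"construct {self.construct}"
                )


@dataclass(frozen=True)
class ConstructSummary:
    """Per-message construct mean with its standard error.

    ``se`` is the sample (n-1) standard deviation of participant scores
    divided by sqrt(n); it is NaN when only one participant contributed.
    """

    message_id: str
    construct: str
    mean: float
    se: float
    n: int


def score_construct(responses: ItemResponseSet) -> float:
    """Mean of a participant's item scores for one construct.

    Validation (item count, scale bounds) happens when the
    :class:`ItemResponseSet` is built, so the mean is always within the
    construct's scale bounds.
    """
    return float(np.mean(responses.item_scores))


def summarize_construct(
    scores: Sequence[float], message_id: str, construct: str
) -> ConstructSummary:
    """Aggregate participant construct scores to a per-message summary."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise DataValidationError(
            f"no scores for message {message_id}, construct {construct}"
        )
    n = int(arr.size)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
    return ConstructSummary(message_id, construct, mean, se, n)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = k/(k-1) * (1 - sum(item variances) / var(item sums)),
    with sample (n-1) variances over a participants x items matrix.
    Can be negative for discordant items.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2:
        raise DataValidationError("item matrix must be 2-dimensional")
    n, k = x.shape
    if k < 2:
        raise DataValidationError(f"alpha requires at least 2 items, got {k}")
    if n < 2:
        raise DataValidationError(
            f"alpha requires at least 2 participants, got {n}"
        )
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DataValidationError("total-score variance is zero")
    item_vars = x.var(axis=0, ddof=1)
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


# ---------------------------------------------------------------------------
# Cohort aggregation and CSV interchange
# ---------------------------------------------------------------------------

def read_responses_csv(path) -> list[ItemResponseSet]:
    """Read long-format item responses.

    Expected columns: participant_id, message_id, construct, item_index,
    score.  Incomplete or out-of-bounds participant-message-construct
    records are rejected (counted at INFO, detailed at DEBUG) rather than
    silently prorated.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "message_id": str})
    required = {"participant_id", "message_id", "construct", "item_index", "score"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"responses CSV missing columns: {sorted(missing)}")
    kept: list[ItemResponseSet] = []
    rejected = 0
    for (pid, mid, construct), grp in df.groupby(
        ["participant_id", "message_id", "construct"], sort=False
    ):
        ordered = grp.sort_values("item_index")["score"].tolist()
        try:
            kept.append(ItemResponseSet(pid, mid, construct, tuple(ordered)))
        except DataValidationError as exc:
            rejected += 1
            logger.debug("rejected record %s/%s/%s: %s", pid, mid, construct, exc)
    logger.info(
        "read %d self-report records (%d rejected)", len(kept), rejected
    )
    return kept


def summarize_cohort(responses: Iterable[ItemResponseSet]) -> pd.DataFrame:
    """Per-message, per-construct summaries for a whole cohort.

    Returns a tidy frame with columns message_id, construct, mean, se, n.
    """
    scored: dict[tuple[str, str], list[float]] = {}
    for r in responses:
        scored.setdefault((r.message_id, r.construct), []).append(score_construct(r))
    if not scored:
        raise DataValidationError("no responses to summarize")
    rows = [
        summarize_construct(scores, mid, construct)
        for (mid, construct), scores in sorted(scored.items())
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def attribute_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot a cohort summary into a message x construct table of means,
    the self-report block of the decision matrix."""
    wide = summary.pivot(index="message_id", columns="construct", values="mean")
    wide.columns.name = None
    return wide[[c for c in CONSTRUCTS if c in wide.columns]]


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)
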