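"""Per-message psychophysiological attribute scores for the lab arm.

Three measures are summarized per message:

* **Heart-rate deceleration** — per-second BPM deviations from the last
  pre-message baseline second, folded to absolute values and averaged over
  the exposure; larger scores index more cognitive resources allocated to
  encoding.
* **Recognition accuracy** — the hit rate on a recognition task whose
  target fragments are excerpts of the viewed messages (foils never enter
  the hit rate).
* **Visual attention** — mean dwell time in milliseconds over the three
  areas of interest (two sentences and the hashtag).

ECG R-peak detection and gaze-to-AOI assignment are upstream: this module
consumes per-second BPM traces and per-AOI dwell durations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import DataValidationError

logger = logging.getLogger(__name__)

#: AOIs per message: sentence 1, sentence 2, hashtag.
N_AOI = 3
#: Recognition task composition: 24 targets (2 per message) + 24 foils.
TARGETS_PER_MESSAGE = 2
N_TARGETS = 24
N_FOILS = 24


@dataclass(frozen=True)
class HeartRateTrace:
    """Per-second BPM during one message exposure plus the baseline second."""

    participant_id: str
    message_id: str
    baseline_bpm: float
    bpm_by_second: tuple = field(default=())

    def __post_init__(self):
        series = tuple(float(b) for b in self.bpm_by_second)
        object.__setattr__(self, "bpm_by_second", series)
        if self.baseline_bpm <= 0:
            raise DataValidationError(
                f"baseline BPM must be positive, got {self.baseline_bpm}"
            )
        if not series:
            raise DataValidationError(
                f"empty exposure series (participant {self.participant_id}, "
                f"message {self.message_id})"
            )
        if any(b <= 0 for b in series):
            raise DataValidationError("all per-second BPM values must be positive")


@dataclass(frozen=True)
class RecognitionTrial:
    """One yes/no judgment on a message fragment (target or foil)."""

    participant_id: str
    fragment_id: str
    is_target: bool
    response_yes: bool
    source_message_id: Optional[str] = None

    def __post_init__(self):
        if self.is_target and not self.source_message_id:
            raise DataValidationError(
                f"target fragment {self.fragment_id} has no source message"
            )
        if not self.is_target and self.source_message_id:
            raise DataValidationError(
                f"foil fragment {self.fragment_id} must not name a source message"
            )


@dataclass(frozen=True)
class AOIRecord:
    """Dwell time (ms) in each of the three AOIs for one participant-message.

    A missing fixation is recorded as 0 ms: absence of fixation is
    informative non-attention, and dropping it would bias means upward.
    """

    participant_id: str
    message_id: str
    dwell_ms: tuple = field(default=())

    def __post_init__(self):
        dwells = tuple(float(d) for d in self.dwell_ms)
        object.__setattr__(self, "dwell_ms", dwells)
        if len(dwells) != N_AOI:
            raise DataValidationError(
                f"expected {N_AOI} AOI dwell values, got {len(dwells)}"
            )
        if any(d < 0 for d in dwells):
            raise DataValidationError("AOI dwell times must be non-negative")


def hr_deceleration_score(trace: HeartRateTrace) -> float:
    """Mean absolute per-second deviation from the pre-message baseline.

    Each second's BPM has the last baseline second subtracted; deviations
    are folded to absolute values before averaging, so acceleration seconds
    also add to the score.  With message content that predominantly slows
    the heart, larger values mean greater deceleration.
    """
    dev = np.asarray(trace.bpm_by_second) - trace.baseline_bpm
    return float(np.abs(dev).mean())


def recognition_accuracy(
    trials: Iterable[RecognitionTrial], message_id: str
) -> float:
    """Hit rate for one message: proportion of "yes" responses to its targets.

    Hit proportions are computed per participant and then averaged, which
    coincides with the pooled proportion when every participant saw the
    same number of targets but stays unbiased if trials were dropped.
    Foils never enter numerator or denominator.
    """
    per_participant: dict[str, list[bool]] = {}
    for t in trials:
        if t.is_target and t.source_message_id == message_id:
            per_participant.setdefault(t.participant_id, []).append(t.response_yes)
    if not per_participant:
        raise DataValidationError(f"no target trials for message {message_id}")
    props = [float(np.mean(v)) for v in per_participant.values()]
    return float(np.mean(props))


def mean_dwell(records: Iterable[AOIRecord], message_id: str) -> float:
    """Mean AOI dwell (ms) for one message: per-record mean of the three
    AOIs, then an unweighted mean across participants."""
    per_record = [
        float(np.mean(r.dwell_ms)) for r in records if r.message_id == message_id
    ]
    if not per_record:
        raise DataValidationError(f"no AOI records for message {message_id}")
    return float(np.mean(per_record))


# ---------------------------------------------------------------------------
# Cohort aggregation and CSV interchange
# ---------------------------------------------------------------------------

def summarize_cohort(
    traces: Iterable[HeartRateTrace],
    trials: Iterable[RecognitionTrial],
    aoi_records: Iterable[AOIRecord],
) -> pd.DataFrame:
    """Per-message lab attribute table: hr_decel, recog_acc, dwell_ms.

    Traces are scored individually and averaged unweighted across
    participants regardless of exposure length.
    """
    traces = list(traces)
    trials = list(trials)
    aoi_records = list(aoi_records)

    hr: dict[str, list[float]] = {}
    for tr in traces:
        hr.setdefault(tr.message_id, []).append(hr_deceleration_score(tr))
    message_ids = sorted(
        set(hr)
        | {t.source_message_id for t in trials if t.is_target}
        | {r.message_id for r in aoi_records}
    )
    if not message_ids:
        raise DataValidationError("no lab records to summarize")
    rows = []
    for mid in message_ids:
        if mid not in hr:
            raise DataValidationError(f"no heart-rate traces for message {mid}")
        rows.append(
            {
                "message_id": mid,
                "hr_deceleration": float(np.mean(hr[mid])),
                "recognition_accuracy": recognition_accuracy(trials, mid),
                "visual_attention": mean_dwell(aoi_records, mid),
            }
        )
    logger.info(
        "summarized lab arm: %d traces, %d trials, %d AOI records, %d messages",
        len(traces), len(trials), len(aoi_records), len(message_ids),
    )
    return pd.DataFrame(rows).set_index("message_id")


def validate_recognition_task(trials: Iterable[RecognitionTrial]) -> None:
    """Warn when a participant's task deviates from 24 targets + 24 foils."""
    counts: dict[str, list[int]] = {}
    for t in trials:
        c = counts.setdefault(t.participant_id, [0, 0])
        c[0 if t.is_target else 1] += 1
    for pid, (n_targ, n_foil) in counts.items():
        if n_targ != N_TARGETS or n_foil != N_FOILS:
            logger.warning(
                "participant %s has %d targets / %d foils (expected %d/%d)",
                pid, n_targ, n_foil, N_TARGETS, N_FOILS,
            )


def read_traces_csv(traces_path, baselines_path) -> list[HeartRateTrace]:
    """Traces CSV: participant_id, message_id, second_index, bpm.
    Baselines CSV: participant_id, message_id, baseline_bpm."""
    df = pd.read_csv(traces_path, dtype={"participant_id": str, "message_id": str})
    base = pd.read_csv(
        baselines_path, dtype={"participant_id": str, "message_id": str}
    )
    baseline = {
        (r.participant_id, r.message_id): float(r.baseline_bpm)
        for r in base.itertuples()
    }
    out = []
    for (pid, mid), grp in df.groupby(["participant_id", "message_id"], sort=False):
        if (pid, mid) not in baseline:
            raise DataValidationError(
                f"no baseline BPM for participant {pid}, message {mid}"
            )
        series = grp.sort_values("second_index")["bpm"].tolist()
        out.append(HeartRateTrace(pid, mid, baseline[(pid, mid)], tuple(series)))
    logger.info("read %d heart-rate traces", len(out))
    return out


def read_recognition_csv(path) -> list[RecognitionTrial]:
    """One row per trial: participant_id, fragment_id, is_target,
    source_message_id (blank for foils), response_yes."""
    df = pd.read_csv(path, dtype={"participant_id": str, "fragment_id": str})
    out = []
    for r in df.itertuples():
        src = getattr(r, "source_message_id", None)
        if pd.isna(src):
            src = None
        out.append(
            RecognitionTrial(
                r.participant_id,
                r.fragment_id,
                bool(r.is_target),
                bool(r.response_yes),
                src,
            )
        )
    logger.info("read %d recognition trials", len(out))
    return out


def read_aoi_csv(path) -> list[AOIRecord]:
    """One row per participant-message: participant_id, message_id,
    dwell_aoi1_ms, dwell_aoi2_ms, dwell_aoi3_ms."""
    df = pd.read_csv(path, dtype={"participant_id": str, "message_id": str})
    cols = ["dwell_aoi1_ms", "dwell_aoi2_ms", "dwell_aoi3_ms"]
    missing = set(cols) - set(df.columns)
    if missing:
        raise DataValidationError(f"AOI CSV missing columns: {sorted(missing)}")
    out = [
        AOIRecord(r.participant_id, r.message_id,
                  tuple(float(getattr(r, c)) for c in cols))
        for r in df.itertuples()
    ]
    logger.info("read %d AOI records", len(out))
    return out


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path)
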