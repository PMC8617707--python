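"""Synthetic participant-level cohorts with planted per-message effects.

Two arms are emulated so the whole pipeline can be exercised end-to-end
without external data:

* a **crowdsourced self-report arm** (between-subjects: each participant
  rates one of the 12 messages, assignment balanced round-robin), with
  item responses generated from a latent participant construct value plus
  item noise, discretized to the Likert scale points; and
* a **lab arm** (within-subjects: each participant views all 12 messages
  in random order) producing per-second heart-rate traces against a
  pre-message baseline, a 48-fragment recognition task (24 targets, two
  per message, plus 24 foils), and three AOI dwell times per message.

Planted truths default to the bundled reference decision matrix, and the
default cohort sizes mirror the two study arms (713 crowdsourced, 120
lab).  The inter-item correlation of each self-report scale is derived
from a target Cronbach's alpha (0.9 by default) via the Spearman-Brown
relation ``rho = alpha / (k - alpha (k - 1))``.

``deterministic=True`` is the noise-free limit: construct scores equal
the planted means exactly (no discretization), traces decelerate by
exactly the planted amount, dwells equal the planted means, and
recognition hits are assigned by quota so each message's hit rate is
``round(p * n_targets) / n_targets``.  This mode exists so that exact
table reproduction through the full pipeline can be verified.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from . import fixtures, psychophys, selfreport
from .errors import DataValidationError
from .madm import DecisionMatrix
from .psychophys import (
    AOIRecord,
    HeartRateTrace,
    RecognitionTrial,
    TARGETS_PER_MESSAGE,
    N_FOILS,
)
from .selfreport import CONSTRUCTS, ItemResponseSet

#: default between-participant sd of the latent construct value, per scale
DEFAULT_PARTICIPANT_SD = {
    "receptivity": 0.9,
    "engagement": 0.9,
    "positive_attitude": 0.9,
    "negative_emotion": 0.6,  # narrower 1-4 scale
}


def default_truth() -> pd.DataFrame:
    """Planted per-message truths: the bundled reference means."""
    return fixtures.load_decision_matrix().means.copy()


@dataclass
class CohortConfig:
    """Generator configuration; identical config + seed gives identical data."""

    n_selfreport: int = 713
    n_lab: int = 120
    seed: int = 0
    #: message x attribute table of planted truths (construct means,
    #: hr_deceleration in BPM, recognition_accuracy as a hit probability,
    #: visual_attention as mean dwell in ms)
    truth: pd.DataFrame = field(default_factory=default_truth)
    alpha_target: float = 0.9
    participant_sd: dict = field(
        default_factory=lambda: dict(DEFAULT_PARTICIPANT_SD)
    )
    discretize: bool = True
    exposure_seconds: int = 15
    baseline_bpm_mean: float = 72.0
    baseline_bpm_sd: float = 8.0
    #: participant-message variation of the deceleration effect (BPM)
    bpm_trace_sd: float = 0.45
    #: per-second BPM measurement noise
    bpm_second_sd: float = 0.3
    dwell_sd_ms: float = 780.0
    dwell_within_sd_ms: float = 150.0
    foil_false_alarm: float = 0.2
    deterministic: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_selfreport < 1 or self.n_lab < 1:
            raise DataValidationError("cohort sizes must be >= 1")
        if self.exposure_seconds < 1:
            raise DataValidationError("exposure_seconds must be >= 1")
        if not (0 <= self.foil_false_alarm <= 1):
            raise DataValidationError("foil_false_alarm must lie in [0, 1]")
        if not (0 < self.alpha_target < 1):
            raise DataValidationError("alpha_target must lie in (0, 1)")
        for sd_name in ("baseline_bpm_sd", "bpm_trace_sd", "bpm_second_sd",
                        "dwell_sd_ms", "dwell_within_sd_ms"):
            if getattr(self, sd_name) < 0:
                raise DataValidationError(f"{sd_name} must be non-negative")
        t = self.truth
        for construct, scale in CONSTRUCTS.items():
            if construct in t.columns:
                col = t[construct]
                if ((col < scale.lo) | (col > scale.hi)).any():
                    raise DataValidationError(
                        f"planted {construct} means outside "
                        f"[{scale.lo}, {scale.hi}]"
                    )
        if "recognition_accuracy" in t.columns:
            p = t["recognition_accuracy"]
            if ((p < 0) | (p > 1)).any():
                raise DataValidationError(
                    "planted recognition probabilities must lie in [0, 1]"
                )
        if "hr_deceleration" in t.columns and (t["hr_deceleration"] < 0).any():
            raise DataValidationError("planted decelerations must be >= 0")
        if "visual_attention" in t.columns and (t["visual_attention"] < 0).any():
            raise DataValidationError("planted dwell means must be >= 0")

    @property
    def message_ids(self) -> list[str]:
        return list(self.truth.index)

    def _streams(self):
        """One root seed; independent child streams per arm."""
        ss_self, ss_lab = np.random.SeedSequence(self.seed).spawn(2)
        return np.random.default_rng(ss_self), np.random.default_rng(ss_lab)

    def inter_item_rho(self, construct: str) -> float:
        """Inter-item correlation implied by the target alpha for this
        construct's item count."""
        k = CONSTRUCTS[construct].n_items
        a = self.alpha_target
        return a / (k - a * (k - 1))


def _discretized_mean(mu: float, sigma: float, lo: int, hi: int) -> float:
    """Population mean of clip(round(N(mu, sigma)), lo, hi)."""
    points = np.arange(lo, hi + 1)
    upper = norm.cdf((points + 0.5 - mu) / sigma)
    upper[-1] = 1.0
    lower = np.concatenate([[0.0], upper[:-1]])
    return float(points @ (upper - lower))


@lru_cache(maxsize=4096)
def _calibrated_latent_mean(target: float, sigma: float, lo: int, hi: int) -> float:
    """Latent mean whose discretized (rounded and clipped) normal has the
    target population mean.

    Rounding to scale points and clipping at the bounds would otherwise
    pull generated means toward the scale centre, so the latent location
    is shifted to compensate; the discretized mean is strictly increasing
    in the latent mean, making the root unique.
    """
    f = lambda mu: _discretized_mean(mu, sigma, lo, hi) - target
    lo_b, hi_b = lo - 8 * sigma, hi + 8 * sigma
    return float(brentq(f, lo_b, hi_b, xtol=1e-10))


def generate_selfreport_arm(config: CohortConfig) -> list[ItemResponseSet]:
    """Between-subjects crowdsourced arm: one message per participant."""
    config.validate()
    rng, _ = config._streams()
    messages = config.message_ids
    out: list[ItemResponseSet] = []
    for i in range(config.n_selfreport):
        mid = messages[i % len(messages)]
        pid = f"S{i + 1:05d}"
        for construct, scale in CONSTRUCTS.items():
            mean = float(config.truth.loc[mid, construct])
            if config.deterministic:
                items = np.full(scale.n_items, mean)
            else:
                sigma_p = float(config.participant_sd.get(construct, 0.9))
                rho = config.inter_item_rho(construct)
                sigma_e = sigma_p * math.sqrt((1 - rho) / rho)
                loc = mean
                if config.discretize and sigma_p > 0:
                    loc = _calibrated_latent_mean(
                        mean,
                        math.hypot(sigma_p, sigma_e),
                        int(scale.lo),
                        int(scale.hi),
                    )
                latent = loc + rng.normal(0.0, sigma_p)
                items = latent + rng.normal(0.0, sigma_e, scale.n_items)
                if config.discretize:
                    items = np.round(items)
                items = np.clip(items, scale.lo, scale.hi)
            out.append(ItemResponseSet(pid, mid, construct, tuple(items)))
    return out


def generate_lab_arm(
    config: CohortConfig,
) -> tuple[list[HeartRateTrace], list[RecognitionTrial], list[AOIRecord]]:
    """Within-subjects lab arm: every participant views all messages."""
    config.validate()
    _, rng = config._streams()
    messages = config.message_ids
    n = config.n_lab
    T = config.exposure_seconds

    traces: list[HeartRateTrace] = []
    aoi: list[AOIRecord] = []
    trials: list[RecognitionTrial] = []

    # deterministic recognition: per-message hit quota over the cohort's
    # target trials, assigned to the earliest participants
    quota = {}
    if config.deterministic:
        total = TARGETS_PER_MESSAGE * n
        for mid in messages:
            p = float(config.truth.loc[mid, "recognition_accuracy"])
            quota[mid] = int(round(p * total))

    for j in range(n):
        pid = f"L{j + 1:04d}"
        if config.deterministic:
            baseline = config.baseline_bpm_mean
            order = list(messages)
        else:
            baseline = max(40.0, rng.normal(config.baseline_bpm_mean,
                                            config.baseline_bpm_sd))
            order = [messages[k] for k in rng.permutation(len(messages))]
        for mid in order:
            delta = float(config.truth.loc[mid, "hr_deceleration"])
            dwell_mean = float(config.truth.loc[mid, "visual_attention"])
            if config.deterministic:
                series = np.full(T, baseline - delta)
                dwells = np.full(psychophys.N_AOI, dwell_mean)
            else:
                delta_pm = delta + rng.normal(0.0, config.bpm_trace_sd)
                series = baseline - delta_pm + rng.normal(
                    0.0, config.bpm_second_sd, T
                )
                series = np.maximum(series, 30.0)  # keep traces physiological
                dwell_pm = max(0.0, rng.normal(dwell_mean, config.dwell_sd_ms))
                dwells = np.clip(
                    rng.normal(dwell_pm, config.dwell_within_sd_ms,
                               psychophys.N_AOI),
                    0.0, None,
                )
            traces.append(HeartRateTrace(pid, mid, baseline, tuple(series)))
            aoi.append(AOIRecord(pid, mid, tuple(dwells)))

        # recognition task: 2 targets per message + 24 foils
        for mid in messages:
            p = float(config.truth.loc[mid, "recognition_accuracy"])
            for t in range(TARGETS_PER_MESSAGE):
                if config.deterministic:
                    slot = j * TARGETS_PER_MESSAGE + t
                    yes = slot < quota[mid]
                else:
                    yes = bool(rng.random() < p)
                trials.append(
                    RecognitionTrial(pid, f"{mid}_t{t + 1}", True, yes, mid)
                )
        for f in range(N_FOILS):
            if config.deterministic:
                yes = False
            else:
                yes = bool(rng.random() < config.foil_false_alarm)
            trials.append(RecognitionTrial(pid, f"foil{f + 1:02d}", False, yes))

    return traces, trials, aoi


def cohort_decision_matrix(
    responses, traces, trials, aoi_records,
    attributes=None,
) -> DecisionMatrix:
    """Run both summarization stages and assemble the decision matrix."""
    sr = selfreport.attribute_table(selfreport.summarize_cohort(responses))
    lab = psychophys.summarize_cohort(traces, trials, aoi_records)
    means = sr.join(lab, how="inner")
    if attributes is None:
        attributes = fixtures.load_attribute_defs()
    return DecisionMatrix(means, attributes)


# ---------------------------------------------------------------------------
# CSV emission (the `simulate` CLI verb)
# ---------------------------------------------------------------------------

def write_selfreport_csv(responses, path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "message_id": r.message_id,
            "construct": r.construct,
            "item_index": i + 1,
            "score": s,
        }
        for r in responses
        for i, s in enumerate(r.item_scores)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_lab_csvs(traces, trials, aoi_records, traces_path, baselines_path,
                   recognition_path, aoi_path) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "message_id": t.message_id,
                "second_index": i + 1,
                "bpm": b,
            }
            for t in traces
            for i, b in enumerate(t.bpm_by_second)
        ]
    ).to_csv(traces_path, index=False)
    pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "message_id": t.message_id,
                "baseline_bpm": t.baseline_bpm,
            }
            for t in traces
        ]
    ).to_csv(baselines_path, index=False)
    pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "fragment_id": t.fragment_id,
                "is_target": t.is_target,
                "source_message_id": t.source_message_id or "",
                "response_yes": t.response_yes,
            }
            for t in trials
        ]
    ).to_csv(recognition_path, index=False)
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "message_id": r.message_id,
                "dwell_aoi1_ms": r.dwell_ms[0],
                "dwell_aoi2_ms": r.dwell_ms[1],
                "dwell_aoi3_ms": r.dwell_ms[2],
            }
            for r in aoi_records
        ]
    ).to_csv(aoi_path, index=False)


def write_truth_manifest(config: CohortConfig, path) -> None:
    """Planted truths plus scalar settings, for recovery testing."""
    manifest = config.truth.copy()
    manifest.to_csv(path, index_label="message_id")


def config_from_dict(d: dict) -> CohortConfig:
    """Build a config from a plain mapping (e.g. parsed YAML).  The truth
    table may be given inline as {message_id: {attribute: value}}."""
    d = dict(d)
    truth = d.pop("truth", None)
    kwargs = {}
    names = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(d) - names
    if unknown:
        raise DataValidationError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(d)
    if truth is not None:
        kwargs["truth"] = pd.DataFrame.from_dict(truth, orient="index")
    return CohortConfig(**kwargs)
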