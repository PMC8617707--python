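"""Multi-attribute decision-making engine for message selection.

Rows of the decision matrix are candidate messages, columns are measured
attributes (mean scores from either study arm).  Within each attribute the
messages are ranked with *competition* ("minimum") ranking: the highest
mean gets rank 1, tied values share the minimum rank, and the next
distinct value skips by the size of the tie group (1, 2, 2, 4, ...).
Attribute ranks are summed within each study arm to give per-study rank
totals, and weighted means of rank components produce summary scores and
an overall ranking under configurable weighting scenarios.

The engine deliberately performs no statistical inference: it aggregates
observed mean scores into rankings and leaves hypothesis testing to other
tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DataValidationError

SELF_REPORT = "self_report"
LAB = "lab"
STUDIES = (SELF_REPORT, LAB)


@dataclass(frozen=True)
class MessageSpec:
    """A candidate message in the 2 (risk content) x 3 (theme) design."""

    message_id: str
    risk_content: str  # "harms" | "addiction"
    theme: str  # "alone" | "flavors" | "social"
    text: str = ""
    hashtag: str = ""

    def __post_init__(self):
        if self.risk_content not in ("harms", "addiction"):
            raise DataValidationError(
                f"risk_content must be harms|addiction, got {self.risk_content!r}"
            )
        if self.theme not in ("alone", "flavors", "social"):
            raise DataValidationError(
                f"theme must be alone|flavors|social, got {self.theme!r}"
            )


@dataclass(frozen=True)
class AttributeDef:
    """One decision-matrix column: its study arm and scoring direction."""

    name: str
    study: str
    higher_is_better: bool = True

    def __post_init__(self):
        if self.study not in STUDIES:
            raise DataValidationError(
                f"study must be one of {STUDIES}, got {self.study!r}"
            )


class DecisionMatrix:
    """Complete message x attribute table of mean scores."""

    def __init__(
        self,
        means: pd.DataFrame,
        attributes: Sequence[AttributeDef],
        messages: Optional[Sequence[MessageSpec]] = None,
    ):
        means = means.copy()
        means.index = means.index.astype(str)
        if means.index.duplicated().any():
            dupes = means.index[means.index.duplicated()].tolist()
            raise DataValidationError(f"duplicate message ids: {dupes}")
        attr_names = [a.name for a in attributes]
        missing_cols = set(attr_names) - set(means.columns)
        if missing_cols:
            raise DataValidationError(
                f"decision matrix missing attribute columns: {sorted(missing_cols)}"
            )
        means = means[attr_names].astype(float)
        if means.isna().any().any():
            cells = [
                f"{m}/{a}"
                for m in means.index
                for a in means.columns
                if pd.isna(means.loc[m, a])
            ]
            raise DataValidationError(f"missing decision-matrix cells: {cells}")
        self.means = means
        self.attributes = tuple(attributes)
        self.messages = tuple(messages) if messages is not None else None

    @property
    def message_ids(self) -> list[str]:
        return list(self.means.index)

    def attribute(self, name: str) -> AttributeDef:
        for a in self.attributes:
            if a.name == name:
                return a
        raise DataValidationError(f"unknown attribute {name!r}")

    def study_attributes(self, study: str) -> list[AttributeDef]:
        if study not in STUDIES:
            raise DataValidationError(f"unknown study label {study!r}")
        return [a for a in self.attributes if a.study == study]


@dataclass(frozen=True)
class RankMatrix:
    """Integer competition ranks per attribute, with per-cell tie flags."""

    ranks: pd.DataFrame
    ties: pd.DataFrame


def rank_values(
    values: pd.Series, higher_is_better: bool = True
) -> tuple[pd.Series, pd.Series]:
    """Competition-rank a vector of scores.

    With ``higher_is_better`` the largest value gets rank 1; tied values
    share the minimum rank and the following distinct value's rank skips
    by the tie-group size.  Returns (integer ranks, tie flags).
    """
    vals = pd.Series(values, dtype=float)
    if vals.isna().any():
        bad = vals.index[vals.isna()].tolist()
        raise DataValidationError(
            f"missing value for {bad} in {vals.name or 'attribute'}"
        )
    keyed = -vals if higher_is_better else vals
    ranks = pd.Series(
        rankdata(keyed, method="min").astype(int), index=vals.index, name=vals.name
    )
    ties = vals.duplicated(keep=False)
    ties.name = vals.name
    return ranks, ties


def rank_attribute(dm: DecisionMatrix, name: str) -> tuple[pd.Series, pd.Series]:
    """Competition ranks for one decision-matrix attribute."""
    attr = dm.attribute(name)
    return rank_values(dm.means[name], attr.higher_is_better)


def compute_ranks(dm: DecisionMatrix) -> RankMatrix:
    """Rank every attribute column of the decision matrix."""
    ranks, ties = {}, {}
    for a in dm.attributes:
        r, t = rank_values(dm.means[a.name], a.higher_is_better)
        ranks[a.name], ties[a.name] = r, t
    return RankMatrix(pd.DataFrame(ranks), pd.DataFrame(ties))


def study_totals(dm: DecisionMatrix, rm: RankMatrix, study: str) -> pd.DataFrame:
    """Per-message sum of one study's attribute ranks, plus the competition
    rank of those totals (smaller total = better message)."""
    attrs = dm.study_attributes(study)
    if not attrs:
        raise DataValidationError(f"no attributes for study {study!r}")
    total = rm.ranks[[a.name for a in attrs]].sum(axis=1)
    total.name = f"{study}_total"
    total_rank, tie = rank_values(total, higher_is_better=False)
    return pd.DataFrame(
        {"total": total.astype(int), "total_rank": total_rank, "tie": tie}
    )


@dataclass(frozen=True)
class Component:
    """One ingredient of a weighting scenario: an attribute's rank column
    or a study's total-rank column, with a non-negative weight."""

    kind: str  # "attribute" | "study_total"
    key: str
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in ("attribute", "study_total"):
            raise DataValidationError(f"unknown component kind {self.kind!r}")
        if self.weight < 0:
            raise DataValidationError(f"negative weight {self.weight}")


@dataclass(frozen=True)
class WeightingScenario:
    name: str
    components: tuple = field(default=())
    #: decimals used when rendering summary scores (ranking is unrounded)
    display_decimals: int = 1

    def __post_init__(self):
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise DataValidationError(f"scenario {self.name!r} has no components")
        if sum(c.weight for c in comps) <= 0:
            raise DataValidationError(
                f"scenario {self.name!r} weights must sum to a positive value"
            )


def preset_scenarios(dm: DecisionMatrix) -> list[WeightingScenario]:
    """The four canonical weighting scenarios.

    1. ``equal_attributes`` — unweighted mean of all attribute ranks.
    2. ``equal_studies`` — mean of the two per-study total ranks.
    3. ``prefer_self_report`` — the self-report attribute ranks plus the
       lab total rank, equally weighted.
    4. ``prefer_lab`` — the self-report total rank plus the lab attribute
       ranks, equally weighted.
    """
    sr = [a.name for a in dm.study_attributes(SELF_REPORT)]
    lab = [a.name for a in dm.study_attributes(LAB)]
    attr = lambda n: Component("attribute", n)
    tot = lambda s: Component("study_total", s)
    return [
        WeightingScenario(
            "equal_attributes", tuple(attr(n) for n in sr + lab)
        ),
        WeightingScenario("equal_studies", (tot(SELF_REPORT), tot(LAB))),
        WeightingScenario(
            "prefer_self_report", tuple(attr(n) for n in sr) + (tot(LAB),)
        ),
        WeightingScenario(
            "prefer_lab",
            (tot(SELF_REPORT),) + tuple(attr(n) for n in lab),
            display_decimals=2,
        ),
    ]


def scenario_score(
    rm: RankMatrix,
    total_ranks: Mapping[str, pd.Series],
    scenario: WeightingScenario,
) -> pd.DataFrame:
    """Evaluate one weighting scenario.

    Returns a frame indexed by message with columns ``summary_score`` (the
    weighted mean of the component rank values), ``rank`` (competition
    rank of the scores, smaller score = better) and ``tie``.  Ranking uses
    the unrounded scores.
    """
    values = []
    weights = []
    for c in scenario.components:
        if c.kind == "attribute":
            if c.key not in rm.ranks.columns:
                raise DataValidationError(
                    f"scenario {scenario.name!r} references unknown attribute "
                    f"{c.key!r}"
                )
            values.append(rm.ranks[c.key].astype(float))
        else:
            if c.key not in total_ranks:
                raise DataValidationError(
                    f"scenario {scenario.name!r} references unknown study "
                    f"total {c.key!r}"
                )
            values.append(pd.Series(total_ranks[c.key], dtype=float))
        weights.append(c.weight)
    mat = pd.concat(values, axis=1)
    if mat.isna().any().any():
        raise DataValidationError(
            f"scenario {scenario.name!r}: components cover different message sets"
        )
    w = np.asarray(weights, dtype=float)
    score = pd.Series(mat.to_numpy() @ w / w.sum(), index=mat.index,
                      name="summary_score")
    rank, tie = rank_values(score, higher_is_better=False)
    return pd.DataFrame({"summary_score": score, "rank": rank, "tie": tie})


def evaluate_scenarios(
    dm: DecisionMatrix,
    scenarios: Optional[Sequence[WeightingScenario]] = None,
    total_rank_override: Optional[Mapping[str, pd.Series]] = None,
) -> dict[str, pd.DataFrame]:
    """Rank the matrix, form study totals, and evaluate each scenario.

    ``total_rank_override`` replaces the computed total-rank column for the
    named studies (reproduction mode for matching a published table whose
    total-rank column differs from the rank of the printed rank sums).
    """
    rm = compute_ranks(dm)
    totals = {s: study_totals(dm, rm, s)["total_rank"] for s in STUDIES
              if dm.study_attributes(s)}
    if total_rank_override:
        for study, col in total_rank_override.items():
            totals[study] = pd.Series(col, dtype=int).reindex(dm.means.index)
    if scenarios is None:
        scenarios = preset_scenarios(dm)
    return {s.name: scenario_score(rm, totals, s) for s in scenarios}


def consensus_top_half(results: Iterable[pd.DataFrame]) -> list[str]:
    """Messages ranked in the top half (rank <= floor(n/2)) of every
    supplied scenario result, sorted by message id."""
    results = list(results)
    if not results:
        raise DataValidationError("no scenario results supplied")
    base = set(results[0].index)
    for r in results[1:]:
        if set(r.index) != base:
            raise DataValidationError("scenario results cover different message sets")
    cutoff = len(base) // 2
    keep = base
    for r in results:
        keep &= set(r.index[r["rank"] <= cutoff])
    return sorted(keep)


def weight_sweep(
    rm: RankMatrix, n_samples: int, seed: int
) -> pd.Series:
    """Win frequency of each message over random attribute weightings.

    Weight vectors are sampled uniformly on the simplex over the attribute
    rank columns; a message wins a sample when its weighted mean rank is
    minimal (all members of a tie win).  Deterministic given ``seed``.
    """
    if n_samples < 1:
        raise DataValidationError(f"n_samples must be >= 1, got {n_samples}")
    rng = np.random.default_rng(seed)
    r = rm.ranks.to_numpy(dtype=float)  # messages x attributes
    w = rng.dirichlet(np.ones(r.shape[1]), size=n_samples)  # samples x attrs
    scores = w @ r.T  # samples x messages
    wins = scores <= scores.min(axis=1, keepdims=True) + 1e-12
    return pd.Series(wins.mean(axis=0), index=rm.ranks.index, name="win_frequency")
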