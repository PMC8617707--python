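"""Tabular rendering and CSV interchange for decision matrices and rankings.

Two presentation formats are produced:

* a decision-matrix table (per-attribute mean + rank, per-study rank sum
  and total rank), and
* a weighting-scenario table (summary score + rank per scenario, with
  ``*`` marking tied ranks and a footnote line).
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import DataValidationError
from .madm import (
    DecisionMatrix,
    RankMatrix,
    STUDIES,
    WeightingScenario,
    compute_ranks,
    study_totals,
)


def write_decision_matrix(dm: DecisionMatrix, means_path, attributes_path=None):
    dm.means.to_csv(means_path, index_label="message_id")
    if attributes_path is not None:
        pd.DataFrame(
            {
                "name": [a.name for a in dm.attributes],
                "study": [a.study for a in dm.attributes],
                "direction": [
                    "higher" if a.higher_is_better else "lower"
                    for a in dm.attributes
                ],
            }
        ).to_csv(attributes_path, index=False)


def render_rank_table(
    dm: DecisionMatrix,
    rm: Optional[RankMatrix] = None,
    total_rank_override: Optional[Mapping[str, pd.Series]] = None,
) -> pd.DataFrame:
    """Decision-matrix presentation: mean and rank per attribute, then rank
    sum and total rank per study arm.

    ``total_rank_override`` substitutes a published total-rank column for
    the computed rank-of-sums (reproduction mode).
    """
    if rm is None:
        rm = compute_ranks(dm)
    out = pd.DataFrame(index=dm.means.index)
    for study in STUDIES:
        attrs = dm.study_attributes(study)
        if not attrs:
            continue
        for a in attrs:
            out[f"{a.name}_mean"] = dm.means[a.name]
            out[f"{a.name}_rank"] = rm.ranks[a.name]
        tot = study_totals(dm, rm, study)
        out[f"{study}_total"] = tot["total"]
        if total_rank_override and study in total_rank_override:
            out[f"{study}_total_rank"] = pd.Series(
                total_rank_override[study], dtype=int
            ).reindex(dm.means.index)
        else:
            out[f"{study}_total_rank"] = tot["total_rank"]
    out.index.name = "message_id"
    return out


def render_scenario_table(
    results: Mapping[str, pd.DataFrame],
    scenarios: Optional[Sequence[WeightingScenario]] = None,
) -> pd.DataFrame:
    """Scenario presentation: per message, one summary-score column and one
    rank column per scenario; tied ranks carry a trailing ``*``.

    Summary scores are rendered at each scenario's display precision;
    the ranks were computed from the unrounded scores.
    """
    results = dict(results)
    if not results:
        raise DataValidationError("no scenario results to render")
    decimals = {s.name: s.display_decimals for s in scenarios or []}
    frames = list(results.values())
    base = frames[0].index
    for f in frames[1:]:
        if set(f.index) != set(base):
            raise DataValidationError(
                "scenario results cover different message sets"
            )
    out = pd.DataFrame(index=base)
    for name, res in results.items():
        res = res.reindex(base)
        nd = decimals.get(name, 1)
        out[f"{name}_score"] = res["summary_score"].map(lambda v: f"{v:.{nd}f}")
        out[f"{name}_rank"] = [
            f"{r} *" if t else f"{r}"
            for r, t in zip(res["rank"], res["tie"])
        ]
    out.index.name = "message_id"
    return out


SCENARIO_FOOTNOTE = "* denotes tied ranking."


def scenario_table_text(table: pd.DataFrame) -> str:
    """Plain-text rendering of a scenario table with the tie footnote."""
    return table.to_string() + "\n\n" + SCENARIO_FOOTNOTE + "\n"
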