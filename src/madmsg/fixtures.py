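"""Bundled reference data: the 12-message decision matrix of printed means.

The package ships the published message-testing decision matrix — twelve
waterpipe tobacco smoking (WTS) risk messages crossed with seven
attributes (four self-report, three psychophysiological) — together with
the two published per-study total-rank columns.

Note on the published lab total-rank column: it is *not* the competition
rank of the lab attribute-rank sums (the message with the smallest lab
rank sum is not printed as lab rank 1); it instead coincides with the
visual-attention ranks.  The engine's default recomputes total ranks from
the sums; :func:`published_total_ranks` exposes the printed column so the
published scenario table can be matched bit-for-bit (reproduction mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import DataValidationError
from .madm import (
    AttributeDef,
    DecisionMatrix,
    MessageSpec,
    SELF_REPORT,
    compute_ranks,
    rank_values,
    study_totals,
)

FIXTURE_NAME = "table1"


def _data(name: str):
    return resources.files("madmsg.data").joinpath(name)


def load_messages() -> list[MessageSpec]:
    """The 12 messages of the 2 (harms/addiction) x 3 (alone/flavors/social)
    design.  Texts are included where publicly quoted; all share the
    campaign hashtag."""
    with resources.as_file(_data("messages.csv")) as p:
        df = pd.read_csv(p, keep_default_na=False)
    return [
        MessageSpec(r.message_id, r.risk_content, r.theme, r.text, r.hashtag)
        for r in df.itertuples()
    ]


def load_attribute_defs(path=None) -> list[AttributeDef]:
    """Attribute sidecar: name, study (self_report|lab), direction
    (higher|lower)."""
    if path is None:
        with resources.as_file(_data("attributes.csv")) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"name", "study", "direction"}
    if not required <= set(df.columns):
        raise DataValidationError(
            f"attribute sidecar needs columns {sorted(required)}"
        )
    return [
        AttributeDef(r.name, r.study, r.direction == "higher")
        for r in df.itertuples()
    ]


def published_total_ranks() -> pd.DataFrame:
    """The printed per-study total-rank columns (message x {self_report, lab})."""
    with resources.as_file(_data("published_total_ranks.csv")) as p:
        return pd.read_csv(p, index_col="message_id")


@dataclass(frozen=True)
class PaperFixture:
    """Bundle of the published decision matrix and its rank columns."""

    matrix: DecisionMatrix
    published_self_report_total_rank: pd.Series
    published_lab_total_rank: pd.Series


def load_decision_matrix(source=FIXTURE_NAME, attributes_path=None) -> DecisionMatrix:
    """Load a decision matrix from a CSV path or the bundled fixture.

    ``source="table1"`` loads the bundled published means.  Otherwise
    ``source`` is a CSV (row = message_id, columns = attribute names) read
    together with an attribute sidecar file.
    """
    if source == FIXTURE_NAME:
        with resources.as_file(_data("table1_means.csv")) as p:
            means = pd.read_csv(p, index_col="message_id")
        return DecisionMatrix(means, load_attribute_defs(), load_messages())
    means = pd.read_csv(source, index_col="message_id")
    return DecisionMatrix(means, load_attribute_defs(attributes_path))


def paper_fixture() -> PaperFixture:
    """Load the bundled matrix plus published total ranks, after a
    self-consistency check: ranks recomputed from the bundled self-report
    means, summed and re-ranked, must reproduce the published self-report
    total-rank column."""
    dm = load_decision_matrix(FIXTURE_NAME)
    pub = published_total_ranks().reindex(dm.means.index)
    rm = compute_ranks(dm)
    sr = study_totals(dm, rm, SELF_REPORT)
    if not sr["total_rank"].equals(pub[SELF_REPORT].astype(int)):
        raise DataValidationError(
            "fixture self-consistency failure: recomputed self-report total "
            "ranks do not match the bundled published column"
        )
    return PaperFixture(dm, pub[SELF_REPORT].astype(int), pub["lab"].astype(int))
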