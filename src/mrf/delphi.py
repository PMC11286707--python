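"""Delphi consensus statistics and decision rules for tool validation.

Panellists rate each proposed criterion (a medication class with an assigned
falls-risk tier and mechanism statement) on a 5-point Likert scale
(Strongly agree = 5 ... Strongly disagree = 1). Per item the engine computes the
percentage agreeing (responses >= 4), the median, the 25th/75th percentiles and
the IQR, then applies the consensus rules:

* retain  — median >= 4 and P25 >= 4 (equivalently, roughly three-quarters of
  respondents agree or strongly agree);
* exclude — median <= 3, in any round;
* modify  — median >= 4 but P25 < 4: the statement is revised per panellists'
  comments and re-rated in the next round. In the final round no further
  revision is possible, so every non-retained item is excluded.

A median strictly between 3 and 4 (possible with an even respondent count) is
outside the three stated clauses; it is treated conservatively as modify in
non-final rounds and exclude in the final round, and the rule trace records
when this edge fires.

Quantiles use weighted-average interpolation at position (n+1)p by default
(the convention of the statistics package the survey data were analysed with);
the method is configurable because no published convention is attached to the
rules themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QUANTILE_METHODS",
    "LikertMatrix",
    "ItemStats",
    "ItemDecision",
    "RoundResult",
    "item_stats",
    "decide",
    "run_round",
    "panel_summary",
    "round_half_away_from_zero",
]

#: Friendly name -> numpy quantile method. "weighted-average" is the default:
#: position (n+1)p with linear interpolation between order statistics.
QUANTILE_METHODS: dict[str, str] = {
    "weighted-average": "weibull",
    "linear": "linear",
    "hazen": "hazen",
    "nearest": "closest_observation",
}

Verdict = Literal["retain", "modify", "exclude"]


def round_half_away_from_zero(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (the convention of the reported
    percentages), unlike Python's banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# --- response matrix ----------------------------------------------------------


class LikertMatrix:
    """Items x panellists table of 1-5 Likert responses with missing allowed.

    Wraps a pandas DataFrame (rows = item ids, columns = panellist ids, values
    in {1,...,5} or NaN for missing).
    """

    def __init__(self, responses: pd.DataFrame):
        values = responses.to_numpy(dtype=float)
        present = values[~np.isnan(values)]
        if present.size and not np.isin(present, [1, 2, 3, 4, 5]).all():
            bad = sorted(set(present[~np.isin(present, [1, 2, 3, 4, 5])]))
            raise ValueError(f"Likert responses must be integers 1..5; found {bad}")
        self.responses = responses.astype(float)

    @property
    def items(self) -> list:
        return list(self.responses.index)

    @property
    def panellists(self) -> list:
        return list(self.responses.columns)

    def item_responses(self, item_id) -> np.ndarray:
        """Non-missing responses for one item."""
        row = self.responses.loc[item_id].to_numpy(dtype=float)
        return row[~np.isnan(row)]

    @classmethod
    def from_csv(cls, path: str | Path) -> "LikertMatrix":
        """Read responses from CSV.

        Wide format: first column ``item_id``, one column per panellist, blank
        cells for missing. Long format: columns ``item_id``, ``panellist_id``,
        ``response``.
        """
        df = pd.read_csv(path)
        cols = [c.strip() for c in df.columns]
        df.columns = cols
        if {"item_id", "panellist_id", "response"}.issubset(cols):
            wide = df.pivot(index="item_id", columns="panellist_id", values="response")
            return cls(wide)
        if cols and cols[0] == "item_id":
            return cls(df.set_index("item_id"))
        raise ValueError(
            "responses CSV must be wide (first column 'item_id') or long "
            "(columns item_id, panellist_id, response)"
        )

    def to_csv(self, path: str | Path) -> None:
        self.responses.to_csv(path, index_label="item_id")


# --- per-item statistics ------------------------------------------------------


@dataclass(frozen=True)
class ItemStats:
    """Consensus statistics for one item over its non-missing responses."""

    n_responses: int
    agreement_pct: float  # % of non-missing responses >= 4, unrounded
    median: float
    p25: float
    p75: float

    @property
    def iqr(self) -> float:
        return self.p75 - self.p25

    def to_dict(self) -> dict:
        return {
            "n_responses": self.n_responses,
            "agreement_pct": round_half_away_from_zero(self.agreement_pct),
            "median": self.median,
            "p25": self.p25,
            "p75": self.p75,
            "iqr": self.iqr,
        }


def item_stats(
    responses: Iterable[float],
    quantile_method: str = "weighted-average",
    item_id=None,
) -> ItemStats:
    """Agreement %, median and quartiles for one item's responses.

    Missing values (NaN/None) are excluded from both the numerator and the
    denominator of the agreement percentage and from the quantiles — the
    statistics describe respondents, not the full panel roster. Values are
    never rounded here; rounding happens only at presentation.
    """
    arr = np.asarray(
        [np.nan if r is None else float(r) for r in responses], dtype=float
    )
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        name = f" for item {item_id!r}" if item_id is not None else ""
        raise ValueError(f"no non-missing responses{name}")
    if not np.isin(arr, [1, 2, 3, 4, 5]).all():
        raise ValueError("Likert responses must be integers 1..5")
    try:
        method = QUANTILE_METHODS[quantile_method]
    except KeyError:
        raise ValueError(
            f"unknown quantile method {quantile_method!r}; "
            f"expected one of {sorted(QUANTILE_METHODS)}"
        ) from None
    p25, p75 = np.percentile(arr, [25, 75], method=method)
    return ItemStats(
        n_responses=int(arr.size),
        agreement_pct=100.0 * float(np.count_nonzero(arr >= 4)) / arr.size,
        median=float(np.median(arr)),
        p25=float(p25),
        p75=float(p75),
    )


# --- decision rule ------------------------------------------------------------


@dataclass(frozen=True)
class ItemDecision:
    """Verdict for one item plus the statistics and the clause that fired."""

    stats: ItemStats
    verdict: Verdict
    final_round: bool
    rule_trace: str
    item_id: object = None

    def to_dict(self) -> dict:
        return {
            "item_id": self.item_id,
            "verdict": self.verdict,
            "final_round": self.final_round,
            "rule_trace": self.rule_trace,
            **self.stats.to_dict(),
        }


def decide(stats: ItemStats, final_round: bool, item_id=None) -> ItemDecision:
    """Apply the consensus decision rule to one item's statistics.

    Retention requires median >= 4 with P25 >= 4; a median <= 3 excludes the
    item in any round; a median >= 4 with P25 < 4 is modified and re-rated,
    except in the final round where every non-retained item is excluded.
    """
    m, p25 = stats.median, stats.p25
    if m >= 4 and p25 >= 4:
        verdict: Verdict = "retain"
        trace = f"retain: median {m:g} >= 4 and P25 {p25:g} >= 4"
        if m not in (4.0, 5.0):
            trace += " (non-integer median from even respondent count)"
    elif m <= 3:
        verdict = "exclude"
        trace = f"exclude: median {m:g} <= 3"
    elif m >= 4:  # median ok, consensus (P25) not reached
        if final_round:
            verdict = "exclude"
            trace = (
                f"exclude: final round and P25 {p25:g} < 4 "
                f"(median {m:g} alone is insufficient)"
            )
        else:
            verdict = "modify"
            trace = f"modify: median {m:g} >= 4 but P25 {p25:g} < 4"
    else:  # 3 < median < 4: outside the stated clauses; conservative handling
        if final_round:
            verdict = "exclude"
            trace = (
                f"exclude: final round, median {m:g} strictly between 3 and 4 "
                "(edge case outside the stated clauses)"
            )
        else:
            verdict = "modify"
            trace = (
                f"modify: median {m:g} strictly between 3 and 4 "
                "(edge case outside the stated clauses)"
            )
    return ItemDecision(
        stats=stats, verdict=verdict, final_round=final_round,
        rule_trace=trace, item_id=item_id,
    )


# --- round orchestration ------------------------------------------------------


@dataclass
class RoundResult:
    """Outcome of one Delphi round: decisions, carry-forward set, feedback."""

    round_number: int
    decisions: list[ItemDecision]
    retained: list
    excluded: list
    carried_forward: list  # modify verdicts plus newly suggested items
    group_feedback: pd.DataFrame  # one row of stats + verdict per decided item
    individual_feedback: dict  # panellist -> DataFrame (own response vs group)

    def summary(self) -> dict:
        return {
            "round": self.round_number,
            "n_items": len(self.decisions),
            "retained": len(self.retained),
            "excluded": len(self.excluded),
            "carried_forward": len(self.carried_forward),
        }


def run_round(
    matrix: LikertMatrix,
    round_number: int,
    max_rounds: int = 3,
    new_items: Sequence = (),
    closed_items: Iterable = (),
    quantile_method: str = "weighted-average",
) -> RoundResult:
    """Decide every item rated in one Delphi round and build feedback.

    ``new_items`` are criteria suggested in free-text comments of the previous
    round (sorted into survey items by the research team — a manual input, not
    a computation); they join the carried-forward set for the next round.
    ``closed_items`` are ids already retained or excluded in earlier rounds;
    their reappearance in the matrix is an error. In the final round
    (``round_number == max_rounds``) the modify verdict is unavailable.
    """
    if round_number < 1:
        raise ValueError("round_number must be >= 1")
    if round_number > max_rounds:
        raise ValueError(f"round_number {round_number} exceeds max_rounds {max_rounds}")
    closed = set(closed_items)
    reopened = [i for i in matrix.items if i in closed]
    if reopened:
        raise ValueError(
            f"items already decided in a prior round reappear in round "
            f"{round_number}: {reopened}"
        )
    final = round_number == max_rounds
    decisions = [
        decide(
            item_stats(
                matrix.item_responses(item), quantile_method, item_id=item
            ),
            final_round=final,
            item_id=item,
        )
        for item in matrix.items
    ]
    retained = [d.item_id for d in decisions if d.verdict == "retain"]
    excluded = [d.item_id for d in decisions if d.verdict == "exclude"]
    modified = [d.item_id for d in decisions if d.verdict == "modify"]
    carried = modified + [i for i in new_items if i not in modified]

    group = pd.DataFrame([d.to_dict() for d in decisions]).set_index("item_id")
    individual: dict = {}
    medians = group["median"]
    for p in matrix.panellists:
        own = matrix.responses[p]
        individual[p] = pd.DataFrame(
            {"own_response": own, "group_median": medians,
             "group_agreement_pct": group["agreement_pct"]}
        )
    return RoundResult(
        round_number=round_number,
        decisions=decisions,
        retained=retained,
        excluded=excluded,
        carried_forward=carried,
        group_feedback=group,
        individual_feedback=individual,
    )


# --- panel demographics -------------------------------------------------------


def panel_summary(
    demographics: Mapping[str, int], total: int | None = None
) -> pd.DataFrame:
    """Counts -> (count, percentage) table for panel characteristics.

    Percentages are 100*count/total rounded to one decimal, half away from
    zero. ``total`` defaults to the sum of the counts; pass it explicitly when
    summarizing a single category against the whole panel.
    """
    counts = dict(demographics)
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be >= 0")
    denom = sum(counts.values()) if total is None else total
    if denom <= 0:
        raise ValueError("total must be > 0")
    rows = [
        {"category": k, "count": v,
         "percentage": round_half_away_from_zero(100.0 * v / denom)}
        for k, v in counts.items()
    ]
    return pd.DataFrame(rows).set_index("category")
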