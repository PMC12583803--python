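"""Pairwise cost-effectiveness arithmetic: ICERs versus a reference
strategy, net monetary benefit (NMB) and NMB-based ranking.

Comparisons are made against no treatment rather than along a full
incremental frontier; the strategy with the highest NMB at a given
willingness-to-pay threshold is the most cost-effective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = ["ICEResult", "compute_icer", "compute_nmb", "rank_by_nmb"]


@dataclass(frozen=True)
class ICEResult:
    """Incremental comparison of one strategy against a reference."""

    delta_cost: float
    delta_qalys: float
    icer: float | None          # unrounded GBP per QALY, when defined
    flag: str                   # "icer", "dominant", "dominated",
                                # "less_effective_cheaper" or "zero_increment"
    comparator: str = "no treatment"

    @property
    def icer_rounded(self) -> int | None:
        return None if self.icer is None else round(self.icer)


def compute_icer(cost_i: float, qalys_i: float, cost_ref: float,
                 qalys_ref: float, comparator: str = "no treatment",
                 ) -> ICEResult:
    """ICER = (cost_i - cost_ref) / (qalys_i - qalys_ref).

    Degenerate increments become flags instead of a ratio: a strategy with
    more QALYs at lower cost is *dominant*; fewer (or equal) QALYs at equal
    or higher cost is *dominated*; fewer QALYs at lower cost sits in the
    south-west quadrant and is reported without a ratio.
    """
    dc = cost_i - cost_ref
    dq = qalys_i - qalys_ref
    if dq > 0:
        flag = "dominant" if dc < 0 else "icer"
        return ICEResult(dc, dq, dc / dq, flag, comparator)
    if dq == 0 and dc == 0:
        return ICEResult(dc, dq, None, "zero_increment", comparator)
    if dc < 0:
        return ICEResult(dc, dq, None, "less_effective_cheaper", comparator)
    return ICEResult(dc, dq, None, "dominated", comparator)


def compute_nmb(qalys: float, cost: float, threshold: float) -> float:
    """Net monetary benefit: QALYs x threshold - cost."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return qalys * threshold - cost


def rank_by_nmb(results: Mapping[str, tuple[float, float]] | pd.DataFrame,
                threshold: float) -> pd.DataFrame:
    """Rank strategies by NMB (descending) at one threshold.

    ``results`` maps strategy -> (cost, qalys) (or a DataFrame with
    ``cost``/``qalys`` columns indexed by strategy). Ties break by lower
    cost, then name. Returns a DataFrame with columns
    ``cost, qalys, nmb, rank`` ordered by rank.
    """
    if isinstance(results, pd.DataFrame):
        items = [(name, (row["cost"], row["qalys"]))
                 for name, row in results.iterrows()]
    else:
        items = list(results.items())
    if len(items) < 2:
        raise ValueError("ranking needs at least two strategies")
    rows = [(name, cost, qalys, compute_nmb(qalys, cost, threshold))
            for name, (cost, qalys) in items]
    rows.sort(key=lambda r: (-r[3], r[1], r[0]))
    df = pd.DataFrame(rows, columns=["strategy", "cost", "qalys", "nmb"])
    df["rank"] = range(1, len(df) + 1)
    return df.set_index("strategy")
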