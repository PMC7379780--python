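"""Behavioral scoring (NOR percent exploration, CCFC percent freezing).

Implements the study's scores and exclusion rules: novel-object
recognition is scored as 100 × novel / (novel + familiar) exploration
time, with mice excluded when total exploration in the novel phase is
under 10 s; fear-conditioning freezing is scored as percent of the phase
duration, with mice excluded when contextual-phase freezing is under
30 s.  Exclusion rules never drop or mutate data — they set flags that
downstream summaries honor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "nor_percent_exploration",
    "percent_freezing",
    "score_behavior_table",
]

NOR_MIN_TOTAL_EXPLORATION_S = 10.0
CONTEXTUAL_MIN_FREEZING_S = 30.0


def nor_percent_exploration(
    novel_s: float,
    familiar_s: float,
    min_total: float = NOR_MIN_TOTAL_EXPLORATION_S,
) -> dict:
    """Percent exploration of the novel object, with the 10 s exclusion rule.

    Returns ``{"percent", "excluded", "reason"}``.  Chance performance is
    50%; an excluded animal (total exploration < ``min_total`` seconds,
    including zero) still gets a percent when the total is positive.
    """
    if novel_s < 0 or familiar_s < 0:
        raise ValueError("exploration times must be >= 0")
    total = novel_s + familiar_s
    excluded = total < min_total
    percent = 100.0 * novel_s / total if total > 0 else np.nan
    return {
        "percent": percent,
        "excluded": bool(excluded),
        "reason": "total exploration below minimum" if excluded else None,
    }


def percent_freezing(
    freezing_s: float,
    duration_s: float,
    phase: str = "contextual",
    contextual_min: float = CONTEXTUAL_MIN_FREEZING_S,
) -> dict:
    """Percent freezing of the total time in the chamber for one phase.

    The exclusion rule applies only to the contextual phase: animals with
    total contextual freezing under ``contextual_min`` seconds are flagged.
    Freezing longer than the phase duration is a validation error.
    """
    if duration_s <= 0:
        raise ValueError("phase duration must be positive")
    if freezing_s < 0:
        raise ValueError("freezing time must be >= 0")
    if freezing_s > duration_s:
        raise ValueError("freezing time exceeds the phase duration")
    excluded = phase == "contextual" and freezing_s < contextual_min
    return {
        "percent": 100.0 * freezing_s / duration_s,
        "excluded": bool(excluded),
        "reason": "contextual freezing below minimum" if excluded else None,
    }


def score_behavior_table(records: pd.DataFrame) -> pd.DataFrame:
    """Score a per-mouse behavior table, adding percents and exclusion flags.

    Expects columns ``novel_s``, ``familiar_s`` and, when present,
    ``contextual_freezing_s`` + ``contextual_duration_s`` (and optionally
    ``cued_freezing_s`` + ``cued_duration_s``).  The input is not mutated;
    the result adds ``nor_percent``, ``nor_excluded``,
    ``contextual_percent``, ``contextual_excluded`` (and cued columns when
    available) plus a combined ``excluded`` flag.
    """
    out = records.copy()
    nor = [
        nor_percent_exploration(r.novel_s, r.familiar_s) for r in records.itertuples()
    ]
    out["nor_percent"] = [d["percent"] for d in nor]
    out["nor_excluded"] = [d["excluded"] for d in nor]
    excluded = out["nor_excluded"].copy()
    if "contextual_freezing_s" in records:
        ctx = [
            percent_freezing(r.contextual_freezing_s, r.contextual_duration_s, "contextual")
            for r in records.itertuples()
        ]
        out["contextual_percent"] = [d["percent"] for d in ctx]
        out["contextual_excluded"] = [d["excluded"] for d in ctx]
        excluded |= out["contextual_excluded"]
    if "cued_freezing_s" in records:
        cued = [
            percent_freezing(r.cued_freezing_s, r.cued_duration_s, "cued")
            for r in records.itertuples()
        ]
        out["cued_percent"] = [d["percent"] for d in cued]
    out["excluded"] = excluded
    return out
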