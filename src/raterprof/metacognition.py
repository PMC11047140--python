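"""Confidence extraction and confidence/difficulty/accuracy correlations.

Confidence is the absolute value of the identity judgment (range 0-3): a
+3 and a -3 are equally confident decisions in opposite directions. The
trial-level analysis asks how confidence tracks rated difficulty response
by response; the participant-level analysis asks whether raters who are
more confident (or find the task easier) on average are also more
accurate — the metacognitive-insight question. All correlations are
Kendall's tau-b (tie-corrected), appropriate for coarse ordinal scales.

Incorrect high-confidence responses are retained as-is: the trial-level
confidence-difficulty analysis is direction-free and says nothing about
accuracy by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .accuracy import SingleClassError, compute_auc
from .judgment_data import JudgmentTable

logger = logging.getLogger("raterprof")


class UndefinedCorrelationError(ValueError):
    """Kendall's tau is undefined when either variable has zero variance."""


@dataclass(frozen=True)
class TauResult:
    tau: float
    p_value: float
    n: int
    level: str  # "trial" or "participant"
    pair: str  # named variable pair, e.g. "confidence~difficulty"


@dataclass(frozen=True)
class RaterSummary:
    rater_id: str
    group: str
    mean_confidence: float
    mean_difficulty: float
    auc: float


def to_confidence(judgment) -> np.ndarray | int:
    """Confidence of a judgment: its absolute value (0-3)."""
    if np.isscalar(judgment):
        if not -3 <= judgment <= 3:
            raise ValueError(f"judgment must lie in [-3, 3], got {judgment}")
        return abs(int(judgment))
    arr = np.asarray(judgment, dtype=int)
    if arr.size and (arr.min() < -3 or arr.max() > 3):
        raise ValueError("judgments must lie in [-3, 3]")
    return np.abs(arr)


def kendall_tau(x, y, level: str = "trial", pair: str = "x~y") -> TauResult:
    """Kendall's tau-b with two-sided p via the normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1-d vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError(
            "one variable has zero variance; tau undefined"
        )
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return TauResult(
        tau=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(x.size),
        level=level,
        pair=pair,
    )


def trial_level_confidence_difficulty(table: JudgmentTable, group: str) -> TauResult:
    """Tau between confidence and difficulty over all of a group's
    responses, pooled across raters and trials (one observation per
    response; within-rater dependence noted in report metadata)."""
    sub = table.select(group=group)
    if sub.empty:
        raise ValueError(f"group {group!r} not present in table")
    conf = to_confidence(sub["judgment"].to_numpy())
    return kendall_tau(
        conf,
        sub["difficulty"].to_numpy(),
        level="trial",
        pair="confidence~difficulty",
    )


def rater_summaries(table: JudgmentTable, group: str | None = None) -> list[RaterSummary]:
    """Per-rater mean confidence, mean difficulty, and AUC.

    Raters whose AUC is undefined (single trial type) carry ``auc = nan``
    and are logged; downstream correlations exclude them.
    """
    raters = table.raters_in(group) if group is not None else table.raters
    out: list[RaterSummary] = []
    for rater in raters:
        sub = table.df[table.df["rater_id"] == rater]
        try:
            auc = compute_auc(sub["judgment"].to_numpy(), sub["trial_type"].to_numpy())
        except SingleClassError:
            logger.warning("rater %s: AUC undefined, excluded from correlations", rater)
            auc = float("nan")
        out.append(
            RaterSummary(
                rater_id=rater,
                group=table.group_of(rater),
                mean_confidence=float(np.mean(to_confidence(sub["judgment"].to_numpy()))),
                mean_difficulty=float(sub["difficulty"].mean()),
                auc=auc,
            )
        )
    return out


def participant_level_correlations(
    table: JudgmentTable, group: str | None = None
) -> dict[str, TauResult]:
    """The three participant-level taus for one group (or pooled when
    ``group`` is None): mean confidence ~ mean difficulty, mean confidence
    ~ AUC, and mean difficulty ~ AUC."""
    summaries = [s for s in rater_summaries(table, group) if not math.isnan(s.auc)]
    if len(summaries) < 3:
        raise ValueError("need at least 3 raters with defined AUC")
    conf = np.array([s.mean_confidence for s in summaries])
    diff = np.array([s.mean_difficulty for s in summaries])
    auc = np.array([s.auc for s in summaries])
    return {
        "confidence~difficulty": kendall_tau(
            conf, diff, level="participant", pair="mean_confidence~mean_difficulty"
        ),
        "confidence~auc": kendall_tau(
            conf, auc, level="participant", pair="mean_confidence~auc"
        ),
        "difficulty~auc": kendall_tau(
            diff, auc, level="participant", pair="mean_difficulty~auc"
        ),
    }
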