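"""Per-rater accuracy as AUC from ordinal identity judgments.

The ROC curve is built directly from the 7-point judgments labelled by
trial type; its area equals the tie-corrected pair-comparison probability
(the Mann-Whitney functional): over all (same, different) trial pairs,
the proportion of pairs in which the same-identity trial received the
higher judgment, with ties credited 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("raterprof")


class SingleClassError(ValueError):
    """AUC is undefined without at least one trial of each type."""


@dataclass(frozen=True)
class AccuracyResult:
    rater_id: str
    group: str
    auc: float
    n_same: int
    n_different: int


@dataclass(frozen=True)
class RankTestResult:
    """Two-sided Mann-Whitney U with normal approximation.

    ``u_statistic`` is U for the first sample (number of cross-pairs in
    which the first sample's value exceeds the second's, ties counted 0.5);
    ``effect_r = z_score / sqrt(n_total)``.
    """

    u_statistic: float
    z_score: float
    p_value: float
    effect_r: float
    n_total: int
    degenerate: bool = False


def compute_auc(judgments, labels) -> float:
    """AUC of ordinal judgments against same/different trial labels.

    Orientation: higher judgments support "same", so a perfect rater
    (all same-identity judgments above all different-identity ones)
    scores 1.0; chance is 0.5. Equivalent to trapezoidal integration of
    the ROC over the seven judgment thresholds.
    """
    judgments = np.asarray(judgments, dtype=float)
    labels = np.asarray(labels)
    same = judgments[labels == "same"]
    diff = judgments[labels == "different"]
    if len(same) == 0 or len(diff) == 0:
        raise SingleClassError(
            f"AUC needs both trial types; got {len(same)} same and {len(diff)} different"
        )
    # midrank formulation of the pair-comparison probability
    ranks = stats.rankdata(np.concatenate([same, diff]))
    r_same = ranks[: len(same)].sum()
    u = r_same - len(same) * (len(same) + 1) / 2.0
    return float(u / (len(same) * len(diff)))


def group_accuracy(table) -> tuple[list[AccuracyResult], dict[str, float]]:
    """Per-rater AUC plus the median AUC of each group.

    Raters exposed to a single trial type carry ``auc = nan``, are logged,
    and are excluded from the group median.
    """
    results: list[AccuracyResult] = []
    for rater in table.raters:
        sub = table.df[table.df["rater_id"] == rater]
        labels = sub["trial_type"].to_numpy()
        n_same = int((labels == "same").sum())
        n_diff = int((labels == "different").sum())
        try:
            auc = compute_auc(sub["judgment"].to_numpy(), labels)
        except SingleClassError:
            logger.warning("rater %s saw a single trial type; AUC undefined", rater)
            auc = float("nan")
        results.append(
            AccuracyResult(rater, table.group_of(rater), auc, n_same, n_diff)
        )
    medians = {}
    for group in table.groups:
        vals = [r.auc for r in results if r.group == group and not math.isnan(r.auc)]
        medians[group] = float(np.median(vals)) if vals else float("nan")
    return results, medians


def compare_groups_rank(values_a, values_b) -> RankTestResult:
    """Two-sided Mann-Whitney U test between two samples.

    Uses the normal approximation with tie correction and continuity
    correction; the effect size is r = Z / sqrt(N) with N the total number
    of observations. When every value in both samples is identical the
    comparison is degenerate: p = 1, r = 0, flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0  # U for sample a
    if np.all(pooled == pooled[0]):
        return RankTestResult(float(u), 0.0, 1.0, 0.0, n, degenerate=True)
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    sigma = math.sqrt(sigma2)
    if sigma == 0:
        return RankTestResult(float(u), 0.0, 1.0, 0.0, n, degenerate=True)
    # continuity correction shrinks |U - mu| by 0.5
    delta = u - mu
    cc = 0.5 * np.sign(delta) if delta != 0 else 0.0
    z = (delta - cc) / sigma
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return RankTestResult(
        u_statistic=float(u),
        z_score=float(z),
        p_value=p,
        effect_r=float(z / math.sqrt(n)),
        n_total=n,
    )
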