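"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the code paths they check: weighted kappa
is evaluated by the explicit double sums over the 7x7 contingency table,
AUC by looping over all (same, different) trial pairs, the K-S statistic
by scanning every support point, and Kendall's tau-b by O(n^2) pair
enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from raterprof import JudgmentTable, StudyDesign
from raterprof.judgment_data import COLUMNS


# -- oracles ---------------------------------------------------------------


def kappa_oracle(a, b, weighting="linear") -> float:
    """Weighted kappa via explicit double sums over the contingency table."""
    q = 1 if weighting == "linear" else 2
    cats = list(range(-3, 4))
    n = len(a)
    w = {(i, j): 1.0 - (abs(i - j) / 6.0) ** q for i in cats for j in cats}
    p_o = sum(w[(ai, bi)] for ai, bi in zip(a, b)) / n
    pa = {c: sum(1 for x in a if x == c) / n for c in cats}
    pb = {c: sum(1 for x in b if x == c) / n for c in cats}
    p_e = sum(pa[i] * pb[j] * w[(i, j)] for i in cats for j in cats)
    if abs(1.0 - p_e) < 1e-12:
        return math.nan
    return (p_o - p_e) / (1.0 - p_e)


def auc_oracle(judgments, labels) -> float:
    """AUC by looping over all (same, different) pairs with 0.5 tie credit."""
    same = [j for j, lab in zip(judgments, labels) if lab == "same"]
    diff = [j for j, lab in zip(judgments, labels) if lab == "different"]
    total = 0.0
    for s in same:
        for d in diff:
            total += 1.0 if s > d else (0.5 if s == d else 0.0)
    return total / (len(same) * len(diff))


def auc_trapezoid_oracle(judgments, labels) -> float:
    """AUC by trapezoidal integration of the ROC over the 7 thresholds."""
    judgments = np.asarray(judgments)
    labels = np.asarray(labels)
    same = judgments[labels == "same"]
    diff = judgments[labels == "different"]
    # sweep the decision threshold across the scale from strict to lax
    tprs, fprs = [0.0], [0.0]
    for thresh in range(3, -4, -1):
        tprs.append(np.mean(same >= thresh))
        fprs.append(np.mean(diff >= thresh))
    tprs.append(1.0)
    fprs.append(1.0)
    return float(np.trapezoid(tprs, fprs))


def ks_d_oracle(a, b) -> float:
    """K-S statistic by scanning every pooled support point."""
    support = sorted(set(a) | set(b))
    best = 0.0
    for s in support:
        fa = sum(1 for x in a if x <= s) / len(a)
        fb = sum(1 for x in b if x <= s) / len(b)
        best = max(best, abs(fa - fb))
    return best


def tau_b_oracle(x, y) -> float:
    """Kendall's tau-b by exhaustive pair enumeration."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            ties_x += 1
            ties_y += 1
        elif dx == 0:
            ties_x += 1
        elif dy == 0:
            ties_y += 1
        elif dx * dy > 0:
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom if denom else math.nan


# -- fixtures --------------------------------------------------------------


def make_table(rows, design=None) -> JudgmentTable:
    """Build a table from (rater, group, trial, type, judgment, difficulty) rows."""
    return JudgmentTable(pd.DataFrame(rows, columns=list(COLUMNS)), design=design)


@pytest.fixture
def tiny_table() -> JudgmentTable:
    """Two groups x two raters on a 2-same + 2-different design."""
    rows = []
    judgments = {
        ("g1", "r1"): [3, 2, -2, -3],
        ("g1", "r2"): [2, 2, -1, -2],
        ("g2", "r3"): [3, 3, -3, -3],
        ("g2", "r4"): [3, -1, 2, -3],
    }
    for (group, rater), js in judgments.items():
        for t, (ttype, j) in enumerate(zip(["same", "same", "different", "different"], js)):
            rows.append((rater, group, f"t{t + 1}", ttype, j, min(5, abs(j) + 1)))
    return make_table(rows, design=StudyDesign(n_same=2, n_different=2))


@pytest.fixture(scope="session")
def default_study():
    """One paper-shaped simulated study shared across read-only tests."""
    from raterprof import default_study_config, simulate_study

    table, profiles = simulate_study(default_study_config(seed=11))
    return table, profiles
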