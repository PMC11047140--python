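"""Judgment-scale-use analyses: distributions, mirroring, K-S comparisons,
and per-rater extreme/midpoint usage.

Pooling unit: every judgment (not every rater) is one observation in a
pooled distribution — all judgments from all raters of a group and trial
type. The caveat that observations are therefore not independent within a
rater is recorded in the result metadata downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .accuracy import RankTestResult, compare_groups_rank
from .judgment_data import SCALE_POINTS, JudgmentTable


class EmptySelectionError(ValueError):
    """No judgments match the requested group / trial-type selection."""


@dataclass(frozen=True)
class JudgmentDistribution:
    """Proportion of pooled judgments at each scale point (-3 ... +3)."""

    group: str
    trial_type: str  # "same", "different", or "mirrored_different"
    proportions: dict[int, float]
    n: int

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("proportions must be nonnegative")

    def ecdf(self) -> np.ndarray:
        """Cumulative proportions over the scale points, ending at 1."""
        return np.cumsum([self.proportions[s] for s in SCALE_POINTS])


@dataclass(frozen=True)
class KSResult:
    d_statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str = "asymp"


@dataclass(frozen=True)
class ScaleUseSummary:
    rater_id: str
    group: str
    prop_extreme: float
    prop_midpoint: float
    #: modal judgment(s) per trial type; ties reported as the full tied set
    mode_judgment: dict[str, tuple[int, ...]]


def mirror_judgments(judgments) -> np.ndarray:
    """Reverse-code judgments (sign flip): -3 becomes +3 and vice versa.

    Used to put different-identity judgments on the same axis as
    same-identity ones before within-group distribution comparisons.
    """
    return -np.asarray(judgments, dtype=int)


def pooled_distribution(
    table: JudgmentTable, group: str, trial_type: str
) -> JudgmentDistribution:
    """Pooled judgment distribution for one group and trial type.

    ``trial_type`` may be ``"mirrored_different"`` to obtain the
    reverse-coded different-identity distribution. Unused scale points are
    zero-filled so every distribution covers all seven categories.
    """
    mirrored = trial_type == "mirrored_different"
    raw_type = "different" if mirrored else trial_type
    sub = table.select(group=group, trial_type=raw_type)
    if sub.empty:
        raise EmptySelectionError(
            f"no judgments for group {group!r}, trial type {raw_type!r}"
        )
    judgments = sub["judgment"].to_numpy()
    if mirrored:
        judgments = mirror_judgments(judgments)
    n = len(judgments)
    counts = {s: int(np.sum(judgments == s)) for s in SCALE_POINTS}
    return JudgmentDistribution(
        group=group,
        trial_type=trial_type,
        proportions={s: c / n for s, c in counts.items()},
        n=n,
    )


def _ecdf_at_support(sample: np.ndarray, support: np.ndarray) -> np.ndarray:
    sample = np.sort(sample)
    return np.searchsorted(sample, support, side="right") / len(sample)


def ks_two_sample(
    sample_a,
    sample_b,
    method: str = "asymp",
    n_permutations: int = 999,
    seed: int | None = None,
) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test on ordinal judgment samples.

    D is the largest absolute ECDF difference over the pooled support.
    ``method="asymp"`` gives the standard asymptotic two-sided p-value,
    which is conservative on discrete support with heavy ties;
    ``method="permutation"`` resamples pooled labels for a tie-exact
    p-value and is the recommended sensitivity analysis on 7-point data.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    support = np.unique(np.concatenate([a, b]))
    d = float(np.max(np.abs(_ecdf_at_support(a, support) - _ecdf_at_support(b, support))))
    if method == "asymp":
        if d == 0.0:
            p = 1.0  # scipy's asymptotic formula is indeterminate at D = 0
        else:
            scipy_res = stats.ks_2samp(a, b, method="asymp")
            p = float(scipy_res.pvalue)
            if np.isnan(p):
                # degenerate sample sizes: classical Kolmogorov limit
                from scipy.special import kolmogorov

                en = len(a) * len(b) / (len(a) + len(b))
                p = float(np.clip(kolmogorov(np.sqrt(en) * d), 0.0, 1.0))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        count = 0
        for _ in range(n_permutations):
            rng.shuffle(pooled)
            pa, pb = pooled[: len(a)], pooled[len(a):]
            dd = np.max(np.abs(_ecdf_at_support(pa, support) - _ecdf_at_support(pb, support)))
            if dd >= d - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_permutations)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KSResult(d_statistic=d, p_value=p, n_a=len(a), n_b=len(b), method=method)


def run_scale_use_comparisons(
    table: JudgmentTable,
    group_a: str,
    group_b: str,
    method: str = "asymp",
    seed: int | None = None,
) -> dict[str, KSResult]:
    """The four scale-use K-S comparisons between and within two groups.

    1. ``between_same``: group A vs group B on same-identity judgments;
    2. ``between_different``: group A vs group B on different-identity
       judgments;
    3. ``within_<group A>``: same vs *mirrored* different within group A;
    4. ``within_<group B>``: likewise within group B.
    """
    def pooled(group, trial_type, mirrored=False):
        sub = table.select(group=group, trial_type=trial_type)
        if sub.empty:
            raise EmptySelectionError(f"no {trial_type!r} judgments for group {group!r}")
        j = sub["judgment"].to_numpy()
        return mirror_judgments(j) if mirrored else j

    out = {
        "between_same": ks_two_sample(
            pooled(group_a, "same"), pooled(group_b, "same"), method=method, seed=seed
        ),
        "between_different": ks_two_sample(
            pooled(group_a, "different"), pooled(group_b, "different"),
            method=method, seed=seed,
        ),
    }
    for group in (group_a, group_b):
        out[f"within_{group}"] = ks_two_sample(
            pooled(group, "same"),
            pooled(group, "different", mirrored=True),
            method=method,
            seed=seed,
        )
    return out


def extreme_midpoint_summary(
    table: JudgmentTable,
    group_a: str | None = None,
    group_b: str | None = None,
) -> tuple[list[ScaleUseSummary], dict[str, RankTestResult]]:
    """Per-rater extreme (+/-3) and midpoint (0) proportions, with a
    between-group Mann-Whitney comparison of each proportion.

    Groups default to the table's first two groups in sorted order.
    """
    summaries: list[ScaleUseSummary] = []
    for rater in table.raters:
        sub = table.df[table.df["rater_id"] == rater]
        j = sub["judgment"].to_numpy()
        modes: dict[str, tuple[int, ...]] = {}
        for ttype in ("same", "different"):
            jt = sub.loc[sub["trial_type"] == ttype, "judgment"].to_numpy()
            if len(jt) == 0:
                modes[ttype] = ()
                continue
            vals, counts = np.unique(jt, return_counts=True)
            modes[ttype] = tuple(int(v) for v in vals[counts == counts.max()])
        summaries.append(
            ScaleUseSummary(
                rater_id=rater,
                group=table.group_of(rater),
                prop_extreme=float(np.mean(np.abs(j) == 3)),
                prop_midpoint=float(np.mean(j == 0)),
                mode_judgment=modes,
            )
        )
    comparisons: dict[str, RankTestResult] = {}
    groups = table.groups
    if group_a is None and len(groups) >= 2:
        group_a, group_b = groups[0], groups[1]
    if group_a is not None and group_b is not None:
        for attr in ("prop_extreme", "prop_midpoint"):
            va = [getattr(s, attr) for s in summaries if s.group == group_a]
            vb = [getattr(s, attr) for s in summaries if s.group == group_b]
            comparisons[attr] = compare_groups_rank(va, vb)
    return summaries, comparisons
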