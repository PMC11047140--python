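"""Ordinal-weighted Cohen's kappa over all unique rater pairs, agreement
labels, and the trial-bootstrap group comparison.

Because every rater contributes to many pairwise kappa values, the pair
kappas within a group are mutually dependent and no closed-form variance
is available for their mean. The group comparison therefore resamples
*trials* with replacement: each bootstrap iteration draws a trial multiset
of the original size, recomputes every pairwise kappa in both groups on
that multiset, and records the difference of the two group means. The 95%
percentile interval of those differences decides significance (the CI
excluding 0).

Weighted kappa uses agreement weights ``w_ij = 1 - (|i - j| / 6)^q`` over
the full seven-category set -3 ... +3 (q = 1 linear, q = 2 quadratic);
marginals always span all seven categories, so kappa stays well-defined
when raters use only a subset of the scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .judgment_data import SCALE_POINTS, JudgmentTable

logger = logging.getLogger("raterprof")

_N_CAT = len(SCALE_POINTS)  # 7


class UndefinedKappaError(ValueError):
    """Chance agreement is 1 (both raters constant at the same category),
    leaving kappa undefined."""


class InsufficientRatersError(ValueError):
    """Pairwise agreement needs at least two raters in the group."""


def weight_matrix(weighting: str = "linear") -> np.ndarray:
    """7x7 agreement-weight matrix for the ordinal judgment scale."""
    if weighting not in ("linear", "quadratic"):
        raise ValueError(f"weighting must be 'linear' or 'quadratic', got {weighting!r}")
    q = 1 if weighting == "linear" else 2
    idx = np.arange(_N_CAT)
    return 1.0 - (np.abs(idx[:, None] - idx[None, :]) / (_N_CAT - 1)) ** q


def _to_categories(values) -> np.ndarray:
    arr = np.asarray(values, dtype=int)
    if arr.size and (arr.min() < -3 or arr.max() > 3):
        raise ValueError("ratings must lie on the -3 ... +3 scale")
    return arr + 3


def weighted_kappa(ratings_a, ratings_b, weighting: str = "linear") -> float:
    """Weighted Cohen's kappa between two raters' judgment vectors.

    kappa_w = (P_o - P_e) / (1 - P_e), where P_o is the mean agreement
    weight of the observed rating pairs and P_e the expected weight under
    independent marginals. Ranges from +1 (perfect agreement) to -1
    (complete disagreement); 0 is chance-level.

    Raises
    ------
    UndefinedKappaError
        When both raters are constant at the same category (P_e = 1).
    """
    a = _to_categories(ratings_a)
    b = _to_categories(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("ratings must be equal-length nonempty vectors")
    w = weight_matrix(weighting)
    n = a.size
    p_o = w[a, b].mean()
    marg_a = np.bincount(a, minlength=_N_CAT) / n
    marg_b = np.bincount(b, minlength=_N_CAT) / n
    p_e = float(marg_a @ w @ marg_b)
    if 1.0 - p_e < 1e-12:
        raise UndefinedKappaError(
            "both raters constant at the same category; kappa undefined"
        )
    return float((p_o - p_e) / (1.0 - p_e))


def _pairwise_kappa_matrix(ratings: np.ndarray, w: np.ndarray) -> np.ndarray:
    """All-pairs weighted kappa for a raters x trials category matrix.

    Vectorized over pairs; entries with P_e = 1 come back as NaN
    (undefined). ``ratings`` holds categories 0..6.
    """
    n_raters, n_trials = ratings.shape
    # P_o[i, j] = mean_t w[ratings[i, t], ratings[j, t]]
    p_o = w[ratings[:, None, :], ratings[None, :, :]].mean(axis=2)
    marg = np.stack([np.bincount(row, minlength=_N_CAT) for row in ratings]) / n_trials
    p_e = marg @ w @ marg.T
    denom = 1.0 - p_e
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 1e-12, (p_o - p_e) / denom, np.nan)
    return kappa


@dataclass(frozen=True)
class AgreementSet:
    """All unique-pair weighted kappas for one group."""

    group: str
    pair_kappas: np.ndarray
    pairs: tuple[tuple[str, str], ...]
    n_pairs: int
    n_undefined_pairs: int
    mean: float
    sd: float
    weighting: str = "linear"

    def __post_init__(self) -> None:
        k = np.asarray(self.pair_kappas)
        if k.size and (np.nanmin(k) < -1 - 1e-9 or np.nanmax(k) > 1 + 1e-9):
            raise ValueError("kappa values must lie in [-1, 1]")


@dataclass(frozen=True)
class BootstrapResult:
    """Trial-bootstrap distribution of the group mean-kappa difference."""

    differences: np.ndarray
    ci_lower: float
    ci_upper: float
    n_iterations: int
    n_trials_resampled: int
    seed: int
    significant: bool
    group_a: str
    group_b: str
    weighting: str = "linear"
    n_discarded_iterations: int = 0


def pairwise_agreement(
    table: JudgmentTable, group: str, weighting: str = "linear"
) -> AgreementSet:
    """Weighted kappa between all C(n, 2) unique rater pairs of a group.

    Pairs whose kappa is undefined on the current trial set are counted in
    ``n_undefined_pairs`` and excluded from the mean and sd.
    """
    rater_ids, _, matrix = table.ratings_matrix(group)
    if len(rater_ids) < 2:
        raise InsufficientRatersError(
            f"group {group!r} has {len(rater_ids)} rater(s); need at least 2"
        )
    w = weight_matrix(weighting)
    kappa_mat = _pairwise_kappa_matrix(matrix + 3, w)
    iu, ju = np.triu_indices(len(rater_ids), k=1)
    kappas = kappa_mat[iu, ju]
    pairs = tuple((rater_ids[i], rater_ids[j]) for i, j in zip(iu, ju))
    defined = kappas[~np.isnan(kappas)]
    n_undef = int(np.isnan(kappas).sum())
    if n_undef:
        logger.warning("group %s: %d pair(s) with undefined kappa", group, n_undef)
    return AgreementSet(
        group=group,
        pair_kappas=kappas,
        pairs=pairs,
        n_pairs=len(kappas),
        n_undefined_pairs=n_undef,
        mean=float(defined.mean()) if defined.size else float("nan"),
        sd=float(defined.std(ddof=1)) if defined.size > 1 else float("nan"),
        weighting=weighting,
    )


def classify_agreement(kappa: float) -> str:
    """Rule-of-thumb label: >= 0.75 excellent; 0.40 < kappa < 0.75 fair;
    <= 0.40 poor."""
    if not -1 - 1e-9 <= kappa <= 1 + 1e-9:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa >= 0.75:
        return "excellent"
    if kappa > 0.40:
        return "fair"
    return "poor"


def bootstrap_group_difference(
    table: JudgmentTable,
    group_a: str,
    group_b: str,
    n_iterations: int = 1000,
    seed: int = 0,
    weighting: str = "linear",
    n_trials: int | None = None,
    stratified: bool = False,
) -> BootstrapResult:
    """Percentile bootstrap CI for the difference in mean pairwise kappa.

    Each iteration draws ``n_trials`` trial ids with replacement from the
    full trial set (default: the table's own trial count; unstratified by
    trial type unless ``stratified=True``), recomputes every pairwise kappa
    in both groups on the resampled trial multiset — repeated trials
    contribute repeated observations — and records
    ``mean kappa(group_a) - mean kappa(group_b)``. The 2.5th and 97.5th
    percentiles of the recorded differences form the 95% CI; the
    difference is judged significant when the CI excludes 0.

    Iterations in which a group has no defined pair kappas are discarded
    and re-drawn (counted in ``n_discarded_iterations``). Deterministic
    under a fixed seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    ids_a, trials_a, mat_a = table.ratings_matrix(group_a)
    ids_b, trials_b, mat_b = table.ratings_matrix(group_b)
    if trials_a != trials_b:
        raise ValueError("both groups must share the same trial set")
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise InsufficientRatersError("both groups need at least 2 raters")
    n_trials_total = len(trials_a)
    if n_trials is None:
        n_trials = n_trials_total
    w = weight_matrix(weighting)
    cat_a = mat_a + 3
    cat_b = mat_b + 3
    if stratified:
        ttypes = np.array([table.trial_type_of(t) for t in trials_a])
        same_idx = np.flatnonzero(ttypes == "same")
        diff_idx = np.flatnonzero(ttypes == "different")

    rng = np.random.default_rng(seed)
    iu_a, ju_a = np.triu_indices(len(ids_a), k=1)
    iu_b, ju_b = np.triu_indices(len(ids_b), k=1)
    differences = np.empty(n_iterations)
    n_discarded = 0
    it = 0
    max_attempts = 100 * n_iterations
    attempts = 0
    while it < n_iterations:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("bootstrap could not find enough non-degenerate iterations")
        if stratified:
            idx = np.concatenate(
                [
                    rng.choice(same_idx, size=len(same_idx), replace=True),
                    rng.choice(diff_idx, size=len(diff_idx), replace=True),
                ]
            )
        else:
            idx = rng.integers(0, n_trials_total, size=n_trials)
        means = []
        for cat, iu, ju in ((cat_a, iu_a, ju_a), (cat_b, iu_b, ju_b)):
            kap = _pairwise_kappa_matrix(cat[:, idx], w)[iu, ju]
            defined = kap[~np.isnan(kap)]
            means.append(defined.mean() if defined.size else np.nan)
        if np.isnan(means[0]) or np.isnan(means[1]):
            n_discarded += 1
            continue
        differences[it] = means[0] - means[1]
        it += 1
    if n_discarded:
        logger.warning("bootstrap discarded %d degenerate iteration(s)", n_discarded)
    ci_lower, ci_upper = np.percentile(differences, [2.5, 97.5])
    return BootstrapResult(
        differences=differences,
        ci_lower=float(ci_lower),
        ci_upper=float(ci_upper),
        n_iterations=n_iterations,
        n_trials_resampled=n_trials,
        seed=seed,
        significant=bool(ci_lower > 0 or ci_upper < 0),
        group_a=group_a,
        group_b=group_b,
        weighting=weighting,
        n_discarded_iterations=n_discarded,
    )
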