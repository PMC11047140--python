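"""Signal-detection rater simulator with group-specific response styles.

Generates :class:`~raterprof.judgment_data.JudgmentTable` objects from an
equal-variance Gaussian evidence model with ordered response thresholds
(ordinal SDT). Each simulated rater carries:

``sensitivity``
    separation (d', in latent s.d. units) between the evidence
    distributions for same- and different-identity trials;
``thresholds``
    six strictly increasing cut points partitioning the latent axis into
    the seven judgment categories -3 ... +3;
``extremity``
    a threshold-compression factor. Compression acts on category widths,
    not on the evidence itself, so it moves response mass toward the scale
    extremes (+/-3) and away from the midpoint 0 *without changing the
    rater's underlying accuracy* — it models response style, not skill;
``asymmetry``
    a shift applied to the evidence on different-identity trials only,
    modelling raters who are more cautious when concluding "different";
``difficulty_noise``
    s.d. of the noise added when mapping evidence extremity onto the
    5-point difficulty scale. Difficulty is generated from the *same*
    latent evidence as the judgment, which couples difficulty negatively
    to confidence (|judgment|).

Randomness is split hierarchically (one child stream per rater, indexed by
group and position) so that adding a rater never perturbs the data of
existing raters under the same seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .judgment_data import JudgmentTable, StudyDesign, COLUMNS

logger = logging.getLogger("raterprof")

#: Baseline equal-width partition of the latent axis into 7 categories.
BASELINE_THRESHOLDS = np.array([-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])

#: Difficulty mapping constants: raw difficulty = intercept - slope * |evidence|.
DIFFICULTY_INTERCEPT = 5.0
DIFFICULTY_SLOPE = 1.2

_MAX_REDRAWS = 20


@dataclass(frozen=True)
class RaterProfile:
    """Ground-truth parameters of one simulated rater."""

    sensitivity: float
    thresholds: tuple[float, ...]
    extremity: float = 0.0
    asymmetry: float = 0.0
    difficulty_noise: float = 0.5

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if t.shape != (6,):
            raise ValueError(f"expected 6 thresholds, got shape {t.shape}")
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"thresholds must be strictly increasing, got {t}")
        if self.sensitivity <= 0:
            raise ValueError(f"sensitivity must be positive, got {self.sensitivity}")
        if self.extremity < 0:
            raise ValueError(f"extremity must be nonnegative, got {self.extremity}")
        if self.difficulty_noise <= 0:
            raise ValueError(
                f"difficulty_noise must be positive, got {self.difficulty_noise}"
            )
        object.__setattr__(self, "thresholds", tuple(float(x) for x in t))


@dataclass(frozen=True)
class ProfileDistribution:
    """Per-parameter means and spreads from which rater profiles are drawn.

    Between-rater threshold variation has two components:
    ``threshold_bias_sd`` shifts a rater's whole partition (criterion
    bias — the rater leans "same" or "different" overall), while
    ``threshold_jitter_sd`` perturbs each cut point independently
    (category-spacing noise). Both act before extremity compression and
    together control within-group threshold homogeneity, and hence
    pairwise agreement; the bias component is by far the stronger
    disagreement driver because it displaces every judgment of a rater
    in the same direction. ``scale_thresholds_with_sensitivity``
    rescales a rater's thresholds in proportion to their sensitivity,
    which decouples confidence from accuracy across raters; by default
    thresholds are absolute (criterion placement shared across raters), so
    more sensitive raters produce more extreme, more confident judgments.
    """

    sensitivity_mean: float = 2.5
    sensitivity_sd: float = 0.3
    extremity_mean: float = 0.0
    extremity_sd: float = 0.0
    asymmetry_mean: float = 0.0
    asymmetry_sd: float = 0.0
    threshold_jitter_sd: float = 0.15
    threshold_bias_sd: float = 0.0
    difficulty_noise: float = 0.5
    scale_thresholds_with_sensitivity: bool = False


@dataclass(frozen=True)
class GroupSpec:
    """Name, size, and profile distribution of one rater group."""

    label: str
    n_raters: int
    profile_distribution: ProfileDistribution = field(default_factory=ProfileDistribution)

    def __post_init__(self) -> None:
        if self.n_raters < 1:
            raise ValueError(f"n_raters must be >= 1, got {self.n_raters}")


@dataclass(frozen=True)
class SimulationConfig:
    """Full study recipe: design, groups, trial variation, and seed."""

    design: StudyDesign = field(default_factory=StudyDesign)
    groups: tuple[GroupSpec, ...] = ()
    trial_difficulty_spread: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trial_difficulty_spread < 0:
            raise ValueError("trial_difficulty_spread must be nonnegative")
        object.__setattr__(self, "groups", tuple(self.groups))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "design": {"n_same": self.design.n_same, "n_different": self.design.n_different},
            "groups": [
                {
                    "label": g.label,
                    "n_raters": g.n_raters,
                    "profile_distribution": asdict(g.profile_distribution),
                }
                for g in self.groups
            ],
            "trial_difficulty_spread": self.trial_difficulty_spread,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SimulationConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            design=StudyDesign(**payload["design"]),
            groups=tuple(
                GroupSpec(
                    label=g["label"],
                    n_raters=g["n_raters"],
                    profile_distribution=ProfileDistribution(**g["profile_distribution"]),
                )
                for g in payload["groups"]
            ),
            trial_difficulty_spread=payload["trial_difficulty_spread"],
            seed=payload["seed"],
        )


def compress_thresholds(baseline: np.ndarray, extremity: float) -> np.ndarray:
    """Compress a threshold partition toward its centre.

    Division by ``1 + extremity`` pulls every cut point toward 0, shrinking
    the inner categories (the judgment-0 band most of all) and widening the
    two outer ones; ``extremity = 0`` is the identity.
    """
    return np.asarray(baseline, dtype=float) / (1.0 + extremity)


def draw_rater(spec: GroupSpec, rng: np.random.Generator) -> RaterProfile:
    """Draw one rater profile from a group's profile distribution.

    Thresholds are built by jittering the baseline equal-width partition,
    then applying extremity compression (and optional sensitivity scaling).
    A jitter draw that breaks monotonicity is re-drawn; if re-draws are
    exhausted the cut points are projected to sorted order, logged.
    """
    d = spec.profile_distribution
    sensitivity = max(rng.normal(d.sensitivity_mean, d.sensitivity_sd), 0.05)
    extremity = max(rng.normal(d.extremity_mean, d.extremity_sd), 0.0)
    asymmetry = rng.normal(d.asymmetry_mean, d.asymmetry_sd)
    bias = rng.normal(0.0, d.threshold_bias_sd) if d.threshold_bias_sd > 0 else 0.0
    base = None
    for _ in range(_MAX_REDRAWS):
        candidate = BASELINE_THRESHOLDS + bias + rng.normal(0.0, d.threshold_jitter_sd, size=6)
        if np.all(np.diff(candidate) > 0):
            base = candidate
            break
    if base is None:
        candidate = BASELINE_THRESHOLDS + bias + rng.normal(0.0, d.threshold_jitter_sd, size=6)
        base = np.sort(candidate)
        base += np.arange(6) * 1e-9  # break exact ties after projection
        logger.warning("threshold draw projected to monotone order for group %s", spec.label)
    thresholds = compress_thresholds(base, extremity)
    if d.scale_thresholds_with_sensitivity:
        thresholds = thresholds * (sensitivity / max(d.sensitivity_mean, 1e-9))
    return RaterProfile(
        sensitivity=float(sensitivity),
        thresholds=tuple(thresholds),
        extremity=float(extremity),
        asymmetry=float(asymmetry),
        difficulty_noise=float(d.difficulty_noise),
    )


def simulate_trial_response(
    profile: RaterProfile,
    trial_type: str,
    trial_strength: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Simulate one (judgment, difficulty) response.

    Evidence is ``+/-(sensitivity/2 + trial_strength)`` (positive on
    same-identity trials), shifted by ``asymmetry`` on different-identity
    trials, plus unit-normal noise. The judgment is the threshold category
    of the evidence; difficulty is a clamped 5-point discretization of a
    decreasing affine function of |evidence| plus difficulty noise.
    """
    sign = 1.0 if trial_type == "same" else -1.0
    mean = sign * (profile.sensitivity / 2.0 + trial_strength)
    if trial_type == "different":
        mean += profile.asymmetry
    evidence = mean + rng.normal()
    judgment = int(np.searchsorted(np.asarray(profile.thresholds), evidence)) - 3
    raw = (
        DIFFICULTY_INTERCEPT
        - DIFFICULTY_SLOPE * abs(evidence)
        + rng.normal(0.0, profile.difficulty_noise)
    )
    difficulty = int(np.clip(np.rint(raw), 1, 5))
    return judgment, difficulty


def _rater_rng(seed: int, group_index: int, rater_index: int) -> np.random.Generator:
    # stable per-rater stream: adding raters or groups never shifts others
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(1, group_index, rater_index))
    )


def simulate_study(config: SimulationConfig) -> tuple[JudgmentTable, list[RaterProfile]]:
    """Simulate a complete study and return the table plus ground truth.

    The table holds ``n_raters * (n_same + n_different)`` records per the
    design; identical configs (including seed) produce bit-identical
    tables. Trial strengths are shared across raters so that trials carry
    a common easiness component, which is what makes resampling trials
    (rather than raters) the meaningful bootstrap unit downstream.
    """
    if not config.groups:
        raise ValueError("config needs at least one group")
    design = config.design
    n_trials = design.n_trials
    trial_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    trial_strengths = trial_rng.normal(0.0, config.trial_difficulty_spread, size=n_trials)
    width = len(str(n_trials))
    trial_ids = [f"t{idx + 1:0{width}d}" for idx in range(n_trials)]
    trial_types = ["same"] * design.n_same + ["different"] * design.n_different

    rows: list[tuple] = []
    profiles: list[RaterProfile] = []
    rater_width = max(len(str(g.n_raters)) for g in config.groups)
    for gi, spec in enumerate(config.groups):
        for ri in range(spec.n_raters):
            rng = _rater_rng(config.seed, gi, ri)
            profile = draw_rater(spec, rng)
            profiles.append(profile)
            rater_id = f"{spec.label}_{ri + 1:0{rater_width}d}"
            for tid, ttype, strength in zip(trial_ids, trial_types, trial_strengths):
                judgment, difficulty = simulate_trial_response(profile, ttype, strength, rng)
                rows.append((rater_id, spec.label, tid, ttype, judgment, difficulty))
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    return JudgmentTable(df, design=design), profiles


# -- paper-shaped default configurations ----------------------------------


def examiner_style() -> ProfileDistribution:
    """Full-scale-use style: symmetric thresholds, no extremity preference."""
    return ProfileDistribution(
        sensitivity_mean=2.5,
        sensitivity_sd=0.3,
        extremity_mean=0.0,
        extremity_sd=0.0,
        asymmetry_mean=0.0,
        asymmetry_sd=0.0,
        threshold_jitter_sd=0.15,
        difficulty_noise=0.5,
    )


def super_recognizer_style() -> ProfileDistribution:
    """Extremity-preferring style: compressed thresholds (mass at +/-3,
    midpoint avoided), positive asymmetry (more caution on
    different-identity trials), and looser threshold homogeneity."""
    return ProfileDistribution(
        sensitivity_mean=2.5,
        sensitivity_sd=0.3,
        extremity_mean=1.5,
        extremity_sd=0.3,
        asymmetry_mean=0.4,
        asymmetry_sd=0.1,
        threshold_jitter_sd=0.30,
        difficulty_noise=0.5,
    )


def heterogeneous_skill_style() -> ProfileDistribution:
    """Wide skill spread with absolute (shared) criterion placement.

    With thresholds fixed across raters, a more sensitive rater's evidence
    reaches the outer categories more often, so confidence rises — and
    rated difficulty falls — with accuracy. This is the documented config
    for recovering the metacognitive-insight sign pattern at the
    participant level."""
    return ProfileDistribution(
        sensitivity_mean=2.2,
        sensitivity_sd=0.8,
        extremity_mean=0.0,
        extremity_sd=0.0,
        asymmetry_mean=0.0,
        asymmetry_sd=0.0,
        threshold_jitter_sd=0.15,
        difficulty_noise=0.5,
        scale_thresholds_with_sensitivity=False,
    )


def default_study_config(
    seed: int = 0,
    n_examiners: int = 57,
    n_super_recognizers: int = 13,
) -> SimulationConfig:
    """Study-shaped default: 57 + 13 raters, 12 same + 8 different trials,
    two groups of equal sensitivity but distinct response styles."""
    return SimulationConfig(
        design=StudyDesign(),
        groups=(
            GroupSpec("examiner", n_examiners, examiner_style()),
            GroupSpec("super_recognizer", n_super_recognizers, super_recognizer_style()),
        ),
        trial_difficulty_spread=0.5,
        seed=seed,
    )
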