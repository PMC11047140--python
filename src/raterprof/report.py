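"""Pipeline orchestration: one reproducible report over a judgment table.

``run_pipeline`` chains the four analyses (accuracy, scale use, agreement,
metacognition) over a judgment table — either supplied directly or
simulated from a :class:`~raterprof.synthetic_raters.SimulationConfig` —
and assembles a single :class:`AnalysisReport` with full provenance. All
stage seeds derive from one top-level seed by a fixed splitting rule
(``SeedSequence(seed, spawn_key=(stage_index,))``), so each stochastic
stage is reproducible in isolation. Re-running with identical inputs and
seed reproduces the report bit-identically apart from the timestamp,
which is isolated in its own field.
"""

from __future__ import annotations

import logging
import time
from datetime import datetime, timezone

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .accuracy import compare_groups_rank, group_accuracy
from .agreement import bootstrap_group_difference, classify_agreement, pairwise_agreement
from .judgment_data import JudgmentTable
from .metacognition import (
    UndefinedCorrelationError,
    participant_level_correlations,
    trial_level_confidence_difficulty,
)
from .scale_use import extreme_midpoint_summary, pooled_distribution, run_scale_use_comparisons
from .synthetic_raters import SimulationConfig, simulate_study

logger = logging.getLogger("raterprof")

# stage indices for the seed-splitting rule
_STAGE_SIMULATE = 0
_STAGE_BOOTSTRAP = 1


def stage_seed(seed: int, stage_index: int) -> int:
    """Derive a stage seed (< 2^31) from the top-level seed."""
    return int(np.random.SeedSequence(seed, spawn_key=(stage_index,)).generate_state(1)[0] % (2**31))


class Fingerprint(BaseModel):
    n_records: int
    n_raters: int
    groups: list[str]
    n_same_trials: int
    n_different_trials: int


class RankTest(BaseModel):
    u_statistic: float
    z_score: float
    p_value: float
    effect_r: float
    n_total: int
    degenerate: bool = False


class AccuracySection(BaseModel):
    per_rater: dict[str, float]
    group_medians: dict[str, float]
    group_comparison: RankTest | None = None


class KSEntry(BaseModel):
    d_statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str


class ScaleUseSection(BaseModel):
    distributions: dict[str, dict[str, float]]
    ks_comparisons: dict[str, KSEntry]
    per_rater_extreme: dict[str, float]
    per_rater_midpoint: dict[str, float]
    extreme_comparison: RankTest | None = None
    midpoint_comparison: RankTest | None = None
    pooling_note: str = (
        "pooled distributions treat each judgment as one observation; "
        "observations are not independent within a rater"
    )


class AgreementGroup(BaseModel):
    n_pairs: int
    n_undefined_pairs: int
    mean: float
    sd: float
    label: str
    pair_kappas: list[float] | None = None


class BootstrapSection(BaseModel):
    ci_lower: float
    ci_upper: float
    significant: bool
    n_iterations: int
    n_trials_resampled: int
    seed: int
    weighting: str
    group_a: str
    group_b: str
    n_discarded_iterations: int


class AgreementSection(BaseModel):
    groups: dict[str, AgreementGroup]
    bootstrap: BootstrapSection | None = None
    weighting: str


class TauEntry(BaseModel):
    tau: float
    p_value: float
    n: int
    level: str
    pair: str


class MetacognitionSection(BaseModel):
    trial_level: dict[str, TauEntry]
    participant_level: dict[str, dict[str, TauEntry]]
    dependence_note: str = (
        "trial-level taus pool responses within a group; responses of one "
        "rater are not independent observations"
    )


class AnalysisReport(BaseModel):
    """Full pipeline output with provenance."""

    fingerprint: Fingerprint
    accuracy: AccuracySection
    scale_use: ScaleUseSection
    agreement: AgreementSection
    metacognition: MetacognitionSection
    software_version: str
    seed_registry: dict[str, int]
    config_echo: dict | None = None
    timestamp: str = Field(default="", description="isolated volatile field")

    def to_json(self, **kwargs) -> str:
        return self.model_dump_json(**kwargs)


def run_pipeline(
    table: JudgmentTable | None = None,
    config: SimulationConfig | None = None,
    seed: int = 0,
    n_iterations: int = 1000,
    weighting: str = "linear",
    include_pair_kappas: bool = True,
    ks_method: str = "asymp",
) -> AnalysisReport:
    """Run the full beyond-accuracy pipeline and assemble the report.

    Exactly one of ``table`` or ``config`` must be given; with a config,
    the study is first simulated (the simulation seed is the config's
    own). Comparative stages use the table's first two groups in sorted
    order. Any stage failure is re-raised annotated with the stage name.
    """
    if (table is None) == (config is None):
        raise ValueError("provide exactly one of table or config")
    if config is not None:
        table, _ = simulate_study(config)
    assert table is not None
    groups = table.groups
    if len(groups) < 2:
        raise ValueError("the pipeline's comparative stages need two groups")
    group_a, group_b = groups[0], groups[1]
    seeds = {
        "top_level": seed,
        "bootstrap": stage_seed(seed, _STAGE_BOOTSTRAP),
    }

    def _stage(name, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs (n_records=%d)", name, time.perf_counter() - t0, len(table))
        return out

    # accuracy
    per_rater, medians = _stage("accuracy", group_accuracy, table)
    auc_a = [r.auc for r in per_rater if r.group == group_a and not np.isnan(r.auc)]
    auc_b = [r.auc for r in per_rater if r.group == group_b and not np.isnan(r.auc)]
    rank = _stage("accuracy_comparison", compare_groups_rank, auc_a, auc_b)
    accuracy = AccuracySection(
        per_rater={r.rater_id: r.auc for r in per_rater},
        group_medians=medians,
        group_comparison=RankTest(**rank.__dict__),
    )

    # scale use
    distributions = {}
    for g in (group_a, group_b):
        for tt in ("same", "different", "mirrored_different"):
            dist = _stage("scale_use_distribution", pooled_distribution, table, g, tt)
            distributions[f"{g}:{tt}"] = {str(k): v for k, v in dist.proportions.items()}
    ks = _stage(
        "scale_use_ks", run_scale_use_comparisons, table, group_a, group_b,
        method=ks_method, seed=seeds["bootstrap"],
    )
    summaries, comparisons = _stage("scale_use_summary", extreme_midpoint_summary, table, group_a, group_b)
    scale_section = ScaleUseSection(
        distributions=distributions,
        ks_comparisons={k: KSEntry(**v.__dict__) for k, v in ks.items()},
        per_rater_extreme={s.rater_id: s.prop_extreme for s in summaries},
        per_rater_midpoint={s.rater_id: s.prop_midpoint for s in summaries},
        extreme_comparison=RankTest(**comparisons["prop_extreme"].__dict__),
        midpoint_comparison=RankTest(**comparisons["prop_midpoint"].__dict__),
    )

    # agreement
    agreement_groups = {}
    for g in (group_a, group_b):
        aset = _stage("agreement", pairwise_agreement, table, g, weighting)
        agreement_groups[g] = AgreementGroup(
            n_pairs=aset.n_pairs,
            n_undefined_pairs=aset.n_undefined_pairs,
            mean=aset.mean,
            sd=aset.sd,
            label=classify_agreement(aset.mean) if not np.isnan(aset.mean) else "undefined",
            pair_kappas=[float(k) for k in aset.pair_kappas] if include_pair_kappas else None,
        )
    boot = _stage(
        "bootstrap", bootstrap_group_difference, table, group_a, group_b,
        n_iterations=n_iterations, seed=seeds["bootstrap"], weighting=weighting,
    )
    agreement_section = AgreementSection(
        groups=agreement_groups,
        bootstrap=BootstrapSection(
            ci_lower=boot.ci_lower,
            ci_upper=boot.ci_upper,
            significant=boot.significant,
            n_iterations=boot.n_iterations,
            n_trials_resampled=boot.n_trials_resampled,
            seed=boot.seed,
            weighting=boot.weighting,
            group_a=boot.group_a,
            group_b=boot.group_b,
            n_discarded_iterations=boot.n_discarded_iterations,
        ),
        weighting=weighting,
    )

    # metacognition
    trial_level = {}
    participant_level = {}
    for g in (group_a, group_b):
        tau = _stage("metacognition_trial", trial_level_confidence_difficulty, table, g)
        trial_level[g] = TauEntry(**tau.__dict__)
        try:
            taus = _stage("metacognition_participant", participant_level_correlations, table, g)
            participant_level[g] = {k: TauEntry(**v.__dict__) for k, v in taus.items()}
        except RuntimeError as exc:
            if isinstance(exc.__cause__, (UndefinedCorrelationError, ValueError)):
                logger.warning("participant-level correlations undefined for %s", g)
                participant_level[g] = {}
            else:
                raise
    meta_section = MetacognitionSection(
        trial_level=trial_level, participant_level=participant_level
    )

    return AnalysisReport(
        fingerprint=Fingerprint(
            n_records=len(table),
            n_raters=len(table.raters),
            groups=groups,
            n_same_trials=table.design.n_same,
            n_different_trials=table.design.n_different,
        ),
        accuracy=accuracy,
        scale_use=scale_section,
        agreement=agreement_section,
        metacognition=meta_section,
        software_version=__version__,
        seed_registry=seeds,
        config_echo=None if config is None else {"json": config.to_json()},
        timestamp=datetime.now(timezone.utc).isoformat(),
    )


def report_json_schema() -> dict:
    """Published JSON schema of the analysis report."""
    return AnalysisReport.model_json_schema()
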