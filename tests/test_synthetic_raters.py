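"""Properties of the ordinal signal-detection rater simulator."""

import numpy as np
import pytest

from raterprof import (
    BASELINE_THRESHOLDS,
    GroupSpec,
    ProfileDistribution,
    RaterProfile,
    SimulationConfig,
    StudyDesign,
    compress_thresholds,
    compute_auc,
    default_study_config,
    draw_rater,
    examiner_style,
    ks_two_sample,
    simulate_study,
    simulate_trial_response,
)


def _profile(**kw):
    defaults = dict(
        sensitivity=2.5,
        thresholds=tuple(BASELINE_THRESHOLDS),
        extremity=0.0,
        asymmetry=0.0,
        difficulty_noise=0.5,
    )
    defaults.update(kw)
    return RaterProfile(**defaults)


class TestRaterProfile:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            _profile(thresholds=(0, 0, 1, 2, 3, 4))
        with pytest.raises(ValueError, match="sensitivity"):
            _profile(sensitivity=-1)
        with pytest.raises(ValueError, match="extremity"):
            _profile(extremity=-0.1)

    def test_zero_extremity_leaves_baseline_unchanged(self):
        np.testing.assert_array_equal(
            compress_thresholds(BASELINE_THRESHOLDS, 0.0), BASELINE_THRESHOLDS
        )

    def test_extremity_shrinks_central_category(self):
        # width of the judgment-0 band falls below its baseline width
        base_width = BASELINE_THRESHOLDS[3] - BASELINE_THRESHOLDS[2]
        t = compress_thresholds(BASELINE_THRESHOLDS, 2.0)
        assert t[3] - t[2] < base_width
        assert np.all(np.diff(t) > 0)

    def test_symmetric_spec_yields_symmetric_thresholds(self):
        spec = GroupSpec("g", 1, ProfileDistribution(threshold_jitter_sd=0.0))
        profile = draw_rater(spec, np.random.default_rng(0))
        t = np.array(profile.thresholds)
        np.testing.assert_allclose(t, -t[::-1], atol=1e-12)

    def test_draw_rater_deterministic_under_rng_state(self):
        spec = GroupSpec("g", 1, examiner_style())
        p1 = draw_rater(spec, np.random.default_rng(42))
        p2 = draw_rater(spec, np.random.default_rng(42))
        assert p1 == p2

    def test_large_jitter_still_yields_monotone_thresholds(self):
        spec = GroupSpec("g", 1, ProfileDistribution(threshold_jitter_sd=2.0))
        rng = np.random.default_rng(7)
        for _ in range(50):
            profile = draw_rater(spec, rng)
            assert np.all(np.diff(profile.thresholds) > 0)


class TestTrialResponse:
    def test_extreme_sensitivity_saturates_judgments(self):
        profile = _profile(sensitivity=1000.0)
        rng = np.random.default_rng(0)
        assert simulate_trial_response(profile, "same", 0.0, rng)[0] == 3
        assert simulate_trial_response(profile, "different", 0.0, rng)[0] == -3

    def test_symmetric_construction_mirrors_in_expectation(self):
        # asymmetry 0 + symmetric thresholds: P(judgment = j | same)
        # equals P(judgment = -j | different)
        profile = _profile()
        rng = np.random.default_rng(1)
        same = np.array(
            [simulate_trial_response(profile, "same", 0.0, rng)[0] for _ in range(4000)]
        )
        diff = np.array(
            [simulate_trial_response(profile, "different", 0.0, rng)[0] for _ in range(4000)]
        )
        res = ks_two_sample(same, -diff, method="permutation", n_permutations=299, seed=0)
        assert res.p_value > 0.01

    def test_confidence_difficulty_coupling_negative(self):
        from scipy.stats import kendalltau

        profile = _profile()
        rng = np.random.default_rng(2)
        responses = [
            simulate_trial_response(profile, t, 0.0, rng)
            for t in ["same", "different"] * 5000
        ]
        conf = np.abs([r[0] for r in responses])
        diff = [r[1] for r in responses]
        tau = kendalltau(conf, diff).statistic
        assert tau < -0.3

    def test_difficulty_clamped_to_scale(self):
        profile = _profile(sensitivity=50.0, difficulty_noise=5.0)
        rng = np.random.default_rng(3)
        for ttype in ("same", "different"):
            for _ in range(200):
                _, d = simulate_trial_response(profile, ttype, 0.0, rng)
                assert 1 <= d <= 5


class TestSimulateStudy:
    def test_record_count_matches_design(self):
        table, profiles = simulate_study(default_study_config(seed=0))
        assert len(table) == 70 * 20
        assert len(profiles) == 70
        assert table.design == StudyDesign(12, 8)

    def test_bit_identical_under_fixed_seed(self):
        cfg = default_study_config(seed=9, n_examiners=5, n_super_recognizers=4)
        t1, p1 = simulate_study(cfg)
        t2, p2 = simulate_study(cfg)
        assert t1 == t2
        assert p1 == p2

    def test_adding_a_rater_preserves_existing_data(self):
        small = SimulationConfig(
            groups=(GroupSpec("g", 5, examiner_style()),), seed=3
        )
        big = SimulationConfig(groups=(GroupSpec("g", 6, examiner_style()),), seed=3)
        ts, _ = simulate_study(small)
        tb, _ = simulate_study(big)
        shared = tb.df[tb.df["rater_id"].isin(ts.df["rater_id"])].reset_index(drop=True)
        assert shared.equals(ts.df)

    def test_extremity_group_prefers_scale_extremes(self):
        style = examiner_style()
        extreme_style = ProfileDistribution(
            **{**style.__dict__, "extremity_mean": 2.0}
        )
        cfg = SimulationConfig(
            groups=(GroupSpec("flat", 50, style), GroupSpec("extreme", 50, extreme_style)),
            seed=5,
        )
        table, _ = simulate_study(cfg)
        j_flat = table.select(group="flat")["judgment"].abs()
        j_ext = table.select(group="extreme")["judgment"].abs()
        assert np.mean(j_ext == 3) > np.mean(j_flat == 3) + 0.1

    def test_mean_auc_nondecreasing_in_sensitivity(self):
        # 3-point sensitivity grid, 200 raters per point
        mean_aucs = []
        for i, sens in enumerate([1.0, 2.0, 3.0]):
            style = ProfileDistribution(sensitivity_mean=sens, sensitivity_sd=0.1)
            cfg = SimulationConfig(groups=(GroupSpec("g", 200, style),), seed=100 + i)
            table, _ = simulate_study(cfg)
            aucs = [
                compute_auc(sub["judgment"].to_numpy(), sub["trial_type"].to_numpy())
                for _, sub in table.df.groupby("rater_id")
            ]
            mean_aucs.append(np.mean(aucs))
        assert mean_aucs[0] < mean_aucs[1] < mean_aucs[2]


def test_mirror_symmetry_ks_rejects_at_nominal_rate():
    """With asymmetry 0, symmetric shared thresholds, and no trial or
    rater heterogeneity, pooled same vs mirrored-different judgments are
    exchangeable, so the permutation K-S test should reject at ~5%."""
    style = ProfileDistribution(
        sensitivity_sd=0.0, threshold_jitter_sd=0.0, asymmetry_mean=0.0
    )
    rejections = 0
    n_rep = 400
    for rep in range(n_rep):
        cfg = SimulationConfig(
            groups=(GroupSpec("g", 8, style),),
            trial_difficulty_spread=0.0,
            seed=10_000 + rep,
        )
        table, _ = simulate_study(cfg)
        same = table.select(trial_type="same")["judgment"].to_numpy()
        diff = table.select(trial_type="different")["judgment"].to_numpy()
        res = ks_two_sample(same, -diff, method="permutation", n_permutations=199, seed=rep)
        rejections += res.p_value <= 0.05
    assert 0.02 <= rejections / n_rep <= 0.08


def test_config_json_round_trip(tmp_path):
    cfg = default_study_config(seed=4)
    path = tmp_path / "cfg.json"
    cfg.to_json(path)
    assert SimulationConfig.from_json(path) == cfg
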