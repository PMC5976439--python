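import dataclasses

import numpy as np
import pytest
from scipy import stats

from slidekin import (
    TrajectorySimConfig,
    XlmsSimConfig,
    simulate_atpase_timecourse,
    simulate_inhibition_series,
    simulate_titration,
    simulate_trajectory,
    simulate_trajectory_set,
    simulate_xlms_csms,
)
from slidekin.simulate import _simulate_kinetic_path


class TestTrajectorySimulation:
    def test_static_proximal_trace_sits_at_high_fret_cluster(self, calib, clean_config):
        # wait pause much longer than the trace: constant E = calib(0) = 0.95
        cfg = dataclasses.replace(clean_config, wait_mean_s=1e9, n_frames=200)
        traj, gt = simulate_trajectory(cfg, calib, seed=0, label_class="proximal")
        fret = traj.acceptor / (traj.donor + traj.acceptor)
        np.testing.assert_allclose(fret, 0.95, atol=1e-9)
        assert len(gt.segments) == 1 and gt.segments[0].kind == "pause"

    def test_zero_variance_first_step_is_exactly_mean(self, calib, clean_config):
        traj, gt = simulate_trajectory(clean_config, calib, seed=3, label_class="proximal")
        steps = gt.step_sizes()
        assert steps, "trace too short to contain a translocation"
        assert steps[0] == pytest.approx(8.0)

    def test_fixed_seed_is_byte_identical(self, calib):
        cfg = TrajectorySimConfig(n_frames=300)
        t1, _ = simulate_trajectory(cfg, calib, seed=42)
        t2, _ = simulate_trajectory(cfg, calib, seed=42)
        assert t1.donor.tobytes() == t2.donor.tobytes()
        assert t1.acceptor.tobytes() == t2.acceptor.tobytes()

    def test_invalid_configs_rejected(self, calib):
        with pytest.raises(ValueError):
            simulate_trajectory(
                TrajectorySimConfig(n_frames=0), calib, seed=0
            )
        with pytest.raises(ValueError):
            TrajectorySimConfig(labeled_fraction=1.5).validate()
        with pytest.raises(ValueError):
            TrajectorySimConfig(wait_mean_s=-1).validate()

    def test_ground_truth_segments_contiguous_and_monotone(self, calib):
        cfg = TrajectorySimConfig(n_frames=400, backtrack_prob=0.0)
        for seed in range(8):
            _, gt = simulate_trajectory(cfg, calib, seed=seed, label_class="proximal")
            starts = [s.start_s for s in gt.segments]
            ends = [s.end_s for s in gt.segments]
            assert starts[0] == 0.0
            assert ends[-1] == pytest.approx(cfg.duration_s)
            np.testing.assert_allclose(ends[:-1], starts[1:])
            bp = [s.end_bp for s in gt.segments]
            assert all(b2 >= b1 - 1e-9 for b1, b2 in zip(bp, bp[1:]))

    def test_backtracks_are_flagged(self, calib):
        cfg = TrajectorySimConfig(n_frames=2000, backtrack_prob=0.9)
        flagged = 0
        for seed in range(5):
            _, gt = simulate_trajectory(cfg, calib, seed=seed, label_class="proximal")
            for s in gt.segments:
                if s.kind == "translocation" and s.end_bp < s.start_bp:
                    assert s.backtrack
                    flagged += 1
        assert flagged > 0


class TestTrajectorySet:
    def test_all_both_when_fully_labeled(self, calib):
        cfg = TrajectorySimConfig(n_frames=20, labeled_fraction=1.0)
        out = simulate_trajectory_set(cfg, calib, 10, seed=0)
        assert all(gt.label_class == "both" for _, gt in out)

    def test_zero_trajectories_rejected(self, calib):
        with pytest.raises(ValueError):
            simulate_trajectory_set(TrajectorySimConfig(n_frames=20), calib, 0, seed=0)

    def test_label_mixture_follows_binomial_law(self, calib):
        # 2:1 unlabeled:labeled H3 mixing: per-H3 Bernoulli(1/3), so
        # P(both)=1/9, P(proximal)=P(distal)=2/9, P(none)=4/9
        cfg = TrajectorySimConfig(n_frames=2)
        n = 10_000
        out = simulate_trajectory_set(cfg, calib, n, seed=5)
        classes = [gt.label_class for _, gt in out]
        obs = np.array(
            [classes.count(c) for c in ("both", "proximal", "distal", "none")]
        )
        exp = np.array([1 / 9, 2 / 9, 2 / 9, 4 / 9]) * n
        chi2 = stats.chisquare(obs, exp)
        assert chi2.pvalue > 0.01

    def test_unlabeled_traces_carry_no_fret_signal(self, calib, clean_config):
        cfg = dataclasses.replace(clean_config, n_frames=100)
        traj, gt = simulate_trajectory(cfg, calib, seed=0, label_class="none")
        assert np.all(traj.donor == 0) and np.all(traj.acceptor == 0)

    def test_pause_duration_means_match_configured_exponentials(self, calib):
        # distributional check on the kinetic path generator itself
        cfg = TrajectorySimConfig(
            n_frames=74 * 600, backtrack_prob=0.0  # long window: no censoring
        )
        rng = np.random.default_rng(77)
        by_index = {0: [], 1: [], 2: []}
        n_traces = 1500
        for _ in range(n_traces):
            segs = _simulate_kinetic_path(cfg, bp_max=1e9, rng=rng)
            pauses = [s for s in segs if s.kind == "pause"]
            for i, s in enumerate(pauses[:-1]):  # last pause is censored
                if i in by_index:
                    by_index[i].append(s.end_s - s.start_s)
        for i, mean in [(0, 20.0), (1, 10.0), (2, 10.0)]:
            d = np.array(by_index[i])
            assert d.size >= 1000
            se = d.std(ddof=1) / np.sqrt(d.size)
            assert abs(d.mean() - mean) < 3 * se + 1e-9


class TestEnsembleGenerators:
    MODEL = {"k_max": 2.5, "K_m_app": 61.0, "h": 1.5}

    def test_half_saturation_identity(self):
        t = np.linspace(0, 10, 5)
        (course,) = simulate_titration(self.MODEL, [61.0], t)
        assert course.meta["k_obs_true"] == pytest.approx(2.5 / 2)

    def test_saturation_limit(self):
        t = np.linspace(0, 10, 5)
        (course,) = simulate_titration(self.MODEL, [1e9], t)
        assert course.meta["k_obs_true"] == pytest.approx(2.5, rel=1e-6)

    def test_hill_one_reduces_to_hyperbola(self):
        model = {"k_max": 2.0, "K_m_app": 50.0, "h": 1.0}
        X = np.array([10.0, 50.0, 200.0])
        t = np.linspace(0, 10, 5)
        for course, x in zip(simulate_titration(model, X, t), X):
            assert course.meta["k_obs_true"] == pytest.approx(
                2.0 * x / (50.0 + x)
            )

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_titration(self.MODEL, [10.0], [0, 1], noise_sd=-1)

    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 1.0), (1.21, 0.5), (50.0, 1 / (1 + 50 / 1.21))],
    )
    def test_inhibition_series_values(self, x, expected):
        df = simulate_inhibition_series(1.0, 1.21, [x])
        assert df["k_obs"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_inhibition_worked_value(self):
        # k0/(1 + 50/1.21) evaluates to 0.023628...
        df = simulate_inhibition_series(1.0, 1.21, [50.0])
        assert df["k_obs"].iloc[0] == pytest.approx(0.02362, abs=1e-5)

    def test_atpase_zero_rate_is_flat(self):
        df = simulate_atpase_timecourse(0.0, np.linspace(0, 10, 11), 7.5)
        assert np.all(df["Pi"] == 0)

    def test_atpase_early_slope_equals_rate(self):
        t = np.linspace(0, 0.5, 10)  # well inside the linear phase
        df = simulate_atpase_timecourse(0.3, t, 7.5)
        slope = np.polyfit(df["t"], df["Pi"], 1)[0]
        assert slope == pytest.approx(0.3, rel=1e-9)

    def test_atpase_noise_reproducible(self):
        t = np.linspace(0, 10, 20)
        a = simulate_atpase_timecourse(0.3, t, 7.5, noise_sd=0.1, seed=9)
        b = simulate_atpase_timecourse(0.3, t, 7.5, noise_sd=0.1, seed=9)
        assert np.array_equal(a["Pi"], b["Pi"])


class TestXlmsGenerator:
    def test_no_ambiguity_gives_single_candidates(self):
        cfg = XlmsSimConfig(n_target_csms=50, n_decoy_csms=5, ambiguity_prob=0.0)
        table = simulate_xlms_csms(cfg, seed=0)
        assert all(len(c) == 1 for c in table["candidates"])

    def test_deterministic_under_seed(self):
        cfg = XlmsSimConfig(n_target_csms=30, n_decoy_csms=5)
        a = simulate_xlms_csms(cfg, seed=3)
        b = simulate_xlms_csms(cfg, seed=3)
        assert a.drop(columns="candidates").equals(b.drop(columns="candidates"))
        assert list(a["candidates"]) == list(b["candidates"])

    def test_enrichment_multiplier_shows_in_counts(self):
        pair = ("H2A:Acidic Patch", "SNF2h:AutoN")
        cfg = XlmsSimConfig(
            n_target_csms=4000,
            n_decoy_csms=0,
            ambiguity_prob=0.0,
            condition_enrichment={tuple(sorted(pair)): 2.0},
        )
        table = simulate_xlms_csms(cfg, seed=1)
        from slidekin import default_domain_map

        dmap = default_domain_map()

        def count(cond):
            sub = table[table["condition"] == cond]
            n = 0
            for cands in sub["candidates"]:
                p1, r1, p2, r2 = cands[0]
                doms = tuple(
                    sorted([dmap.domain_of(p1, r1), dmap.domain_of(p2, r2)])
                )
                n += doms == tuple(sorted(pair))
            return n

        na, nb = count("ADP"), count("ADP-BeFx")
        ratio = nb / na
        se = ratio * np.sqrt(1 / na + 1 / nb)
        assert abs(ratio - 2.0) < 3 * se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            XlmsSimConfig(ambiguity_prob=2.0).validate()
        with pytest.raises(ValueError):
            XlmsSimConfig(condition_enrichment={("a", "b"): -1}).validate()
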