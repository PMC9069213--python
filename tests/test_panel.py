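import numpy as np
import pytest

from procad.coverage import NormalizedCoverage
from procad.panel import (
    arm_zscores,
    bin_zscores,
    build_panel,
    summarize_cnv_events,
)


def _nc(sid, values):
    values = np.asarray(values, dtype=float)
    return NormalizedCoverage(sid, values, np.arange(values.size))


def _noisy_controls(grid, n, sd=0.05, seed=0):
    rng = np.random.default_rng(seed)
    return [
        _nc(f"c{i}", 1.0 + rng.normal(0, sd, grid.n_bins)) for i in range(n)
    ]


class TestBuildPanel:
    def test_two_point_sd(self, toy_grid):
        a = _nc("a", np.full(toy_grid.n_bins, 0.9))
        b = _nc("b", np.full(toy_grid.n_bins, 1.1))
        # constant-per-sample panels have zero *arm* SD only if bin SD > 0;
        # here every bin has mean 1.0 and sd sqrt(0.02) across the two controls
        panel = build_panel([a, b], toy_grid, min_bins_per_arm=10)
        assert np.allclose(panel.bin_mean, 1.0)
        assert np.allclose(panel.bin_sd, np.std([0.9, 1.1], ddof=1))
        assert panel.bin_sd[0] == pytest.approx(0.1414, abs=2e-4)

    def test_identical_controls_rejected(self, toy_grid):
        a = _nc("a", np.ones(toy_grid.n_bins))
        b = _nc("b", np.ones(toy_grid.n_bins))
        with pytest.raises(ValueError, match="degenerate"):
            with pytest.warns(UserWarning):
                build_panel([a, b], toy_grid)

    def test_single_control_rejected(self, toy_grid):
        with pytest.raises(ValueError, match=">= 2"):
            build_panel([_nc("a", np.ones(toy_grid.n_bins))], toy_grid)

    def test_nine_control_stats_match_direct_recomputation(self, toy_grid):
        controls = _noisy_controls(toy_grid, 9, seed=4)
        panel = build_panel(controls, toy_grid, min_bins_per_arm=10)
        mat = np.stack([c.values for c in controls])
        assert np.allclose(panel.bin_mean, mat.mean(axis=0))
        assert np.allclose(panel.bin_sd, mat.std(axis=0, ddof=1))
        arm_ids = toy_grid.arm_ids
        for k, arm in enumerate(panel.retained_arms):
            va = mat[:, arm_ids[panel.bin_index] == arm].mean(axis=1)
            assert panel.arm_mean[k] == pytest.approx(va.mean())
            assert panel.arm_sd[k] == pytest.approx(va.std(ddof=1))

    def test_min_bins_filter_drops_short_arms(self, toy_grid):
        # toy arms have 50 bins each: a 60-bin floor retains nothing and raises
        controls = _noisy_controls(toy_grid, 5)
        with pytest.raises(ValueError, match="no arm"):
            build_panel(controls, toy_grid, min_bins_per_arm=60)


class TestBinZscores:
    def test_sample_at_panel_mean_scores_zero(self, toy_grid):
        controls = _noisy_controls(toy_grid, 6)
        panel = build_panel(controls, toy_grid)
        z = bin_zscores(_nc("s", panel.bin_mean), panel)
        assert np.allclose(z, 0.0)

    def test_two_sd_shift_scores_two(self, toy_grid):
        controls = _noisy_controls(toy_grid, 6)
        panel = build_panel(controls, toy_grid)
        z = bin_zscores(_nc("s", panel.bin_mean + 2 * panel.bin_sd), panel)
        assert np.allclose(z, 2.0)

    def test_null_sample_against_large_panel_is_calibrated(self, toy_grid):
        rng = np.random.default_rng(8)
        controls = _noisy_controls(toy_grid, 20, sd=0.05, seed=8)
        panel = build_panel(controls, toy_grid)
        sample = _nc("s", 1.0 + rng.normal(0, 0.05, toy_grid.n_bins))
        z = bin_zscores(sample, panel)
        assert abs(z.mean()) < 0.15
        assert 0.8 < z.std() < 1.3

    def test_leave_one_out_needs_three_controls(self, toy_grid):
        controls = _noisy_controls(toy_grid, 2)
        panel = build_panel(controls, toy_grid)
        with pytest.raises(ValueError, match=">= 3"):
            bin_zscores(controls[0], panel, leave_one_out=True)


class TestArmZscores:
    def test_sample_at_panel_mean_scores_zero(self, toy_grid):
        controls = _noisy_controls(toy_grid, 6)
        panel = build_panel(controls, toy_grid)
        # reconstruct the coverage whose arm means equal the panel arm means
        prof = arm_zscores(_nc("s", panel.bin_mean), panel)
        arm_ids = toy_grid.arm_ids[panel.bin_index]
        for k, arm in enumerate(panel.retained_arms):
            va = panel.bin_mean[arm_ids == arm].mean()
            assert prof.z[k] == pytest.approx(
                (va - panel.arm_mean[k]) / panel.arm_sd[k]
            )

    def test_uniform_three_sd_shift_scores_three(self, toy_grid):
        controls = _noisy_controls(toy_grid, 9)
        panel = build_panel(controls, toy_grid)
        v = panel.bin_mean.copy()
        arm_ids = toy_grid.arm_ids[panel.bin_index]
        base = arm_zscores(_nc("s", v), panel).z
        arm0 = panel.retained_arms[0]
        v[arm_ids == arm0] += 3 * panel.arm_sd[0] * 1.0  # uniform shift of V_a
        prof = arm_zscores(_nc("s", v), panel)
        assert prof.z[0] - base[0] == pytest.approx(3.0)

    def test_simulated_gain_detected(self, event_cohort, toy_grid):
        """Single-copy gain at f = 0.4 (ratio 1.2) clears |Z| >= 2.5."""
        from procad.coverage import filter_bins, normalize_sample
        from procad.simulate import SimConfig

        counts, truth, sheet, grid = event_cohort
        ctrl = [c for c in counts if c.sample_id.startswith("CTRL")]
        mask = filter_bins(ctrl)
        panel = build_panel([normalize_sample(c, mask) for c in ctrl], grid)
        for c in counts:
            if not c.sample_id.startswith("CASE"):
                continue
            ev = truth.events[c.sample_id][0]
            prof = arm_zscores(normalize_sample(c, mask), panel)
            z = prof.z[prof.arms.index(ev.arm)]
            assert z >= 2.5 and z > 0

    def test_modes_agree_in_sign_on_uniform_shift(self, toy_grid):
        controls = _noisy_controls(toy_grid, 9)
        panel = build_panel(controls, toy_grid)
        v = panel.bin_mean.copy()
        arm_ids = toy_grid.arm_ids[panel.bin_index]
        v[arm_ids == panel.retained_arms[2]] *= 1.2
        a = arm_zscores(_nc("s", v), panel, mode="arm-mean")
        s = arm_zscores(_nc("s", v), panel, mode="stouffer")
        k = 2
        assert np.sign(a.z[k]) == np.sign(s.z[k]) == 1.0

    def test_unknown_mode_rejected(self, toy_grid):
        controls = _noisy_controls(toy_grid, 4)
        panel = build_panel(controls, toy_grid)
        with pytest.raises(ValueError, match="unknown mode"):
            arm_zscores(controls[0], panel, mode="median")

    def test_affine_depth_contract(self, toy_grid):
        """Scaling panel and sample coverage identically leaves Z unchanged
        (depth normalization upstream guarantees inputs are scale-free)."""
        controls = _noisy_controls(toy_grid, 6, seed=13)
        panel = build_panel(controls, toy_grid)
        sample = _nc("s", 1.0 + np.random.default_rng(14).normal(0, 0.05, toy_grid.n_bins))
        z1 = arm_zscores(sample, panel).z
        scaled = [_nc(c.sample_id, 3.0 * c.values) for c in controls]
        panel2 = build_panel(scaled, toy_grid)
        z2 = arm_zscores(_nc("s", 3.0 * sample.values), panel2).z
        assert np.allclose(z1, z2)


class TestSummarizeCnvEvents:
    def _profile(self, arms, z):
        from procad.panel import ArmZProfile

        return ArmZProfile("s", arms, np.asarray(z, dtype=float))

    def test_flat_profile_negative(self):
        cs = summarize_cnv_events(self._profile(["chr1p", "chr1q"], [0.0, 0.0]), 2.5)
        assert cs.n_events == 0 and not cs.positive

    def test_gain_and_loss_called_with_direction(self):
        cs = summarize_cnv_events(
            self._profile(["chr8q", "chr18q", "chr2p"], [3.0, -2.6, 1.0]), 2.5
        )
        assert cs.n_events == 2 and cs.positive
        assert {(c.arm, c.direction) for c in cs.calls} == {
            ("chr8q", "gain"),
            ("chr18q", "loss"),
        }

    def test_strict_boundary_is_inclusive_at_cutoff(self):
        below = summarize_cnv_events(self._profile(["a"], [2.49]), 2.5)
        at = summarize_cnv_events(self._profile(["a"], [2.5]), 2.5)
        assert not below.positive and at.positive
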