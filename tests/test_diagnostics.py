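"""Conditional tables, tolerance bands, MAD curves, envelopes, bias report."""

import numpy as np
import pytest

from fmx.chemio import MoleculeRecord
from fmx.diagnostics import (
    band_compliance,
    bias_similarity_report,
    conditional_score_table,
    mad_at_quantile,
    mad_curve,
    tolerance_band,
    trajectory_summary,
)
from fmx.graphga import Trajectory, TrajectoryStep


def rec(smiles):
    return MoleculeRecord.from_smiles(smiles)


class TestConditionalTable:
    def test_single_bin_holds_everything(self):
        table = conditional_score_table([0.1, 0.5, 0.9], [0.2, 0.3, 0.4], n_bins=1)
        assert len(table.samples) == 1 and len(table.samples[0]) == 3

    def test_manual_binning_oracle(self):
        table = conditional_score_table([0.1, 0.2, 0.8], [0.2, 0.4, 0.9], n_bins=2)
        assert sorted(table.samples[0]) == [0.2, 0.4]
        assert list(table.samples[1]) == [0.9]

    def test_counts_partition_input(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0, 1, 500)
        table = conditional_score_table(s, s, n_bins=25)
        assert table.counts.sum() == 500

    def test_boundary_one_goes_to_last_bin(self):
        table = conditional_score_table([1.0], [0.5], n_bins=4)
        assert len(table.samples[3]) == 1

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            conditional_score_table([], [], n_bins=5)


def flat_trajectory(score_vectors):
    return [np.asarray(v, dtype=float) for v in score_vectors]


class TestToleranceBand:
    def test_degenerate_constant_controls(self):
        table = conditional_score_table([0.1, 0.5, 0.9], [0.7, 0.7, 0.7], n_bins=5)
        band = tolerance_band(table, flat_trajectory([[0.2, 0.6], [0.8]]), 10, 0.95, seed=0)
        assert np.allclose(band.lower, 0.7) and np.allclose(band.upper, 0.7)

    def test_two_point_bin_quantiles(self):
        # single occupied bin with sample {0.2, 0.4}: a large pooled draw has
        # empirical 2.5/97.5 quantiles at the extremes of the support
        table = conditional_score_table([0.5] * 2, [0.2, 0.4], n_bins=1)
        band = tolerance_band(table, flat_trajectory([[0.5] * 200]), 10, 0.95, seed=1)
        assert band.lower[0] == pytest.approx(0.2)
        assert band.upper[0] == pytest.approx(0.4)

    def test_empty_bin_falls_back_to_nearest(self):
        table = conditional_score_table([0.05, 0.95], [0.1, 0.9], n_bins=10)
        band = tolerance_band(table, flat_trajectory([[0.5]]), 50, 0.95, seed=0)
        # bin 5 empty; nearest occupied bins hold 0.1 or 0.9
        assert band.lower[0] in (0.1, 0.9)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        table = conditional_score_table(
            rng.uniform(0, 1, 1000), rng.uniform(0, 1, 1000), n_bins=25
        )
        traj = flat_trajectory([rng.uniform(0, 1, 50) for _ in range(5)])
        narrow = tolerance_band(table, traj, 10, 0.50, seed=9)
        wide = tolerance_band(table, traj, 10, 0.95, seed=9)
        assert np.all(wide.lower <= narrow.lower) and np.all(wide.upper >= narrow.upper)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(4)
        table = conditional_score_table(rng.uniform(0, 1, 200), rng.uniform(0, 1, 200), 25)
        traj = flat_trajectory([rng.uniform(0, 1, 20)])
        b1 = tolerance_band(table, traj, 10, 0.95, seed=5)
        b2 = tolerance_band(table, traj, 10, 0.95, seed=5)
        assert np.array_equal(b1.lower, b2.lower) and np.array_equal(b1.upper, b2.upper)

    def test_coverage_when_law_matches(self):
        # controls truly drawn from the estimated conditional law fall inside
        # the 95% band with frequency ~0.95
        rng = np.random.default_rng(0)
        s_opt_ref = rng.uniform(0, 1, 4000)
        s_ctrl_ref = np.clip(0.7 * s_opt_ref + rng.normal(0, 0.08, 4000), 0, 1)
        table = conditional_score_table(s_opt_ref, s_ctrl_ref, 25)
        traj = flat_trajectory([rng.uniform(0.2, 0.9, 150) for _ in range(40)])
        band = tolerance_band(table, traj, 10, 0.95, seed=7)
        inside = total = 0
        for t, s in enumerate(traj):
            bins = table.bin_of(s)
            true_ctrl = np.array([rng.choice(table.samples[b]) for b in bins])
            inside += ((true_ctrl >= band.lower[t]) & (true_ctrl <= band.upper[t])).sum()
            total += len(s)
        coverage = inside / total
        se = np.sqrt(0.95 * 0.05 / total)
        assert abs(coverage - 0.95) <= 3 * se + 1 / np.sqrt(total)


class TestMADCurve:
    def test_identity_controls_zero(self):
        s = np.linspace(0.1, 0.9, 20)
        curve = mad_curve(s, s)
        assert np.allclose(curve.values, 0.0)

    def test_worked_examples(self):
        s_opt = [0.1, 0.4, 0.6, 0.9]
        s_dc = [0.1, 0.2, 0.3, 0.5]
        assert mad_curve(s_opt, s_dc, [0.5]).values[0] == pytest.approx(0.35)
        assert mad_curve(s_opt, s_dc, [0.89]).values[0] == pytest.approx(0.4)

    def test_curve_stops_at_x_max(self):
        curve = mad_curve([0.1, 0.4], [0.1, 0.2], thresholds=[0.0, 0.3, 0.5, 0.9])
        assert curve.x_max == pytest.approx(0.4)
        assert curve.thresholds.max() < 0.4

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(5, 200))
            s_opt = rng.uniform(0, 1, n)
            s_ctrl = rng.uniform(0, 1, n)
            thresholds = rng.uniform(0, 1, 15)
            curve = mad_curve(s_opt, s_ctrl, thresholds)
            for x, v in zip(curve.thresholds, curve.values):
                diffs = [so - sc for so, sc in zip(s_opt, s_ctrl) if so > x]
                assert v == pytest.approx(sum(diffs) / len(diffs), abs=1e-12)

    def test_absolute_mode(self):
        curve = mad_curve([0.5, 0.9], [0.8, 0.1], thresholds=[0.0], absolute=True)
        assert curve.values[0] == pytest.approx((0.3 + 0.8) / 2)

    def test_mad_at_quantile_top_decile(self):
        s_opt = np.linspace(0, 1, 100)
        s_ctrl = s_opt - 0.2
        assert mad_at_quantile(s_opt, s_ctrl, 0.9) == pytest.approx(0.2)


def make_run(means, channel_value=None):
    steps = []
    for t, m in enumerate(means):
        v = np.full(4, m)
        c = np.full(4, channel_value) if channel_value is not None else None
        steps.append(TrajectoryStep(t, [rec("C")] * 4, v, s_mc=c, s_dc=c))
    return Trajectory(steps)


class TestTrajectorySummary:
    def test_degenerate_constant_runs(self):
        runs = [make_run([0.4, 0.4, 0.4]) for _ in range(5)]
        summary = trajectory_summary(runs)
        opt = summary.channel("opt")
        assert np.allclose(opt["median"], 0.4)
        assert np.allclose(opt["q75"] - opt["q25"], 0.0)

    def test_two_run_median_is_midpoint(self):
        summary = trajectory_summary([make_run([0.2, 0.2]), make_run([0.4, 0.4])])
        assert np.allclose(summary.channel("opt")["median"], 0.3)

    def test_permutation_invariant(self):
        runs = [make_run([0.1 * k, 0.2 * k]) for k in range(1, 6)]
        s1 = trajectory_summary(runs)
        s2 = trajectory_summary(runs[::-1])
        assert s1.table.equals(s2.table)

    def test_mismatched_grids_raise(self):
        with pytest.raises(ValueError):
            trajectory_summary([make_run([0.1]), make_run([0.1, 0.2])])


class TestBandCompliance:
    def test_inside_everywhere(self):
        from fmx.diagnostics import ToleranceBand

        band = ToleranceBand(np.arange(3), np.zeros(3), np.ones(3), 0.95, 10)
        frac, trace = band_compliance(np.full(3, 0.5), band)
        assert frac == 1.0 and trace.all()

    def test_below_everywhere(self):
        from fmx.diagnostics import ToleranceBand

        band = ToleranceBand(np.arange(3), np.full(3, 0.5), np.ones(3), 0.95, 10)
        frac, trace = band_compliance(np.full(3, 0.2), band)
        assert frac == 0.0 and not trace.any()


class TestBiasReport:
    def test_identical_splits_identical_similarities(self):
        heldout = [rec("CCO"), rec("CCCO"), rec("c1ccccc1")]
        ref = [rec("CCN"), rec("CCC")]
        report = bias_similarity_report(heldout, [0.9, 0.5, 0.1], ref, ref, top_pct=80)
        assert np.array_equal(report.sim_split1, report.sim_split2)

    def test_copies_of_split1_have_similarity_one(self):
        split1 = [rec("CCO"), rec("c1ccccc1")]
        split2 = [rec("CCCCCCCCCC")]
        heldout = [rec("CCO"), rec("c1ccccc1")]
        report = bias_similarity_report(heldout, [0.9, 0.8], split1, split2, top_pct=99)
        assert np.allclose(report.sim_split1, 1.0)
        assert report.median_gap > 0

    def test_planted_scaffold_bias(self):
        # split1 uniquely contains the sulfonamide family that scores high
        fam = [rec(f"NS(=O)(=O)c1ccccc1{'C' * n}") for n in range(1, 6)]
        alk = [rec("C" * n) for n in range(3, 8)]
        heldout = [rec("NS(=O)(=O)c1ccccc1CCCCCCC"), rec("CCCCCCCCCCCC")]
        report = bias_similarity_report(heldout, [0.95, 0.1], fam, alk, top_pct=50)
        assert np.median(report.sim_split1) > np.median(report.sim_split2)

    def test_selection_size(self):
        heldout = [rec("C" * n) for n in range(1, 41)]
        s = np.linspace(0, 1, 40)
        report = bias_similarity_report(heldout, s, heldout[:5], heldout[5:], top_pct=5)
        assert len(report.smiles) == 2  # ceil(40 * 5%)

    def test_invalid_top_pct(self):
        with pytest.raises(ValueError):
            bias_similarity_report([rec("C")], [0.5], [rec("C")], [rec("C")], top_pct=0)
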