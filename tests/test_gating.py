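"""Gating steps against counting, density and ECDF oracles."""

import numpy as np
import pandas as pd
import pytest

from flowdisp._density import kde_1d
from flowdisp.core import CHANNELS, NoValleyError
from flowdisp.gating import (
    GatingConfig,
    apply_gate,
    dapi_stain_threshold,
    density_gate_2d,
    filter_saturated,
    g1_threshold,
    pooled_channel_bounds,
    replicate_outlier_scores,
    run_gating,
    size_correct,
    warp_align,
)
from flowdisp.simulate import SimCohortConfig, SimSampleConfig, simulate_cohort, simulate_sample_events

from conftest import make_table


def ks_statistic_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Brute-force two-sample KS statistic from the two ECDFs."""
    both = np.sort(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), both, side="right") / x.size
    fy = np.searchsorted(np.sort(y), both, side="right") / y.size
    return float(np.abs(fx - fy).max())


def _mode(x):
    grid, dens = kde_1d(np.asarray(x, dtype=float))
    return grid[int(np.argmax(dens))]


class TestChannelBounds:
    def test_interpolated_percentiles(self):
        rng = np.random.default_rng(0)
        t = make_table(100, rng, dapi=np.arange(1.0, 101.0))
        b = pooled_channel_bounds([t], "DAPI")
        assert b.lower == pytest.approx(5.95)
        assert b.upper == pytest.approx(95.05)
        assert b.shift == 0.0

    def test_negative_lower_bound_sets_shift(self):
        rng = np.random.default_rng(0)
        values = np.linspace(-10.0, 90.0, 1000)  # 5th percentile at -5
        t = make_table(1000, rng, fl=values)
        b = pooled_channel_bounds([t], "FL")
        assert b.lower == pytest.approx(-5.0, abs=0.01)
        assert b.shift == pytest.approx(abs(b.lower))

    def test_degenerate_inputs_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            pooled_channel_bounds([], "FL")
        t = make_table(50, rng, fl=np.full(50, 3.0))
        with pytest.raises(ValueError):
            pooled_channel_bounds([t], "FL")


class TestFilterSaturated:
    def test_counting_oracle_on_uniform_channels(self):
        """Independent uniform channels retain ~0.9^5; counts match a direct oracle."""
        rng = np.random.default_rng(1)
        n = 20000
        t = make_table(
            n, rng,
            fsc=rng.uniform(0, 1, n), ssc=rng.uniform(0, 1, n),
            fsc_w=rng.uniform(0, 1, n), dapi=rng.uniform(0, 1, n),
            fl=rng.uniform(0, 1, n),
        )
        bounds = [pooled_channel_bounds([t], ch) for ch in CHANNELS]
        out = filter_saturated(t, bounds)
        keep = np.ones(n, dtype=bool)
        for b in bounds:
            v = t.channel(b.channel)
            keep &= (v >= b.lower) & (v <= b.upper)
        assert out.n_events == keep.sum()
        assert abs(out.n_events / n - 0.9**5) < 0.02

    def test_single_event_above_upper_removed(self):
        rng = np.random.default_rng(2)
        fl = np.concatenate([np.linspace(0, 1, 99), [100.0]])
        t = make_table(100, rng, fl=fl)
        bounds = [
            pooled_channel_bounds([t], ch) if ch != "FL"
            else type(pooled_channel_bounds([t], ch))("FL", 0.0, 2.0)
            for ch in CHANNELS
        ]
        out = filter_saturated(t, bounds)
        assert 100.0 not in out.channel("FL")

    def test_shift_applied_after_filtering(self):
        rng = np.random.default_rng(3)
        t = make_table(1000, rng, fl=rng.normal(0, 1, 1000))
        bounds = [pooled_channel_bounds([t], ch) for ch in CHANNELS]
        out = filter_saturated(t, bounds)
        assert (out.channel("FL") >= 0).all()


class TestDapiThreshold:
    def test_valley_between_debris_and_stained(self):
        """Threshold lands between the near-zero debris and the stained peak.

        Oracle: grid-evaluated density, argmin between the two argmax.
        """
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 0.3, 2000), rng.normal(5, 0.5, 8000)])
        thr = dapi_stain_threshold(x)
        assert 1.0 < thr < 4.0
        grid, dens = kde_1d(x)
        lo = int(np.argmax(dens[grid < 2]))
        hi = int(np.argmax(np.where(grid > 2, dens, -1)))
        oracle = grid[lo + int(np.argmin(dens[lo:hi]))]
        assert abs(thr - oracle) < 0.2
        assert (x[x > thr] > thr).all()

    def test_unimodal_raises(self):
        rng = np.random.default_rng(5)
        with pytest.raises(NoValleyError):
            dapi_stain_threshold(rng.normal(100, 5, 5000))


class TestDensityGate:
    def test_target_mass_contained(self, cohort):
        _, tables, _ = cohort
        gate = density_gate_2d(tables[:6], "FSC-A", "SSC-A", 0.75)
        x = np.concatenate([t.channel("FSC-A") for t in tables[:6]])
        y = np.concatenate([t.channel("SSC-A") for t in tables[:6]])
        frac = gate.contains(x, y).mean()
        assert 0.75 <= frac <= 0.78

    def test_doublets_fall_outside_width_gate(self):
        """At 5% simulated doublets the 80% FSC-A/FSC-W gate excludes >=90%."""
        cfg = SimSampleConfig(frac_doublets=0.05)
        t = simulate_sample_events(cfg, 20000, seed=6, keep_truth=True)
        gate = density_gate_2d([t], "FSC-A", "FSC-W", 0.80)
        inside = gate.contains(t.channel("FSC-A"), t.channel("FSC-W"))
        dbl = t.data["doublet"].to_numpy()
        assert (~inside[dbl]).mean() >= 0.90

    def test_gaussian_cloud_contains_centroid(self):
        rng = np.random.default_rng(7)
        t = make_table(10000, rng, fsc=rng.normal(100, 10, 10000), ssc=rng.normal(50, 5, 10000))
        gate = density_gate_2d([t], "FSC-A", "SSC-A", 0.75)
        assert gate.contains(np.array([100.0]), np.array([50.0]))[0]

    def test_apply_gate_limits(self):
        rng = np.random.default_rng(8)
        t = make_table(500, rng)
        gate = density_gate_2d([t], "FSC-A", "SSC-A", 0.75)
        everything = type(gate)(
            "FSC-A", "SSC-A", 0.99, gate.x_edges, gate.y_edges,
            np.ones_like(gate.inside), 1.0,
        )
        assert apply_gate(t, everything).n_events == t.n_events
        nothing = type(gate)(
            "FSC-A", "SSC-A", 0.01, gate.x_edges, gate.y_edges,
            np.zeros_like(gate.inside), 0.0,
        )
        assert apply_gate(t, nothing).n_events == 0

    def test_self_gate_retention(self):
        rng = np.random.default_rng(9)
        t = make_table(10000, rng)
        gate = density_gate_2d([t], "FSC-A", "SSC-A", 0.75)
        out = apply_gate(t, gate)
        assert 0.70 <= out.n_events / t.n_events <= 0.80

    def test_too_few_events_error(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError):
            density_gate_2d([make_table(50, rng)], "FSC-A", "SSC-A", 0.75)


class TestG1Threshold:
    def test_bimodal_dapi_keeps_g1(self):
        """Labelled G1 (mode 100) vs G2 (mode 200): >=95% of G1 retained."""
        rng = np.random.default_rng(11)
        g1 = rng.normal(100, 10, 7000)
        g2 = rng.normal(200, 10, 2000)
        s = rng.uniform(120, 180, 1000)
        thr = g1_threshold(np.concatenate([g1, g2, s]))
        assert 100 < thr < 200
        assert (g1 < thr).mean() >= 0.95
        assert (g2 < thr).mean() <= 0.05

    def test_pure_g1_keeps_nearly_all(self):
        rng = np.random.default_rng(12)
        g1 = rng.normal(100, 10, 5000)
        thr = g1_threshold(g1)
        assert thr > _mode(g1)
        assert (g1 < thr).mean() >= 0.99

    def test_postcondition_and_min_events(self):
        rng = np.random.default_rng(13)
        d = rng.normal(100, 10, 5000)
        thr = g1_threshold(d)
        assert d[d < thr].max() < thr
        with pytest.raises(ValueError):
            g1_threshold(d[:50])


class TestSizeCorrect:
    def test_zero_coupling_is_identity_limit(self):
        rng = np.random.default_rng(14)
        t = make_table(5000, rng)
        out = size_correct(t)
        assert np.abs(out.channel("FL") - t.channel("FL")).max() < 0.05

    def test_removes_planted_coupling(self):
        """FL = 0.5 log(FSC-A) + noise: post-correction OLS slope < 0.02."""
        rng = np.random.default_rng(15)
        n = 10000
        log_fsc = rng.normal(10, 0.3, n)
        fl = 0.5 * log_fsc + rng.normal(0, 0.2, n)
        t = make_table(n, rng, fl=fl, fsc=np.exp(log_fsc))
        out = size_correct(t)
        slope = np.polyfit(np.log(out.channel("FSC-A")), out.channel("FL"), 1)[0]
        assert abs(slope) < 0.02
        assert out.channel("FL").mean() == pytest.approx(fl.mean(), abs=1e-2)

    def test_singular_design_skipped(self):
        rng = np.random.default_rng(16)
        t = make_table(1000, rng, fsc=np.full(1000, 5e4))
        out = size_correct(t)
        assert np.array_equal(out.channel("FL"), t.channel("FL"))


class TestWarpAlign:
    def test_identical_replicates_identity(self):
        rng = np.random.default_rng(17)
        fl = rng.normal(5, 0.5, 5000)
        a = make_table(5000, rng, fl=fl.copy(), sample_id="a", line_id="L", protein="P")
        b = make_table(5000, rng, fl=fl.copy(), sample_id="b", line_id="L", protein="P")
        wa, wb = warp_align([a, b])
        assert np.allclose(wa.channel("FL"), fl)
        assert np.allclose(wb.channel("FL"), fl)

    def test_shift_is_removed(self):
        """A +0.3 shifted replicate aligns to < 0.05 mode difference."""
        rng = np.random.default_rng(18)
        a = make_table(5000, rng, fl=rng.normal(5, 0.5, 5000), sample_id="a")
        b = make_table(5000, rng, fl=rng.normal(5, 0.5, 5000) + 0.3, sample_id="b")
        wa, wb = warp_align([a, b])
        assert abs(_mode(wa.channel("FL")) - _mode(wb.channel("FL"))) < 0.05

    def test_monotone_and_cv_preserving(self):
        """Order preserved; CV of a single-mode replicate changes < 1%."""
        rng = np.random.default_rng(19)
        group = [
            make_table(5000, rng, fl=rng.normal(5, 0.5, 5000), sample_id=f"s{i}")
            for i in range(3)
        ]
        warped = warp_align(group)
        for before, after in zip(group, warped):
            order = np.argsort(before.channel("FL"))
            assert (np.diff(after.channel("FL")[order]) >= 0).all()
            cv0 = before.channel("FL").std(ddof=1) / before.channel("FL").mean()
            cv1 = after.channel("FL").std(ddof=1) / after.channel("FL").mean()
            assert abs(cv1 - cv0) / cv0 < 0.01


class TestReplicateOutliers:
    def test_identical_replicates_have_zero_k(self):
        rng = np.random.default_rng(20)
        fl = rng.normal(5, 0.5, 2000)
        group = [make_table(2000, rng, fl=fl.copy(), sample_id=f"r{i}") for i in range(3)]
        scores = replicate_outlier_scores(group)
        assert all(k == 0.0 for k, _ in scores)

    def test_k_equals_ecdf_oracle(self):
        rng = np.random.default_rng(21)
        group = [make_table(1500, rng, sample_id=f"r{i}") for i in range(4)]
        scores = replicate_outlier_scores(group)
        fls = [g.channel("FL") for g in group]
        for i, (k, _) in enumerate(scores):
            partners = [j for j in range(4) if j != i]
            oracle = np.mean([ks_statistic_oracle(fls[i], fls[j]) for j in partners])
            assert abs(k - oracle) < 1e-12

    def test_shifted_replicate_scores_highest(self):
        rng = np.random.default_rng(22)
        group = [
            make_table(2000, rng, fl=rng.normal(5, 0.5, 2000), sample_id="a"),
            make_table(2000, rng, fl=rng.normal(5, 0.5, 2000), sample_id="b"),
            make_table(2000, rng, fl=rng.normal(6.5, 0.5, 2000), sample_id="c"),
        ]
        scores = replicate_outlier_scores(group)
        assert np.argmax([k for k, _ in scores]) == 2
        shuffled = replicate_outlier_scores(group[::-1])
        assert shuffled[0][0] == pytest.approx(scores[2][0], abs=1e-12)

    def test_small_group_undefined(self):
        rng = np.random.default_rng(23)
        group = [make_table(500, rng, sample_id=f"r{i}") for i in range(2)]
        scores = replicate_outlier_scores(group)
        assert all(np.isnan(k) and not flag for k, flag in scores)


class TestRunGating:
    def test_monotone_retention_and_min_events(self, gated_cohort):
        gated, report = gated_cohort
        assert gated
        for sample in gated:
            assert sample.n_events > 1000
        for trace in report.retention.values():
            counts = [c for _, c in trace]
            assert counts == sorted(counts, reverse=True)

    def test_small_sample_dropped_with_reason(self, cohort):
        _, tables, _ = cohort
        rng = np.random.default_rng(24)
        tiny = make_table(
            900, rng, sample_id="tiny", line_id="LX", protein="SIM", batch_id="batch0"
        )
        _, report = run_gating(
            [tiny] + list(tables[:3]),
            GatingConfig(saturation=False, dapi_filter=False, size_gate=False,
                         doublet_gate=False, g1_gate=False, outlier_filter=False),
        )
        assert report.dropped["tiny"] == "min-events"

    def test_noise_free_retention_compounds_gate_fractions(self):
        """Without simulator noise, retention >= 0.75 * 0.80 * frac_G1."""
        sample_cfg = SimSampleConfig(frac_doublets=0.0, frac_unstained=0.0)
        cfg = SimCohortConfig(
            n_lines=2, n_replicates=3, n_events=10000, n_null_snps=2,
            seed=25, sample=sample_cfg,
        )
        _, tables, _ = simulate_cohort(cfg)
        gated, report = run_gating(
            tables, GatingConfig(saturation=False, dapi_filter=False, outlier_filter=False)
        )
        frac_g1 = sample_cfg.frac_g1 / (
            sample_cfg.frac_g1 + sample_cfg.frac_s + sample_cfg.frac_g2
        )
        floor = 0.75 * 0.80 * frac_g1 * 0.93  # sampling slack
        for sample in gated:
            assert sample.n_events / 10000 >= floor
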