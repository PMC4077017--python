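"""Epoching, pointwise reliability Z, latency ranges, window containment."""

import numpy as np
import pytest
from scipy import stats

from eegfmri.icselect import (
    AnalysisWindows, ConditionStats, LatencyRange, StatisticError, ZSeries,
    condition_stats, epoch_units, extract_ranges, pointwise_z,
    select_for_windows, select_nogo_ics,
)
from eegfmri.synth import SimConfig, gen_paradigm


@pytest.fixture(scope="module")
def events():
    return gen_paradigm(SimConfig(seed=42, n_trials=120))


class TestEpoching:
    def test_epoch_geometry(self, events):
        rng = np.random.default_rng(0)
        ep = epoch_units(rng.standard_normal((3, 13000)), 100.0, events)
        assert ep.values.shape[1:] == (3, 120)  # 1200 ms at 100 Hz
        assert ep.times[0] == pytest.approx(-0.2)
        # trial at onset 0 has no baseline samples and is dropped
        assert ep.n_trials == len(events) - 1
        assert 0 not in ep.trial_rows

    def test_constant_signal_zero_after_baseline(self, events):
        ep = epoch_units(np.full((2, 13000), 7.3), 100.0, events)
        np.testing.assert_allclose(ep.values, 0.0, atol=1e-9)

    def test_baseline_mean_is_zero(self, events):
        rng = np.random.default_rng(1)
        ep = epoch_units(rng.standard_normal((2, 13000)), 100.0, events)
        bmask = ep.times < 0
        np.testing.assert_allclose(
            ep.values[:, :, bmask].mean(axis=2), 0.0, atol=1e-9
        )

    def test_matches_loop_oracle(self, events):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 13000))
        ep = epoch_units(x, 100.0, events)
        for k, row in enumerate(ep.trial_rows[:10]):
            s0 = int(round(events.onsets[row] * 100)) - 20
            seg = x[:, s0:s0 + 120]
            seg = seg - seg[:, :20].mean(axis=1, keepdims=True)
            np.testing.assert_allclose(ep.values[k], seg, atol=1e-12)


class TestConditionStats:
    def test_hand_calculation(self):
        ep_vals = np.array([[[1.0]], [[3.0]]])  # two epochs, one unit, one time
        import eegfmri.icselect as m

        class TinyEp:
            values = ep_vals
            conditions = np.array(["go_correct", "go_correct"], dtype=object)
            in_condition = m.EpochSet.in_condition

        st = condition_stats(TinyEp(), "go_correct")
        assert st.mean[0, 0] == pytest.approx(2.0)
        assert st.var[0, 0] == pytest.approx(2.0)  # unbiased
        assert st.n == 2

    def test_four_event_type_averages(self, events):
        rng = np.random.default_rng(3)
        ep = epoch_units(rng.standard_normal((2, 13000)), 100.0, events)
        produced = [
            condition_stats(ep, c).condition
            for c in ("go_correct", "nogo_correct", "omission", "commission")
            if (ep.conditions == c).sum() >= 2
        ]
        assert {"go_correct", "nogo_correct"} <= set(produced)

    def test_matches_loop_oracle(self, events):
        rng = np.random.default_rng(4)
        ep = epoch_units(rng.standard_normal((2, 13000)), 100.0, events)
        st = condition_stats(ep, "nogo_correct")
        x = ep.values[ep.conditions == "nogo_correct"]
        m = np.zeros_like(st.mean)
        v = np.zeros_like(st.var)
        for u in range(x.shape[1]):
            for t in range(x.shape[2]):
                col = x[:, u, t]
                m[u, t] = col.sum() / len(col)
                v[u, t] = ((col - m[u, t]) ** 2).sum() / (len(col) - 1)
        np.testing.assert_allclose(st.mean, m, atol=1e-12)
        np.testing.assert_allclose(st.var, v, atol=1e-12)

    def test_single_epoch_rejected(self):
        with pytest.raises(StatisticError):
            ConditionStats(mean=np.zeros((1, 1)), var=np.zeros((1, 1)), n=1)


class TestPointwiseZ:
    def test_identical_conditions_give_zero(self):
        rng = np.random.default_rng(5)
        m = rng.standard_normal((2, 50))
        v = rng.random((2, 50)) + 0.5
        a = ConditionStats(mean=m, var=v, n=90)
        b = ConditionStats(mean=m.copy(), var=v.copy(), n=90)
        zs = pointwise_z(a, b)
        np.testing.assert_array_equal(zs.z, 0.0)
        assert zs.df == 89

    def test_threshold_anchor(self):
        """t = 2.609 at n_ref = 90 standardizes to the Z = 0.275 threshold."""
        a = ConditionStats(mean=np.array([[2.609]]), var=np.array([[90.0]]), n=90)
        zs = pointwise_z(a)  # one-sample: t = 2.609 / sqrt(90/90) = 2.609
        assert zs.z[0, 0] == pytest.approx(2.609 / np.sqrt(90), abs=1e-12)
        assert zs.z[0, 0] == pytest.approx(0.275, abs=5e-4)

    def test_welch_formula_oracle(self):
        rng = np.random.default_rng(6)
        xa = rng.standard_normal((90, 1, 64))
        xb = 2 * rng.standard_normal((40, 1, 64))
        a = ConditionStats(xa.mean(0), xa.var(0, ddof=1), 90)
        b = ConditionStats(xb.mean(0), xb.var(0, ddof=1), 40)
        zs = pointwise_z(a, b)
        t_oracle = stats.ttest_ind(xa, xb, axis=0, equal_var=False).statistic
        np.testing.assert_allclose(zs.z, t_oracle / np.sqrt(40), atol=1e-10)
        assert zs.n_ref == 40 and zs.df == 39

    def test_null_tail_calibration(self):
        """Fraction of |Z| > 0.275 on null data matches the t tail."""
        rng = np.random.default_rng(7)
        n, pts = 90, 10000
        xa = rng.standard_normal((n, 1, pts))
        xb = rng.standard_normal((n, 1, pts))
        a = ConditionStats(xa.mean(0), xa.var(0, ddof=1), n)
        b = ConditionStats(xb.mean(0), xb.var(0, ddof=1), n)
        zs = pointwise_z(a, b)
        frac = float((np.abs(zs.z) > 0.275).mean())
        p_true = 2 * stats.t.sf(0.275 * np.sqrt(n), 2 * n - 2)
        se = np.sqrt(p_true * (1 - p_true) / pts)
        assert abs(frac - p_true) < 3 * se

    def test_zero_variance_handling(self):
        a = ConditionStats(mean=np.array([[0.0, 1.0]]),
                           var=np.array([[0.0, 0.0]]), n=10)
        b = ConditionStats(mean=np.array([[0.0, 0.0]]),
                           var=np.array([[0.0, 0.0]]), n=10)
        zs = pointwise_z(a, b)
        assert zs.z[0, 0] == 0.0
        assert np.isinf(zs.z[0, 1])


def zseries(z_rows, dt=0.01, t0=0.0, n_ref=90):
    z = np.atleast_2d(np.asarray(z_rows, dtype=float))
    times = t0 + np.arange(z.shape[1]) * dt
    return ZSeries(z=z, times=times, mode="two_sample", n_ref=n_ref, df=n_ref - 1)


def stats_like(z, mean_scale=1.0):
    m = np.full_like(np.atleast_2d(z), mean_scale, dtype=float)
    return ConditionStats(mean=m, var=np.ones_like(m), n=90)


class TestExtractRanges:
    def test_simple_threshold_run(self):
        zs = zseries([0.0, 0.3, 0.3, 0.0])
        out = extract_ranges(zs, stats_like(zs.z, 2.0), stats_like(zs.z, 1.0))
        assert len(out) == 1
        assert out[0].t_on == pytest.approx(0.01)
        assert out[0].t_off == pytest.approx(0.03)

    def test_all_subthreshold_empty(self):
        zs = zseries([0.1, -0.2, 0.27, 0.0])
        assert extract_ranges(zs, stats_like(zs.z), stats_like(zs.z)) == []

    def test_dominance_rule(self):
        zs = zseries([0.4, 0.4])
        # Go average larger in magnitude: discarded
        out = extract_ranges(zs, stats_like(zs.z, -1.0), stats_like(zs.z, -3.0))
        assert out == []
        # Nogo average larger: kept, polarity from the Nogo sign
        out = extract_ranges(zs, stats_like(zs.z, -3.0), stats_like(zs.z, -1.0))
        assert len(out) == 1
        assert out[0].polarity == -1
        assert out[0].dominant_condition == "Nogo"

    def test_visual_mode_has_no_dominance_filter(self):
        zs = zseries([0.4, 0.4])
        out = extract_ranges(zs, stats_like(zs.z, -2.0), mode="visual")
        assert len(out) == 1 and out[0].polarity == -1

    def test_union_matches_naive_scan(self):
        rng = np.random.default_rng(8)
        z = rng.standard_normal((4, 200)) * 0.2
        times = -0.2 + np.arange(200) * 0.01
        zs = ZSeries(z=z, times=times, mode="two_sample", n_ref=90, df=89)
        out = extract_ranges(zs, stats_like(z, 2.0), stats_like(z, 1.0))
        for ic in range(4):
            covered = set()
            for r in out:
                if r.ic == ic:
                    covered |= {
                        i for i, t in enumerate(times)
                        if r.t_on <= t < r.t_off
                    }
            naive = {
                i for i in range(200)
                if times[i] >= 0 and abs(z[ic, i]) > 0.275
            }
            assert covered == naive

    def test_prestimulus_span_ignored(self):
        times = -0.2 + np.arange(40) * 0.01
        z = np.zeros((1, 40))
        z[0, :20] = 0.9  # entirely pre-stimulus
        zs = ZSeries(z=z, times=times, mode="two_sample", n_ref=90, df=89)
        assert extract_ranges(zs, stats_like(z), stats_like(z, 0.5)) == []


class TestWindowContainment:
    def test_windows_from_median_rt(self):
        w = AnalysisWindows.from_median_rt(0.400)
        assert w.early == pytest.approx((0.200, 0.400))
        assert w.late == pytest.approx((0.300, 0.700))
        assert w.visual == pytest.approx((0.090, 0.140))

    def make_range(self, t_on, t_off):
        return LatencyRange(ic=0, t_on=t_on, t_off=t_off, polarity=1)

    def test_overlap_range_tagged_both(self):
        w = AnalysisWindows.from_median_rt(0.400)
        out = select_for_windows([self.make_range(0.32, 0.38)], w)
        assert out[0].windows == ("early", "late")

    def test_strict_containment_drops_early_starter(self):
        w = AnalysisWindows.from_median_rt(0.400)
        assert select_for_windows([self.make_range(0.15, 0.25)], w) == []

    def test_range_in_early_only(self):
        w = AnalysisWindows.from_median_rt(0.400)
        out = select_for_windows([self.make_range(0.25, 0.35)], w)
        assert out[0].windows == ("early",)

    def test_boundary_containment_inclusive(self):
        w = AnalysisWindows.from_median_rt(0.400)
        out = select_for_windows([self.make_range(0.200, 0.400)], w)
        assert "early" in out[0].windows

    def test_empty_early_window_rejected(self):
        with pytest.raises(StatisticError):
            AnalysisWindows.from_median_rt(0.150)


class TestSelectionInvariants:
    def test_sign_flip_invariance(self, sim_run, ic_epochs, selections):
        """Flipping an IC's sign flips polarity tags but leaves the
        polarity-corrected amplitudes identical."""
        from eegfmri.features import single_trial_amplitudes
        import dataclasses

        cfg, events, *_ = sim_run
        windows, nogo, _ = selections
        assert any("early" in r.windows for r in nogo)
        flipped = dataclasses.replace(
            ic_epochs, values=ic_epochs.values * -1.0
        )
        nogo_f = select_nogo_ics(flipped, windows)
        nogo_all = select_nogo_ics(ic_epochs, windows)
        key = lambda rs: sorted((r.ic, r.t_on, r.t_off) for r in rs)
        assert key(nogo_f) == key(nogo_all)
        pol = {(r.ic, r.t_on): r.polarity for r in nogo_all}
        for r in nogo_f:
            assert r.polarity == -pol[(r.ic, r.t_on)]
        a = single_trial_amplitudes(ic_epochs, nogo_all, "early", events)
        b = single_trial_amplitudes(flipped, nogo_f, "early", events)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_planted_source_selected_for_early_window(
        self, sim_run, decomposition, selections
    ):
        from conftest import best_matching_ic

        _, _, _, truth, _ = sim_run
        _, nogo, _ = selections
        best, cos = best_matching_ic(
            decomposition, truth.source_topographies["inhibition"])
        assert cos > 0.9
        assert any(r.ic == best and "early" in r.windows for r in nogo)

    def test_null_specificity_far_below_rough_noise_regime(self):
        """Without a Nogo-specific source, false early selections are rare
        enough that the containment rule is doing real work (white-noise
        variability would make every run select something)."""
        from eegfmri.features import median_rt
        from conftest import scaled_config
        from eegfmri.synth import gen_eeg

        n_any = 0
        seeds = range(900, 910)
        for seed in seeds:
            cfg = scaled_config(seed, inhibition_gain=0.0, n_channels=8)
            ev = gen_paradigm(cfg)
            rec, _ = gen_eeg(ev, cfg)
            ep = epoch_units(rec.data[:6], rec.sfreq, ev)
            w = AnalysisWindows.from_median_rt(median_rt(ev))
            sel = select_nogo_ics(ep, w)
            n_any += any("early" in r.windows for r in sel)
        assert n_any / len(seeds) <= 0.5
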