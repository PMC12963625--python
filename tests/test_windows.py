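"""Sliding-window metrics: completeness, trimming, means, window grid."""

import numpy as np
import pandas as pd
import pytest

import respirad as rr
from respirad.segmentation import RespiratoryCycle
from respirad.windows import (
    REASON_TOO_FEW,
    REASON_TRIMMED_OUT,
    complete_cycles_in_window,
    sliding_window_metrics,
    trim_extreme_cycles,
    window_means,
)


def cycle(start, ti, te):
    return RespiratoryCycle(start, start + ti, start + ti + te)


def cycles_from(ti_list, te_list):
    out, t = [], 0.0
    for ti, te in zip(ti_list, te_list):
        out.append(cycle(t, ti, te))
        t += ti + te
    return out


class TestCompleteness:
    spec = rr.WindowSpec(length_s=120.0, step_s=30.0)

    @pytest.mark.parametrize(
        "start, end, included",
        [
            (118.0, 121.0, False),  # ending valley outside the window
            (10.0, 14.0, True),
            (116.0, 120.0, False),  # half-open window: end exactly at 120
            (0.0, 4.0, True),       # starting valley exactly on the boundary
        ],
    )
    def test_both_valleys_must_fall_inside(self, start, end, included):
        c = RespiratoryCycle(start, (start + end) / 2, end)
        got = complete_cycles_in_window([c], 0.0, self.spec)
        assert (c in got) is included


class TestTrimming:
    def test_co_monotone_removes_two(self):
        cs = cycles_from([1, 2, 3, 4, 5, 6], [2, 3, 4, 5, 6, 7])
        kept, dropped = trim_extreme_cycles(cs)
        assert dropped == [0, 5]
        assert len(kept) == 4

    def test_anti_monotone_removes_two(self):
        cs = cycles_from([1, 2, 3, 4], [4, 3, 2, 1])
        kept, dropped = trim_extreme_cycles(cs)
        assert dropped == [0, 3]
        assert len(kept) == 2

    def test_scrambled_removes_four_leaving_none(self):
        cs = cycles_from([1, 2, 3, 4], [3, 1, 4, 2])
        kept, dropped = trim_extreme_cycles(cs)
        assert dropped == [0, 1, 2, 3]
        assert kept == []

    def test_identical_cycles_still_remove_two(self):
        cs = cycles_from([2.0] * 8, [3.0] * 8)
        kept, dropped = trim_extreme_cycles(cs)
        assert dropped == [0, 7]
        assert len(kept) == 6

    def test_trim_always_removes_two_to_four(self, snr20_result):
        w = snr20_result.radar_windows
        valid = w[w.valid]
        removed = valid.n_cycles_total - valid.n_cycles_used
        assert removed.between(2, 4).all()


class TestWindowMeans:
    def test_single_cycle(self):
        m = window_means([cycle(0, 1.7, 2.3)])
        assert m.mean_ti_s == pytest.approx(1.7)
        assert m.mean_te_s == pytest.approx(2.3)
        assert m.mean_rr_brpm == pytest.approx(15.0)
        assert m.mean_ie_ratio == pytest.approx(1.7 / 2.3)

    def test_rr_is_mean_of_per_cycle_rates(self):
        m = window_means([cycle(0, 2, 2), cycle(4, 2, 6)])
        assert m.mean_rr_brpm == pytest.approx(11.25)  # not 60/mean(TI+TE) = 10
        assert m.mean_ie_ratio == pytest.approx(np.mean([1.0, 2 / 6]))

    def test_identical_cycles_exact_ratio(self):
        m = window_means([cycle(4 * k, 1.7, 2.3) for k in range(5)])
        assert m.mean_ie_ratio == pytest.approx(1.7 / 2.3, abs=1e-12)

    def test_order_invariance(self):
        cs = cycles_from([1.5, 2.5, 2.0], [2.0, 3.0, 2.6])
        a, b = window_means(cs), window_means(cs[::-1])
        for fa, fb in [
            (a.mean_ti_s, b.mean_ti_s), (a.mean_te_s, b.mean_te_s),
            (a.mean_rr_brpm, b.mean_rr_brpm), (a.mean_ie_ratio, b.mean_ie_ratio),
        ]:
            assert fa == pytest.approx(fb, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            window_means([])


class TestSlidingWindows:
    def test_ten_minute_recording_yields_17_windows(self):
        cs = cycles_from([2.0] * 120, [3.0] * 120)  # 600 s of cycles
        df = sliding_window_metrics(cs, rr.WindowSpec(), recording_span_s=600.0)
        assert len(df) == 17  # floor((600-120)/30)+1

    def test_exact_length_recording_single_window(self):
        cs = cycles_from([2.0] * 24, [3.0] * 24)
        df = sliding_window_metrics(cs, rr.WindowSpec(), recording_span_s=120.0)
        assert len(df) == 1

    def test_cv0_truth_windows_report_exact_metrics(self):
        cfg = rr.SimulationConfig(
            duration_s=600.0, cycle_cv=0.0, mean_ti=1.7, mean_te=2.3,
            noise_std=0.0, ref_noise_std=0.0, cardiac_amp_mm=0.0,
        )
        truth = rr.simulate_recording(cfg, seed=0).truth
        df = sliding_window_metrics(truth.to_cycles(), recording_span_s=600.0)
        valid = df[df.valid]
        assert len(valid) == 17
        assert np.allclose(valid.mean_rr_brpm, 15.0, atol=0.1)
        assert np.allclose(valid.mean_ie_ratio, 1.7 / 2.3, atol=0.01)

    def test_too_few_cycles_marks_window_invalid(self):
        cs = cycles_from([2.0] * 3, [3.0] * 3)
        df = sliding_window_metrics(cs, rr.WindowSpec(), recording_span_s=120.0)
        assert not df.valid.iloc[0]
        assert df.reason.iloc[0] == REASON_TOO_FEW

    def test_trim_leaving_under_two_marks_window_invalid(self):
        # 6 cycles whose TI/TE extremes name 4 distinct cycles -> 2 remain: valid;
        # with min_cycles=6 but a scrambled 6 where union is 4 -> 2 kept, so
        # force the invalid path with 6 cycles where trim leaves 1? not
        # constructible (union <= 4); instead check the guard via min_cycles=5
        cs = cycles_from([1, 2, 3, 4, 2.5], [3, 1, 4, 2, 2.5])
        spec = rr.WindowSpec(length_s=120.0, step_s=120.0, min_cycles=5)
        df = sliding_window_metrics(cs, spec, recording_span_s=120.0)
        assert not df.valid.iloc[0]
        assert df.reason.iloc[0] == REASON_TRIMMED_OUT

    def test_radar_and_reference_share_window_grid(self, snr20_result):
        r, f = snr20_result.radar_windows, snr20_result.reference_windows
        assert np.array_equal(r.window_start_s, f.window_start_s)

    def test_empty_table_when_recording_shorter_than_window(self):
        df = sliding_window_metrics([], rr.WindowSpec(), recording_span_s=60.0)
        assert df.empty and "mean_rr_brpm" in df.columns


class TestRecoveryOnSynthetic:
    def test_rr_recovered_within_03_brpm(self, snr20_rec, snr20_result):
        """Window RR agrees with ground truth: cycle totals survive the
        band-limiting that shifts the TI/TE split point."""
        truth_w = sliding_window_metrics(
            snr20_rec.truth.to_cycles(), recording_span_s=600.0
        )
        radar_w = snr20_result.radar_windows
        m = truth_w.merge(radar_w, on="window_start_s", suffixes=("_t", "_r"))
        both = m[m.valid_t & m.valid_r]
        assert len(both) >= 10
        assert np.abs(both.mean_rr_brpm_t - both.mean_rr_brpm_r).max() <= 0.3

    def test_radar_reference_window_agreement(self, snr20_result):
        """Radar and impedance see the same breathing through the same filter,
        so their window metrics agree tightly even with channel noise."""
        m = snr20_result.radar_windows.merge(
            snr20_result.reference_windows, on="window_start_s",
            suffixes=("_r", "_f"),
        )
        both = m[m.valid_r & m.valid_f]
        assert len(both) >= 10
        assert np.abs(both.mean_ti_s_r - both.mean_ti_s_f).max() <= 0.05
        assert np.abs(both.mean_te_s_r - both.mean_te_s_f).max() <= 0.05
        assert np.abs(both.mean_rr_brpm_r - both.mean_rr_brpm_f).max() <= 0.3
        assert np.abs(both.mean_ie_ratio_r - both.mean_ie_ratio_f).max() <= 0.05

    def test_noiseless_pair_agrees_within_two_reference_samples(self, noiseless_result):
        m = noiseless_result.radar_windows.merge(
            noiseless_result.reference_windows, on="window_start_s",
            suffixes=("_r", "_f"),
        )
        both = m[m.valid_r & m.valid_f]
        assert len(both) >= 3
        tol = 2 / 100.0
        assert np.abs(both.mean_ti_s_r - both.mean_ti_s_f).max() <= tol
        assert np.abs(both.mean_te_s_r - both.mean_te_s_f).max() <= tol
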