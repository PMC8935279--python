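import numpy as np
import pytest

from plantclock.analysis import (
    chi_square_periodogram,
    detect_peaks,
    error_from_times,
    expected_final_peak_time,
    final_peak_time,
    final_peak_times,
    peak_to_peak_period,
    periodogram_periods,
    roi_timeseries,
    space_time_plot,
)


class TestPeriodogram:
    def test_pure_sinusoid_recovered(self):
        t = np.arange(0.0, 144.1, 0.1)
        res = chi_square_periodogram(t, np.sin(2 * np.pi * t / 24.0))
        assert res.assessable and res.significant
        assert res.period == pytest.approx(24.0, abs=0.1)

    def test_white_noise_false_positive_rate(self, rng):
        """At alpha = 1%, noise is called rhythmic in about 1% of draws."""
        t = np.arange(0.0, 120.0, 0.5)
        X = rng.normal(size=(1000, len(t)))
        _, significant = periodogram_periods(t, X, period_range=(20.0, 30.0))
        assert significant.mean() <= 0.03

    def test_short_series_flagged_non_assessable(self):
        t = np.arange(0.0, 30.0, 0.1)
        res = chi_square_periodogram(t, np.sin(2 * np.pi * t / 24.0),
                                     period_range=(18.0, 34.0))
        assert not res.assessable and np.isnan(res.period)

    def test_agrees_with_peak_to_peak_on_clean_signal(self):
        t = np.arange(0.0, 240.0, 0.1)
        x = 1.0 + np.sin(2 * np.pi * t / 25.5)
        pg = chi_square_periodogram(t, x)
        p2p = peak_to_peak_period(detect_peaks(t, x))
        assert abs(pg.period - p2p) < 0.2


class TestDetectPeaks:
    def test_sinusoid_peak_times_closed_form(self):
        """sin(2 pi t / 24) peaks at t = 6 mod 24; window [24, 144]."""
        t = np.arange(0.0, 144.1, 0.1)
        ps = detect_peaks(t, np.sin(2 * np.pi * t / 24.0), window=(24.0, 144.0))
        np.testing.assert_allclose(
            ps.times, [30.0, 54.0, 78.0, 102.0, 126.0], atol=0.05
        )
        assert ps.rhythmic

    def test_close_candidates_resolve_to_the_higher(self):
        """Two maxima 10 h apart violate the 19-h rule; keep the taller."""
        t = np.arange(0.0, 48.0, 0.1)
        x = (np.exp(-0.5 * ((t - 20.0) / 1.5) ** 2)
             + 0.6 * np.exp(-0.5 * ((t - 30.0) / 1.5) ** 2))
        ps = detect_peaks(t, x)
        assert len(ps) == 1
        assert ps.times[0] == pytest.approx(20.0, abs=0.1)

    def test_monotone_series_has_no_peaks(self):
        t = np.arange(0.0, 48.0, 0.1)
        ps = detect_peaks(t, 0.1 * t)
        assert len(ps) == 0 and not ps.rhythmic

    def test_peaks_exceed_series_mean_and_separation(self, rng):
        t = np.arange(0.0, 240.0, 0.1)
        x = np.sin(2 * np.pi * t / 24.0) + 0.3 * rng.normal(size=len(t))
        ps = detect_peaks(t, x)
        assert np.all(ps.heights > x.mean())
        if len(ps) > 1:
            assert np.all(np.diff(ps.times) > 19.0)

    def test_troughs_mirror_peaks_of_negated_series(self):
        t = np.arange(0.0, 96.0, 0.1)
        x = 2.0 + np.cos(2 * np.pi * t / 24.0)
        troughs = detect_peaks(t, x, troughs=True)
        np.testing.assert_allclose(troughs.times % 24.0, 12.0, atol=0.05)

    def test_empty_window_returns_empty_peakset(self):
        t = np.arange(0.0, 48.0, 0.1)
        ps = detect_peaks(t, np.sin(t), window=(100.0, 120.0))
        assert len(ps) == 0

    def test_nonuniform_time_axis_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.array([0.0, 0.1, 0.3, 0.4]), np.zeros(4))


class TestPeakToPeakPeriod:
    @pytest.mark.parametrize("times,expected", [
        ([30.0, 54.0, 78.0], 24.0),
        ([24.0, 49.5, 75.0], 25.5),
    ])
    def test_mean_of_consecutive_intervals(self, times, expected):
        from plantclock.analysis import PeakSet

        ps = PeakSet(np.asarray(times), np.ones(len(times)), (0.0, 100.0))
        assert peak_to_peak_period(ps) == pytest.approx(expected)

    def test_fewer_than_two_peaks_is_arrhythmic(self):
        from plantclock.analysis import PeakSet

        ps = PeakSet(np.array([30.0]), np.array([1.0]), (0.0, 100.0))
        assert not ps.rhythmic
        assert np.isnan(peak_to_peak_period(ps))


class FakeResult:
    """Minimal stand-in (synthetic) exposing the result interface analysis needs."""

    def __init__(self, t, X, template):
        self.t = t
        self.data = {"cP97m": X}
        self.template = template
        self.n_cells = X.shape[1]

    def series(self, var):
        return self.data[var]

    def mean_series(self, var):
        return np.nanmean(self.data[var], axis=1)


@pytest.fixture()
def uniform_result():
    from plantclock import build_template

    template = build_template()  # ROIs need the full-width anatomy
    t = np.arange(0.0, 96.0, 0.1)
    base = 1.0 + np.sin(2 * np.pi * t / 24.0)
    X = np.tile(base[:, None], (1, template.n_cells))
    return FakeResult(t, X, template)


class TestROIs:
    def test_uniform_field_equals_any_cell(self, uniform_result):
        rois = roi_timeseries(uniform_result, "cP97m")
        assert set(rois) == {"cotyledon", "hypocotyl", "root", "root_tip"}
        for series in rois.values():
            np.testing.assert_allclose(
                series, uniform_result.series("cP97m")[:, 0], atol=1e-12
            )

    def test_roi_mean_equals_explicit_average(self, uniform_result, rng):
        res = uniform_result
        res.data["cP97m"] = rng.uniform(0.0, 2.0, res.data["cP97m"].shape)
        tpl = res.template
        rois = roi_timeseries(res, "cP97m", rois={"root": (tpl.geometry.cotyledon_w, 20)})
        mask = ((tpl.col >= tpl.geometry.cotyledon_w)
                & (tpl.col < tpl.geometry.cotyledon_w + 5)
                & (tpl.row >= 20) & (tpl.row < 23))
        assert mask.sum() == 15
        oracle = res.data["cP97m"][:, mask].mean(axis=1)
        np.testing.assert_allclose(rois["root"], oracle, atol=1e-12)

    def test_off_template_roi_rejected(self, uniform_result):
        with pytest.raises(ValueError, match="off-template"):
            roi_timeseries(uniform_result, "cP97m", rois={"root": (999, 999)})


class TestSpaceTime:
    def test_uniform_field_gives_constant_sections(self, uniform_result):
        rows, M = space_time_plot(uniform_result, "cP97m")
        assert M.shape == (len(rows), len(uniform_result.t))
        assert np.max(np.abs(M - M[[0], :])) < 1e-12
        assert np.all(np.diff(rows) > 0)  # cotyledon end -> root tip

    def test_sections_match_explicit_row_means(self, uniform_result, rng):
        res = uniform_result
        res.data["cP97m"] = rng.uniform(0.0, 2.0, res.data["cP97m"].shape)
        rows, M = space_time_plot(res, "cP97m")
        tpl = res.template
        for s, r in enumerate(rows):
            oracle = res.data["cP97m"][:, tpl.row == r].mean(axis=1)
            np.testing.assert_allclose(M[s], oracle, atol=1e-12)


class TestFinalPeaks:
    def _bump_series(self, t, centers, heights):
        x = np.full_like(t, 0.05)
        for c, h in zip(centers, heights):
            x = x + h * np.exp(-0.5 * ((t - c) / 1.0) ** 2)
        return x

    def test_single_clean_peak_returned(self):
        t = np.arange(0.0, 96.0, 0.1)
        x = self._bump_series(t, [70.0], [1.0])
        assert final_peak_time(t, x, 72.0) == pytest.approx(70.0, abs=0.05)

    def test_tallest_wins_except_for_toc1_which_takes_earliest(self):
        t = np.arange(0.0, 120.0, 0.1)
        x = self._bump_series(t, [60.0, 80.0], [0.8, 1.2])  # 20 h apart
        assert final_peak_time(t, x, 70.0, gene="P97") == pytest.approx(80.0, abs=0.05)
        assert final_peak_time(t, x, 70.0, gene="P51") == pytest.approx(60.0, abs=0.05)

    def test_no_peak_in_window_is_missing_value(self):
        t = np.arange(0.0, 96.0, 0.1)
        x = np.full_like(t, 1.0)
        assert np.isnan(final_peak_time(t, x, 48.0))

    def test_matches_brute_force_windowed_argmax(self, rng):
        """Oracle: enumerate admissible local maxima in the window directly."""
        t = np.arange(0.0, 120.0, 0.1)
        for _ in range(10):
            centers = rng.uniform(30.0, 110.0, 3)
            heights = rng.uniform(0.5, 1.5, 3)
            x = self._bump_series(t, centers, heights)
            expected_t = 70.0
            got = final_peak_time(t, x, expected_t)
            lo, hi = expected_t - 12.0, expected_t + 12.0
            cand = [i for i in range(1, len(t) - 1)
                    if x[i] >= x[i - 1] and x[i] >= x[i + 1]
                    and lo <= t[i] <= hi and x[i] > x[(t >= lo) & (t <= hi)].mean()]
            # apply the 19-h suppression tallest-first
            kept = []
            for i in sorted(cand, key=lambda i: -x[i]):
                if all(abs(t[i] - t[j]) > 19.0 for j in kept):
                    kept.append(i)
            if not kept:
                assert np.isnan(got)
            else:
                best = max(kept, key=lambda i: x[i])
                assert got == pytest.approx(t[best], abs=0.2)

    def test_per_section_final_peaks(self):
        t = np.arange(0.0, 120.0, 0.1)
        M = np.vstack([self._bump_series(t, [60.0 + 2 * s], [1.0])
                       for s in range(5)])
        fp = final_peak_times(M, t, 65.0)
        np.testing.assert_allclose(fp, 60.0 + 2 * np.arange(5), atol=0.05)


class TestTimingError:
    def test_identical_runs_give_zero(self):
        te = error_from_times([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert te.E == 0.0 and te.n_excluded == 0

    def test_hand_built_vectors(self):
        te = error_from_times([1.0, 2.0, 3.0], [1.5, 2.5, 2.5])
        assert te.E == pytest.approx(0.5)

    def test_invariant_under_relabeling(self, rng):
        Ti = rng.uniform(200.0, 220.0, 50)
        Tn = Ti + rng.normal(0.0, 0.5, 50)
        perm = rng.permutation(50)
        assert error_from_times(Ti, Tn).E == pytest.approx(
            error_from_times(Ti[perm], Tn[perm]).E
        )

    def test_undefined_peaks_excluded_and_counted(self):
        te = error_from_times([1.0, np.nan, 3.0], [1.5, 2.0, np.nan])
        assert te.n_used == 1 and te.n_excluded == 2
        assert te.E == pytest.approx(0.5)
        assert te.exclusion_rate == pytest.approx(2 / 3)

    def test_nonnegative(self, rng):
        te = error_from_times(rng.uniform(0, 10, 20), rng.uniform(0, 10, 20))
        assert te.E >= 0.0
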