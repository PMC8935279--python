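import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantclock.light import (
    FluctuationTrack,
    LightField,
    LightProtocol,
    make_fluctuation_track,
)


class TestFluctuationTrack:
    def test_same_seed_identical_track(self):
        a = make_fluctuation_track(7, 48.0)
        b = make_fluctuation_track(7, 48.0)
        np.testing.assert_array_equal(a.edges, b.edges)
        np.testing.assert_array_equal(a.values, b.values)

    def test_interval_and_deviation_distributions(self):
        """Monte-Carlo check: mean duration 2.4 h, mean deviation 0."""
        tr = make_fluctuation_track(3, 2.4 * 1e5)
        durations = np.diff(tr.edges)
        assert len(durations) > 9e4
        assert np.mean(durations) == pytest.approx(2.4, abs=0.02)
        assert np.mean(tr.values) == pytest.approx(0.0, abs=0.002)
        assert np.all(np.abs(tr.values) <= 0.5)
        assert np.all(durations > 0)

    def test_track_covers_span(self):
        tr = make_fluctuation_track(1, 12.0, t_start=24.0)
        assert tr.edges[0] == 24.0
        assert tr.edges[-1] >= 36.0

    def test_invalid_t_max(self):
        with pytest.raises(ValueError):
            make_fluctuation_track(0, -1.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            FluctuationTrack(edges=np.array([0.0, 1.0]), values=np.array([]))


class TestProtocolBasics:
    @pytest.mark.parametrize("t,L,D", [(6.0, 1.0, 0.0), (18.0, 0.0, 1.0),
                                       (0.0, 1.0, 0.0)])
    def test_ideal_LD_schedule(self, t, L, D):
        pr = LightProtocol("LD_ideal", entrain_days=2)
        li = pr.light_at(0, t)
        assert (li.L, li.D) == (L, D)

    def test_constant_protocols(self):
        ll = LightProtocol("LL", entrain_days=1)
        dd = LightProtocol("DD", entrain_days=1)
        assert ll.light_at(0, 13.0).L == 1.0 and ll.light_at(0, 13.0).D == 0.0
        assert dd.light_at(0, 13.0).L == 0.0 and dd.light_at(0, 13.0).D == 1.0

    def test_release_phase(self):
        pr = LightProtocol("LD_ideal", entrain_days=1, release_kind="LL",
                           release_days=1)
        assert pr.light_at(0, 40.0).L == 1.0  # would be night if still LD

    def test_unknown_cell_and_out_of_span_rejected(self):
        pr = LightProtocol("LD_ideal", entrain_days=1)
        with pytest.raises(ValueError):
            pr.light_at(-1, 2.0)
        with pytest.raises(ValueError):
            pr.light_at(0, 30.0)

    @given(st.floats(min_value=0.0, max_value=47.999))
    @settings(max_examples=50, deadline=None)
    def test_dark_indicator_consistency(self, t):
        """D = 1 exactly when L = 0, for any time in a noisy protocol."""
        pr = LightProtocol("LD_noisy", entrain_days=2, lam=0.3, seed=5)
        li = pr.light_at(4, t)
        assert (li.D == 1.0) == (li.L == 0.0)
        assert li.L >= 0.0


class TestNoisyLD:
    def test_night_is_exactly_dark_and_day_in_band(self):
        pr = LightProtocol("LD_noisy", entrain_days=4, lam=0.25, seed=9)
        ts = np.linspace(0.0, 95.9, 500)
        for t in ts:
            li = pr.light_at(2, float(t))
            if (t % 24.0) >= 12.0:
                assert li.L == 0.0 and li.D == 1.0
            else:
                assert 0.5 - 1e-9 <= li.L <= 1.5 + 1e-9

    def test_daytime_mean_intensity_is_one(self):
        pr = LightProtocol("LD_noisy", entrain_days=60, lam=0.0, seed=2)
        ts = np.arange(0.05, 12.0, 0.1)
        vals = [pr.light_at(0, d * 24.0 + t) for d in range(60) for t in ts]
        assert np.mean([v.L for v in vals]) == pytest.approx(1.0, abs=0.03)

    def test_lam_one_shares_the_global_track(self):
        pr = LightProtocol("LD_noisy", entrain_days=2, lam=1.0, seed=4)
        ts = np.linspace(0.0, 11.9, 60)
        for t in ts:
            assert pr.light_at(0, float(t)).L == pr.light_at(17, float(t)).L

    def test_lam_zero_cells_are_independent(self):
        """Daytime light traces of two cells are uncorrelated at lam = 0."""
        pr = LightProtocol("LD_noisy", entrain_days=150, lam=0.0, seed=6)
        field = LightField(pr)
        a, b = [], []
        for day in range(150):
            bounds, L = field.day_segments(day, 2)
            mids = 0.5 * (bounds[:-1] + bounds[1:])
            day_mask = (mids % 24.0) < pr.day_length_h
            w = np.diff(bounds)[day_mask]
            # sample on a common uniform grid to compare the two traces
            grid = np.arange(day * 24.0 + 0.05, day * 24.0 + 12.0, 0.1)
            idx = np.clip(np.searchsorted(bounds, grid, "right") - 1, 0,
                          len(mids) - 1)
            a.extend(L[idx, 0])
            b.extend(L[idx, 1])
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 0.05

    def test_zero_halfwidth_reduces_to_ideal(self):
        noisy = LightProtocol("LD_noisy", entrain_days=2, lam=0.0, seed=8,
                              intensity_halfwidth=0.0)
        ideal = LightProtocol("LD_ideal", entrain_days=2)
        for t in np.linspace(0.0, 47.9, 200):
            assert noisy.light_at(3, float(t)).L == ideal.light_at(0, float(t)).L

    def test_switch_times_exported_for_integrator(self):
        pr = LightProtocol("LD_noisy", entrain_days=1, lam=0.5, seed=10)
        sw = pr.switch_times(0.0, 24.0, cell_id=0)
        assert 12.0 in sw          # dusk
        assert len(sw) > 4         # fluctuation breakpoints of both tracks
        assert np.all((sw >= 0.0) & (sw <= 24.0))

    def test_track_frame_is_piecewise_audit_table(self):
        pr = LightProtocol("LD_noisy", entrain_days=1, lam=0.0, seed=11)
        df = pr.track_frame(0)
        assert list(df.columns) == ["t_start", "t_end", "L"]
        assert df.t_start.iloc[0] == 0.0 and df.t_end.iloc[-1] == 24.0
        night = df[(df.t_start >= 12.0)]
        assert (night.L == 0.0).all()


class TestLightField:
    def test_field_matches_pointwise_evaluation(self):
        pr = LightProtocol("LD_noisy", entrain_days=1, lam=0.4, seed=13)
        bounds, L = LightField(pr).day_segments(0, 3)
        mids = 0.5 * (bounds[:-1] + bounds[1:])
        for k in range(len(mids)):
            for c in range(3):
                assert L[k, c] == pytest.approx(
                    pr.light_at(c, float(mids[k])).L, abs=1e-12
                )
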