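"""Trace analysis: FRET correction, segmentation, autocorrelation, dwells."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkrscan import fret_analysis as fa
from pkrscan import fret_sim as fs

from conftest import ar1_fret_series, fitted_sliding_time


def _series(e, dt=0.033, valid=None):
    e = np.asarray(e, dtype=float)
    valid = np.ones(e.size, dtype=bool) if valid is None else valid
    return fa.FretSeries(e, valid, dt)


class TestComputeFret:
    def test_equal_channels_give_half(self):
        p = fs.FretModelParams(donor_total_intensity=100.0)
        tr = fs.FluorescenceTrace(times=np.arange(3.0),
                                  donor=np.full(3, 50.0),
                                  acceptor=np.full(3, 50.0),
                                  frame_interval=1.0)
        out = fa.compute_fret(tr, p)
        assert np.allclose(out.efficiency, 0.5)

    def test_zero_acceptor_gives_zero(self):
        p = fs.FretModelParams(donor_total_intensity=100.0)
        tr = fs.FluorescenceTrace(times=np.arange(3.0),
                                  donor=np.full(3, 80.0),
                                  acceptor=np.zeros(3),
                                  frame_interval=1.0)
        assert np.allclose(fa.compute_fret(tr, p).efficiency, 0.0)

    def test_low_total_frames_masked_and_all_masked_flag(self):
        p = fs.FretModelParams(donor_total_intensity=1000.0)
        tr = fs.FluorescenceTrace(times=np.arange(4.0),
                                  donor=np.array([500.0, 1.0, 1.0, 1.0]),
                                  acceptor=np.array([500.0, 1.0, 1.0, 1.0]),
                                  frame_interval=1.0)
        out = fa.compute_fret(tr, p)
        assert out.valid.tolist() == [True, False, False, False]
        assert not out.all_masked
        tr2 = fs.FluorescenceTrace(times=np.arange(2.0),
                                   donor=np.ones(2), acceptor=np.ones(2),
                                   frame_interval=1.0)
        assert fa.compute_fret(tr2, p).all_masked


class TestSegmentEvents:
    def test_single_clean_event(self):
        e = np.full(200, 0.05)
        e[30:121] = 0.7
        events = fa.segment_events(_series(e), on_threshold=0.6,
                                   min_frames=3)
        assert [(ev.start_frame, ev.end_frame) for ev in events] \
            == [(30, 121)]

    def test_abortive_classification_by_duration(self):
        e = np.full(400, 0.05)
        e[10:55] = 0.7       # 45 frames * 0.033 s = 1.485 s < 2 s
        e[100:200] = 0.7     # 100 frames * 0.033 s = 3.3 s
        ev1, ev2 = fa.segment_events(_series(e))
        assert ev1.duration == pytest.approx(1.485)
        assert ev1.classification == "abortive"
        assert ev2.classification == "on"

    def test_never_above_threshold_gives_no_events(self):
        assert fa.segment_events(_series(np.full(100, 0.4))) == []

    def test_masked_frames_break_runs(self):
        e = np.full(60, 0.7)
        valid = np.ones(60, dtype=bool)
        valid[30] = False
        events = fa.segment_events(_series(e, valid=valid), min_frames=3)
        assert [(ev.start_frame, ev.end_frame) for ev in events] \
            == [(0, 30), (31, 60)]


class TestAnticorrelation:
    def _trace(self, donor, acceptor):
        donor = np.asarray(donor, dtype=float)
        return fs.FluorescenceTrace(times=np.arange(donor.size, dtype=float),
                                    donor=donor,
                                    acceptor=np.asarray(acceptor,
                                                        dtype=float),
                                    frame_interval=1.0)

    def test_perfectly_anticorrelated(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(100, 900, size=50)
        tr = self._trace(d, 1000.0 - d)
        ev = fa.BindingEvent(0, 50, 50.0, "on", 0.5)
        assert fa.anticorrelation_score(tr, ev) == pytest.approx(-1.0)

    def test_identical_channels(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(100, 900, size=50)
        tr = self._trace(d, d)
        ev = fa.BindingEvent(0, 50, 50.0, "on", 0.5)
        assert fa.anticorrelation_score(tr, ev) == pytest.approx(1.0)

    def test_zero_variance_channel_flagged_nan(self):
        tr = self._trace(np.full(10, 5.0), np.arange(10.0))
        ev = fa.BindingEvent(0, 10, 10.0, "on", 0.5)
        assert np.isnan(fa.anticorrelation_score(tr, ev))
        assert np.isnan(ev.anticorrelation)

    def test_independent_noise_near_zero(self):
        # null distribution: |r| < 0.1 for ~95% of seeds at n=1000
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            tr = self._trace(rng.normal(500, 30, 1000),
                             rng.normal(500, 30, 1000))
            ev = fa.BindingEvent(0, 1000, 33.0, "on", 0.5)
            if abs(fa.anticorrelation_score(tr, ev)) < 0.1:
                hits += 1
        assert hits >= 34


class TestAutocorrelation:
    def test_oracle_equivalence_double_loop(self):
        rng = np.random.default_rng(3)
        for n in (17, 57, 150):
            x = rng.uniform(size=n)
            ev = [fa.BindingEvent(0, n, n * 0.033, "on", 0.5)]
            r = fa.autocorrelate_events(ev, _series(x), max_lag=0.5)
            xc = x - x.mean()
            var = np.mean(xc * xc)
            oracle = np.array([
                sum(xc[t] * xc[t + k] for t in range(n - k)) / n / var
                for k in range(r.g.size)])
            assert np.max(np.abs(r.g - oracle)) < 1e-10

    def test_g0_is_one_and_lag_grid(self):
        series, events = ar1_fret_series(n_events=5, n_frames_per_event=100,
                                         seed=4)
        r = fa.autocorrelate_events(events, series, max_lag=0.5)
        assert r.g[0] == pytest.approx(1.0)
        assert r.lags[0] == 0.0
        assert np.allclose(np.diff(r.lags), 0.033)

    def test_white_noise_null(self):
        rng = np.random.default_rng(5)
        n = 20_000
        x = rng.normal(0.5, 0.1, size=n)
        ev = [fa.BindingEvent(0, n, n * 0.033, "on", 0.5)]
        r = fa.autocorrelate_events(ev, _series(x), max_lag=0.5)
        assert np.all(np.abs(r.g[1:]) < 3.0 / np.sqrt(r.n_pairs[1:]))

    def test_constant_event_raises(self):
        ev = [fa.BindingEvent(0, 50, 50 * 0.033, "on", 0.5)]
        with pytest.raises(ValueError):
            fa.autocorrelate_events(ev, _series(np.full(50, 0.7)),
                                    max_lag=0.5)

    def test_abortive_events_excluded(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(size=100)
        evs = [fa.BindingEvent(0, 50, 1.65, "abortive", 0.5),
               fa.BindingEvent(50, 100, 1.65, "abortive", 0.5)]
        with pytest.raises(ValueError):
            fa.autocorrelate_events(evs, _series(x), max_lag=0.3)

    def test_ar1_recovery(self):
        series, events = ar1_fret_series(n_events=60, seed=7)
        r = fa.autocorrelate_events(events, series, max_lag=1.0)
        tau_frames = -1.0 / np.log(max(r.g[1], 1e-9))
        assert tau_frames == pytest.approx(5.0, rel=0.15)


class TestFitSlidingTime:
    def test_exact_exponential_recovered(self):
        lags = np.arange(0, 30) * 0.033
        g = np.exp(-lags / 0.165)
        r = fa.AutocorrelationResult(lags=lags, g=g,
                                     n_pairs=np.full(30, 1000.0),
                                     n_events=10)
        out = fa.fit_sliding_time(r, fit_range=(0.0, 1.0))
        assert out.sliding_time == pytest.approx(0.165, abs=1e-9)
        assert not out.fit_failed

    def test_noise_autocorrelation_fails_or_tiny(self):
        rng = np.random.default_rng(8)
        n = 5000
        x = rng.normal(0.5, 0.1, size=n)
        ev = [fa.BindingEvent(0, n, n * 0.033, "on", 0.5)]
        r = fa.autocorrelate_events(ev, _series(x), max_lag=0.5)
        out = fa.fit_sliding_time(r, fit_range=(0.0, 0.5))
        assert out.fit_failed or out.sliding_time < 2 * 0.033 \
            or (out.amplitude is not None and out.amplitude < 0.1)

    def test_too_few_points_flagged(self):
        lags = np.arange(3) * 0.033
        r = fa.AutocorrelationResult(lags=lags, g=np.exp(-lags / 0.1),
                                     n_pairs=np.full(3, 10.0), n_events=1)
        assert fa.fit_sliding_time(r).fit_failed

    def test_sliding_time_recovers_box_relaxation(self, scan_geometry):
        # tau* = L_eff^2/(pi^2 D); FRET nonlinearity permits modest bias
        L, D = 59.0, 1000.0
        tau_star = (L - 15.0) ** 2 / (np.pi ** 2 * D)
        taus = [fitted_sliding_time(L, seed, scan_geometry,
                                    n_frames=60_000) for seed in range(5)]
        assert np.mean(taus) == pytest.approx(tau_star, rel=0.25)

    def test_monotone_in_duplex_length(self, scan_geometry):
        for seed in range(3):
            taus = [fitted_sliding_time(L, seed, scan_geometry,
                                        n_frames=60_000)
                    for L in (42.0, 59.0, 112.0)]
            assert taus[0] < taus[1] < taus[2]


class TestResidenceStats:
    def test_mean_of_simple_durations(self):
        evs = [fa.BindingEvent(0, n, n * 0.033, "on", 0.5)
               for n in (10, 20, 30)]
        out = fa.residence_stats({"ctrl": evs})
        assert out.mean["ctrl"] == pytest.approx(0.66)
        assert out.t_statistic is None

    def test_identical_conditions_t0_p1(self):
        evs = [fa.BindingEvent(0, n, n * 0.033, "on", 0.5)
               for n in (10, 20, 30)]
        out = fa.residence_stats({"a": evs, "b": list(evs)})
        assert out.t_statistic == 0.0
        assert out.p_value == 1.0

    def test_welch_detects_shift(self):
        rng = np.random.default_rng(9)
        a = [fa.BindingEvent(0, 1, float(d), "on", 0.5)
             for d in rng.exponential(8.0, 200)]
        b = [fa.BindingEvent(0, 1, float(d), "on", 0.5)
             for d in rng.exponential(3.0, 200)]
        out = fa.residence_stats({"ctrl": a, "pact": b})
        assert out.p_value < 0.05
        assert out.mean["pact"] < out.mean["ctrl"]


class TestGatedHistogram:
    def test_single_constant_event_in_one_bin(self):
        e = np.full(200, 0.05)
        e[10:110] = 0.85    # 3.3 s: long enough not to be abortive
        series = _series(e)
        events = fa.segment_events(series, min_frames=3)
        h = fa.gated_fret_histogram([series], [events], 0.8, bins=40)
        assert h.counts.sum() == 100
        hot = int(np.argmax(h.counts))
        assert h.counts[hot] == 100
        assert h.bin_edges[hot] <= 0.85 <= h.bin_edges[hot + 1]

    def test_below_gate_trace_contributes_nothing(self):
        e = np.full(100, 0.05)
        e[10:80] = 0.7
        series = _series(e)
        events = fa.segment_events(series, min_frames=3)
        h = fa.gated_fret_histogram([series], [events], 0.8)
        assert h.empty
        assert h.counts.sum() == 0

    def test_count_conservation(self):
        series, events = ar1_fret_series(n_events=20,
                                         n_frames_per_event=150, seed=10)
        h = fa.gated_fret_histogram([series], [events], 0.6)
        on_frames = sum(ev.n_frames for ev in events)
        assert h.counts.sum() == on_frames == h.n_frames


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_autocorrelation_matches_oracle_property(seed):
    """Pooled estimator equals the direct per-event double loop."""
    rng = np.random.default_rng(seed)
    lens = rng.integers(10, 60, size=3)
    chunks, events, pos = [], [], 0
    for n in lens:
        chunks.append(rng.uniform(size=n))
        events.append(fa.BindingEvent(pos, pos + n, n * 0.033, "on", 0.5))
        pos += n
    series = _series(np.concatenate(chunks))
    r = fa.autocorrelate_events(events, series, max_lag=0.3)
    num = np.zeros(r.g.size)
    den = np.zeros(r.g.size)
    for ev, x in zip(events, chunks):
        xc = x - x.mean()
        var = np.mean(xc * xc)
        for k in range(min(r.g.size, x.size)):
            gk = sum(xc[t] * xc[t + k] for t in range(x.size - k)) \
                / x.size / var
            num[k] += gk * (x.size - k)
            den[k] += x.size - k
    assert np.max(np.abs(r.g - num / den)) < 1e-10
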