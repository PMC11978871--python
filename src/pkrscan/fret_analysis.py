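"""Analysis of smFRET traces: segmentation, autocorrelation, dwell statistics.

The pipeline mirrors the standard single-molecule workflow for scanning
proteins on nucleic acids: ratiometric FRET with background/leakage
correction, On-event segmentation at a FRET threshold (events shorter than
an abortive cutoff are kept but excluded from autocorrelation), per-event
FRET autocorrelation pooled across events, and a single-exponential fit of
the pooled decay whose time constant is reported as the *sliding time* — the
timescale of 1D diffusion along the duplex.

The autocorrelation is implemented as the mean-subtracted, variance-
normalized sample autocovariance of E within each event (biased 1/n
estimator), pooled across events with weights equal to the number of
contributing frame pairs.  This is the reading of the convolution-style
correlation integral under which a single-exponential decay fit is
meaningful; the per-event mean subtraction removes event-to-event offsets
before pooling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .fret_sim import FluorescenceTrace, FretModelParams

__all__ = [
    "FretSeries",
    "BindingEvent",
    "AutocorrelationResult",
    "DwellStats",
    "FretHistogram",
    "SlidingTimeModel",
    "SlidingTimeResults",
    "compute_fret",
    "segment_events",
    "anticorrelation_score",
    "autocorrelate_events",
    "autocorrelate_traces",
    "fit_sliding_time",
    "residence_stats",
    "gated_fret_histogram",
]


@dataclass
class FretSeries:
    """Per-frame FRET efficiency with a validity mask.

    ``efficiency`` is clamped to [0, 1]; ``valid`` is False for frames whose
    corrected total intensity fell below the masking floor.  Masked frames
    are excluded from every downstream statistic.
    """

    efficiency: np.ndarray
    valid: np.ndarray
    frame_interval: float

    @property
    def all_masked(self) -> bool:
        return not bool(self.valid.any())


@dataclass
class BindingEvent:
    """One contiguous On interval, half-open in frames."""

    start_frame: int
    end_frame: int
    duration: float
    classification: str  # "on" | "abortive"
    mean_fret: float
    anticorrelation: Optional[float] = None

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class AutocorrelationResult:
    """Pooled FRET autocorrelation and (optionally) its exponential fit."""

    lags: np.ndarray
    g: np.ndarray
    n_pairs: np.ndarray
    n_events: int
    sliding_time: Optional[float] = None
    sliding_time_se: Optional[float] = None
    amplitude: Optional[float] = None
    offset: float = 0.0
    fit_failed: bool = False


@dataclass
class DwellStats:
    """Residence ('on') times per condition with a two-sample comparison."""

    times: dict[str, np.ndarray]
    mean: dict[str, float]
    sd: dict[str, float]
    t_statistic: Optional[float] = None
    p_value: Optional[float] = None
    comparison: Optional[tuple[str, str]] = None
    paired: bool = False


@dataclass
class FretHistogram:
    """High-FRET-gated histogram of On-state frames."""

    bin_edges: np.ndarray
    counts: np.ndarray
    gate: float
    n_traces: int
    n_frames: int
    empty: bool = False

    def interdecile_span(self) -> float:
        """Span between the 10th and 90th percentiles of the binned E values."""
        if self.counts.sum() == 0:
            return 0.0
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        cum = np.cumsum(self.counts) / self.counts.sum()
        q10 = centers[np.searchsorted(cum, 0.10)]
        q90 = centers[np.searchsorted(cum, 0.90)]
        return float(q90 - q10)


def compute_fret(trace: FluorescenceTrace,
                 corrections: FretModelParams,
                 min_total_fraction: float = 0.1) -> FretSeries:
    """Ratiometric FRET with background subtraction and leakage correction.

    ``E = A' / (A' + D')`` where ``D' = I_D - bg_D`` and
    ``A' = I_A - bg_A - leakage * D'``.  Frames with corrected total
    ``A' + D'`` below ``min_total_fraction * donor_total_intensity`` are
    masked.  E is clamped to [0, 1].
    """
    d = trace.donor - corrections.background_donor
    a = (trace.acceptor - corrections.background_acceptor
         - corrections.leakage_fraction * d)
    total = a + d
    floor = min_total_fraction * corrections.donor_total_intensity
    valid = total >= floor
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(valid, a / np.where(valid, total, 1.0), np.nan)
    e = np.clip(e, 0.0, 1.0)
    return FretSeries(efficiency=e, valid=valid,
                      frame_interval=trace.frame_interval)


def segment_events(fret: FretSeries,
                   on_threshold: float = 0.6,
                   min_frames: int = 3,
                   abortive_cutoff: float = 2.0) -> list[BindingEvent]:
    """Segment maximal runs of unmasked frames with E > threshold.

    Runs of at least ``min_frames`` become events; events shorter than
    ``abortive_cutoff`` seconds are classified abortive (they are retained
    in the event list but excluded from autocorrelation pooling).
    """
    if not (0.0 < on_threshold < 1.0):
        raise ValueError("on_threshold must be in (0, 1)")
    on = fret.valid & (fret.efficiency > on_threshold)
    padded = np.concatenate(([False], on, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    events: list[BindingEvent] = []
    for s, t in zip(starts, ends):
        if t - s < min_frames:
            continue
        dur = (t - s) * fret.frame_interval
        cls = "abortive" if dur < abortive_cutoff else "on"
        events.append(BindingEvent(
            start_frame=int(s), end_frame=int(t), duration=float(dur),
            classification=cls,
            mean_fret=float(np.mean(fret.efficiency[s:t]))))
    return events


def anticorrelation_score(trace: FluorescenceTrace,
                          event: BindingEvent) -> float:
    """Pearson correlation of frame-to-frame donor vs acceptor changes.

    Genuine binding/scanning gives strongly negative scores (donor loss is
    acceptor gain).  Returns NaN for zero-variance channels; the caller can
    flag such events.  The score is stored on the event.
    """
    if event.n_frames < 3:
        raise ValueError("anticorrelation needs an event of >= 3 frames")
    s, t = event.start_frame, event.end_frame
    dd = np.diff(trace.donor[s:t])
    da = np.diff(trace.acceptor[s:t])
    if np.std(dd) == 0 or np.std(da) == 0:
        event.anticorrelation = float("nan")
        return float("nan")
    r = float(stats.pearsonr(dd, da).statistic)
    event.anticorrelation = r
    return r


def _event_autocov(x: np.ndarray, n_lags: int):
    """Biased (1/n) normalized autocovariance of one event; None if flat."""
    n = x.size
    xc = x - x.mean()
    var = float(np.mean(xc * xc))
    # flat within rounding error: no defined normalized autocorrelation
    if var <= 1e-20 * max(1.0, float(x.mean()) ** 2):
        return None
    k_max = min(n_lags, n)
    g = np.full(n_lags, np.nan)
    w = np.zeros(n_lags)
    for k in range(k_max):
        g[k] = float(np.dot(xc[: n - k], xc[k:])) / n / var
        w[k] = n - k
    return g, w


def autocorrelate_events(events: Sequence[BindingEvent],
                         fret: FretSeries,
                         max_lag: float = 1.0) -> AutocorrelationResult:
    """Pool per-event FRET autocorrelations into one decay curve.

    Only non-abortive ("on") events contribute.  Each event's curve is the
    biased, per-event-mean-subtracted, variance-normalized autocovariance;
    pooling averages G(lag) across events weighted by the number of frame
    pairs each event contributes at that lag, so G(0) = 1 exactly.
    Raises if every usable event has zero FRET variance.
    """
    dt = fret.frame_interval
    n_lags = int(round(max_lag / dt)) + 1
    num = np.zeros(n_lags)
    den = np.zeros(n_lags)
    n_used = 0
    for ev in events:
        if ev.classification != "on" or ev.n_frames < 2:
            continue
        x = fret.efficiency[ev.start_frame:ev.end_frame]
        out = _event_autocov(np.asarray(x, dtype=float), n_lags)
        if out is None:
            continue
        g, w = out
        ok = w > 0
        num[ok] += g[ok] * w[ok]
        den[ok] += w[ok]
        n_used += 1
    if n_used == 0 or den[0] == 0:
        raise ValueError(
            "no event with non-zero FRET variance: autocorrelation undefined")
    g_pooled = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    lags = np.arange(n_lags) * dt
    keep = den > 0
    return AutocorrelationResult(lags=lags[keep], g=g_pooled[keep],
                                 n_pairs=den[keep], n_events=n_used)


def autocorrelate_traces(pairs: Sequence[tuple[Sequence[BindingEvent],
                                               FretSeries]],
                         max_lag: float = 1.0) -> AutocorrelationResult:
    """Pool event autocorrelations across many traces (movies).

    Equivalent to :func:`autocorrelate_events` run over the union of events,
    with the same pair-count weighting; traces whose events all have zero
    FRET variance are skipped, and an error is raised only if no trace
    contributes.
    """
    num = den = None
    lags = None
    n_events = 0
    for events, fret in pairs:
        try:
            r = autocorrelate_events(events, fret, max_lag=max_lag)
        except ValueError:
            continue
        if num is None:
            lags = r.lags
            num = r.g * r.n_pairs
            den = r.n_pairs.copy()
        else:
            n = min(num.size, r.g.size)
            num[:n] += r.g[:n] * r.n_pairs[:n]
            den[:n] += r.n_pairs[:n]
        n_events += r.n_events
    if num is None:
        raise ValueError("no trace with usable events for autocorrelation")
    return AutocorrelationResult(lags=lags, g=num / np.maximum(den, 1e-300),
                                 n_pairs=den, n_events=n_events)


class SlidingTimeModel:
    """Single-exponential decay model ``G(lag) = A exp(-lag/tau) + C``.

    A minimal model/results pair around the weighted least-squares fit of a
    pooled autocorrelation curve.  Weights default to sqrt(n_pairs), the
    effective information content of each lag.
    """

    def __init__(self, lags: np.ndarray, g: np.ndarray,
                 weights: Optional[np.ndarray] = None,
                 fit_offset: bool = False):
        self.lags = np.asarray(lags, dtype=float)
        self.g = np.asarray(g, dtype=float)
        self.weights = (np.ones_like(self.lags) if weights is None
                        else np.asarray(weights, dtype=float))
        self.fit_offset = fit_offset
        if self.lags.size < 4:
            raise ValueError("need >= 4 lag points to fit a decay")

    def fit(self) -> "SlidingTimeResults":
        lags, g = self.lags, self.g
        sigma = 1.0 / np.sqrt(np.maximum(self.weights, 1.0))
        span = max(lags[-1] - lags[0], lags[1] - lags[0])
        below = np.flatnonzero(g < np.exp(-1.0))
        tau0 = lags[below[0]] if below.size and below[0] > 0 else span / 3.0
        tau0 = max(tau0, 1e-6)
        try:
            if self.fit_offset:
                def f(l, a, tau, c):
                    return a * np.exp(-l / tau) + c
                p0 = [max(g[0], 0.1), tau0, 0.0]
                bounds = ([0.0, 1e-9, -1.0], [10.0, 100.0 * span, 1.0])
            else:
                def f(l, a, tau):
                    return a * np.exp(-l / tau)
                p0 = [max(g[0], 0.1), tau0]
                bounds = ([0.0, 1e-9], [10.0, 100.0 * span])
            popt, pcov = optimize.curve_fit(
                f, lags, g, p0=p0, sigma=sigma, absolute_sigma=False,
                bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            return SlidingTimeResults(model=self, failed=True)
        perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        tau, tau_se = float(popt[1]), float(perr[1])
        if not np.isfinite(tau) or tau <= 0:
            return SlidingTimeResults(model=self, failed=True)
        return SlidingTimeResults(
            model=self, amplitude=float(popt[0]), tau=tau, tau_se=tau_se,
            offset=float(popt[2]) if self.fit_offset else 0.0)


@dataclass
class SlidingTimeResults:
    model: SlidingTimeModel
    amplitude: Optional[float] = None
    tau: Optional[float] = None
    tau_se: Optional[float] = None
    offset: float = 0.0
    failed: bool = False

    def summary(self) -> str:
        if self.failed:
            return "SlidingTimeModel fit: FAILED (non-convergence or tau <= 0)"
        lines = [
            "SlidingTimeModel fit: G(lag) = A exp(-lag/tau) + C",
            f"  sliding time tau : {self.tau:.4g} s (SE {self.tau_se:.2g})",
            f"  amplitude A      : {self.amplitude:.4g}",
            f"  offset C         : {self.offset:.4g}"
            + ("" if self.model.fit_offset else " (fixed)"),
            f"  n lag points     : {self.model.lags.size}",
        ]
        return "\n".join(lines)


def fit_sliding_time(result: AutocorrelationResult,
                     fit_range: Optional[tuple[float, float]] = None,
                     fit_offset: bool = False,
                     g_floor: float = 0.05) -> AutocorrelationResult:
    """Fit the pooled decay; returns a copy with tau and its SE filled in.

    The default window runs from lag 0 up to (and including) the first lag
    where G drops below ``g_floor``; pass ``fit_range=(lo, hi)`` in seconds
    to override.  Failure to converge, or tau <= 0, sets ``fit_failed``
    rather than silently substituting a value.
    """
    lags, g, w = result.lags, result.g, result.n_pairs
    if fit_range is not None:
        sel = (lags >= fit_range[0]) & (lags <= fit_range[1])
    else:
        below = np.flatnonzero(g < g_floor)
        stop = below[0] + 1 if below.size else lags.size
        sel = np.zeros(lags.size, dtype=bool)
        sel[:stop] = True
    if sel.sum() < 4:
        return dataclasses.replace(result, fit_failed=True)
    try:
        res = SlidingTimeModel(lags[sel], g[sel], weights=w[sel],
                               fit_offset=fit_offset).fit()
    except ValueError:
        return dataclasses.replace(result, fit_failed=True)
    if res.failed:
        return dataclasses.replace(result, fit_failed=True)
    return dataclasses.replace(result, sliding_time=res.tau,
                               sliding_time_se=res.tau_se,
                               amplitude=res.amplitude, offset=res.offset,
                               fit_failed=False)


def residence_stats(events_by_condition: dict[str, Sequence[BindingEvent]],
                    paired: bool = False) -> DwellStats:
    """Residence-time lists with a two-tailed two-sample t comparison.

    With exactly two conditions a Welch t-test is run by default; ``paired``
    switches to a paired test (conditions must then have equal length, with
    entries matched by position — the explicit pairing key).
    """
    times = {c: np.array([ev.duration for ev in evs], dtype=float)
             for c, evs in events_by_condition.items()}
    for c, t in times.items():
        if t.size < 2:
            raise ValueError(f"condition {c!r} needs >= 2 events")
        if np.any(t <= 0):
            raise ValueError("residence times must be > 0")
    mean = {c: float(t.mean()) for c, t in times.items()}
    sd = {c: float(t.std(ddof=1)) for c, t in times.items()}
    out = DwellStats(times=times, mean=mean, sd=sd, paired=paired)
    if len(times) == 2:
        (c1, t1), (c2, t2) = times.items()
        if paired:
            if t1.size != t2.size:
                raise ValueError("paired comparison needs matched lists")
            if np.array_equal(t1, t2):
                tt, pp = 0.0, 1.0
            else:
                r = stats.ttest_rel(t1, t2)
                tt, pp = float(r.statistic), float(r.pvalue)
        else:
            if np.array_equal(t1, t2):
                tt, pp = 0.0, 1.0
            else:
                r = stats.ttest_ind(t1, t2, equal_var=False)
                tt, pp = float(r.statistic), float(r.pvalue)
        out.t_statistic, out.p_value, out.comparison = tt, pp, (c1, c2)
    return out


def gated_fret_histogram(fret_series: Sequence[FretSeries],
                         events_per_trace: Sequence[Sequence[BindingEvent]],
                         high_fret_gate: float = 0.8,
                         bins: int = 40) -> FretHistogram:
    """Histogram of On-state frames from traces that visit high FRET.

    A trace qualifies if any frame inside one of its non-abortive events
    exceeds the gate; all On-state frames of qualifying traces are binned
    over [0, 1].  The total count equals the number of gated On frames
    (conservation is a tested invariant).
    """
    if not (0.0 < high_fret_gate < 1.0):
        raise ValueError("gate must be in (0, 1)")
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts = np.zeros(bins, dtype=int)
    n_traces = 0
    n_frames = 0
    for fs, events in zip(fret_series, events_per_trace):
        on_idx = []
        for ev in events:
            if ev.classification == "on":
                on_idx.append(np.arange(ev.start_frame, ev.end_frame))
        if not on_idx:
            continue
        idx = np.concatenate(on_idx)
        e = fs.efficiency[idx]
        if not np.any(e > high_fret_gate):
            continue
        h, _ = np.histogram(np.clip(e, 0.0, 1.0 - 1e-12), bins=edges)
        counts += h
        n_traces += 1
        n_frames += idx.size
    return FretHistogram(bin_edges=edges, counts=counts, gate=high_fret_gate,
                         n_traces=n_traces, n_frames=n_frames,
                         empty=(n_traces == 0))
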