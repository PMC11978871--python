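import numpy as np
import pytest

from pkrscan import fret_analysis as fa
from pkrscan import fret_sim as fs


@pytest.fixture(scope="session")
def scan_geometry():
    """FRET geometry resolving the full length of a ~100 bp duplex."""
    return fs.SCANNING_GEOMETRY


def make_scanning_config(length=112.0, seed=0, n_frames=120_000,
                         diffusion=1000.0, k_off=0.12, **kw):
    """Study-condition trace simulation: 33 ms frames, 15 bp footprint."""
    return fs.SimulationConfig(
        duplex_length=length, n_frames=n_frames, substeps_per_frame=5,
        diffusion_coeff=diffusion, k_on=0.02, protein_conc=50.0,
        k_off=k_off, rng_seed=seed, **kw)


def analyze_trace(config, geometry, on_threshold=0.1, min_frames=5,
                  max_lag=2.0):
    """Simulate, render, segment and pool-autocorrelate one long trace."""
    truth = (fs.simulate_with_obstacle(config) if config.pact_present
             else fs.simulate_trajectory(config))
    trace = fs.render_intensities(truth, geometry)
    fret = fa.compute_fret(trace, geometry)
    events = fa.segment_events(fret, on_threshold=on_threshold,
                               min_frames=min_frames)
    return truth, trace, fret, events


def fitted_sliding_time(length, seed, geometry, **kw):
    cfg = make_scanning_config(length=length, seed=seed, **kw)
    _, _, fret, events = analyze_trace(cfg, geometry)
    r = fa.autocorrelate_events(events, fret, max_lag=2.0)
    r = fa.fit_sliding_time(r)
    assert not r.fit_failed
    return r.sliding_time


def ar1_fret_series(n_events=200, n_frames_per_event=400, tau_frames=5.0,
                    dt=0.033, seed=0):
    """Exact AR(1) FRET with known correlation time, as stacked events."""
    rng = np.random.default_rng(seed)
    phi = np.exp(-1.0 / tau_frames)
    innov_sd = np.sqrt(1.0 - phi ** 2)
    chunks, events = [], []
    pos = 0
    for _ in range(n_events):
        x = np.empty(n_frames_per_event)
        x[0] = rng.normal()
        eps = rng.normal(0.0, innov_sd, size=n_frames_per_event - 1)
        for t in range(1, n_frames_per_event):
            x[t] = phi * x[t - 1] + eps[t - 1]
        chunks.append(0.5 + 0.1 * x)
        events.append(fa.BindingEvent(pos, pos + n_frames_per_event,
                                      n_frames_per_event * dt, "on", 0.5))
        pos += n_frames_per_event
    series = fa.FretSeries(np.concatenate(chunks), np.ones(pos, dtype=bool),
                           dt)
    return series, events
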