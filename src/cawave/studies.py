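"""Reference study conditions: canned simulation + analysis workflows.

Each function builds one of the package's benchmark studies — synthetic
recordings whose ground-truth parameters are chosen to match published
cochlear imaging quantities — runs the full pipeline on them, and
returns the measured quantity.  They are used by the test suite and by
``scripts/acceptance.py``; everything is deterministic given the seed.

Problem sizes (number of seeds, recording durations, field sizes) are
chosen so the whole set runs in a few minutes on one core; see the
methods note for the rationale behind each fixture's nuisance
parameters (rise times, amplitudes, debounce windows).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import classify_transients, track_cell_area, transient_prevalence
from .event_detect import (
    DetectionParams,
    detect_events,
    detect_peaks,
    estimate_baseline,
    peak_kinetics,
    peak_rate,
)
from .synthgen import Cell, SynthConfig, event_waveform, generate_movie, generate_traces
from .trace_extract import extract_traces, make_roi_grid
from .wave_detect import WaveParams, cluster_waves, wave_rate, wave_speed

#: ROI pitch of the standard 56-px grid, um
PITCH = 11.0


def _subseed(seed: int, i: int) -> int:
    return (seed * 1000 + i) % (2**31 - 1)


def chain_wave_speed(lag_s: float, n_waves: int = 20, n_members: int = 8) -> float:
    """Mean estimated speed of noiseless chain waves, um/s.

    Each wave is a chain of ``n_members`` adjacent ROIs at 11-um pitch
    whose onsets step by ``lag_s`` per ROI; successive waves run over
    the same chain 50 s apart (far beyond the linking window).  The
    generating speed is ``11 / lag_s`` and the origin-constrained
    regression recovers it exactly, so the mean is a pure check of the
    clustering + speed estimator path.
    """
    grid = make_roi_grid(56 * n_members, 56)
    rows = []
    for w in range(n_waves):
        t0 = 50.0 * w
        for m in range(n_members):
            rows.append((m, t0 + m * lag_s))
    events = pd.DataFrame(rows, columns=["roi", "onset_s"])
    waves = cluster_waves(events, grid, WaveParams())
    assert len(waves) == n_waves, f"expected {n_waves} waves, found {len(waves)}"
    speeds = [wave_speed(w) for w in waves]
    assert all(v is not None for v in speeds)
    return float(np.mean(speeds))


def _wave_field(n_sites_x: int, n_sites_y: int, radius_um: float):
    """Sites on a 110-um grid of ROI centers, cells filling their disks."""
    spacing_cols = 10  # 110 um at 11-um pitch
    margin = 5
    n_cols = spacing_cols * (n_sites_x - 1) + 2 * margin + 1
    n_rows = spacing_cols * (n_sites_y - 1) + 2 * margin + 1
    sites = []
    for sy in range(n_sites_y):
        for sx in range(n_sites_x):
            col = margin + spacing_cols * sx
            row = margin + spacing_cols * sy
            sites.append((5.5 + PITCH * col, 5.5 + PITCH * row))
    cells = []
    for row in range(n_rows):
        for col in range(n_cols):
            x, y = 5.5 + PITCH * col, 5.5 + PITCH * row
            if any(np.hypot(x - px, y - py) <= radius_um for px, py in sites):
                cells.append(Cell(x, y, "supporting"))
    return 56 * n_cols, 56 * n_rows, sites, cells


def wave_rate_study(
    n_sites: int,
    site_rate: float,
    duration: float,
    speed: float,
    seed: int,
    n_seeds: int = 10,
    radius_um: float = 44.0,
) -> np.ndarray:
    """Organ-level wave rates (waves/s) per seed.

    Initiation sites sit on a 110-um grid (disks of supporting cells at
    11-um pitch around each site, spatially disjoint so concurrent
    waves cannot cross-link); each site fires as an independent Poisson
    process, so the nominal organ-level rate is ``n_sites * site_rate``.
    Returns ``(detected, planted)`` arrays, one entry per seed.
    """
    layouts = {6: (6, 1), 40: (8, 5)}
    nx, ny = layouts.get(n_sites, (n_sites, 1))
    w_px, h_px, sites, cells = _wave_field(nx, ny, radius_um)
    detected, planted = [], []
    for i in range(n_seeds):
        cfg = SynthConfig(
            field_width_px=w_px,
            field_height_px=h_px,
            duration=duration,
            cells=cells,
            transient_rate=0.0,
            transient_amplitude=30.0,
            rise_duration=2.0,
            decay_tau=4.0,
            wave_sites=sites,
            wave_site_rate=site_rate,
            wave_speed=speed,
            wave_radius=radius_um,
            seed=_subseed(seed, i),
        )
        tm, truth = generate_traces(cfg)
        events = detect_events(tm, DetectionParams(min_separation=0.0))
        waves = cluster_waves(events, tm.grid, WaveParams())
        detected.append(wave_rate(waves, tm.duration))
        planted.append(truth.n_waves / tm.duration)
    return np.asarray(detected), np.asarray(planted)


def peak_rate_study(
    n_cells: int,
    cell_rate: float,
    seed: int,
    n_seeds: int = 10,
    duration: float = 600.0,
    amplitude: float = 20.0,
    decay_tau: float = 2.0,
    rise_duration: float = 2.5,
) -> np.ndarray:
    """Field-level peak rates (peaks/s) per seed.

    ``n_cells`` active ROIs fire independent Poisson transients at
    ``cell_rate`` each, so the nominal field rate is their product.
    The 2.5-s rise keeps every transient above threshold for more than
    one 2-s frame interval, so losses are dominated by genuinely
    overlapping excursions rather than sampling.
    Returns ``(detected, planted)`` arrays, one entry per seed.
    """
    side = int(np.ceil(np.sqrt(n_cells)))
    cells = [Cell(5.5 + PITCH * (i % side), 5.5 + PITCH * (i // side), "supporting")
             for i in range(n_cells)]
    detected, planted = [], []
    for i in range(n_seeds):
        cfg = SynthConfig(
            field_width_px=56 * side,
            field_height_px=56 * side,
            duration=duration,
            cells=cells,
            transient_rate=cell_rate,
            transient_amplitude=amplitude,
            rise_duration=rise_duration,
            decay_tau=decay_tau,
            seed=_subseed(seed, i),
        )
        tm, truth = generate_traces(cfg)
        events = detect_events(tm, DetectionParams(min_separation=0.0))
        detected.append(peak_rate(events, tm.duration).peaks_per_s)
        planted.append(truth.n_events / tm.duration)
    return np.asarray(detected), np.asarray(planted)


def decay_time_study(
    decay_tau: float,
    n_traces: int,
    seed: int,
    amplitude_sd: float = 100.0,
    sample_interval: float = 0.1,
    duration: float = 600.0,
) -> np.ndarray:
    """Measured decay times of isolated high-SNR transients, s.

    One transient per trace (1-s linear rise to ``amplitude_sd`` baseline
    SDs, exponential decay), unit-SD Gaussian noise, 0.1-s sampling.
    The full estimation path runs per trace (robust baseline, 10x-SD
    detection, interpolated threshold-crossing kinetics); a 5-s debounce
    window suppresses threshold chatter, which at this sampling rate
    spans a few seconds around the slow downward crossing.  Censored
    decays are excluded.
    """
    t = np.arange(0.0, duration, sample_interval)
    params = DetectionParams(min_separation=5.0)
    decays = []
    for i in range(n_traces):
        rng = np.random.default_rng(_subseed(seed, i))
        trace = 100.0 + rng.normal(0.0, 1.0, t.size) + event_waveform(
            t, 50.0, amplitude_sd, 1.0, decay_tau
        )
        base = estimate_baseline(trace, params)
        events = detect_peaks(trace, base, params, sample_interval)
        for ev in events:
            _, decay = peak_kinetics(trace, ev, base, params, sample_interval)
            if ev.complete and decay is not None:
                decays.append(decay)
    return np.asarray(decays)


def classification_study(seed: int) -> dict:
    """The 80-outer-hair-cell fast/slow prevalence fixture.

    80 OHCs in a 20 x 4 ROI field; 7 carry one fast transient each (no
    morphology change), 13 carry one slow transient each (1.5x radial
    swelling then fragmentation), 60 stay silent.  Runs the full movie
    pipeline: render, extract, detect, track areas, classify.  Returns
    the per-label prevalence percentages (half-up, one decimal).
    """
    cells = [Cell(5.5 + PITCH * (i % 20), 5.5 + PITCH * (i // 20), "OHC")
             for i in range(80)]
    fixed = [(i, "fast", 40.0 + 2.0 * i) for i in range(7)]
    fixed += [(i, "slow", 40.0 + 1.5 * (i - 7)) for i in range(7, 20)]
    cfg = SynthConfig(
        field_width_px=56 * 20,
        field_height_px=56 * 4,
        duration=160.0,
        cells=cells,
        transient_rate=0.0,
        transient_amplitude=20.0,
        rise_duration=2.0,
        decay_tau=4.0,
        slow_tau=30.0,
        swell_factor=1.5,
        fixed_events=fixed,
        seed=seed,
    )
    movie, _ = generate_movie(cfg)
    grid = cfg.grid()
    traces = extract_traces(movie, grid)
    events = detect_events(traces, DetectionParams())
    baseline_frames = range(15)  # first 30 s precede every planted event
    records = []
    for roi in sorted(events["roi"].unique()):
        x0, y0 = grid.boxes[roi]
        track = track_cell_area(movie, (int(x0), int(y0), grid.roi_size_px),
                                baseline_frames)
        for ev in events[events["roi"] == roi].itertuples():
            records.append((int(roi), ev, track))
    classes = classify_transients(records)
    return transient_prevalence(len(cells), classes)
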