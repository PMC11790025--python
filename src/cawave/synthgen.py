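"""Synthetic GCaMP recordings with known ground truth.

Emulates the features of cochlear calcium imaging that the analysis
pipeline consumes: a static field of cells with baseline fluorescence
and i.i.d. Gaussian noise, spontaneous cell-level transients (linear
rise, single-exponential decay), intercellular Ca2+ waves propagating
radially from point initiation sites at constant speed, and rare "slow"
hair-cell transients accompanied by cell swelling and fragmentation.

The generator exists so every downstream stage (extraction, detection,
kinetics, wave clustering, classification) can be validated against an
exact ground truth instead of unavailable raw movies.  It deliberately
omits photophysics (bleaching, indicator kinetics), the optical PSF and
motion; see the methods note for what that implies about the tests.

Two output levels are provided:

* :func:`generate_traces` — directly synthesises the ROI-by-frame trace
  table (fast; used for rate and kinetics studies).
* :func:`generate_movie` — renders a pixel-level movie of disk-shaped
  cells (used to exercise extraction and area tracking/classification).

Reproducibility: one random stream per seed, with fixed substreams per
cell / wave site / ROI, so adding a cell never perturbs the noise or
event times of the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .trace_extract import (
    DEFAULT_PIXEL_SIZE,
    DEFAULT_ROI_SIZE_PX,
    Movie,
    RoiGrid,
    TraceMatrix,
    make_roi_grid,
)

CELL_KINDS = ("IHC", "OHC", "supporting")

# substream domains for per-entity random streams
_D_CELL, _D_SITE, _D_NOISE, _D_PIXEL, _D_ASSIGN = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class Cell:
    """A cell at physical position (x, y) um with a class label."""

    x_um: float
    y_um: float
    kind: str = "supporting"

    def __post_init__(self):
        if self.kind not in CELL_KINDS:
            raise ValueError(f"unknown cell kind {self.kind!r}; expected one of {CELL_KINDS}")


@dataclass
class SynthConfig:
    """Parameters of one synthetic recording.

    Defaults describe a juvenile/adult-style recording: 2-s frame
    interval, 10-minute duration, a 1400 x 728-px field that tiles into
    325 ROIs of 56 px (11 um), and transient amplitudes of 20x the
    noise SD (comfortably above the 10x-SD detection threshold).
    Rates are per-cell / per-site Poisson rates in events/s.
    """

    field_width_px: int = 1400
    field_height_px: int = 728
    pixel_size: float = DEFAULT_PIXEL_SIZE  # um/px; 56 px = 11 um
    roi_size_px: int = DEFAULT_ROI_SIZE_PX
    frame_interval: float = 2.0  # s
    duration: float = 600.0  # s
    baseline_level: float = 100.0  # intensity units
    noise_sd: float = 2.0  # intensity units
    cells: list = field(default_factory=list)  # list of Cell
    transient_rate: float = 0.0  # events/s per cell
    transient_amplitude: float = 20.0  # multiple of noise_sd
    rise_duration: float = 1.0  # s, linear rise to peak
    decay_tau: float = 2.0  # s, exponential decay constant
    wave_sites: list = field(default_factory=list)  # list of (x_um, y_um)
    wave_site_rate: float = 0.005  # events/s per site
    wave_speed: float = 15.5  # um/s
    wave_radius: float = 44.0  # um, hard spatial cutoff
    slow_fraction: float = 0.0  # fraction of OHCs given one slow transient
    slow_tau: float = 60.0  # s, decay constant of slow transients
    swell_factor: float = 1.5  # linear radius multiplier at slow peak
    cell_radius: float = 3.0  # um, rendered disk radius
    cell_contrast: float = 10.0  # resting interior elevation, x noise_sd
    fixed_events: list = field(default_factory=list)  # (cell_idx, "fast"|"slow", onset_s)
    seed: int = 0

    def __post_init__(self):
        self.cells = [c if isinstance(c, Cell) else Cell(*c) for c in self.cells]
        if min(self.transient_rate, self.wave_site_rate, self.rise_duration,
               self.decay_tau, self.slow_tau, self.noise_sd) < 0:
            raise ValueError("rates, durations and noise_sd must be >= 0")
        if self.swell_factor < 1:
            raise ValueError("swell_factor must be >= 1")
        if self.wave_sites and self.wave_speed <= 0:
            raise ValueError("wave_speed must be positive when wave_sites are present")
        if not 0 <= self.slow_fraction <= 1:
            raise ValueError("slow_fraction must lie in [0, 1]")
        if self.duration < self.frame_interval:
            raise ValueError("duration must cover at least one frame interval")
        w_um = self.field_width_px * self.pixel_size
        h_um = self.field_height_px * self.pixel_size
        for c in self.cells:
            if not (0 <= c.x_um < w_um and 0 <= c.y_um < h_um):
                raise ValueError(f"cell at ({c.x_um}, {c.y_um}) um lies outside the field")
        for (x, y) in self.wave_sites:
            if not (0 <= x < w_um and 0 <= y < h_um):
                raise ValueError(f"wave site at ({x}, {y}) um lies outside the field")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration / self.frame_interval + 1e-9))

    def grid(self) -> RoiGrid:
        return make_roi_grid(
            self.field_width_px, self.field_height_px, self.roi_size_px, self.pixel_size
        )

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cells" in raw:
            raw["cells"] = [Cell(**c) if isinstance(c, dict) else Cell(*c) for c in raw["cells"]]
        if "wave_sites" in raw:
            raw["wave_sites"] = [tuple(s) for s in raw["wave_sites"]]
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted events and waves of one synthetic recording.

    ``events`` columns: cell_id, roi, kind, type (fast|slow|wave),
    onset_s, amplitude (intensity units), rise_s, decay_tau_s, wave_id
    (-1 for non-wave events).  ``waves`` columns: wave_id, x_um, y_um,
    start_s, speed_um_s, radius_um, n_members.
    """

    events: pd.DataFrame
    waves: pd.DataFrame

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_waves(self) -> int:
        return len(self.waves)


_EVENT_COLS = ["cell_id", "roi", "kind", "type", "onset_s", "amplitude",
               "rise_s", "decay_tau_s", "wave_id"]
_WAVE_COLS = ["wave_id", "x_um", "y_um", "start_s", "speed_um_s", "radius_um", "n_members"]


def _rng(seed: int, domain: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(domain, index)))


def event_waveform(t: np.ndarray, onset: float, amplitude: float,
                   rise: float, tau: float) -> np.ndarray:
    """Linear rise over ``rise`` seconds to ``amplitude``, then exp decay.

    ``t`` may be any array of sample times; values before ``onset`` are 0.
    A zero ``rise`` gives an instantaneous step to the peak.
    """
    dt = np.asarray(t, dtype=float) - onset
    out = np.zeros_like(dt)
    if rise > 0:
        rising = (dt >= 0) & (dt < rise)
        out[rising] = amplitude * dt[rising] / rise
    decaying = dt >= rise
    out[decaying] = amplitude * np.exp(-(dt[decaying] - rise) / tau)
    return out


def _poisson_times(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _plan_events(config: SynthConfig, grid: RoiGrid):
    """Draw all ground-truth events and waves for a config.

    Returns (events_df, waves_df, cell_rois).  Activation times of wave
    members are exactly ``start + distance/speed`` (machine precision).
    """
    cells = config.cells
    cell_xy = np.array([[c.x_um, c.y_um] for c in cells]).reshape(-1, 2)
    cell_rois = np.array([grid.roi_index(c.x_um, c.y_um) for c in cells], dtype=int)
    if len(set(cell_rois)) != len(cell_rois):
        raise ValueError("each cell must map to its own ROI (two cells share one)")

    amp = config.transient_amplitude * config.noise_sd
    rows = []

    # spontaneous fast transients, one Poisson stream per cell
    if config.transient_rate > 0:
        for i, c in enumerate(cells):
            for t0 in _poisson_times(_rng(config.seed, _D_CELL, i),
                                     config.transient_rate, config.duration):
                rows.append((i, cell_rois[i], c.kind, "fast", t0, amp,
                             config.rise_duration, config.decay_tau, -1))

    # deterministically planted events (for fixtures with exact counts)
    for cell_i, ev_type, t0 in config.fixed_events:
        if ev_type not in ("fast", "slow"):
            raise ValueError(f"fixed_events type must be fast or slow, got {ev_type!r}")
        tau = config.slow_tau if ev_type == "slow" else config.decay_tau
        rows.append((cell_i, cell_rois[cell_i], cells[cell_i].kind, ev_type, float(t0),
                     amp, config.rise_duration, tau, -1))

    # slow transients: a fixed fraction of OHCs get exactly one each
    ohc_idx = [i for i, c in enumerate(cells) if c.kind == "OHC"]
    n_slow = int(round(config.slow_fraction * len(ohc_idx)))
    if n_slow > 0:
        assign_rng = _rng(config.seed, _D_ASSIGN, 0)
        chosen = assign_rng.permutation(len(ohc_idx))[:n_slow]
        for j in sorted(chosen):
            i = ohc_idx[j]
            # onset early enough that swelling and fragmentation are recorded
            t0 = assign_rng.uniform(0.2, 0.4) * config.duration
            rows.append((i, cell_rois[i], cells[i].kind, "slow", t0, amp,
                         config.rise_duration, config.slow_tau, -1))

    # radial waves from point sites; members are cells within wave_radius
    wave_rows = []
    wave_id = 0
    for s, (sx, sy) in enumerate(config.wave_sites):
        if cell_xy.size:
            dists = np.hypot(cell_xy[:, 0] - sx, cell_xy[:, 1] - sy)
            members = np.flatnonzero(dists <= config.wave_radius)
        else:
            members = np.array([], dtype=int)
        for t0 in _poisson_times(_rng(config.seed, _D_SITE, s),
                                 config.wave_site_rate, config.duration):
            n_mem = 0
            for i in members:
                t_act = t0 + dists[i] / config.wave_speed
                if t_act <= config.duration:
                    rows.append((i, cell_rois[i], cells[i].kind, "wave", t_act, amp,
                                 config.rise_duration, config.decay_tau, wave_id))
                    n_mem += 1
            wave_rows.append((wave_id, sx, sy, t0, config.wave_speed,
                              config.wave_radius, n_mem))
            wave_id += 1

    events = pd.DataFrame(rows, columns=_EVENT_COLS)
    if len(events):
        events = events.sort_values(["cell_id", "onset_s"], kind="stable").reset_index(drop=True)
    waves = pd.DataFrame(wave_rows, columns=_WAVE_COLS)
    return events, waves, cell_rois


def _roi_signal(events: pd.DataFrame, roi: int, times: np.ndarray) -> np.ndarray:
    """Sum of event waveforms landing in one ROI."""
    sig = np.zeros_like(times)
    if len(events) == 0:
        return sig
    for ev in events[events["roi"] == roi].itertuples():
        sig += event_waveform(times, ev.onset_s, ev.amplitude, ev.rise_s, ev.decay_tau_s)
    return sig


def generate_traces(config: SynthConfig) -> tuple[TraceMatrix, GroundTruth]:
    """Synthesize the ROI-by-frame trace table directly.

    Each trace is ``baseline_level + N(0, noise_sd)`` per frame plus the
    sum of the waveforms of the events planted in that ROI.
    """
    grid = config.grid()
    events, waves, _ = _plan_events(config, grid)
    times = np.arange(config.n_frames) * config.frame_interval

    values = np.empty((grid.n_rois, config.n_frames))
    event_rois = set(events["roi"].tolist()) if len(events) else set()
    for r in range(grid.n_rois):
        noise = _rng(config.seed, _D_NOISE, r).normal(0.0, config.noise_sd, config.n_frames)
        values[r] = config.baseline_level + noise
        if r in event_rois:
            values[r] += _roi_signal(events, r, times)

    tm = TraceMatrix(values=values, grid=grid, frame_interval=config.frame_interval)
    return tm, GroundTruth(events=events, waves=waves)


def _disk_mask(h: int, w: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


class _CellWindow:
    """A local pixel window around one cell; keeps rendering O(window)."""

    def __init__(self, h: int, w: int, cx: float, cy: float, r_max: float):
        pad = int(np.ceil(r_max)) + 3
        self.x0 = max(int(np.floor(cx)) - pad, 0)
        self.y0 = max(int(np.floor(cy)) - pad, 0)
        self.x1 = min(int(np.ceil(cx)) + pad + 1, w)
        self.y1 = min(int(np.ceil(cy)) + pad + 1, h)
        self.cx, self.cy = cx - self.x0, cy - self.y0
        self.shape = (self.y1 - self.y0, self.x1 - self.x0)

    def disk(self, r: float, dx: float = 0.0, dy: float = 0.0) -> np.ndarray:
        return _disk_mask(self.shape[0], self.shape[1],
                          self.cx + dx, self.cy + dy, r)

    def add(self, frame: np.ndarray, mask: np.ndarray, value: float) -> None:
        frame[self.y0 : self.y1, self.x0 : self.x1][mask] += value


def generate_movie(config: SynthConfig) -> tuple[Movie, GroundTruth]:
    """Render a pixel-level movie of disk-shaped cells.

    Cell interiors sit ``cell_contrast * noise_sd`` above the background
    at rest and follow the same event waveforms as the trace model.
    Cells with a slow transient swell linearly with the transient (up to
    ``swell_factor`` times the resting radius at the peak) and, once the
    transient has decayed to half its peak, fragment into two disjoint
    half-area blobs.  Pixel noise is i.i.d. Gaussian.
    """
    grid = config.grid()
    events, waves, _ = _plan_events(config, grid)
    h, w = config.field_height_px, config.field_width_px
    n_frames = config.n_frames
    times = np.arange(n_frames) * config.frame_interval
    r0_px = config.cell_radius / config.pixel_size

    # warn (once per pair) about overlapping cells at maximal extent
    cells = config.cells
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            d = np.hypot(cells[i].x_um - cells[j].x_um, cells[i].y_um - cells[j].y_um)
            if d < 2 * config.cell_radius * config.swell_factor:
                warnings.warn(
                    f"cells {i} and {j} overlap (centers {d:.1f} um apart)",
                    stacklevel=2,
                )

    rest = config.cell_contrast * config.noise_sd
    slow_by_cell = {}
    if len(events):
        for ev in events[events["type"] == "slow"].itertuples():
            slow_by_cell[ev.cell_id] = ev

    stack = np.empty((n_frames, h, w), dtype=np.float32)
    noise_rng = _rng(config.seed, _D_PIXEL, 0)
    for j in range(n_frames):
        stack[j] = config.baseline_level + noise_rng.normal(
            0.0, config.noise_sd, size=(h, w)
        ).astype(np.float32)

    for i, c in enumerate(cells):
        cx, cy = c.x_um / config.pixel_size, c.y_um / config.pixel_size
        sub = events[events["cell_id"] == i] if len(events) else events
        signal = np.zeros(n_frames)
        for ev in sub.itertuples():
            signal += event_waveform(times, ev.onset_s, ev.amplitude, ev.rise_s, ev.decay_tau_s)

        win = _CellWindow(h, w, cx, cy, r0_px * config.swell_factor + 4)
        slow = slow_by_cell.get(i)
        if slow is None:
            mask = win.disk(r0_px)
            for j in range(n_frames):
                win.add(stack[j], mask, rest + signal[j])
            continue

        # morphology of a dying cell: swell with the transient, fragment
        # after it has decayed to half-maximum
        peak_t = slow.onset_s + slow.rise_s
        frag_t = peak_t + slow.decay_tau_s * np.log(2.0)
        wf = event_waveform(times, slow.onset_s, slow.amplitude, slow.rise_s, slow.decay_tau_s)
        frac = wf / slow.amplitude  # normalized 0..1 transient course
        r_frag = r0_px / np.sqrt(2.0)  # two half-area blobs
        sep = r_frag + 2.0  # center offset; >= r_frag + 1 px gap keeps blobs disjoint
        for j in range(n_frames):
            if times[j] >= frag_t:
                mask = win.disk(r_frag, dx=-sep) | win.disk(r_frag, dx=sep)
            else:
                r_t = r0_px * (1.0 + (config.swell_factor - 1.0) * frac[j])
                mask = win.disk(r_t)
            win.add(stack[j], mask, rest + signal[j])

    movie = Movie(data=stack, pixel_size=config.pixel_size, frame_interval=config.frame_interval)
    return movie, GroundTruth(events=events, waves=waves)
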