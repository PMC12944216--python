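"""Synthetic protonemal-colony timelapse generator with full ground truth.

Emulates the statistical structure of chitin-stimulated calcium imaging in
moss protonemata: filamentous branching colonies of elongated cells on a dark
background; per-ROI Gaussian-shaped calcium waves (time-symmetric, FW10
~30-120 s); per-ROI characteristic inter-wave intervals (within-ROI CV
~19%, across-ROI CV ~40%); stimulus-locked responses whose onset latency
(tens of seconds) drifts upward over repeated pulses; fast spontaneous
oscillations confined to caulonemal apical tip (CA*) regions; shot/read noise
and PSF blur.  Every stack comes with exact ground truth (geometry, ROI label
map, wave schedule), so each pipeline stage can be scored against what was
actually rendered.

Wave shape is Gaussian in time, parameterized through its FW10 duration via
``sigma = FW10 / (2*sqrt(2 ln 10))``, which matches the observed symmetric
onset/offset and makes the shape metrics analytically checkable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import ROILabelMap, StimulusProtocol, TimelapseStack

__all__ = [
    "Cell",
    "ROIRegion",
    "ColonyGeometry",
    "WaveParams",
    "WaveProgram",
    "AcquisitionModel",
    "GroundTruth",
    "build_geometry",
    "schedule_waves",
    "render_stack",
    "program_traces",
    "simulate_colony",
]

_SIGMA_PER_FW10 = 1.0 / (2.0 * np.sqrt(2.0 * np.log(10.0)))
_PEAK_OFFSET_PER_SIGMA = np.sqrt(2.0 * np.log(10.0))  # 10%-onset to peak

CELL_TYPES = ("CA*", "CA", "CAs", "CH", "CHs", "B")


@dataclass
class Cell:
    filament_id: int
    s0_um: float
    s1_um: float
    width_um: float
    cell_type: str


@dataclass
class ROIRegion:
    region_id: int
    cell_index: int
    s0_um: float
    s1_um: float
    cell_type: str


@dataclass
class ColonyGeometry:
    """Filament centerlines (µm), cells along them, and ground-truth ROI regions."""

    filaments: list[np.ndarray]
    cells: list[Cell]
    roi_regions: list[ROIRegion]

    @property
    def n_regions(self) -> int:
        return len(self.roi_regions)

    def region_types(self) -> list[str]:
        return [r.cell_type for r in self.roi_regions]


@dataclass
class WaveParams:
    """Wave-program parameters; the defaults are the emulated study conditions.

    Intervals: chitin-driven waves recur at a per-ROI characteristic interval
    drawn lognormally around 159.7 s with across-ROI CV ~40%, jittered within
    an ROI with CV 19.2%; CA* tip regions oscillate spontaneously at a median
    85.5 s interval and, when driven, around 144.6 s.  Other spontaneous waves
    are rare (~1.3 per 30 min).  Stimulus-locked latency: mean drifts linearly
    from 25 s (first pulse) to 64 s (last pulse) unless an explicit per-pulse
    drift is given; jitter SD 24 s.  Amplitudes: ~2.5 dF/F0 driven vs
    0.7 spontaneous; durations FW10 ~72 s driven vs 61 s spontaneous, clipped
    to 30-120 s.  A 30 s refractory period suppresses wave initiation after
    each wave.  ``None`` for an interval parameter disables that wave source.
    """

    interval_mean_s: float | None = 159.7
    interval_across_cv: float = 0.40
    interval_within_cv: float = 0.192
    tip_interval_median_s: float | None = 85.5
    tip_driven_interval_s: float = 144.6
    spont_interval_mean_s: float | None = 1385.0
    spont_interval_cv: float = 1.0
    latency_mean_s: float = 25.0
    latency_end_mean_s: float = 64.0
    latency_drift_s_per_pulse: float | None = None
    latency_sd_s: float = 24.0
    response_prob: float = 0.985
    amp_stim: float = 2.5
    amp_spont: float = 0.7
    amp_cv: float = 0.25
    fw10_stim_s: float = 72.0
    fw10_spont_s: float = 61.0
    fw10_cv: float = 0.15
    fw10_min_s: float = 30.0
    fw10_max_s: float = 120.0
    refractory_s: float = 30.0
    f0_mean: float = 120.0
    f0_cv: float = 0.3
    baseline_boost: float = 0.0
    baseline_tau_s: float = 600.0


@dataclass
class ScheduledWave:
    peak_time_s: float
    amplitude: float  # dF/F0
    sigma_s: float
    stimulus_locked: bool = False
    pulse_index: int = -1


@dataclass
class WaveProgram:
    """Per-region wave schedules plus baselines — the rendering ground truth."""

    waves: list[list[ScheduledWave]]
    f0: np.ndarray
    params: WaveParams
    protocol: StimulusProtocol

    @property
    def n_regions(self) -> int:
        return len(self.waves)

    def n_waves(self) -> int:
        return sum(len(w) for w in self.waves)

    def schedule_dict(self) -> dict:
        return {
            "f0": [float(v) for v in self.f0],
            "waves": [
                [
                    {
                        "peak_time_s": w.peak_time_s,
                        "amplitude": w.amplitude,
                        "sigma_s": w.sigma_s,
                        "stimulus_locked": w.stimulus_locked,
                        "pulse_index": w.pulse_index,
                    }
                    for w in region
                ]
                for region in self.waves
            ],
        }


@dataclass
class AcquisitionModel:
    """Camera/optics model: 2.9 µm pixels at 1 frame/s, 1.1 µm PSF, Poisson
    shot noise (gain 1.2) plus Gaussian read noise (SD 3 counts) giving
    per-pixel SNR ~10 at a typical baseline, over a dim sloped background."""

    pixel_size_um: float = 2.9
    frame_interval_s: float = 1.0
    psf_diameter_um: float = 1.1
    poisson_gain: float = 1.2
    read_noise_sd: float = 3.0
    background_level: float = 20.0
    background_gradient: float = 0.2
    noise: bool = True
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "frame_interval_s", "psf_diameter_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class GroundTruth:
    label_map: ROILabelMap
    program: WaveProgram
    stimulus_state: np.ndarray
    region_types: list[str]
    weights: np.ndarray | None = None


# ---------------------------------------------------------------------------
# geometry


def build_geometry(
    seed: int,
    n_filaments: int,
    cells_per_filament: int,
    branch_prob: float = 0.0,
    cell_length_um: tuple[float, float] = (45.0, 75.0),
    tip_region_um: float = 15.0,
) -> ColonyGeometry:
    """Grow a branching filamentous colony; deterministic for a fixed seed.

    Primary filaments radiate from a common origin, each a chain of
    ``cells_per_filament`` cells.  A filament is caulonemal (longer, thinner
    cells, tip typed CA) or chloronemal (tip CH) with equal probability;
    non-tip cells are subapical (CAs/CHs).  Interior cells spawn side branches
    with probability ``branch_prob`` and are retyped B.  Every cell is one ROI
    region, except CA tip cells, whose apical ``tip_region_um`` becomes a
    separate fast-oscillating CA* region.
    """
    if n_filaments < 1 or cells_per_filament < 1:
        raise ValueError("n_filaments and cells_per_filament must be >= 1")
    rng = np.random.default_rng(seed)
    filaments: list[np.ndarray] = []
    cells: list[Cell] = []

    def grow(start: np.ndarray, angle: float, n_cells: int, allow_branch: bool) -> None:
        fid = len(filaments)
        caulonemal = rng.random() < 0.5
        lo, hi = cell_length_um
        if caulonemal:
            lo, hi = lo * 1.2, hi * 1.2
        width = (13.0 if caulonemal else 17.0) * (1.0 + 0.1 * rng.normal())
        width = max(8.0, width)
        pts = [start.astype(float)]
        arcs = [0.0]
        a = angle
        branch_requests = []
        for ci in range(n_cells):
            a += rng.normal(0.0, np.deg2rad(8.0))
            length = rng.uniform(lo, hi)
            nxt = pts[-1] + length * np.array([np.sin(a), np.cos(a)])
            pts.append(nxt)
            arcs.append(arcs[-1] + length)
            is_tip = ci == n_cells - 1
            if is_tip:
                ctype = "CA" if caulonemal else "CH"
            else:
                ctype = "CAs" if caulonemal else "CHs"
            cell = Cell(filament_id=fid, s0_um=arcs[-2], s1_um=arcs[-1],
                        width_um=width, cell_type=ctype)
            cells.append(cell)
            if allow_branch and not is_tip and rng.random() < branch_prob:
                cell.cell_type = "B"
                side = 1.0 if rng.random() < 0.5 else -1.0
                b_angle = a + side * rng.uniform(np.deg2rad(40), np.deg2rad(70))
                n_branch_cells = int(rng.integers(1, max(2, n_cells)))
                branch_requests.append((nxt.copy(), b_angle, n_branch_cells))
        filaments.append(np.asarray(pts))
        for origin_pt, b_angle, nb in branch_requests:
            grow(origin_pt, b_angle, nb, allow_branch=False)

    for i in range(n_filaments):
        angle = 2.0 * np.pi * i / n_filaments + rng.normal(0.0, np.deg2rad(10.0))
        grow(np.zeros(2), angle, cells_per_filament, allow_branch=True)

    regions: list[ROIRegion] = []
    for ci, cell in enumerate(cells):
        if cell.cell_type == "CA":
            tip = min(tip_region_um, 0.5 * (cell.s1_um - cell.s0_um))
            regions.append(ROIRegion(len(regions) + 1, ci, cell.s0_um,
                                     cell.s1_um - tip, "CA"))
            regions.append(ROIRegion(len(regions) + 1, ci, cell.s1_um - tip,
                                     cell.s1_um, "CA*"))
        else:
            regions.append(ROIRegion(len(regions) + 1, ci, cell.s0_um,
                                     cell.s1_um, cell.cell_type))
    return ColonyGeometry(filaments=filaments, cells=cells, roi_regions=regions)


def _polyline_point(pts: np.ndarray, arcs: np.ndarray, s: float) -> np.ndarray:
    i = int(np.clip(np.searchsorted(arcs, s) - 1, 0, len(arcs) - 2))
    span = arcs[i + 1] - arcs[i]
    f = 0.0 if span == 0 else (s - arcs[i]) / span
    return pts[i] + f * (pts[i + 1] - pts[i])


def rasterize_geometry(
    geometry: ColonyGeometry,
    pixel_size_um: float = 2.9,
    taper_px: float = 2.0,
    margin_px: int = 4,
    frame_shape: tuple[int, int] | None = None,
) -> tuple[ROILabelMap, np.ndarray]:
    """Rasterize regions to a label map and per-pixel emission weights.

    Cells are thick rounded-end polylines; the emission weight is 1 in the
    cell core and falls to 0 over ``taper_px`` pixels toward the border with a
    cosine profile (intensity is greatest at the cell centre and lowest at the
    borders).  Returns the ground-truth label map (ownership by highest
    weight; ties to the lower region id) and the (R, m, n) weight array.
    """
    all_pts = np.concatenate(geometry.filaments)
    wmax = max(c.width_um for c in geometry.cells) / 2.0
    lo = all_pts.min(axis=0) - wmax
    hi = all_pts.max(axis=0) + wmax
    if frame_shape is None:
        m = int(np.ceil((hi[0] - lo[0]) / pixel_size_um)) + 2 * margin_px
        n = int(np.ceil((hi[1] - lo[1]) / pixel_size_um)) + 2 * margin_px
    else:
        m, n = frame_shape
        need_m = (hi[0] - lo[0]) / pixel_size_um + 2 * margin_px
        need_n = (hi[1] - lo[1]) / pixel_size_um + 2 * margin_px
        if need_m > m or need_n > n:
            extents = [
                (fi, (f.max(0) - f.min(0)) / pixel_size_um)
                for fi, f in enumerate(geometry.filaments)
            ]
            worst = max(extents, key=lambda e: e[1].max())[0]
            raise ValueError(
                f"geometry exceeds frame bounds {(m, n)}; largest filament id {worst}"
            )
    origin = lo - margin_px * pixel_size_um

    R = geometry.n_regions
    weights = np.zeros((R, m, n), dtype=np.float32)
    taper_um = taper_px * pixel_size_um
    for r, region in enumerate(geometry.roi_regions):
        cell = geometry.cells[region.cell_index]
        pts = geometry.filaments[cell.filament_id]
        arcs = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        half = cell.width_um / 2.0
        step = pixel_size_um / 2.0
        ss = np.arange(region.s0_um, region.s1_um + step, step)
        centerline = np.array([_polyline_point(pts, arcs, s) for s in ss])
        tree = cKDTree(centerline)
        pad = half + taper_um
        y0 = max(0, int((centerline[:, 0].min() - pad - origin[0]) / pixel_size_um))
        y1 = min(m, int((centerline[:, 0].max() + pad - origin[0]) / pixel_size_um) + 2)
        x0 = max(0, int((centerline[:, 1].min() - pad - origin[1]) / pixel_size_um))
        x1 = min(n, int((centerline[:, 1].max() + pad - origin[1]) / pixel_size_um) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        coords = np.column_stack([
            origin[0] + (yy.ravel() + 0.5) * pixel_size_um,
            origin[1] + (xx.ravel() + 0.5) * pixel_size_um,
        ])
        d, _ = tree.query(coords)
        d = d.reshape(yy.shape)
        w = np.zeros_like(d)
        core = half - taper_um
        w[d <= core] = 1.0
        ramp = (d > core) & (d <= half)
        w[ramp] = 0.5 * (1.0 + np.cos(np.pi * (d[ramp] - core) / taper_um))
        weights[r, y0:y1, x0:x1] = w

    owner = np.argmax(weights, axis=0)
    best = np.max(weights, axis=0)
    labels = np.where(best > 0, owner + 1, 0).astype(np.int32)
    # ownership must be a contiguous 1..K relabeling if some region rendered empty
    present = np.unique(labels[labels > 0])
    if present.size != R:
        remap = np.zeros(R + 1, dtype=np.int32)
        remap[present] = np.arange(1, present.size + 1)
        labels = remap[labels]
        weights = weights[present - 1]
    return ROILabelMap(labels=labels, pixel_size_um=pixel_size_um), weights


# ---------------------------------------------------------------------------
# wave scheduling


def _lognormal_mean(rng, mean: float, cv: float) -> float:
    """Lognormal draw with the given arithmetic mean and CV."""
    s2 = np.log(1.0 + cv * cv)
    mu = np.log(mean) - 0.5 * s2
    return float(rng.lognormal(mu, np.sqrt(s2)))


def _lognormal_median(rng, median: float, cv: float) -> float:
    s2 = np.log(1.0 + cv * cv)
    return float(rng.lognormal(np.log(median), np.sqrt(s2)))


def schedule_waves(
    geometry: ColonyGeometry,
    protocol: StimulusProtocol,
    params: WaveParams | None = None,
    seed: int = 0,
) -> WaveProgram:
    """Draw the per-region wave schedule implied by the study conditions.

    Each region gets a characteristic driven interval (drawn once); during
    each stimulus pulse a responsive region fires a first wave at onset plus a
    drifting, jittered latency and then recurs at its characteristic interval
    while the stimulus lasts.  Outside stimulation, CA* tip regions oscillate
    at fast spontaneous intervals and other regions produce rare spontaneous
    waves.  All scheduled peaks within a region respect the refractory period.
    """
    if geometry.n_regions == 0:
        raise ValueError("geometry contains no ROI regions")
    p = params or WaveParams()
    rng = np.random.default_rng(seed)
    duration = protocol.recording_duration_s
    n_pulses = protocol.n_pulses
    if p.latency_drift_s_per_pulse is not None:
        drift = p.latency_drift_s_per_pulse
    elif n_pulses > 1:
        drift = (p.latency_end_mean_s - p.latency_mean_s) / (n_pulses - 1)
    else:
        drift = 0.0

    def fw10_sigma(driven: bool) -> float:
        base = p.fw10_stim_s if driven else p.fw10_spont_s
        fw = np.clip(_lognormal_median(rng, base, p.fw10_cv), p.fw10_min_s, p.fw10_max_s)
        return fw * _SIGMA_PER_FW10

    def amp(driven: bool) -> float:
        return _lognormal_mean(rng, p.amp_stim if driven else p.amp_spont, p.amp_cv)

    waves: list[list[ScheduledWave]] = []
    f0 = np.empty(geometry.n_regions)
    for r, region in enumerate(geometry.roi_regions):
        f0[r] = _lognormal_mean(rng, p.f0_mean, p.f0_cv)
        is_tip = region.cell_type == "CA*"
        ev: list[ScheduledWave] = []

        if is_tip:
            t_char = (
                _lognormal_median(rng, p.tip_driven_interval_s, p.interval_across_cv)
                if p.interval_mean_s is not None
                else None
            )
        elif p.interval_mean_s is not None:
            t_char = _lognormal_mean(rng, p.interval_mean_s, p.interval_across_cv)
        else:
            t_char = None

        # spontaneous waves: the unstimulated state, i.e. before the first
        # stimulus onset (stimulus exposure entrains/slows them afterwards)
        spont_end = protocol.onsets[0] if n_pulses else duration
        if is_tip and p.tip_interval_median_s is not None:
            t = _lognormal_median(rng, p.tip_interval_median_s, p.interval_within_cv) * rng.random()
            while t < spont_end:
                ev.append(ScheduledWave(t, amp(False), fw10_sigma(False)))
                t += _lognormal_median(rng, p.tip_interval_median_s, p.interval_within_cv)
        elif not is_tip and p.spont_interval_mean_s is not None and np.isfinite(p.spont_interval_mean_s):
            t = _lognormal_mean(rng, p.spont_interval_mean_s, p.spont_interval_cv) * rng.random()
            while t < spont_end:
                ev.append(ScheduledWave(t, amp(False), fw10_sigma(False)))
                t += _lognormal_mean(rng, p.spont_interval_mean_s, p.spont_interval_cv)

        # stimulus-locked waves
        if t_char is not None:
            for i, (on, off) in enumerate(protocol.pulses):
                if rng.random() > p.response_prob:
                    continue
                lat = max(0.0, rng.normal(p.latency_mean_s + drift * i, p.latency_sd_s))
                sig = fw10_sigma(True)
                peak = on + lat + _PEAK_OFFSET_PER_SIGMA * sig
                ev.append(ScheduledWave(peak, amp(True), sig, True, i))
                t = peak
                while True:
                    t = t + t_char * _lognormal_mean(rng, 1.0, p.interval_within_cv)
                    if t > off:
                        break
                    ev.append(ScheduledWave(t, amp(True), fw10_sigma(True), False, i))

        ev.sort(key=lambda w: w.peak_time_s)
        kept: list[ScheduledWave] = []
        for w in ev:
            if w.peak_time_s > duration:
                continue
            if kept and w.peak_time_s - kept[-1].peak_time_s < p.refractory_s:
                continue
            kept.append(w)
        waves.append(kept)

    return WaveProgram(waves=waves, f0=f0, params=p, protocol=protocol)


def program_traces(
    program: WaveProgram,
    duration_s: float | None = None,
    frame_interval_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate the programmed fluorescence of every region over time.

    Returns ``(times, F, dFF)`` where ``F[r, t] = F0_r * (1 + boost(t) +
    sum_waves A * exp(-(t - t_peak)^2 / (2 sigma^2)))`` and ``dFF`` is the
    corresponding (F - F0)/F0.
    """
    dur = duration_s if duration_s is not None else program.protocol.recording_duration_s
    times = np.arange(0.0, dur, frame_interval_s)
    R = program.n_regions
    dff = np.zeros((R, times.size))
    p = program.params
    if p.baseline_boost > 0 and program.protocol.n_pulses:
        on0 = program.protocol.onsets[0]
        post = times >= on0
        boost = np.zeros_like(times)
        boost[post] = p.baseline_boost * np.exp(-(times[post] - on0) / p.baseline_tau_s)
    else:
        boost = 0.0
    for r, evs in enumerate(program.waves):
        acc = np.zeros_like(times)
        for w in evs:
            acc += w.amplitude * np.exp(-((times - w.peak_time_s) ** 2) / (2.0 * w.sigma_s**2))
        dff[r] = acc + boost
    F = program.f0[:, None] * (1.0 + dff)
    return times, F, dff


# ---------------------------------------------------------------------------
# rendering


def render_stack(
    geometry: ColonyGeometry,
    program: WaveProgram,
    acq: AcquisitionModel | None = None,
    duration_s: int | None = None,
    seed: int = 0,
) -> tuple[TimelapseStack, GroundTruth]:
    """Render the colony's programmed dynamics into a noisy 16-bit timelapse.

    Per-frame pixel intensity is the background field plus each region's
    emission weight times its programmed fluorescence, blurred by the Gaussian
    PSF, with Poisson shot noise and Gaussian read noise applied.
    Deterministic (bit-identical) for a fixed seed.
    """
    if acq is None:
        acq = AcquisitionModel()
    dur = duration_s if duration_s is not None else program.protocol.recording_duration_s
    if dur < 1:
        raise ValueError("duration_s must be >= 1")
    labels, weights = rasterize_geometry(
        geometry, acq.pixel_size_um, frame_shape=acq.frame_shape
    )
    times, F, _ = program_traces(program, dur, acq.frame_interval_s)
    T = times.size
    R, m, n = weights.shape
    if F.shape[0] != R:
        raise ValueError("program regions do not match rasterized regions")
    # each pixel emits its owning region's program only (amplitude tapered
    # toward the border); cross-talk between ROI traces is then PSF-only
    lab2d = labels.labels
    for r in range(R):
        weights[r][lab2d != r + 1] = 0.0

    # background field: dim level with a mild planar gradient
    yy, xx = np.mgrid[:m, :n]
    grad = (yy / max(m - 1, 1) + xx / max(n - 1, 1)) / 2.0
    bg = acq.background_level * (1.0 + acq.background_gradient * (grad - 0.5))

    W = weights.reshape(R, m * n)
    scene = (F.T @ W).astype(np.float32)  # (T, m*n)
    scene = scene.reshape(T, m, n) + bg.astype(np.float32)

    sigma_px = (acq.psf_diameter_um / acq.pixel_size_um) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    for t in range(T):
        scene[t] = ndimage.gaussian_filter(scene[t], sigma=sigma_px)

    if acq.noise:
        rng = np.random.default_rng(seed)
        gain = acq.poisson_gain
        if gain > 0:
            scene = rng.poisson(scene / gain).astype(np.float32) * gain
        if acq.read_noise_sd > 0:
            scene = scene + rng.normal(0.0, acq.read_noise_sd, scene.shape).astype(np.float32)
    data = np.clip(np.round(scene), 0, 65535).astype(np.uint16)

    stack = TimelapseStack(
        data=data,
        pixel_size_um=acq.pixel_size_um,
        frame_interval_s=acq.frame_interval_s,
    )
    gt = GroundTruth(
        label_map=labels,
        program=program,
        stimulus_state=program.protocol.stimulus_state(times),
        region_types=geometry.region_types(),
        weights=weights,
    )
    return stack, gt


def simulate_colony(
    seed: int = 0,
    n_filaments: int = 6,
    cells_per_filament: int = 4,
    branch_prob: float = 0.25,
    protocol: StimulusProtocol | None = None,
    params: WaveParams | None = None,
    acq: AcquisitionModel | None = None,
) -> tuple[TimelapseStack, GroundTruth, ColonyGeometry]:
    """One-call benchmark colony: geometry + schedule + rendered stack.

    The default protocol is 300 s of buffer followed by stimulus to the end of
    a 900 s recording, which drives every region into sustained oscillation at
    its characteristic interval — the regime the segmentation stage expects.
    """
    if protocol is None:
        protocol = StimulusProtocol(pulses=[(300.0, 900.0)], recording_duration_s=900.0)
    geometry = build_geometry(seed, n_filaments, cells_per_filament, branch_prob)
    program = schedule_waves(geometry, protocol, params, seed=seed + 1)
    stack, gt = render_stack(geometry, program, acq, seed=seed + 2)
    return stack, gt, geometry
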