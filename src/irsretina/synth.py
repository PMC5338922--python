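"""Synthetic inputs for every stage of the pipeline.

Generates, from seeds alone: inhomogeneous Poisson spike trains from rate
traces; template IRS cells (recurrence-selective post-fixation bursts) and
less-biphasic LN control cells; binary checkerboard white noise with
ground-truth linear-nonlinear cells for receptive-field recovery;
gap-junction-like correlated spike pairs; natural-like 1/f images at 50%
contrast; and planted-truth populations for the IRS screen.

Template IRS cells are deliberately independent of the circuit model so that
analysis-layer tests do not inherit model assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.signal import fftconvolve

from .circuit import CircuitParams, RateTrace, TemporalFilter, bipolar_filter
from .stimulus import GratingSpec, TransitionSchedule

__all__ = [
    "SyntheticCellSpec",
    "WhiteNoiseStimulus",
    "poisson_spikes",
    "template_irs_rate",
    "control_filter",
    "ln_control_rate",
    "make_population",
    "correlated_pair",
    "make_natural_like_images",
    "generate_frames",
    "ln_whitenoise_spikes",
]


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Recipe for one synthetic cell.

    ``kind`` selects the generator: a template burst cell (``irs_template``),
    the full circuit model (``circuit_model``), or a linear-nonlinear control
    (``ln_control``).  Burst parameters apply to template cells only.
    """

    kind: str = "irs_template"
    rate_scale: float = 1.0
    rf_center: tuple[float, float] = (0.0, 0.0)
    rf_sigma: float = 90.0
    burst_peak_hz: float = 120.0
    burst_latency_ms: float = 120.0
    burst_width_ms: float = 30.0
    transition_peak_hz: float = 80.0
    baseline_hz: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("irs_template", "circuit_model", "ln_control"):
            raise ValueError(f"unknown cell kind {self.kind!r}")
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")
        if self.burst_width_ms <= 0:
            raise ValueError("burst width must be positive")


@dataclass(frozen=True)
class WhiteNoiseStimulus:
    """Binary checkerboard white-noise stimulus description.

    Stixels are ``stixel_um`` on a side; intensities are drawn independently
    from {-1, +1} (100% contrast) at ``update_hz``.
    """

    nx: int = 16
    ny: int = 16
    stixel_um: float = 60.0
    update_hz: float = 50.0
    duration_s: float = 300.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.update_hz))


def generate_frames(stim: WhiteNoiseStimulus) -> np.ndarray:
    """Draw the (n_frames, ny, nx) ±1 frame array; bit-reproducible from seed."""
    rng = np.random.default_rng(stim.seed)
    return rng.integers(0, 2, size=(stim.n_frames, stim.ny, stim.nx)) * 2.0 - 1.0


def poisson_spikes(
    rate: RateTrace | np.ndarray,
    n_trials: int = 1,
    seed: int = 0,
    dt: float | None = None,
) -> list[np.ndarray]:
    """Inhomogeneous Poisson spike times (ms) from a rate trace in Hz.

    Spike counts are drawn per dt-bin with mean rate·dt and placed uniformly
    within the bin.  Returns one sorted array per trial, on the trace clock.
    """
    if isinstance(rate, RateTrace):
        values, dt_, t0 = rate.rate, rate.dt, rate.t0
    else:
        values = np.asarray(rate, dtype=float)
        if dt is None:
            raise ValueError("dt required when passing a bare rate array")
        dt_, t0 = dt, 0.0
    if np.any(values < 0):
        raise ValueError("rates must be nonnegative")
    rng = np.random.default_rng(seed)
    mean_counts = values * dt_ / 1000.0
    trials = []
    for _ in range(n_trials):
        counts = rng.poisson(mean_counts)
        idx = np.repeat(np.nonzero(counts)[0], counts[np.nonzero(counts)[0]])
        times = t0 + (idx + rng.uniform(size=idx.size)) * dt_
        trials.append(np.sort(times))
    return trials


def _gauss_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def template_irs_rate(
    schedule: TransitionSchedule,
    cell: SyntheticCellSpec = SyntheticCellSpec(),
    dt: float = 1.0,
) -> RateTrace:
    """Idealized IRS firing-rate profile over a schedule.

    Every transition evokes a Gaussian burst at transition onset; only
    recurrence transitions (start = target) add a second burst at
    ``burst_latency_ms`` after fixation onset.  A low constant baseline sits
    underneath.  This captures the defining response signature without any
    circuit assumptions.
    """
    n = int(round(schedule.duration / dt))
    t = np.arange(n) * dt
    rate = np.full(n, cell.baseline_hz)
    for e in schedule.entries:
        rate += cell.transition_peak_hz * _gauss_bump(
            t, e.onset_time + e.transition_duration / 2.0, cell.burst_width_ms
        )
        if e.is_recurrence():
            rate += cell.burst_peak_hz * _gauss_bump(
                t, e.fixation_onset + cell.burst_latency_ms, cell.burst_width_ms
            )
    return RateTrace(rate=rate * cell.rate_scale, dt=dt, t0=0.0)


def control_filter(
    params: CircuitParams = CircuitParams(),
    target_index: float = 0.66,
) -> TemporalFilter:
    """Less-biphasic variant of the bipolar filter for LN control cells.

    The antagonistic lobe is rescaled so the biphasic index (secondary/primary
    lobe amplitude) lands at ``target_index``, typical of the non-IRS
    population, and the result is re-normalized to unit Euclidean norm.
    """
    from .analysis import biphasic_index  # local import: avoid cycle

    f = bipolar_filter(params)
    z1, z2 = f.normalization["Z1"], f.normalization["Z2"]
    t = np.arange(f.samples.size) * f.dt

    def lobe(tau):
        return np.exp(-(t**2) / tau**2) - np.exp(-(t**2) / (2.0 * tau) ** 2)

    g1 = lobe(f.normalization["T1"]) / z1
    g2 = lobe(f.normalization["T2"]) / z2

    def index_at(beta: float) -> float:
        return biphasic_index(g1 - beta * g2)

    # the index grows with beta until the first lobe is swallowed; bracket the
    # first crossing on a coarse scan, then refine
    grid = np.linspace(1e-6, 4.0, 81)
    vals = np.array([index_at(b) - target_index for b in grid])
    cross = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
    if cross.size == 0:
        raise ValueError(f"no lobe scaling reaches biphasic index {target_index}")
    k = cross[0]
    beta = brentq(lambda b: index_at(b) - target_index, grid[k], grid[k + 1])
    samples = g1 - beta * g2
    samples /= np.linalg.norm(samples)
    return TemporalFilter(samples=samples, dt=f.dt,
                          normalization={"beta": beta, "target_index": target_index})


def ln_control_rate(
    schedule: TransitionSchedule,
    spec: GratingSpec,
    cell: SyntheticCellSpec,
    dt: float = 1.0,
    region_position: int = 1,
) -> RateTrace:
    """Linear-nonlinear control cell driven by the grating stimulus.

    The cell monitors the local contrast of one quarter-period region (an Off
    cell with a less biphasic filter), half-wave rectifies, and scales to Hz.
    It responds to any darkening of its region at fixation onset — changes and
    recurrences alike — so it fails the recurrence-selectivity screen.
    """
    from .stimulus import render, subunit_contrast
    from .circuit import subunit_extents

    model_params = CircuitParams(dt=0.1)
    movie = render(schedule, spec, dt=model_params.dt)
    ext = subunit_extents(spec.spatial_period, spec.n_positions)[region_position - 1]
    c = subunit_contrast(movie, ext)
    filt = control_filter(model_params)
    drive = fftconvolve(-c, filt.samples)[: c.size]  # Off polarity
    rate_fine = np.maximum(drive, 0.0) * cell.rate_scale + cell.baseline_hz
    # resample to the requested dt
    step = int(round(dt / model_params.dt))
    n = rate_fine.size // step
    rate = rate_fine[: n * step].reshape(n, step).mean(axis=1)
    return RateTrace(rate=rate, dt=dt, t0=0.0)


def correlated_pair(
    base_a: np.ndarray,
    base_b: np.ndarray,
    shared_fraction: float,
    jitter_ms: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Inject gap-junction-like shared spikes into a pair of trains.

    A ``shared_fraction`` subsample of train a's spikes is copied into train b
    with uniform jitter in ±``jitter_ms`` — producing a correlogram peak at
    lags within the jitter, as for electrically coupled neighbors.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if shared_fraction == 0.0:
        return base_a, base_b
    n_shared = int(round(shared_fraction * base_a.size))
    chosen = rng.choice(base_a, size=n_shared, replace=False)
    injected = chosen + rng.uniform(-jitter_ms, jitter_ms, size=n_shared)
    return base_a, np.sort(np.concatenate([base_b, injected]))


def make_population(
    n_irs: int,
    n_control: int,
    schedule: TransitionSchedule,
    spec: GratingSpec = GratingSpec(),
    geometry: tuple[float, float] = (2000.0, 2000.0),
    rf_diameter: float = 275.0,
    n_trials: int = 5,
    shared_fraction: float = 0.0,
    jitter_ms: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, bool], dict[str, tuple[float, float]]]:
    """Planted-truth population: spikes, IRS labels and receptive-field mosaic.

    IRS cells are template burst cells; controls are LN cascades with a less
    biphasic filter.  Receptive-field centers tile ``geometry`` on a grid with
    ``rf_diameter`` spacing (little overlap, like the recorded mosaic).
    Neighboring IRS pairs optionally share a fraction of jittered spikes.
    Returns (spike table with cell_id/trial/time_ms, label dict, center dict).
    """
    n_total = n_irs + n_control
    nx = int(np.ceil(np.sqrt(n_total)))
    centers_all = [
        ((i % nx + 0.5) * rf_diameter, (i // nx + 0.5) * rf_diameter)
        for i in range(n_total)
    ]
    if any(c[0] > geometry[0] or c[1] > geometry[1] for c in centers_all):
        raise ValueError("geometry too small for the receptive-field mosaic")
    if len(set(centers_all)) < n_total:
        raise ValueError("overlapping identical receptive-field centers")

    rng = np.random.default_rng(seed)
    tables = []
    labels: dict[str, bool] = {}
    centers: dict[str, tuple[float, float]] = {}
    spike_cache: dict[str, list[np.ndarray]] = {}
    for i in range(n_total):
        is_irs = i < n_irs
        cell_id = f"{'irs' if is_irs else 'ctl'}_{i:03d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cell = SyntheticCellSpec(
            kind="irs_template" if is_irs else "ln_control",
            rf_center=centers_all[i],
            rate_scale=1.0 if is_irs else 60.0,
            seed=sub_seed,
        )
        if is_irs:
            rate = template_irs_rate(schedule, cell)
        else:
            rate = ln_control_rate(
                schedule, spec, cell,
                region_position=(i - n_irs) % spec.n_positions + 1,
            )
        spike_cache[cell_id] = poisson_spikes(rate, n_trials=n_trials, seed=sub_seed)
        labels[cell_id] = is_irs
        centers[cell_id] = centers_all[i]

    irs_ids = [cid for cid, lab in labels.items() if lab]
    if shared_fraction > 0.0:
        for a_id, b_id in zip(irs_ids, irs_ids[1:]):
            for trial in range(n_trials):
                a, b = correlated_pair(
                    spike_cache[a_id][trial],
                    spike_cache[b_id][trial],
                    shared_fraction,
                    jitter_ms,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                spike_cache[a_id][trial], spike_cache[b_id][trial] = a, b

    for cell_id, trials in spike_cache.items():
        for trial, times in enumerate(trials):
            tables.append(
                pd.DataFrame(
                    {"cell_id": cell_id, "trial": trial, "time_ms": times}
                )
            )
    table = pd.concat(tables, ignore_index=True)
    return table, labels, centers


def make_natural_like_images(
    n: int,
    size: int = 128,
    seed: int = 0,
    pixel_um: float = 15.0,
    mean_level: float = 1.0,
    contrast: float = 0.5,
) -> np.ndarray:
    """Natural-like images: 1/f amplitude spectrum, 50% contrast.

    Contrast is defined as the standard deviation of the pixel intensity
    relative to the mean, matching the normalization applied to the natural
    photographs the stimulus ensemble emulates.  Returns (n, size, size).
    """
    if n < 1:
        raise ValueError("need at least one image")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    freq = np.hypot(fy, fx)
    freq[0, 0] = 1.0
    amplitude = 1.0 / freq
    amplitude[0, 0] = 0.0
    images = np.empty((n, size, size))
    for k in range(n):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(size, size))
        spectrum = amplitude * np.exp(1j * phases)
        img = np.real(np.fft.ifft2(spectrum))
        img = (img - img.mean()) / img.std()
        images[k] = mean_level * (1.0 + contrast * img)
    return images


def ln_whitenoise_spikes(
    stim: WhiteNoiseStimulus,
    frames: np.ndarray,
    rf_center: tuple[float, float],
    rf_sigma: float,
    temporal_filter: np.ndarray | None = None,
    rate_scale: float = 60.0,
    polarity: str = "off",
    seed: int = 0,
) -> np.ndarray:
    """Spikes of a ground-truth LN cell under checkerboard white noise.

    The generator signal is the Gaussian-RF-weighted frame sum passed through
    a temporal filter (sampled at the frame interval) with the requested
    polarity, half-wave rectified and scaled to Hz; spiking is Poisson per
    frame.  Used for receptive-field recovery benchmarks where the planted
    center/sigma are known exactly.
    """
    xs = (np.arange(stim.nx) + 0.5) * stim.stixel_um
    ys = (np.arange(stim.ny) + 0.5) * stim.stixel_um
    xx, yy = np.meshgrid(xs, ys)
    w = np.exp(
        -0.5 * (((xx - rf_center[0]) ** 2 + (yy - rf_center[1]) ** 2) / rf_sigma**2)
    )
    if polarity.lower() == "off":
        w = -w
    g = np.tensordot(frames, w, axes=([1, 2], [0, 1]))
    if temporal_filter is None:
        frame_ms = 1000.0 / stim.update_hz
        t = np.arange(0.0, 120.0, frame_ms)
        temporal_filter = (t / 40.0) * np.exp(1.0 - t / 40.0)
        temporal_filter /= np.linalg.norm(temporal_filter)
    drive = fftconvolve(g, temporal_filter)[: g.size]
    rate = np.maximum(drive, 0.0) * rate_scale / max(np.abs(g).std(), 1e-12)
    frame_ms = 1000.0 / stim.update_hz
    trace = RateTrace(rate=rate, dt=frame_ms, t0=0.0)
    return poisson_spikes(trace, n_trials=1, seed=seed)[0]
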