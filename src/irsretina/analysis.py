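"""Analysis operators for firing-rate traces and spike trains.

Implements the quantitative pipeline used to characterize image-recurrence
sensitivity: peristimulus time histograms (PSTHs) on a grid of transition
types, peak/latency estimation, the derivative-based Recurrence Sensitivity
Index (RSI) and the two-stage IRS-cell screen, the biphasic index of temporal
filters, the spike-triggered-average → SVD → 2-D-Gaussian receptive-field
pipeline, millisecond-scale spike-timing correlations, and the
natural-image darkening score.

All analysis windows are half-open ``[start, stop)`` in ms relative to the
stated alignment event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .circuit import RateTrace, TemporalFilter

__all__ = [
    "PSTHMatrix",
    "RSIResult",
    "RFFit",
    "CorrHistogram",
    "psth",
    "peak_latency",
    "matrix_from_traces",
    "matrix_from_spikes",
    "compute_rsi",
    "biphasic_index",
    "sta",
    "separate_sta",
    "fit_rf",
    "center_distance",
    "spike_correlation",
    "darkening_score",
    "darkening_peak_correlation",
    "screen_population",
]


# --------------------------------------------------------------------------
# PSTHs


@dataclass
class PSTHMatrix:
    """Grid of rate profiles indexed by (start_position, target_position).

    Profiles are aligned to transition onset: bin k covers
    ``[t_start + k·bin, t_start + (k+1)·bin)`` ms relative to it.
    """

    profiles: dict[tuple[int, int], np.ndarray]
    bin: float = 10.0
    t_start: float = 0.0
    n_positions: int = 4
    trial_counts: dict[tuple[int, int], int] = field(default_factory=dict)

    def bin_times(self, key: tuple[int, int] | None = None) -> np.ndarray:
        """Left edges of the bins of one profile."""
        n = len(next(iter(self.profiles.values())) if key is None else self.profiles[key])
        return self.t_start + np.arange(n) * self.bin

    def recurrence_keys(self) -> list[tuple[int, int]]:
        return [(i, i) for i in range(1, self.n_positions + 1)]

    def change_start(self, target: int) -> int:
        """Contrast-reversed (maximally different) starting position."""
        return (target - 1 + self.n_positions // 2) % self.n_positions + 1


def psth(
    spikes: Sequence[np.ndarray] | np.ndarray,
    events: Sequence[float] | None = None,
    bin_ms: float = 10.0,
    duration_ms: float = 900.0,
    t_start: float = 0.0,
) -> np.ndarray:
    """Peristimulus time histogram in Hz.

    Two calling styles: with ``events`` given, ``spikes`` is a flat array of
    spike times and each event time defines one trial (spike times are
    re-referenced to it); with ``events=None``, ``spikes`` is a list of
    per-trial, already event-aligned spike-time arrays.  Bin k counts spikes
    in ``[t_start + k·bin, t_start + (k+1)·bin)``; rates are
    counts / (n_trials · bin width).
    """
    if events is not None:
        events = np.asarray(events, dtype=float)
        if events.size == 0:
            raise ValueError("empty event list")
        flat = np.asarray(spikes, dtype=float)
        aligned = [flat - ev for ev in events]
        n_trials = events.size
    else:
        aligned = [np.asarray(tr, dtype=float) for tr in spikes]
        n_trials = len(aligned)
        if n_trials == 0:
            raise ValueError("need at least one trial")
    n_bins = int(round(duration_ms / bin_ms))
    edges = t_start + np.arange(n_bins + 1) * bin_ms
    counts = np.zeros(n_bins)
    for tr in aligned:
        counts += np.histogram(tr, bins=edges)[0]
    return counts / (n_trials * bin_ms) * 1000.0


def peak_latency(
    profile: np.ndarray, bin_ms: float = 10.0, t_start: float = 0.0
) -> dict[str, float | bool]:
    """Peak rate and its latency from a binned rate profile.

    The peak bin is located and a second-order polynomial is fitted through it
    and its two neighbors; the latency is the parabola's vertex abscissa.  If
    the maximum falls on an edge bin the vertex fit is skipped and the bin
    center is returned (flagged via ``edge=True``).  An all-zero profile has
    undefined latency (NaN, ``undefined=True``).
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 3:
        raise ValueError("profile needs at least three bins")
    centers = t_start + (np.arange(profile.size) + 0.5) * bin_ms
    k = int(np.argmax(profile))
    out: dict[str, float | bool] = {
        "peak_rate": float(profile[k]),
        "edge": False,
        "undefined": False,
    }
    if not profile.any():
        out["latency"] = float("nan")
        out["undefined"] = True
        return out
    if k == 0 or k == profile.size - 1:
        out["latency"] = float(centers[k])
        out["edge"] = True
        return out
    y0, y1, y2 = profile[k - 1 : k + 2]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:  # flat triple: vertex degenerates to the center bin
        out["latency"] = float(centers[k])
        return out
    out["latency"] = float(centers[k] + 0.5 * bin_ms * (y0 - y2) / denom)
    return out


def matrix_from_traces(
    traces: Mapping[tuple[int, int], RateTrace],
    bin_ms: float = 10.0,
    n_positions: int = 4,
) -> PSTHMatrix:
    """Bin deterministic model rate traces into a PSTH matrix.

    Each trace (aligned to transition onset) is averaged within consecutive
    ``bin_ms`` bins, starting at the first full bin boundary ≤ the trace start.
    """
    profiles: dict[tuple[int, int], np.ndarray] = {}
    t_start = None
    for key, tr in traces.items():
        start = np.floor(tr.t0 / bin_ms) * bin_ms
        n_bins = int(np.floor((tr.t0 + tr.rate.size * tr.dt - start) / bin_ms))
        prof = np.empty(n_bins)
        for k in range(n_bins):
            prof[k] = tr.window(start + k * bin_ms, start + (k + 1) * bin_ms).mean()
        profiles[key] = prof
        t_start = start if t_start is None else t_start
    return PSTHMatrix(profiles=profiles, bin=bin_ms, t_start=float(t_start),
                      n_positions=n_positions,
                      trial_counts={k: 1 for k in profiles})


def matrix_from_spikes(
    spikes: np.ndarray,
    schedule,
    bin_ms: float = 10.0,
    t_start: float = -100.0,
    duration_ms: float = 1000.0,
) -> PSTHMatrix:
    """PSTH matrix from a flat spike-time array and a transition schedule.

    Events are the schedule's transition onsets, grouped by transition type;
    repeats of a type within the schedule are the trials.
    """
    profiles: dict[tuple[int, int], np.ndarray] = {}
    counts: dict[tuple[int, int], int] = {}
    n = schedule.n_positions
    for start in range(1, n + 1):
        for target in range(1, n + 1):
            events = schedule.events(start, target)
            if events.size == 0:
                continue
            profiles[(start, target)] = psth(
                spikes, events, bin_ms=bin_ms, duration_ms=duration_ms, t_start=t_start
            )
            counts[(start, target)] = int(events.size)
    return PSTHMatrix(profiles=profiles, bin=bin_ms, t_start=t_start,
                      n_positions=n, trial_counts=counts)


# --------------------------------------------------------------------------
# Recurrence Sensitivity Index


@dataclass
class RSIResult:
    """Per-target maximal PSTH derivatives and the two-stage IRS decision.

    ``rsi`` averages, over target positions, the normalized contrast between
    the maximal PSTH derivative for image recurrence and for the
    contrast-reversed change transition.  ``is_irs`` additionally requires the
    mean recurrence peak rate to pass the rate screen (when one is applied).
    """

    d_rec: np.ndarray
    d_change: np.ndarray
    rsi: float
    mean_recurrence_peak: float
    passed_rate_screen: bool
    is_irs: bool
    degenerate_terms: np.ndarray


def _max_derivative_in_window(
    profile: np.ndarray, bin_ms: float, t_start: float, window: tuple[float, float]
) -> float:
    """Max of successive-bin differences whose bin left edge lies in window.

    The derivative assigned to bin k is ``profile[k] - profile[k-1]``, so the
    first bin inside the window uses the difference from the preceding bin.
    """
    lo, hi = window
    n = profile.size
    edges = t_start + np.arange(n) * bin_ms
    ks = np.nonzero((edges >= lo - 1e-9) & (edges < hi - 1e-9))[0]
    ks = ks[ks >= 1]
    if ks.size == 0:
        raise ValueError("analysis window outside the profile extent")
    return float(np.max(profile[ks] - profile[ks - 1]))


def compute_rsi(
    matrix: PSTHMatrix,
    fixation_onset: float = 100.0,
    window: tuple[float, float] = (50.0, 200.0),
    rate_screen: float | None = 50.0,
    threshold: float = 0.5,
) -> RSIResult:
    """Recurrence Sensitivity Index and IRS classification.

    For each target position i, the maximal PSTH derivative (successive
    10-ms-bin differences) within ``window`` ms after fixation onset is
    compared between the recurrence transition (start = i) and the change
    transition from the contrast-reversed start.  The RSI is the mean of
    ``(D_rec - D_change) / (D_rec + D_change)`` over targets; using
    derivatives makes the index independent of any background rate the peak
    rides on.  A cell is an IRS cell if its mean recurrence peak rate is at
    least ``rate_screen`` (pass ``None`` to skip, e.g. for model rates in
    arbitrary units) and RSI ≥ ``threshold``.

    Degenerate targets with ``D_rec + D_change ≤ 0`` contribute a neutral 0
    term and are flagged.
    """
    n = matrix.n_positions
    abs_window = (fixation_onset + window[0], fixation_onset + window[1])
    d_rec = np.empty(n)
    d_change = np.empty(n)
    peaks = np.empty(n)
    for i in range(1, n + 1):
        rec = matrix.profiles[(i, i)]
        chg = matrix.profiles[(matrix.change_start(i), i)]
        d_rec[i - 1] = _max_derivative_in_window(rec, matrix.bin, matrix.t_start, abs_window)
        d_change[i - 1] = _max_derivative_in_window(chg, matrix.bin, matrix.t_start, abs_window)
        edges = matrix.bin_times((i, i))
        in_win = (edges >= abs_window[0] - 1e-9) & (edges < abs_window[1] - 1e-9)
        peaks[i - 1] = rec[in_win].max()
    denom = d_rec + d_change
    degenerate = denom <= 0.0
    terms = np.zeros(n)
    np.divide(d_rec - d_change, denom, out=terms, where=~degenerate)
    rsi = float(terms.mean())
    mean_peak = float(peaks.mean())
    passed = True if rate_screen is None else mean_peak >= rate_screen
    return RSIResult(
        d_rec=d_rec,
        d_change=d_change,
        rsi=rsi,
        mean_recurrence_peak=mean_peak,
        passed_rate_screen=passed,
        is_irs=bool(passed and rsi >= threshold),
        degenerate_terms=degenerate,
    )


# --------------------------------------------------------------------------
# Biphasic index


def biphasic_index(filt: TemporalFilter | np.ndarray) -> float:
    """Amplitude ratio of a temporal filter's second lobe to its first.

    The first lobe is the earlier of the filter's positive and negative
    extrema, the second the later one; the index is the amplitude of the
    second divided by the first.  Values above 1 mark filters whose rebound
    lobe dominates — the hallmark of strongly biphasic cells.  A monophasic
    filter scores 0.
    """
    samples = filt.samples if isinstance(filt, TemporalFilter) else np.asarray(filt, float)
    if not np.any(samples):
        raise ValueError("all-zero filter has no biphasic index")
    k_pos, k_neg = int(np.argmax(samples)), int(np.argmin(samples))
    amp_pos, amp_neg = float(samples[k_pos]), float(-samples[k_neg])
    if amp_pos <= 0.0 or amp_neg <= 0.0:
        return 0.0
    first, second = (amp_pos, amp_neg) if k_pos < k_neg else (amp_neg, amp_pos)
    return float(second / first)


# --------------------------------------------------------------------------
# Receptive fields: STA → SVD → Gaussian fit


def sta(
    spikes_ms: np.ndarray,
    frames: np.ndarray,
    frame_rate_hz: float,
    window_ms: float = 700.0,
) -> tuple[np.ndarray, int]:
    """Spike-triggered average of the white-noise stimulus.

    ``frames`` has shape (n_frames, ny, nx).  The average is taken over the
    ``window_ms`` stimulus segment preceding each spike; the returned array
    has shape (n_lags, ny, nx) where lag k is the frame shown k frame
    intervals before the spike (lag 0 = frame at spike time).  Spikes earlier
    than one full window into the stimulus are skipped; the count of skipped
    spikes is returned alongside.
    """
    spikes_ms = np.asarray(spikes_ms, dtype=float)
    n_lags = int(round(window_ms * frame_rate_hz / 1000.0))
    idx = np.floor(spikes_ms * frame_rate_hz / 1000.0).astype(int)
    idx = idx[idx < frames.shape[0]]
    valid = idx >= n_lags - 1
    n_skipped = int((~valid).sum())
    idx = idx[valid]
    if idx.size == 0:
        raise ValueError("no spikes with a full stimulus window available")
    if idx.size < 100:
        warnings.warn(f"only {idx.size} usable spikes; STA will be noisy", stacklevel=2)
    lags = np.arange(n_lags)
    gather = idx[:, None] - lags[None, :]
    avg = frames[gather].mean(axis=0)
    return avg, n_skipped


def separate_sta(
    sta_array: np.ndarray, polarity: str = "off"
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-1 space/time separation of an STA by singular value decomposition.

    Returns (spatial_map, temporal_filter) from the leading singular triplet.
    The spatial map has unit Euclidean norm; the temporal component carries
    the amplitude.  The sign is fixed so the temporal primary extremum is
    negative for an Off cell (``polarity='off'``) / positive for On.
    """
    if not np.any(sta_array):
        raise ValueError("degenerate (all-zero) STA")
    n_lags = sta_array.shape[0]
    m = sta_array.reshape(n_lags, -1)
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    temporal = u[:, 0] * s[0]
    spatial = vt[0].reshape(sta_array.shape[1:])
    primary = temporal[np.argmax(np.abs(temporal))]
    want_negative = polarity.lower() == "off"
    if (primary > 0) == want_negative:
        temporal, spatial = -temporal, -spatial
    return spatial, temporal


@dataclass
class RFFit:
    """2-D Gaussian receptive-field fit.

    The outline is the ``contour_scale``-sigma ellipse; ``diameter`` is the
    diameter of the circle with the same area as that ellipse.
    """

    center: tuple[float, float]
    sigmas: tuple[float, float]
    orientation: float
    contour_scale: float = 1.5
    converged: bool = True

    @property
    def diameter(self) -> float:
        return 2.0 * self.contour_scale * float(np.sqrt(self.sigmas[0] * self.sigmas[1]))

    def profile(self, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
        """Unit-amplitude Gaussian profile on coordinate grids (µm)."""
        return _gauss2d(
            (xx, yy), 1.0, self.center[0], self.center[1],
            self.sigmas[0], self.sigmas[1], self.orientation, 0.0,
        )


def _gauss2d(coords, amp, x0, y0, sx, sy, theta, offset):
    xx, yy = coords
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - x0) * ct + (yy - y0) * st
    yr = -(xx - x0) * st + (yy - y0) * ct
    return amp * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2)) + offset


def fit_rf(
    spatial_map: np.ndarray,
    pixel_size: float,
    contour_scale: float = 1.5,
) -> RFFit:
    """Least-squares 2-D Gaussian fit of a spatial receptive-field map.

    The map is sign-flipped if its dominant extremum is negative, so the fit
    always tracks a positive peak.  Coordinates are pixel centers in µm.
    """
    spatial_map = np.asarray(spatial_map, dtype=float)
    if abs(spatial_map.min()) > abs(spatial_map.max()):
        spatial_map = -spatial_map
    ny, nx = spatial_map.shape
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    xx, yy = np.meshgrid(xs, ys)
    j, i = np.unravel_index(np.argmax(spatial_map), spatial_map.shape)
    p0 = [
        float(spatial_map.max()),
        xs[i],
        ys[j],
        2.0 * pixel_size,
        2.0 * pixel_size,
        0.0,
        float(np.median(spatial_map)),
    ]
    try:
        popt, _ = optimize.curve_fit(
            _gauss2d,
            (xx.ravel(), yy.ravel()),
            spatial_map.ravel(),
            p0=p0,
            maxfev=20000,
        )
    except RuntimeError:
        return RFFit(center=(xs[i], ys[j]),
                     sigmas=(p0[3], p0[4]), orientation=0.0,
                     contour_scale=contour_scale, converged=False)
    _, x0, y0, sx, sy, theta, _ = popt
    return RFFit(
        center=(float(x0), float(y0)),
        sigmas=(abs(float(sx)), abs(float(sy))),
        orientation=float(theta),
        contour_scale=contour_scale,
    )


def center_distance(a: RFFit, b: RFFit) -> float:
    """Euclidean distance (µm) between two fitted receptive-field centers."""
    return float(np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1]))


# --------------------------------------------------------------------------
# Spike-timing correlations


@dataclass
class CorrHistogram:
    """Conditional spiking probability vs. lag, and its flank-baseline peak."""

    lags: np.ndarray
    probability: np.ndarray
    peak: float
    peak_lag: float
    baseline: float


def spike_correlation(
    train_a: np.ndarray,
    train_b: np.ndarray,
    max_lag_ms: float = 100.0,
    bin_ms: float = 1.0,
    peak_range_ms: float = 40.0,
    baseline_inner_ms: float = 20.0,
) -> CorrHistogram:
    """Spike-timing correlation of two simultaneously recorded trains.

    For each reference spike of ``train_a``, each 1-ms lag bin is marked if
    ``train_b`` fires at least one spike at that lag; the histogram is the
    fraction of reference spikes with a marked bin.  The peak is searched in
    ±``peak_range_ms`` and reported baseline-subtracted, with the baseline
    averaged over the flanks (±[``baseline_inner_ms``, ``max_lag_ms``]).
    """
    a = np.sort(np.asarray(train_a, dtype=float))
    b = np.sort(np.asarray(train_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("spike trains must be non-empty")
    n_bins = int(round(2.0 * max_lag_ms / bin_ms)) + 1
    lags = (np.arange(n_bins) - n_bins // 2) * bin_ms
    hits = np.zeros(n_bins)
    lo = np.searchsorted(b, a - (max_lag_ms + bin_ms / 2.0))
    hi = np.searchsorted(b, a + (max_lag_ms + bin_ms / 2.0))
    for k, (t, i0, i1) in enumerate(zip(a, lo, hi)):
        if i1 > i0:
            rel = b[i0:i1] - t
            bins = np.unique(np.round(rel / bin_ms).astype(int)) + n_bins // 2
            bins = bins[(bins >= 0) & (bins < n_bins)]
            hits[bins] += 1.0
    prob = hits / a.size
    in_peak = np.abs(lags) <= peak_range_ms + 1e-9
    in_base = (np.abs(lags) >= baseline_inner_ms - 1e-9) & (
        np.abs(lags) <= max_lag_ms + 1e-9
    )
    baseline = float(prob[in_base].mean())
    k = int(np.argmax(prob[in_peak]))
    return CorrHistogram(
        lags=lags,
        probability=prob,
        peak=float(prob[in_peak][k] - baseline),
        peak_lag=float(lags[in_peak][k]),
        baseline=baseline,
    )


# --------------------------------------------------------------------------
# Natural-image darkening score


def darkening_score(
    image: np.ndarray,
    blurred_image: np.ndarray,
    rf: RFFit,
    event: str = "fixation_onset",
    pixel_size: float = 15.0,
) -> float:
    """Integrated darkening of the receptive field by a natural image.

    Pixel contrast is the actual image minus its blurred version (fixation
    onset) or the blurred minus the actual (transition onset).  Each pixel is
    weighted by the cell's Gaussian receptive-field profile, positive values
    are zeroed, and the sign-inverted remainder is summed — an Off-weighted
    measure of how strongly the receptive field darkens at the event.
    """
    if event not in ("fixation_onset", "transition_onset"):
        raise ValueError(f"unknown event {event!r}")
    image = np.asarray(image, dtype=float)
    contrast = image - blurred_image if event == "fixation_onset" else blurred_image - image
    ny, nx = image.shape
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    if not (xs[0] <= rf.center[0] <= xs[-1] and ys[0] <= rf.center[1] <= ys[-1]):
        raise ValueError("receptive field center lies outside the image")
    xx, yy = np.meshgrid(xs, ys)
    weighted = contrast * rf.profile(xx, yy)
    return float(-np.minimum(weighted, 0.0).sum())


def darkening_peak_correlation(
    scores: Mapping[str, Sequence[float]],
    peak_sizes: Mapping[str, Sequence[float]],
) -> dict[str, object]:
    """Correlate darkening scores with firing-rate peak sizes across cells.

    ``scores[cell]`` and ``peak_sizes[cell]`` hold the per-fixation-position
    values of one cell.  Returns each cell's Pearson R and the p-value of a
    Wilcoxon signed-rank test of the pooled R values against zero.
    """
    r_values = {}
    for cell in scores:
        s = np.asarray(scores[cell], dtype=float)
        p = np.asarray(peak_sizes[cell], dtype=float)
        r_values[cell] = float(np.corrcoef(s, p)[0, 1])
    rs = np.array(list(r_values.values()))
    res = stats.wilcoxon(rs)
    return {"r": r_values, "statistic": float(res.statistic), "pvalue": float(res.pvalue)}


# --------------------------------------------------------------------------
# Population screen


def screen_population(
    spike_table: pd.DataFrame,
    schedule,
    bin_ms: float = 10.0,
    window: tuple[float, float] = (50.0, 200.0),
    rate_screen: float = 50.0,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Run the IRS screen on a table of spikes (cell_id, trial, time_ms).

    Trials are repeats of the same schedule; spikes of all trials of a cell
    are pooled per transition type.  Returns one row per cell with the mean
    recurrence peak rate, RSI and the IRS decision.
    """
    required = {"cell_id", "trial", "time_ms"}
    if not required.issubset(spike_table.columns):
        raise ValueError(f"spike table must have columns {sorted(required)}")
    fixation_onset = schedule.entries[0].transition_duration
    rows = []
    for cell_id, group in spike_table.groupby("cell_id", sort=True):
        n_trials = group["trial"].nunique()
        profiles: dict[tuple[int, int], np.ndarray] = {}
        counts: dict[tuple[int, int], int] = {}
        n = schedule.n_positions
        duration = fixation_onset + window[1] + 4 * bin_ms
        t_start = -bin_ms
        for start in range(1, n + 1):
            for target in range(1, n + 1):
                events = schedule.events(start, target)
                if events.size == 0:
                    raise ValueError(
                        f"schedule contains no {start}->{target} transitions"
                    )
                trial_psths = [
                    psth(tg["time_ms"].to_numpy(), events, bin_ms, duration, t_start)
                    for _, tg in group.groupby("trial")
                ]
                profiles[(start, target)] = np.mean(trial_psths, axis=0)
                counts[(start, target)] = int(events.size) * n_trials
        matrix = PSTHMatrix(profiles=profiles, bin=bin_ms, t_start=t_start,
                            n_positions=n, trial_counts=counts)
        res = compute_rsi(matrix, fixation_onset, window, rate_screen, threshold)
        rows.append(
            {
                "cell_id": cell_id,
                "mean_recurrence_peak_hz": res.mean_recurrence_peak,
                "rsi": res.rsi,
                "is_irs": res.is_irs,
            }
        )
    return pd.DataFrame(rows)
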