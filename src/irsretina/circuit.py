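"""Serial-inhibition subunit circuit model of an IRS ganglion cell.

The ganglion cell pools four non-overlapping spatial subunits that together
cover one grating period.  Each subunit contains an Off-type bipolar cell
(excitatory drive), an On-type bipolar cell feeding an On-type amacrine cell
(inhibitory drive), and an Off-type amacrine cell that receives the Off
bipolar signal and inhibits the On amacrine ("serial inhibition").  Cells are
temporal filters; every synapse half-wave rectifies its presynaptic
activation, inhibitory outputs carry sign -1, and the On amacrine adds a tonic
activation ``A0`` and low-pass filters its input.  The half-wave rectified
pooled input is read out as the firing rate (arbitrary units).

The slow, tonically active On-pathway inhibition carries stimulus history
across a saccade-like transition; it is transiently silenced by the serial
Off-amacrine inhibition only where the image after the transition matches the
image before it, which releases the characteristic post-fixation burst for
image recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.signal import fftconvolve

from .stimulus import (
    GratingSpec,
    ScheduleEntry,
    StimulusMovie,
    TransitionSchedule,
    make_variant_schedule,
    render,
    shift_distance,
    subunit_contrast,
)

__all__ = [
    "CircuitParams",
    "TemporalFilter",
    "RateTrace",
    "CellInputTraces",
    "bipolar_filter",
    "amacrine_lowpass",
    "simulate",
    "ablate",
    "transition_traces",
    "compare_flash_vs_recurrence",
]


@dataclass(frozen=True)
class CircuitParams:
    """All free parameters of the circuit model.

    Time constants in ms; gains dimensionless.  ``T1``/``T2`` set the
    excitatory and antagonistic lobes of the biphasic bipolar filter,
    ``tac_rise``/``tac_decay`` the On-amacrine low-pass.  ``g_on`` scales the
    On-bipolar → On-amacrine excitation, ``g_serial`` the Off-amacrine →
    On-amacrine serial inhibition.  ``A0`` is the tonic On-amacrine
    activation (2 standard, 16 for the increased-tonic-inhibition regime).
    ``inhibition_site`` selects whether On-amacrine inhibition acts on the
    ganglion cell directly (postsynaptic) or on the bipolar terminals before
    their rectification (presynaptic, scaled by ``presyn_scale``).
    """

    T1: float = 40.0
    T2: float = 60.0
    tac_rise: float = 30.0
    tac_decay: float = 200.0
    g_on: float = 0.05
    g_serial: float = 0.2
    A0: float = 2.0
    dt: float = 0.1
    n_subunits: int = 4
    inhibition_site: str = "postsynaptic"
    presyn_scale: float = 0.5
    time_scale_bc: float = 1.0
    time_scale_ac: float = 1.0
    on_inhibition_blocked: bool = False

    def __post_init__(self) -> None:
        for name in ("T1", "T2", "tac_rise", "tac_decay", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.g_on < 0 or self.g_serial < 0:
            raise ValueError("gains must be nonnegative")
        if self.n_subunits < 2:
            raise ValueError("need at least two subunits")
        if self.inhibition_site not in ("postsynaptic", "presynaptic"):
            raise ValueError(f"unknown inhibition site {self.inhibition_site!r}")


@dataclass
class TemporalFilter:
    """Sampled causal filter with its normalization record."""

    samples: np.ndarray
    dt: float
    normalization: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    def norm(self) -> float:
        return float(np.linalg.norm(self.samples))

    def integral(self) -> float:
        return float(self.samples.sum() * self.dt)


@dataclass
class RateTrace:
    """Nonnegative firing-rate samples (arbitrary units) on the movie clock."""

    rate: np.ndarray
    dt: float
    t0: float = 0.0

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.rate.size) * self.dt

    def window(self, start: float, stop: float) -> np.ndarray:
        """Samples with t in the half-open window [start, stop) ms."""
        i0 = int(np.ceil((start - self.t0) / self.dt - 1e-9))
        i1 = int(np.ceil((stop - self.t0) / self.dt - 1e-9))
        return self.rate[max(i0, 0) : max(i1, 0)]


@dataclass
class CellInputTraces:
    """Per-subunit activations and pooled ganglion-cell inputs.

    Arrays have shape (n_subunits, n_time).  ``excitatory`` and ``inhibitory``
    are the pooled rectified drives to the ganglion cell; inhibitory samples
    carry sign -1.
    """

    b_off: np.ndarray
    b_on: np.ndarray
    a_off: np.ndarray
    a_on: np.ndarray
    excitatory: np.ndarray
    inhibitory: np.ndarray
    dt: float
    t0: float = 0.0


def _rect(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _lobe(t: np.ndarray, tau: float) -> np.ndarray:
    """exp(-t²/τ²) - exp(-t²/(2τ)²): a negative transient bump for t > 0."""
    return np.exp(-(t**2) / tau**2) - np.exp(-(t**2) / (2.0 * tau) ** 2)


def bipolar_filter(params: CircuitParams) -> TemporalFilter:
    """Biphasic temporal filter of the Off-type bipolar cell.

    f(t) = g1(t)/Z1 - g2(t)/Z2 with gi(t) = exp(-t²/Ti²) - exp(-t²/(2Ti)²)
    for t > 0 and 0 otherwise.  Z1 and Z2 are fixed by two conditions: zero
    discrete time integral (transient response to contrast steps) and unit
    Euclidean norm over samples at the model sampling rate.  The On-type
    bipolar filter is the sign-flipped version.  Support is truncated where
    both lobes fall below 1e-6 of the filter peak.
    """
    T1 = params.T1 * params.time_scale_bc
    T2 = params.T2 * params.time_scale_bc
    dt = params.dt
    # generous provisional grid: lobes of width ~2*Ti decay like exp(-t²/(2Ti)²)
    tmax = 2.0 * max(T1, T2) * 6.0
    t = np.arange(0.0, tmax, dt)
    g1, g2 = _lobe(t, T1), _lobe(t, T2)
    # zero-sum + unit-norm on the provisional grid to locate the truncation point
    a, b = _solve_norms(g1, g2)
    f = a * g1 - b * g2
    peak = np.abs(f).max()
    keep = np.nonzero((np.abs(a * g1) >= 1e-6 * peak) | (np.abs(b * g2) >= 1e-6 * peak))[0]
    n = int(keep[-1]) + 1
    g1, g2 = g1[:n], g2[:n]
    a, b = _solve_norms(g1, g2)  # re-solve exactly on the final support
    f = a * g1 - b * g2
    return TemporalFilter(
        samples=f,
        dt=dt,
        normalization={"Z1": 1.0 / a, "Z2": 1.0 / b, "T1": T1, "T2": T2},
    )


def _solve_norms(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float]:
    """Coefficients (a, b) of f = a·g1 - b·g2 with Σf = 0 and ‖f‖₂ = 1."""
    s1, s2 = g1.sum(), g2.sum()
    # zero sum: a·s1 = b·s2  →  b = a·s1/s2
    ratio = s1 / s2
    f0 = g1 - ratio * g2
    a = 1.0 / np.linalg.norm(f0)
    return a, a * ratio


def amacrine_lowpass(params: CircuitParams) -> TemporalFilter:
    """Nonnegative, unimodal low-pass filter of the On-type amacrine cell.

    f(t) = [exp(-t²/τ_decay²) - exp(-t²/τ_rise²)] / Z_AC for t > 0, with
    Z_AC normalizing to unit Euclidean norm over samples.
    """
    rise = params.tac_rise * params.time_scale_ac
    decay = params.tac_decay * params.time_scale_ac
    if decay <= rise:
        raise ValueError("tac_decay must exceed tac_rise (filter would be nonpositive)")
    dt = params.dt
    t = np.arange(0.0, decay * 6.0, dt)
    g = np.exp(-(t**2) / decay**2) - np.exp(-(t**2) / rise**2)
    peak = g.max()
    n = int(np.nonzero(g >= 1e-6 * peak)[0][-1]) + 1
    g = g[:n]
    z = np.linalg.norm(g)
    return TemporalFilter(samples=g / z, dt=dt, normalization={"ZAC": z, "rise": rise, "decay": decay})


def _causal_conv(signals: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal discrete convolution along the last axis (plain sample sum)."""
    full = fftconvolve(signals, kernel[None, :], axes=-1)
    return full[..., : signals.shape[-1]]


def subunit_extents(period: float, n_subunits: int) -> list[tuple[float, float]]:
    """Equal, non-overlapping extents tiling one spatial period from x = 0."""
    w = period / n_subunits
    return [(s * w, (s + 1) * w) for s in range(n_subunits)]


def simulate(
    movie: StimulusMovie,
    params: CircuitParams,
    settle_ms: float = 1000.0,
) -> tuple[RateTrace, CellInputTraces]:
    """Run the circuit on a stimulus movie.

    The first movie frame is held for ``settle_ms`` before the movie proper to
    let the tonic inhibition and slow filters reach steady state; the returned
    traces are aligned to the movie clock with the settling period removed.
    The model is fully deterministic.
    """
    if abs(movie.dt - params.dt) > 1e-9:
        raise ValueError(
            f"movie dt {movie.dt} does not match model dt {params.dt}; resample the movie"
        )
    period = movie.period if movie.period is not None else movie.n_space * movie.dx
    if movie.n_space * movie.dx < period - 1e-9:
        raise ValueError("movie must span at least one spatial period")
    if movie.n_time * movie.dt < 100.0:
        raise ValueError("movie too short for the filter support")

    n_pad = int(round(settle_ms / params.dt))
    extents = subunit_extents(period, params.n_subunits)
    c = np.stack([subunit_contrast(movie, ext) for ext in extents])
    c = np.concatenate([np.repeat(c[:, :1], n_pad, axis=1), c], axis=1)

    f_bc = bipolar_filter(params).samples
    f_ac = amacrine_lowpass(params).samples

    b_off = _causal_conv(c, f_bc)
    b_on = -b_off
    a_off = _rect(b_off)  # Off amacrine: unit gain from Off bipolar, rectified
    ac_input = params.g_on * _rect(b_on) - params.g_serial * a_off
    a_on = _causal_conv(ac_input, f_ac) + params.A0

    rect_a_on = np.zeros_like(a_on) if params.on_inhibition_blocked else _rect(a_on)

    if params.inhibition_site == "postsynaptic":
        excitatory = _rect(b_off).sum(axis=0)
        inhibitory = -rect_a_on.sum(axis=0)
        rate = _rect(excitatory + inhibitory)
    else:  # presynaptic: inhibition subtracted from each terminal pre-rectification
        pooled_inh = params.presyn_scale * rect_a_on.sum(axis=0)
        terminal = _rect(b_off - pooled_inh[None, :])
        excitatory = terminal.sum(axis=0)
        inhibitory = -np.broadcast_to(pooled_inh, excitatory.shape).copy()
        rate = _rect(excitatory)

    sl = slice(n_pad, None)
    trace = RateTrace(rate=rate[sl], dt=params.dt, t0=movie.t0)
    inputs = CellInputTraces(
        b_off=b_off[:, sl],
        b_on=b_on[:, sl],
        a_off=a_off[:, sl],
        a_on=a_on[:, sl],
        excitatory=excitatory[sl],
        inhibitory=inhibitory[sl],
        dt=params.dt,
        t0=movie.t0,
    )
    return trace, inputs


def ablate(params: CircuitParams, component: str) -> CircuitParams:
    """In-silico pharmacology.

    ``on_inhibition`` silences the On-amacrine output onto the ganglion cell
    (glycinergic-block analog); ``serial_inhibition`` zeroes the Off-amacrine →
    On-amacrine gain (GABAergic-block analog).
    """
    if component == "on_inhibition":
        return replace(params, on_inhibition_blocked=True)
    if component == "serial_inhibition":
        return replace(params, g_serial=0.0)
    raise ValueError(f"unknown circuit component {component!r}")


def _single_transition_movie(
    spec: GratingSpec,
    start: int,
    target: int,
    fixation: float,
    transition: float,
    kind: str,
    params: CircuitParams,
    pre_ms: float = 200.0,
) -> tuple[StimulusMovie, float]:
    """Movie of one isolated transition with a long preceding fixation.

    Returns the movie and the transition-onset time on the movie clock.
    """
    entry = ScheduleEntry(
        start_position=start,
        target_position=target,
        transition_kind=kind,
        fixation_duration=fixation,
        transition_duration=transition,
        fixation_contrast=spec.contrast,
        shift_distance=shift_distance(start, target, spec.n_positions,
                                      1.0 if transition < 50.0 else 2.0),
        onset_time=fixation,
    )
    sched = TransitionSchedule([entry], n_positions=spec.n_positions)
    movie = render(sched, spec, dt=params.dt)
    return movie, entry.onset_time


def transition_traces(
    spec: GratingSpec,
    params: CircuitParams,
    fixation: float = 800.0,
    transition: float = 100.0,
    kind: str = "saccadic",
    variant: str | None = None,
    settle_ms: float = 1000.0,
    pre_ms: float = 100.0,
) -> dict[tuple[int, int], RateTrace]:
    """Model rate traces for all n² transition types, aligned to transition onset.

    Each (start, target) pair is simulated in isolation with the starting
    fixation extended by ``settle_ms`` so the trace reflects the steady-state
    history of the starting image.  Trace time 0 is the transition onset and
    traces start at -``pre_ms``.  ``variant`` may be ``dark_only`` or
    ``bright_only`` to decompose the grating into one stripe polarity
    (rendered with gray-masked transitions).
    """
    traces: dict[tuple[int, int], RateTrace] = {}
    n = spec.n_positions
    for start in range(1, n + 1):
        for target in range(1, n + 1):
            entry_kind = "gray_mask" if variant in ("dark_only", "bright_only") else kind
            entry = ScheduleEntry(
                start_position=start,
                target_position=target,
                transition_kind=entry_kind,
                fixation_duration=fixation,
                transition_duration=transition,
                fixation_contrast=spec.contrast,
                shift_distance=shift_distance(start, target, n,
                                              1.0 if transition < 50.0 else 2.0),
                onset_time=fixation,
                metadata={"polarity": variant} if variant else {},
            )
            sched = TransitionSchedule([entry], n_positions=n)
            movie = render(sched, spec, dt=params.dt)
            trace, _ = simulate(movie, params, settle_ms=settle_ms)
            i0 = int(round((fixation - pre_ms) / params.dt))
            traces[(start, target)] = RateTrace(
                rate=trace.rate[i0:], dt=params.dt, t0=-pre_ms
            )
    return traces


def compare_flash_vs_recurrence(
    spec: GratingSpec,
    params: CircuitParams,
    position: int = 1,
    fixation: float = 800.0,
    transition: float = 100.0,
    gray_ms: float = 800.0,
    response_window: float = 400.0,
) -> dict[str, dict[str, float]]:
    """Peak rate and latency for a recurring grating vs. an isolated flash.

    The recurrence condition is the standard saccadic transition with equal
    start and target; the flash condition presents the same grating abruptly
    after an extended period of mean-gray illumination.  Latencies are
    measured from fixation/flash onset to the rate maximum within
    ``response_window`` ms.
    """
    if gray_ms < 500.0:
        raise ValueError("flash must be preceded by at least 500 ms of gray")
    traces = transition_traces(spec, params, fixation, transition)
    rec = traces[(position, position)]
    flash_sched = make_variant_schedule(
        "flash", spec=spec, positions=[position], gray_duration=gray_ms,
        fixation_duration=fixation,
    )
    movie = render(flash_sched, spec, dt=params.dt)
    flash_trace, _ = simulate(movie, params, settle_ms=1000.0)

    def peak_of(trace: RateTrace, onset: float) -> dict[str, float]:
        seg = trace.window(onset, onset + response_window)
        k = int(np.argmax(seg))
        return {"peak_rate": float(seg[k]), "peak_latency": k * trace.dt}

    return {
        "recurrence": peak_of(rec, transition),  # trace t=0 is transition onset
        "flash": peak_of(flash_trace, flash_sched.entries[0].fixation_onset),
    }
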