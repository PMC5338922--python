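"""Saccade-like grating stimuli.

A spatial square-wave grating is held fixed at one of ``n_positions`` linearly
spaced spatial phases for a fixation period and then shifted, during a brief
saccade-like transition, to stop at another (or the same) phase.  Positions two
steps apart (for four positions) are contrast-reversed versions of the same
grating.  The module builds randomized transition schedules, renders them to a
discretized space-time contrast movie, and extracts per-subunit contrast time
courses — the common currency consumed by the circuit model.

Conventions
-----------
* Space is 1-D along the shift axis, in µm; position indices are 1-based and
  map to phases ``(i - 1) / n_positions`` of the spatial period.
* Phase increases in the shift direction; during a saccadic transition the
  phase advances at constant velocity through ``shift_distance`` periods.
* Contrast values are dimensionless in [-1, 1]; 0 is mean luminance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GratingSpec",
    "ScheduleEntry",
    "TransitionSchedule",
    "StimulusMovie",
    "shift_distance",
    "make_schedule",
    "make_variant_schedule",
    "render",
    "subunit_contrast",
    "blur_image",
]

TRANSITION_KINDS = frozenset(
    {"saccadic", "gray_mask", "blur_mask", "flash_from_gray", "drift_reset"}
)

#: reset distances (grating periods) allowed for drift–reset motion
DRIFT_RESET_DISTANCES = (0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class GratingSpec:
    """Geometry and contrast of the square-wave grating.

    Parameters
    ----------
    spatial_period:
        Grating period in µm (270 µm standard).
    contrast:
        Michelson contrast of the stripes, in [0, 1].
    n_positions:
        Number of linearly spaced fixation phases covering one period.
    mean_level:
        Normalized mean intensity; 0 denotes mean luminance.
    """

    spatial_period: float = 270.0
    contrast: float = 0.6
    n_positions: int = 4
    mean_level: float = 0.0

    def __post_init__(self) -> None:
        if self.spatial_period <= 0:
            raise ValueError("spatial_period must be positive")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")
        if self.n_positions < 2:
            raise ValueError("need at least two grating positions")

    def phase_of(self, position: int) -> float:
        """Spatial phase (in periods) of a 1-based position index."""
        if not 1 <= position <= self.n_positions:
            raise ValueError(f"position {position} outside 1..{self.n_positions}")
        return (position - 1) / self.n_positions


@dataclass
class ScheduleEntry:
    """One fixation-then-transition event of a schedule.

    ``onset_time`` is the absolute time (ms) of the transition onset; the
    fixation at ``start_position`` precedes it and the fixation at
    ``target_position`` follows it.
    """

    start_position: int
    target_position: int
    transition_kind: str
    fixation_duration: float
    transition_duration: float
    fixation_contrast: float
    shift_distance: float
    onset_time: float
    metadata: dict = field(default_factory=dict)

    @property
    def fixation_onset(self) -> float:
        """Absolute time (ms) at which the target fixation begins."""
        return self.onset_time + self.transition_duration

    def is_recurrence(self) -> bool:
        return self.start_position == self.target_position


@dataclass
class TransitionSchedule:
    """Ordered fixations/transitions with absolute event times."""

    entries: list[ScheduleEntry]
    n_positions: int = 4
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        onsets = [e.onset_time for e in self.entries]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onset times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def duration(self) -> float:
        """Total schedule duration in ms (last target fixation included)."""
        last = self.entries[-1]
        return last.fixation_onset + last.fixation_duration

    def transition_counts(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for e in self.entries:
            key = (e.start_position, e.target_position)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def events(self, start: int | None = None, target: int | None = None) -> np.ndarray:
        """Transition-onset times, optionally filtered by transition type."""
        return np.array(
            [
                e.onset_time
                for e in self.entries
                if (start is None or e.start_position == start)
                and (target is None or e.target_position == target)
            ]
        )


@dataclass
class StimulusMovie:
    """Discretized space-time contrast signal.

    ``values`` has shape (n_space, n_time); ``dx``/``dt`` give the sample
    spacing in µm/ms and ``t0`` the schedule time of time-sample 0.
    ``period`` records the generating grating period so that downstream
    consumers can place subunits on one spatial period.
    """

    values: np.ndarray
    dx: float
    dt: float
    t0: float = 0.0
    period: float | None = None

    @property
    def n_space(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.n_space) * self.dx

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_time) * self.dt


def shift_distance(
    start: int, target: int, n_positions: int = 4, base: float = 2.0
) -> float:
    """Shift distance (in grating periods) for a saccadic transition.

    The distance is ``base`` plus the signed minimal phase difference from
    start to target.  For standard 100-ms transitions ``base`` is 2.0, putting
    all distances in [1.5, 2.5] periods; for 33-ms transitions ``base`` is 1.0
    (range [0.5, 1.5]).  Contrast-reversed pairs are ambiguous (±half period);
    the convention used is the longer distance for transitions from the lower
    half of the position indices (2.5 for 1→3 and 2→4) and the shorter for
    their opposites.
    """
    d_idx = (target - start) % n_positions
    if n_positions % 2 == 0 and d_idx == n_positions // 2:
        delta = 0.5 if start <= n_positions // 2 else -0.5
    else:
        frac = d_idx / n_positions
        delta = frac if frac < 0.5 else frac - 1.0
    return base + delta


def _distance_base(transition_duration: float) -> float:
    # brief (33 ms) transitions use shorter shifts to limit aliasing
    return 1.0 if transition_duration < 50.0 else 2.0


def _build_entries(
    positions: Sequence[int],
    spec: GratingSpec,
    fixation: float,
    transition: float,
    kind: str,
    contrasts: Sequence[float] | None = None,
) -> list[ScheduleEntry]:
    base = _distance_base(transition)
    entries = []
    for k in range(len(positions) - 1):
        s, tgt = positions[k], positions[k + 1]
        entries.append(
            ScheduleEntry(
                start_position=s,
                target_position=tgt,
                transition_kind=kind,
                fixation_duration=fixation,
                transition_duration=transition,
                fixation_contrast=(
                    spec.contrast if contrasts is None else contrasts[k]
                ),
                shift_distance=shift_distance(s, tgt, spec.n_positions, base),
                onset_time=(k + 1) * fixation + k * transition,
            )
        )
    return entries


def make_schedule(
    spec: GratingSpec,
    n_transitions: int,
    durations: tuple[float, float] = (800.0, 100.0),
    kind: str = "saccadic",
    seed: int = 0,
    balanced: bool = False,
) -> TransitionSchedule:
    """Draw a randomized sequence of fixation positions and package it.

    Positions are i.i.d. uniform over the ``n_positions`` phases (the default),
    so each of the n² transition types has equal expected frequency.  With
    ``balanced=True`` the schedule instead walks an Eulerian circuit visiting
    every transition type exactly once per block of n² transitions.
    """
    if n_transitions < 1:
        raise ValueError("n_transitions must be >= 1")
    if kind not in TRANSITION_KINDS:
        raise ValueError(f"unknown transition kind {kind!r}")
    fixation, transition = durations
    rng = np.random.default_rng(seed)
    if balanced:
        positions = _eulerian_positions(spec.n_positions, n_transitions, rng)
    else:
        positions = rng.integers(1, spec.n_positions + 1, size=n_transitions + 1)
    entries = _build_entries(list(positions), spec, fixation, transition, kind)
    return TransitionSchedule(entries, n_positions=spec.n_positions, seed=seed)


def _eulerian_positions(n: int, n_transitions: int, rng) -> list[int]:
    """Node sequence of Eulerian circuits over the complete digraph with loops."""
    positions = [int(rng.integers(1, n + 1))]
    while len(positions) - 1 < n_transitions:
        # Hierholzer on the complete digraph incl. self-loops (in=out degree)
        edges = {u: list(rng.permutation(np.arange(1, n + 1))) for u in range(1, n + 1)}
        stack = [positions[-1]]
        circuit: list[int] = []
        while stack:
            u = stack[-1]
            if edges[u]:
                stack.append(int(edges[u].pop()))
            else:
                circuit.append(stack.pop())
        circuit.reverse()
        positions.extend(circuit[1:])
    return positions[: n_transitions + 1]


def make_variant_schedule(variant: str, **params) -> TransitionSchedule:
    """Build one of the stimulus-ensemble variants.

    Supported variants: ``contrast_switch`` (per-fixation contrast drawn from
    two levels), ``dark_only``/``bright_only`` (one stripe polarity replaced by
    mean gray; gray-masked transitions), ``duration_sweep`` (per-transition
    durations from a list), ``local_patch`` (stimulus restricted to a patch,
    gray outside), ``fine_phase`` (finer phase grid, e.g. 30° resolution),
    ``drift_reset`` (slow half-period drift then rapid opposite reset), and
    ``flash`` (gratings appearing in isolation from mean gray).
    """
    spec: GratingSpec = params.pop("spec", GratingSpec())
    seed: int = params.pop("seed", 0)
    n_transitions: int = params.pop("n_transitions", 16)
    fixation: float = params.pop("fixation_duration", 800.0)
    transition: float = params.pop("transition_duration", 100.0)
    rng = np.random.default_rng(seed)

    if variant == "contrast_switch":
        levels = tuple(params.pop("levels", (0.30, 0.60)))
        sched = make_schedule(spec, n_transitions, (fixation, transition), "saccadic", seed)
        contrasts = rng.choice(levels, size=len(sched.entries))
        for e, c in zip(sched.entries, contrasts):
            e.fixation_contrast = float(c)
            e.metadata["variant"] = "contrast_switch"
        sched.metadata["variant"] = "contrast_switch"
        return sched

    if variant in ("dark_only", "bright_only"):
        sched = make_schedule(spec, n_transitions, (fixation, transition), "gray_mask", seed)
        for e in sched.entries:
            e.metadata["polarity"] = variant
            e.metadata["variant"] = variant
        sched.metadata["variant"] = variant
        return sched

    if variant == "duration_sweep":
        durations_list = params.pop("transition_durations")
        sched = make_schedule(spec, n_transitions, (fixation, transition), "saccadic", seed)
        t = fixation
        for k, e in enumerate(sched.entries):
            dur = float(durations_list[k % len(durations_list)])
            e.transition_duration = dur
            e.shift_distance = shift_distance(
                e.start_position, e.target_position, spec.n_positions, _distance_base(dur)
            )
            e.onset_time = t
            t += dur + fixation
            e.metadata["variant"] = "duration_sweep"
        sched.metadata["variant"] = "duration_sweep"
        return sched

    if variant == "local_patch":
        patch = params.pop("patch_extent")  # (lo, hi) µm along the shift axis
        sched = make_schedule(spec, n_transitions, (fixation, transition), "saccadic", seed)
        for e in sched.entries:
            e.metadata["patch_extent"] = tuple(patch)
            e.metadata["variant"] = "local_patch"
        sched.metadata["variant"] = "local_patch"
        sched.metadata["patch_extent"] = tuple(patch)
        return sched

    if variant == "fine_phase":
        n_fine = params.pop("n_positions", 12)  # 30° of phase by default
        fine_spec = replace(spec, n_positions=n_fine)
        sched = make_schedule(fine_spec, n_transitions, (fixation, transition), "saccadic", seed)
        sched.metadata["variant"] = "fine_phase"
        return sched

    if variant == "drift_reset":
        reset = float(params.pop("reset_distance"))
        if not any(math.isclose(reset, r) for r in DRIFT_RESET_DISTANCES):
            raise ValueError(
                f"reset distance {reset} not in {DRIFT_RESET_DISTANCES} periods"
            )
        drift_dur = params.pop("drift_duration", 266.0)
        reset_dur = params.pop("reset_duration", 67.0)
        drift_dist = params.pop("drift_distance", 0.5)
        total = drift_dur + reset_dur
        positions = rng.integers(1, spec.n_positions + 1, size=n_transitions + 1)
        entries = []
        for k in range(n_transitions):
            s = int(positions[k])
            # net displacement: drift forward, reset backward
            net = drift_dist - reset
            target_phase = (spec.phase_of(s) + net) % 1.0
            tgt = int(round(target_phase * spec.n_positions)) % spec.n_positions + 1
            entries.append(
                ScheduleEntry(
                    start_position=s,
                    target_position=tgt,
                    transition_kind="drift_reset",
                    fixation_duration=fixation,
                    transition_duration=total,
                    fixation_contrast=spec.contrast,
                    shift_distance=net,
                    onset_time=(k + 1) * fixation + k * total,
                    metadata={
                        "variant": "drift_reset",
                        "drift_duration": drift_dur,
                        "reset_duration": reset_dur,
                        "drift_distance": drift_dist,
                        "reset_distance": reset,
                    },
                )
            )
        return TransitionSchedule(entries, n_positions=spec.n_positions, seed=seed,
                                  metadata={"variant": "drift_reset"})

    if variant == "flash":
        gray = params.pop("gray_duration", 800.0)
        positions = params.pop("positions", None)
        if positions is None:
            positions = list(rng.integers(1, spec.n_positions + 1, size=n_transitions))
        entries = []
        t = gray
        for p in positions:
            entries.append(
                ScheduleEntry(
                    start_position=int(p),
                    target_position=int(p),
                    transition_kind="flash_from_gray",
                    fixation_duration=fixation,
                    transition_duration=0.0,
                    fixation_contrast=spec.contrast,
                    shift_distance=0.0,
                    onset_time=t,
                    metadata={"variant": "flash"},
                )
            )
            t += fixation + gray
        return TransitionSchedule(entries, n_positions=spec.n_positions, seed=seed,
                                  metadata={"variant": "flash"})

    raise ValueError(f"unknown stimulus variant {variant!r}")


def _bright_measure(u: np.ndarray) -> np.ndarray:
    """Measure of the bright set {v in [0, u): frac(v) < 0.5} in period units."""
    k = np.floor(u)
    return 0.5 * k + np.minimum(u - k, 0.5)


def _bright_fraction(
    x: np.ndarray, dx: float, period: float, phase: np.ndarray
) -> np.ndarray:
    """Per-pixel bright fraction of the square wave, area-averaged over [x, x+dx).

    Pixels fully inside a stripe are exactly 0 or 1; a pixel straddling a
    stripe edge takes the fractional coverage, so spatial means over
    pixel-aligned windows equal the continuous-space integral exactly.
    """
    u0 = x[:, None] / period - phase[None, :]
    w = dx / period
    return (_bright_measure(u0 + w) - _bright_measure(u0)) / w


def render(
    schedule: TransitionSchedule,
    spec: GratingSpec,
    dx: float | None = None,
    dt: float = 0.1,
    width: float | None = None,
    blur_sigma: float = 2250.0,
) -> StimulusMovie:
    """Render a schedule to a space-time contrast movie.

    During fixations the movie shows the ±contrast square wave at the fixation
    phase; during saccadic transitions the phase advances at constant velocity
    through ``shift_distance`` periods; gray-masked transitions are uniformly
    zero; blur-masked transitions show the spatially Gaussian-blurred frame
    (σ ``blur_sigma`` µm, truncated at 3σ).
    """
    if dx is None:
        dx = spec.spatial_period / 64.0
    if dx > spec.spatial_period / 4.0:
        raise ValueError("dx must not exceed a quarter period")
    if width is None:
        width = spec.spatial_period
    for e in schedule.entries:
        for dur in (e.fixation_duration, e.transition_duration):
            if abs(dur / dt - round(dur / dt)) > 1e-6:
                raise ValueError(f"dt={dt} does not divide duration {dur}")

    n_t = int(round(schedule.duration / dt))
    x = np.arange(int(round(width / dx))) * dx
    phase = np.empty(n_t)
    contrast = np.empty(n_t)
    gray = np.zeros(n_t, dtype=bool)
    blur = np.zeros(n_t, dtype=bool)
    polarity = np.zeros(n_t, dtype=np.int8)  # 0 full, -1 dark_only, +1 bright_only
    t = np.arange(n_t) * dt

    def seg(a: float, b: float) -> slice:
        return slice(int(round(a / dt)), int(round(b / dt)))

    prev_end = 0.0
    for e in schedule.entries:
        start_phase = spec.phase_of(e.start_position) if e.start_position else 0.0
        target_phase = spec.phase_of(e.target_position)
        pol = {"dark_only": -1, "bright_only": 1}.get(e.metadata.get("polarity"), 0)
        # fixation preceding the transition
        s = seg(prev_end, e.onset_time)
        phase[s] = start_phase
        contrast[s] = e.fixation_contrast
        polarity[s] = pol
        if e.transition_kind == "flash_from_gray":
            gray[s] = True
        # transition period
        s = seg(e.onset_time, e.fixation_onset)
        tt = t[s] - e.onset_time
        if e.transition_kind == "saccadic" or e.transition_kind == "blur_mask":
            phase[s] = start_phase + e.shift_distance * tt / max(e.transition_duration, dt)
            blur[s] = e.transition_kind == "blur_mask"
        elif e.transition_kind == "gray_mask":
            phase[s] = start_phase
            gray[s] = True
        elif e.transition_kind == "flash_from_gray":
            phase[s] = target_phase
            gray[s] = True
        elif e.transition_kind == "drift_reset":
            d_dur = e.metadata["drift_duration"]
            r_dur = e.metadata["reset_duration"]
            d_dist = e.metadata["drift_distance"]
            r_dist = e.metadata["reset_distance"]
            drifting = tt < d_dur
            phase[s] = np.where(
                drifting,
                start_phase + d_dist * tt / d_dur,
                start_phase + d_dist - r_dist * (tt - d_dur) / r_dur,
            )
        else:  # pragma: no cover - guarded at schedule construction
            raise ValueError(f"unknown transition kind {e.transition_kind!r}")
        contrast[s] = e.fixation_contrast
        polarity[s] = pol
        # fixation following the transition
        s = seg(e.fixation_onset, e.fixation_onset + e.fixation_duration)
        phase[s] = target_phase
        contrast[s] = e.fixation_contrast
        polarity[s] = pol
        prev_end = e.fixation_onset + e.fixation_duration

    fb = _bright_fraction(x, dx, spec.spatial_period, phase)
    values = (2.0 * fb - 1.0) * contrast[None, :]
    if polarity.any():
        # decomposed gratings: the removed polarity's stripes sit at mean gray
        values = np.where(polarity[None, :] == -1, -(1.0 - fb) * contrast[None, :], values)
        values = np.where(polarity[None, :] == 1, fb * contrast[None, :], values)
    values[:, gray] = 0.0
    if blur.any():
        sigma_px = blur_sigma / dx
        blurred = ndimage.gaussian_filter1d(
            values[:, blur], sigma=sigma_px, axis=0, mode="wrap", truncate=3.0
        )
        values[:, blur] = blurred

    patch = schedule.metadata.get("patch_extent")
    if patch is not None:
        outside = (x < patch[0]) | (x >= patch[1])
        values[outside, :] = 0.0

    return StimulusMovie(values=values, dx=dx, dt=dt, t0=0.0,
                         period=spec.spatial_period)


def subunit_contrast(movie: StimulusMovie, extent: tuple[float, float]) -> np.ndarray:
    """Spatial mean of the contrast signal over a subunit extent [lo, hi) µm."""
    lo, hi = extent
    if hi <= lo:
        raise ValueError("empty subunit extent")
    x = movie.x
    mask = (x >= lo - 1e-9) & (x < hi - 1e-9)
    if not mask.any():
        raise ValueError("subunit extent contains no spatial samples")
    if lo < x[0] - 1e-9 or hi > x[-1] + movie.dx + 1e-9:
        raise ValueError("subunit extent outside the movie's spatial range")
    return movie.values[mask, :].mean(axis=0)


def blur_image(image: np.ndarray, sigma_um: float, pixel_um: float) -> np.ndarray:
    """Gaussian blur of an image, σ in µm, truncated at 3σ."""
    return ndimage.gaussian_filter(image, sigma=sigma_um / pixel_um, truncate=3.0)
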