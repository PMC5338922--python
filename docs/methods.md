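# Methods

## The phenomenon and the model

Image-recurrence-sensitive (IRS) ganglion cells respond to a saccade-like
image shift with up to two bursts: one during the shift itself, and — only if
the image after the shift equals the image before it — a second burst roughly
100–150 ms after fixation onset. The circuit model explains the second burst
through *serial inhibition* acting inside localized spatial subunits.

The ganglion cell pools `n_subunits` (default 4) equal, non-overlapping
subunits that tile one spatial period of the grating. Per subunit `s`, with
`c_s(t)` the spatially averaged stimulus contrast over the subunit extent:

```
a_Boff,s = f_BC * c_s                     (Off bipolar)
a_Bon,s  = −a_Boff,s                      (On bipolar)
a_Aoff,s = [a_Boff,s]+                    (Off amacrine, unit gain)
a_Aon,s  = f_AC * (g_on·[a_Bon,s]+ − g_serial·a_Aoff,s) + A0
rate     = [ Σ_s ( [a_Boff,s]+ − [a_Aon,s]+ ) ]+     (postsynaptic variant)
```

`[·]+` is half-wave rectification (the synaptic nonlinearity; inhibitory
outputs carry sign −1). The bipolar filter is biphasic,

```
f_BC(t) = (1/Z1)[exp(−t²/T1²) − exp(−t²/(2T1)²)]
        − (1/Z2)[exp(−t²/T2²) − exp(−t²/(2T2)²)]     for t > 0, else 0,
```

with `Z1`, `Z2` fixed by two conditions: zero discrete time integral
(transient response to contrast steps) and unit Euclidean norm over samples
at 0.1-ms resolution. The On-amacrine low-pass is

```
f_AC(t) = (1/Z_AC)[exp(−t²/T_dec²) − exp(−t²/T_rise²)]   for t > 0, else 0,
```

nonnegative and unit-norm. Because the filters are normalized over samples,
convolutions are plain discrete sums; rate units are arbitrary.

Mechanism: the On amacrine is tonically active (`A0`) and slow (`f_AC`), so
its inhibition of the ganglion cell carries the *pre-transition* image across
the shift. At retinal locations where a dark stripe returns after the shift,
the Off amacrine (driven by the returning dark stripe through the Off bipolar)
suppresses the On amacrine — disinhibition — and the pooled excitation breaks
through as the post-fixation burst. If the image changed, the disinhibition
lands at locations whose excitation is weak, and no burst emerges.

### Parameters (defaults)

| symbol | default | meaning |
|---|---|---|
| `T1`, `T2` | 40, 60 ms | excitatory / antagonistic lobes of `f_BC` |
| `tac_rise`, `tac_decay` | 30, 200 ms | On-amacrine low-pass time constants |
| `g_on` | 0.05 | On bipolar → On amacrine gain |
| `g_serial` | 0.2 | Off amacrine → On amacrine (serial inhibition) gain |
| `A0` | 2 (16: increased tonic regime) | tonic On-amacrine activation |
| `dt` | 0.1 ms | simulation step |
| `inhibition_site` | postsynaptic | presynaptic variant subtracts `0.5·Σ[a_Aon]+` from each bipolar terminal before rectification |
| `time_scale_bc/ac` | 1 | multiplicative sweeps of all filter time constants |

The presynaptic factor 0.5 keeps the net inhibition strength fixed, since the
grating drives two of the four Off bipolar terminals at any time. In-silico
pharmacology: `ablate(params, "on_inhibition")` silences the On-amacrine
output (glycinergic-block analog; responses become non-specific across
transitions), `ablate(params, "serial_inhibition")` zeroes `g_serial`
(GABAergic-block analog; the recurrence burst collapses).

## Stimulus conventions

Space is 1-D along the shift axis. Position indices 1..4 map to phases 0, ¼,
½, ¾ of the 270-µm period; positions two apart are contrast-reversed.
Shift distance for a saccadic transition is `2.0 + signed minimal phase
difference` periods, with the convention 2.5 periods for the contrast-reversed
transitions 1→3 and 2→4 and 1.5 for their opposites; quarter-phase
transitions interpolate to 1.75/2.25. This reproduces every stated case;
since no explicit distance is stated for quarter-phase transitions, the
interpolation is this package's choice. Brief (33-ms) transitions use base
1.0 (range 0.5–1.5 periods). Monitor refresh is not modeled; the stimulus is
a continuous-time contrast signal sampled at the model `dt`.

Rendering uses area-averaged pixels (default `dx` = period/64): each pixel
takes the exact mean of the square wave over its extent, so subunit averages
over pixel-aligned windows equal the continuous-space integral exactly, and
the quarter-period subunit contrast during a constant-velocity shift matches
the analytic piecewise-linear sliding mean to machine precision. Gray-masked
transitions are uniformly zero; blur-masked transitions apply a spatial
Gaussian (σ = 2250 µm, truncated at 3σ). Randomized schedules draw positions
i.i.d. uniform from a single integer seed; a block-balanced option (an
Eulerian circuit visiting each of the 16 transition types exactly once per
block) exists and is used by fixtures that need full coverage at small n.

## Analysis conventions

* All windows are half-open `[start, stop)` in ms relative to the stated
  alignment event; PSTH bins are 10 ms; rates are counts/(trials·bin).
* RSI derivatives are successive-bin differences; the derivative assigned to
  the first bin inside the 50–200 ms post-fixation window uses the preceding
  bin. Targets with `D_rec + D_change ≤ 0` contribute a neutral 0 term and
  are flagged. The "maximally different" change start is
  `target + n_positions/2` (the contrast-reversed grating for 4 positions).
* The 50-Hz rate screen is the mean over the four recurrence transitions of
  each PSTH's maximum in the post-fixation window. Model rates are in
  arbitrary units, so the screen is skipped (`rate_screen=None`) when
  classifying model output; it applies to spike-derived PSTHs in Hz.
* Peak latency: parabola vertex through the maximal bin and its neighbors;
  edge maxima fall back to the bin center and are flagged.
* Biphasic index: amplitude of the later filter lobe over the earlier one
  (0 if monophasic). Values above 1 mark dominant rebound lobes, as observed
  in strongly biphasic cells; "size" is read as amplitude, not area.
* STA uses the 700-ms stimulus segment preceding each spike at the frame
  rate; lag k is the frame k intervals before the spike. SVD separation fixes
  the sign so the temporal primary extremum matches the cell's polarity.
  Receptive-field outlines are 1.5-σ ellipses of a least-squares 2-D Gaussian
  fit; the diameter is that of the equal-area circle.
* Correlograms: 1-ms bins over ±100 ms; for each reference spike a lag bin is
  marked if the partner train fires in it; the peak is searched in ±40 ms and
  baseline-subtracted, the baseline averaging the ±(20–100) ms flanks.
* Gray-masked vs. saccadic comparison: the normalized RMS difference is
  evaluated over the 50–200 ms post-fixation response window — the same
  window every detection and peak measure uses. Including the first 50 ms
  after fixation onset, where the trailing saccade motion still drives the
  bipolar filters, raises the value to ~10%.

## Synthetic data: what it emulates, and what it does not

Template IRS cells place Gaussian bursts at each transition onset and (for
recurrences only) 120 ms after fixation onset on a 2-Hz baseline; they are
independent of the circuit model so analysis tests do not inherit model
assumptions. LN control cells monitor one quarter-period region through a
less biphasic filter (antagonistic lobe rescaled to a biphasic index of 0.66,
typical of the non-IRS population) and therefore respond to any darkening of
their region, failing the RSI criterion. Planted populations tile receptive
fields on a 275-µm grid and can share a fraction of jittered (≤5 ms) spikes
between neighboring IRS cells to mimic gap-junction coupling. Natural-like
images are 1/f-amplitude noise normalized to mean 1 and SD/mean = 0.5
(pixel 15 µm).

None of these generators emulate electrode noise, spike-sorting errors,
adaptation, or real natural-image statistics beyond the power spectrum;
passing the planted-truth recoveries shows the pipeline is correct and
well-calibrated on its stated model classes, not that real recordings would
yield the same population numbers.

## Numerical choices

* Filters are truncated where their lobes fall below 10⁻⁶ of the peak
  (~0.46 s for `f_BC`, ~1 s for `f_AC`); normalization constants are re-solved
  exactly on the truncated support, so the zero-integral and unit-norm
  conditions hold to rounding error.
* Each transition type is simulated in isolation with the starting fixation
  extended by 1 s of settling so slow filters and the tonic level reach steady
  state before the analysis window; the model is deterministic, so a single
  pass per transition type suffices (PSTH "trials" are trivial).
* Convolutions use FFT-based convolution truncated to the causal range.
* `f_AC` requires `tac_decay > tac_rise`; the converse raises. `T2 ≤ T1` is
  permitted (the filter is then defined but atypical).
* Poisson spikes are drawn per dt-bin (counts with mean rate·dt, uniform
  placement within the bin), bit-reproducible from a seed.
* Benchmarks run at desk scale: the receptive-field recovery uses a 14×14
  checkerboard (60-µm stixels, 50 Hz, 400 s, 5000 spikes), the population
  screen 15 cells × 32 balanced transitions × 3 trials. These sizes give
  comfortable statistical margins for the recovery criteria while keeping the
  full suite fast.

## Known limitations

* The model is a qualitative proof of principle: no parameter fitting, no
  photoreceptor adaptation, gain control, or feedback; conductance-based and
  spiking dynamics are out of scope. Responses to very brief (33 ms) and long
  (≥200 ms) transitions are known to deviate from recordings — the bipolar
  filters are too weakly activated by very rapid shifts, and long saccadic
  shifts introduce direction-dependent artifacts tied to the asymmetric
  shift-distance convention.
* With four quarter-period subunits the spatial resolution is one quarter
  period, so the fine-displacement half-suppression scale (tens of µm) is not
  quantitatively reproduced; the stimulus generator nevertheless supports
  fine phase steps.
* Measured population statistics (cell counts, biphasic-index and
  receptive-field-size distributions, patch-clamp currents) require recorded
  data and are not reproduced here; the package instead verifies the
  corresponding computational properties on planted-truth synthetics.
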