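# Methods

This note documents the models, conventions and numerical choices behind
`pulsegate`, in the order data flows through the package.

## Stimulus clock

The paradigm is fully described by a `StimulusSpec`: an 800 Hz carrier
chopped into 25 ms tone bursts with 5 ms linear rise/fall ramps, 80 tones
over 2 s, baseline 65 dB, and two +15 dB pressure increments at 1100 and
1700 ms, each elevating two consecutive tones (600 ms pulse spacing, 500 ms
inter-stimulus interval).  dB increments are interpreted as
pressure-amplitude dB (factor `10^(dB/20) ≈ 5.62` for +15 dB), the sound
pressure level convention.  Pulse onsets must sit on the tone grid; the
derived `EventSchedule` is the single clock shared by the simulator and all
analysis windows, so no stage can drift relative to another.  The audio
waveform exists for documentation and listening checks only; linear ramps
were chosen because nothing in the paradigm constrains the ramp shape, and
the elevated-segment length (two tones) is configurable since it is a
paradigm parameter rather than a physical constraint.

## Trial simulator

Each simulated trial on the signal channels is the sum of:

1. **ASSR** — a sinusoid at the driving frequency (40 Hz) whose per-trial
   phase is drawn from a von Mises distribution with concentration
   `kappa_steady`.  The amplitude ramps linearly from 0 over the first
   250 ms of the sound (the canonical ASSR build-up time), stays constant
   until sound offset, and falls over one tone period.  The population ITPC
   of such phases is the Bessel ratio `R(κ) = I1(κ)/I0(κ)`; the inverse
   mapping (bisection, round-trip error ≤ 1e-6) lets a target coherence be
   configured directly.  Default target: R = 0.35 (κ ≈ 0.75), in the range
   of published pre-pulse coherence levels at the driving frequency.
2. **Desynchronisation** — inside a 0–200 ms window after each pulse the
   trial's phase is replaced by a fresh draw with reduced concentration
   (default target R = 0.10), blended in and out with 10 ms raised-cosine
   edges and restored to the trial's own steady phase afterwards.  The
   phenomenon this emulates is a transient ITPC dip that recovers to the
   steady-state level; a phase redraw with lower κ is the simplest
   generative mechanism producing exactly that, and applying the *same*
   mechanism at both pulses makes the two oscillatory responses
   exchangeable by construction.
3. **Change-related ERPs** — Gaussian-windowed deflections identical across
   trials: N100-like (−4 µV, 100 ms post pulse, σ 20 ms) and P200-like
   (+3 µV, 180 ms, σ 25 ms), both inside the peak search windows.  The
   second pulse's deflections are scaled by `1 − PPS/100` (default 35 %).
4. **Flanker bursts** — phase-locked (identical across trials) oscillatory
   bursts at 32 and 50 Hz (0.35 µV, centred 130 ms post pulse, σ 60 ms).
   Being deterministic they raise ITPC at their frequencies without a
   second circular-statistics machinery.  No published generative scale
   exists for these; the amplitude was fixed once so that the pulse-window
   coherence lands near the observed ~0.2 magnitude.
5. **1/f noise** — white Gaussian noise spectrally shaped to power
   ∝ 1/f (DC bin zeroed), normalised per trial and channel to 1.0 µV RMS,
   independent across trials and channels.
6. **Blink artifacts** (optional) — positive Gaussian transients (peak
   150 µV, σ 120 ms, random latency) on frontal/ocular channels in a
   Bernoulli-selected subset of trials; the contaminated indices are
   returned as ground truth for the rejection stage.

Channel model: Fz carries the full cortical signal, Cz 0.9×, the mastoids
P9/P10 0.25×, the ocular pair 0.1×; noise is full-strength everywhere.
The mastoid copies make linked-mastoid referencing a real operation (it
scales the Fz signal by 0.75) rather than a no-op.  One master seed is
split into named substreams (steady phases, desync redraws, noise,
artifacts), so regenerating one component leaves the others' draws intact;
a fixed seed reproduces the trial set bit-identically.

**What the simulator does not emulate:** dipole geometry and realistic
scalp topography, eye movements other than threshold-exceeding blinks,
line noise, non-stationary arousal effects, and any coupling between the
evoked transients and the oscillatory phase (they are additive).  Passing
recovery tests therefore demonstrates that the *measurement pipeline* is
unbiased under the stated generative model, not that the model captures
everything in recorded EEG.  One consequence surfaced by the tests: the
ERP templates carry some phase-locked energy near 30–34 Hz, so when
suppression makes the two pulses' templates unequal, a small genuine
pulse-1 vs pulse-2 difference appears in the low-band coherence deltas.
Analyses of the oscillatory null therefore disable suppression to keep the
two pulses exchangeable.

## Preprocessing

Order of operations: linked-mastoid re-referencing (mean of P9/P10
subtracted sample-wise from every channel) → offline 0.16–100 Hz band →
±100 µV rejection (a trial survives iff its absolute voltage stays at or
below threshold on every channel and sample; survivors are untouched) →
DC-offset correction using the −200…−100 ms pre-stimulus mean.  The evoked
waveform is the arithmetic trial mean, then 0.16–35 Hz filtered and
baseline-corrected.  Rejection runs on the offline-band data because it
belongs to the recording/averaging stage, before the narrower ERP
filtering.  Fewer than `min_trials` (default 100) survivors raises a
warning, not an error, so small desk-scale runs remain possible.

Filters are 4th-order Butterworth, applied as separate high-pass and
low-pass stages in second-order sections, forward–backward
(`sosfiltfilt` with maximal padding).  Zero-phase filtering is required
because the peak-latency windows presuppose undistorted latencies (a test
pulse's peak moves by < 1 sample).  The cascade rather than a single
band-pass design keeps the sections well conditioned with corner
frequencies three decades apart; DC is suppressed to ~1e-11 of its input.

## ERP measurement

Peaks are closed-window extrema: N100 = most negative sample 65–160 ms,
P200 = most positive sample 150–270 ms after the pulse onset (the change
onset is the only sensible anchor for these windows).  Ties break to the
earliest latency, so a flat trace reports the window start.  The 150–160 ms
overlap between the windows is resolved purely by polarity; no ordering
constraint is imposed.  The response amplitude is peak-to-peak, which makes
it invariant to baseline shifts (shifting a trace by a constant moves both
peak amplitudes but not their difference).  Suppression
`(A1 − A2)/A1 × 100` is undefined for a nonpositive first amplitude and
raises an error there.

## Time-frequency analysis

Complex Morlet kernels with five cycles (`σ_t = 5/(2πf)`, 19.9 ms at
40 Hz), truncated at ±5σ_t and L2-normalised; frequencies 4–100 Hz in 2 Hz
steps; coefficients sampled every 25 ms on a grid anchored at t = 0 so the
baseline windows land on grid points.  ITPC is the plain (unweighted)
magnitude of the across-trial mean of unit-modulus coefficients — the
literature-standard phase-locking factor, which is what the 0-to-1 range
convention implies.  Trials with an exactly zero coefficient carry no phase
and are excluded from that point's mean; points where every trial is zero
are NaN and flagged.

**Edge handling.**  Convolution zero-pads the epoch edges.  A grid point is
flagged edge-contaminated when it lies within 1.65σ_t of an epoch edge,
i.e. when ≥ 1 % of the kernel's energy falls outside the recording; flagged
points are excluded from window statistics.  (Flagging the full ±5σ_t
support would mark *every* baseline point for f < 40 Hz and make low-band
baselines uncomputable, while beyond 1.65σ the Gaussian envelope
contributes ≈ nothing.)  With this rule no 30–52 Hz point in the pre-pulse
or search windows is flagged; the pre-stimulus baseline keeps 3–5 of its 5
grid points.

**Bands and windows.**  A 2 Hz-wide band label (e.g. 40–42 Hz) on a 2 Hz
grid can only contain its two endpoint bins, so a band time course is the
mean of the two endpoint rows (adjacent bands legitimately share a row; a
degenerate band is a single row).  All window intervals are closed.  The
steady-state summary averages 350–850 ms (21 grid points, past the 250 ms
build-up); pulse contrasts take the extremum over 1100–1350 / 1700–1950 ms
against the pre-pulse means over 850–1000 / 1450–1600 ms, with
`delta = extremum − pre-pulse mean` (negative: desynchronisation; positive:
coherence burst).

A single 100-trial steady-state ITPC estimate has a sampling SD near 0.06:
the per-trial phase is constant across the steady window, so the 21 grid
points are essentially one resultant-length draw, whose SD at R = 0.35,
n = 100 follows from circular statistics.  Calibration checks therefore
compare Monte-Carlo means over seeded replicates with the target, not
single runs.

## Statistics

Wilcoxon signed-rank: zero differences dropped before ranking (Wilcoxon's
original treatment), midranks for ties, T = smaller signed-rank sum.  The
large-sample p-value uses the normal approximation *without* continuity
correction — `z = (T − n(n+1)/4)/√(n(n+1)(2n+1)/24)`, two-sided — which at
n = 21 with one-signed differences bottoms out at 6.0×10⁻⁵, the floor that
appears repeatedly in published tables of this design; a tie-corrected
variance is available but off by default.  The exact method evaluates the
full 2ⁿ sign-assignment distribution of T via dynamic programming over the
doubled (integer) midranks — equivalent to brute-force enumeration, which
the tests verify directly.  All-zero differences are flagged degenerate
(p = NaN) rather than raising.

Shapiro–Wilk delegates to scipy's implementation of the standard
approximations (n between 3 and 5000; constant samples rejected).

Sample-size planning uses the asymptotic-relative-efficiency method of
common power software: the Wilcoxon design at nominal n is treated as a
paired t-test at effective `n' = n × ARE` with noncentrality `d√n'` and
`n' − 1` (non-integer) degrees of freedom; n grows from the enforced lower
bound 5 until the two-sided noncentral-t power reaches the target.
ARE = 3/π for a normal parent (default); the distribution-free bound 0.864
and ARE = 1 (plain paired t) are selectable.  At extreme noncentrality,
where scipy's noncentral t loses accuracy, the normal limit is used.

Group tables mirror the per-band layout of paired-pulse ITPC studies: per
electrode, band and extremum kind, the pre-pulse mean (SD), extremum mean
(SD) and paired Wilcoxon p for each pulse, plus the pulse-1 vs pulse-2
comparison of the deltas; optional tables compare steady state against the
pre-stimulus baseline and the first against the second evoked amplitude.
No multiple-testing correction is applied across bands by default,
mirroring the field's per-band-at-0.05 convention for this table (a Holm
option exists in spirit via the returned raw p-values).

## Pipeline and reproducibility

`run_pipeline` chains simulate → preprocess → erp → tfa → stats → report;
each stage consumes and emits files under one output directory, so any
stage can be re-run from cached upstream outputs with identical results.
Cohorts draw per-subject parameters around the configured means (SDs in
`CohortJitter`, clipped to valid ranges) with per-subject seed substreams.
Every table carries a provenance header (package version, SHA-1 hash of the
canonical config JSON, seed); identical config + seed yields byte-identical
tables.  Default problem sizes used throughout the tests — up to 20
subjects × 100 trials, and the 30–52 Hz grid for band analyses — keep a
full validation run in the minutes range while leaving the Monte-Carlo
tolerances meaningful.

## Known limitations

* The simulator's additive, phase-locked ERP and flanker components are a
  deliberate simplification; real change-related responses jitter in
  latency and amplitude across trials.
* EDF export quantises to 16 bits over the data range (the format's
  limit); the npz container is lossless.
* ITPC near the epoch edges and below ~10 Hz is dominated by flagged
  edge-contaminated points; the package computes it but excludes it from
  window statistics, so very-low-frequency dynamics are out of scope.
* The ARE-based sample-size routine reproduces the planning convention of
  the cited tools; it is not an exact small-sample Wilcoxon power
  computation.
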