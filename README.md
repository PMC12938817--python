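# pulsegate

Paired-pulse auditory change analysis for 40 Hz tone-train EEG: change-related
N100/P200 evoked potentials with their paired-pulse suppression, and the
transient inter-trial phase coherence (ITPC) dynamics of low-gamma
oscillations — together with a trial-level synthetic EEG generator whose
ground truth is known analytically.

## The scientific problem

A train of brief tones presented at 40 Hz entrains an auditory steady-state
response (ASSR) — a cortical oscillation phase-locked to the stimulation
rate.  When the sound pressure of the train abruptly increases, two things
happen: a transient *change-related response* (an N100-like negativity
followed by a P200-like positivity) appears in the evoked potential, and the
phase synchrony of the ongoing oscillations is transiently perturbed.
Presenting two identical increments 600 ms apart makes this a *paired-pulse*
paradigm: the second evoked response is attenuated (paired-pulse
suppression, a sensory-gating measure), and one can ask whether the
oscillatory response gates in the same way.  Both measures are candidate
biomarkers of pre-attentive auditory processing and are of interest in
psychiatric-disorder research, where reduced 40 Hz ASSR synchrony and
impaired gating are replicated findings.

`pulsegate` implements the complete measurement pipeline for this paradigm
(for EEG epochs of −200…2300 ms around sound onset at 1000 Hz), and a
simulator that generates trials with every generative parameter known, so
each analysis stage can be validated against ground truth without any
recorded data.

## The quantities it computes

**ITPC** (phase-locking factor).  With per-trial complex Morlet coefficients
$c_k(f,t)$ (five cycles, $\sigma_t = n_{cyc}/(2\pi f)$, frequencies 4–100 Hz
in 2 Hz steps, 25 ms time grid anchored at sound onset),

$$\mathrm{ITPC}(f,t) = \Bigl|\tfrac1N \sum_{k=1}^{N} \tfrac{c_k(f,t)}{|c_k(f,t)|}\Bigr| \in [0,1].$$

Windowed summaries: pre-stimulus baseline (−200…−100 ms), late steady state
(350–850 ms), and per-pulse contrasts of the windowed extremum (1100–1350 /
1700–1950 ms) against the pre-pulse mean (850–1000 / 1450–1600 ms).

**Change-related response and PPS.**  On the 0.16–35 Hz evoked average, the
N100 is the negative extremum 65–160 ms and the P200 the positive extremum
150–270 ms after a pulse; the response amplitude is peak-to-peak
$A = A_{P200} - A_{N100}$ and suppression is
$\mathrm{PPS} = (A_1 - A_2)/A_1 \times 100\,\%$.

**Simulator phase model.**  Per-trial ASSR phases are von Mises distributed;
concentration $\kappa$ maps to the population ITPC through the Bessel ratio
$R(\kappa) = I_1(\kappa)/I_0(\kappa)$, and `kappa_from_target_itpc` inverts
it, so a target coherence level can be dialled in exactly.

**Inference.**  Wilcoxon signed-rank tests (T = smaller signed-rank sum,
normal approximation without continuity correction, or exact enumeration),
Shapiro–Wilk screening, and ARE-based a priori sample-size planning
(effective $n' = n \cdot 3/\pi$ for a normal parent in a noncentral-*t*
power computation).

## Worked example

```bash
python examples/03_change_erp_and_pps.py
python examples/04_itpc_dynamics.py
```

prints (100 simulated trials, seed 42, generator truth: PPS 35 %, steady
ITPC target 0.35):

```
--- Fz ---
pulse at 1100 ms: N100 -2.94 uV @ 105 ms, P200 +2.28 uV @ 183 ms, peak-to-peak 5.22 uV
pulse at 1700 ms: N100 -1.95 uV @ 106 ms, P200 +1.73 uV @ 186 ms, peak-to-peak 3.68 uV
paired-pulse suppression: 29.6 % (generator truth 35 %)

40-42 Hz pre-stimulus baseline : 0.087
40-42 Hz steady state (350-850): 0.324 (population target R(kappa) = 0.350)
40-42 Hz pulse 1 min: pre 0.352 -> 0.130 at 1250 ms (delta -0.222)
40-42 Hz pulse 2 min: pre 0.342 -> 0.108 at 1775 ms (delta -0.234)
48-50 Hz pulse 1 max: pre 0.313 -> 0.460 at 1200 ms (delta +0.147)
48-50 Hz pulse 2 max: pre 0.312 -> 0.440 at 1900 ms (delta +0.128)
```

Reading this: the evoked peaks land at their configured latencies (100 and
180 ms post pulse; amplitudes are 0.75× the templates because linked-mastoid
referencing subtracts the mastoids' attenuated copy), and the measured
suppression scatters around the configured 35 % with the expected
trial-noise spread.  The 40 Hz band shows the steady-state coherence near
its calibrated target, a transient desynchronisation after each pulse
(negative delta), and the flanking 48–50 Hz band a transient coherence
increase (positive delta) — the signed pattern the paradigm is designed to
expose.  The single-run steady-state estimate carries a sampling SD of
about 0.06 (one effective phase draw per trial), so replicate means are
used when calibrating against the target.

The other examples cover the stimulus clock (`01`), preprocessing and
artifact bookkeeping (`02`) and cohort-level statistics plus sample-size
planning (`05`).  The same pipeline is scriptable from a shell:

```bash
pulsegate all --out out/ --seed 7 --subjects 20 --trials 100
```

writes evoked waveforms, ITPC maps, band time courses, ERP/PPS tables and
the Wilcoxon summary tables under `out/`, each with a provenance header
(package version, config hash, seed); identical config + seed reproduces
byte-identical tables.

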