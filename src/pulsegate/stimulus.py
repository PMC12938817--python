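"""Auditory paradigm timing and waveform synthesis.

The paradigm is a 2 s train of short amplitude-modulated pure-tone bursts
presented at the inverse of the tone duration (25 ms tones -> 40 Hz driving
rate).  Twice during the train the sound pressure of a run of consecutive
tones is abruptly raised by a fixed number of dB; these "pulses" are the
change events whose evoked and oscillatory responses the analysis measures.

The :class:`EventSchedule` derived from a :class:`StimulusSpec` is the single
clock shared by the trial simulator and every analysis stage; the audio
waveform itself is only needed for documentation and listening checks.
"""

from __future__ import annotations

import csv
import wave
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "StimulusSpec",
    "EventSchedule",
    "default_spec",
    "build_event_schedule",
    "synthesize_waveform",
    "write_wav",
    "write_schedule_tsv",
]


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of the paired-pulse tone-train stimulus.

    Attributes
    ----------
    carrier_hz:
        Pure-tone carrier frequency in Hz.
    tone_duration_ms:
        Duration of one tone burst; its inverse sets the driving rate
        (25 ms -> 40 Hz).
    rise_fall_ms:
        Linear onset/offset ramp of each tone burst.
    sound_duration_ms:
        Total duration of the tone train.
    baseline_level_db:
        Nominal sound pressure level of baseline tones (dB SPL).
    increment_db:
        Pressure-level increase of the elevated tones, in dB.  Interpreted
        as pressure-amplitude dB, i.e. an amplitude factor of
        ``10**(increment_db / 20)``.
    pulse_onsets_ms:
        Onsets of the pressure increments, in ms after sound onset.  Each
        must sit on the tone grid.
    tones_per_pulse:
        Number of consecutive tones elevated at each pulse.
    inter_stimulus_interval_ms:
        Silence between successive stimulus presentations.
    """

    carrier_hz: float = 800.0
    tone_duration_ms: float = 25.0
    rise_fall_ms: float = 5.0
    sound_duration_ms: float = 2000.0
    baseline_level_db: float = 65.0
    increment_db: float = 15.0
    pulse_onsets_ms: tuple[float, ...] = (1100.0, 1700.0)
    tones_per_pulse: int = 2
    inter_stimulus_interval_ms: float = 500.0

    def __post_init__(self) -> None:
        n_tones = self.sound_duration_ms / self.tone_duration_ms
        if abs(n_tones - round(n_tones)) > 1e-9:
            raise ValueError(
                "tone_duration_ms must divide sound_duration_ms exactly "
                f"({self.tone_duration_ms} vs {self.sound_duration_ms})"
            )
        if 2 * self.rise_fall_ms > self.tone_duration_ms:
            raise ValueError("rise/fall ramps longer than the tone itself")
        for onset in self.pulse_onsets_ms:
            k = onset / self.tone_duration_ms
            if abs(k - round(k)) > 1e-9:
                raise ValueError(
                    f"pulse onset {onset} ms is not on the "
                    f"{self.tone_duration_ms} ms tone grid"
                )
            if not (0 <= onset < self.sound_duration_ms):
                raise ValueError(f"pulse onset {onset} ms outside the sound")

    @property
    def n_tones(self) -> int:
        return int(round(self.sound_duration_ms / self.tone_duration_ms))

    @property
    def driving_rate_hz(self) -> float:
        """Tone repetition rate in Hz (the steady-state driving frequency)."""
        return 1000.0 / self.tone_duration_ms

    @property
    def increment_amplitude_ratio(self) -> float:
        """Pressure-amplitude ratio of elevated to baseline tones."""
        return 10.0 ** (self.increment_db / 20.0)


@dataclass(frozen=True)
class EventSchedule:
    """Discrete event timing shared by simulation and analysis."""

    tone_onsets_ms: tuple[float, ...]
    elevated_tone_indices: frozenset[int]
    pulse_onsets_ms: tuple[float, ...]
    epoch_window_ms: tuple[float, float]
    tone_duration_ms: float

    @property
    def sound_duration_ms(self) -> float:
        return self.tone_onsets_ms[-1] + self.tone_duration_ms


def default_spec() -> StimulusSpec:
    """The reference paradigm: 800 Hz carrier, 25 ms tones with 5 ms ramps,
    2 s train at 65 dB, +15 dB increments of two consecutive tones at 1100
    and 1700 ms, 500 ms inter-stimulus interval."""
    return StimulusSpec()


def build_event_schedule(
    spec: StimulusSpec,
    epoch_window_ms: tuple[float, float] = (-200.0, 2300.0),
) -> EventSchedule:
    """Expand a stimulus spec into explicit tone/pulse event times.

    Tone index ``k`` has onset ``k * tone_duration_ms``; each pulse elevates
    ``tones_per_pulse`` consecutive tones beginning at the pulse onset.
    """
    lo, hi = epoch_window_ms
    if not (lo <= 0 and hi >= spec.sound_duration_ms):
        raise ValueError("epoch window must contain the whole stimulus")
    onsets = tuple(
        k * spec.tone_duration_ms for k in range(spec.n_tones)
    )
    elevated: set[int] = set()
    for pulse in spec.pulse_onsets_ms:
        first = int(round(pulse / spec.tone_duration_ms))
        for j in range(spec.tones_per_pulse):
            idx = first + j
            if idx >= spec.n_tones:
                raise ValueError("elevated tones extend past sound offset")
            elevated.add(idx)
    return EventSchedule(
        tone_onsets_ms=onsets,
        elevated_tone_indices=frozenset(elevated),
        pulse_onsets_ms=tuple(spec.pulse_onsets_ms),
        epoch_window_ms=(float(lo), float(hi)),
        tone_duration_ms=spec.tone_duration_ms,
    )


def synthesize_waveform(spec: StimulusSpec, sample_rate: float) -> np.ndarray:
    """Render the stimulus audio as a float array, peak baseline amplitude 1.

    Each tone is a carrier sinusoid under a trapezoidal envelope with linear
    rise/fall ramps; elevated tones are scaled by ``10**(increment_db/20)``.
    """
    if sample_rate < 2 * spec.carrier_hz:
        raise ValueError(
            f"sample_rate {sample_rate} Hz below Nyquist for "
            f"{spec.carrier_hz} Hz carrier"
        )
    schedule = build_event_schedule(spec)
    # tone boundaries from cumulative time, so non-integer samples-per-tone
    # never drop samples from the total
    bounds = np.round(
        np.arange(spec.n_tones + 1) * spec.tone_duration_ms / 1000.0 * sample_rate
    ).astype(int)
    out = np.empty(bounds[-1])
    ratio = spec.increment_amplitude_ratio
    for k, onset_ms in enumerate(schedule.tone_onsets_ms):
        n_tone = bounds[k + 1] - bounds[k]
        n_ramp = int(round(spec.rise_fall_ms / 1000.0 * sample_rate))
        t = np.arange(n_tone) / sample_rate
        env = np.ones(n_tone)
        if n_ramp > 0:
            # envelope hits exactly 0 at each tone's first and last sample
            env[:n_ramp] = np.linspace(0.0, 1.0, n_ramp)
            env[n_tone - n_ramp :] = np.linspace(1.0, 0.0, n_ramp)
        phase = 2 * np.pi * spec.carrier_hz * (t + onset_ms / 1000.0)
        amp = ratio if k in schedule.elevated_tone_indices else 1.0
        out[bounds[k] : bounds[k + 1]] = amp * env * np.sin(phase)
    return out


def write_wav(path: str | Path, spec: StimulusSpec, sample_rate: int = 44100) -> None:
    """Export the stimulus as a 16-bit mono WAV file (listening check only)."""
    x = synthesize_waveform(spec, sample_rate)
    x = x / (np.abs(x).max() or 1.0)
    pcm = np.round(x * 32767).astype("<i2")
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(2)
        w.setframerate(sample_rate)
        w.writeframes(pcm.tobytes())


def write_schedule_tsv(path: str | Path, schedule: EventSchedule) -> None:
    """Write the event schedule as a TSV of (onset_ms, kind)."""
    rows = [(f"{t:g}", "tone") for t in schedule.tone_onsets_ms]
    rows += [(f"{t:g}", "pulse") for t in schedule.pulse_onsets_ms]
    rows.sort(key=lambda r: (float(r[0]), r[1]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["onset_ms", "kind"])
        w.writerows(rows)
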