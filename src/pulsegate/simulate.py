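"""Trial-level synthetic EEG for the paired-pulse 40 Hz paradigm.

Every downstream stage (re-referencing, artifact rejection, evoked-potential
peak measurement, wavelet ITPC) is tested against data from this module,
because every generative parameter is known exactly:

* a steady-state oscillation at the driving frequency whose per-trial phase
  is von Mises distributed — the concentration ``kappa`` maps analytically
  to the population inter-trial phase coherence via the Bessel ratio
  ``R(kappa) = I1(kappa)/I0(kappa)``, so ITPC recovery can be checked
  against a closed form;
* a transient phase perturbation after each pressure pulse (the mechanism
  behind the observed transient ITPC dip at the driving frequency);
* change-related N100/P200 deflections after each pulse, the second pair
  scaled down by a configurable paired-pulse suppression percentage;
* phase-locked oscillatory bursts at frequencies flanking the driving
  frequency, which raise ITPC off 40 Hz after each pulse;
* 1/f background noise and optional supra-threshold blink artifacts.

Mastoid channels carry an attenuated copy of the scalp signal so that
linked-mastoid re-referencing is exercised rather than a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import special

from .stimulus import EventSchedule, StimulusSpec, build_event_schedule, default_spec

__all__ = [
    "ErpTemplate",
    "DesyncSpec",
    "FlankerSpec",
    "NoiseSpec",
    "ArtifactSpec",
    "SimulationConfig",
    "TrialSet",
    "expected_itpc_from_kappa",
    "kappa_from_target_itpc",
    "simulate_trialset",
    "inject_artifacts",
]

DEFAULT_CHANNELS = ("Fz", "Cz", "P9", "P10", "EOG1", "EOG2")

# relative strength of the cortical signal on each default channel; mastoids
# get a weak copy so linked-mastoid referencing subtracts something real
DEFAULT_CHANNEL_GAINS = {
    "Fz": 1.0,
    "Cz": 0.9,
    "P9": 0.25,
    "P10": 0.25,
    "EOG1": 0.1,
    "EOG2": 0.1,
}


@dataclass(frozen=True)
class ErpTemplate:
    """A Gaussian-windowed evoked deflection, timed relative to pulse onset."""

    latency_ms: float
    amp_uv: float  # signed: negative for N100-like, positive for P200-like
    width_ms: float  # Gaussian sigma


@dataclass(frozen=True)
class DesyncSpec:
    """Transient per-trial phase perturbation at the driving frequency.

    Inside ``window_post_pulse_ms`` (relative to each pulse onset) every
    trial's steady-state phase is replaced by a fresh draw with the reduced
    concentration ``kappa``, blended in and out with ``transition_ms``
    raised-cosine edges, and restored to the trial's own steady phase
    afterwards.  This is the simplest mechanism that produces a transient
    ITPC dip that recovers to the steady-state level.
    """

    window_post_pulse_ms: tuple[float, float] = (0.0, 200.0)
    kappa: float = 0.2007  # population R ~ 0.10, cf. the observed minima
    transition_ms: float = 10.0


@dataclass(frozen=True)
class FlankerSpec:
    """Phase-locked bursts at frequencies flanking the driving frequency.

    Identical across trials, so they raise ITPC toward 1 at their own
    frequencies without a second circular-statistics machinery.
    """

    freqs_hz: tuple[float, ...] = (32.0, 50.0)
    amp_uv: float = 0.35
    latency_ms: float = 130.0  # burst centre relative to pulse onset
    width_ms: float = 60.0  # Gaussian sigma of the burst envelope


@dataclass(frozen=True)
class NoiseSpec:
    """1/f background noise, independent across trials and channels."""

    exponent: float = 1.0
    rms_uv: float = 1.0


@dataclass(frozen=True)
class ArtifactSpec:
    """Occasional blink-like transients exceeding the rejection threshold."""

    probability: float = 0.05
    peak_uv: float = 150.0
    width_ms: float = 120.0  # Gaussian sigma of the blink bump


def _default_kappa() -> float:
    return kappa_from_target_itpc(0.35)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one simulated recording block."""

    n_trials: int = 100
    sample_rate: float = 1000.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    epoch_window_ms: tuple[float, float] = (-200.0, 2300.0)
    stimulus: StimulusSpec = field(default_factory=default_spec)
    assr_amp_uv: float = 1.0
    kappa_steady: float = field(default_factory=_default_kappa)
    onset_ramp_ms: float = 250.0
    erp_n100: ErpTemplate = ErpTemplate(100.0, -4.0, 20.0)
    erp_p200: ErpTemplate = ErpTemplate(180.0, 3.0, 25.0)
    pps_percent: float = 35.0
    desync: DesyncSpec = DesyncSpec()
    flanker: FlankerSpec = FlankerSpec()
    noise: NoiseSpec = NoiseSpec()
    artifact: ArtifactSpec = ArtifactSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.kappa_steady < 0:
            raise ValueError("kappa_steady must be >= 0")
        if not (0.0 <= self.pps_percent <= 100.0):
            raise ValueError("pps_percent must be in [0, 100]")
        lo, hi = self.epoch_window_ms
        if not (lo <= 0 and hi >= self.stimulus.sound_duration_ms):
            raise ValueError("epoch window must contain the full stimulus")
        for pulse in self.stimulus.pulse_onsets_ms:
            for t in (
                pulse + self.desync.window_post_pulse_ms[0],
                pulse + self.desync.window_post_pulse_ms[1],
                pulse + self.erp_p200.latency_ms,
                pulse + self.flanker.latency_ms,
            ):
                if not (lo <= t <= hi):
                    raise ValueError(
                        f"configured event at {t} ms falls outside the epoch"
                    )

    @property
    def assr_freq_hz(self) -> float:
        return self.stimulus.driving_rate_hz

    def times_ms(self) -> np.ndarray:
        lo, hi = self.epoch_window_ms
        dt = 1000.0 / self.sample_rate
        n = int(round((hi - lo) / dt))
        return lo + dt * np.arange(n)


@dataclass
class TrialSet:
    """Epoched multichannel voltage data with its event schedule.

    ``data`` is trials x channels x samples in microvolts; ``times_ms`` is
    relative to sound onset.  ``truth`` holds the generating configuration
    for simulated data and is ``None`` for imported recordings.
    """

    data: np.ndarray
    times_ms: np.ndarray
    channel_names: tuple[str, ...]
    schedule: EventSchedule
    truth: SimulationConfig | None = None
    artifact_truth: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n, c, s = self.data.shape
        if c != len(self.channel_names):
            raise ValueError("channel_names does not match data")
        if s != len(self.times_ms):
            raise ValueError("times_ms does not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def sample_rate(self) -> float:
        return 1000.0 / (self.times_ms[1] - self.times_ms[0])

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def channel(self, name: str) -> np.ndarray:
        """Trials x samples view of one channel."""
        return self.data[:, self.channel_index(name), :]

    def copy(self) -> "TrialSet":
        return TrialSet(
            self.data.copy(),
            self.times_ms.copy(),
            tuple(self.channel_names),
            self.schedule,
            self.truth,
            self.artifact_truth,
        )


def expected_itpc_from_kappa(kappa: float) -> float:
    """Population mean resultant length of a von Mises distribution.

    ``R(kappa) = I1(kappa) / I0(kappa)``; this is the ITPC an infinite
    number of trials with concentration ``kappa`` would produce.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    # exponentially scaled Bessel functions stay finite for large kappa
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_from_target_itpc(r: float, tol: float = 1e-9) -> float:
    """Invert the Bessel ratio: concentration giving population ITPC ``r``."""
    if not (0.0 <= r < 1.0):
        raise ValueError("target resultant length must be in [0, 1)")
    if r == 0.0:
        return 0.0
    hi = 1.0
    while expected_itpc_from_kappa(hi) < r:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - r extremely close to 1
            return hi
    lo = 0.0
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if expected_itpc_from_kappa(mid) < r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _wrap_phase(x: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * x))


def _raised_cosine_window(
    t: np.ndarray, start: float, stop: float, transition: float
) -> np.ndarray:
    """0 outside [start, stop], 1 in the interior, cosine edges."""
    w = np.zeros_like(t)
    core = (t >= start + transition) & (t <= stop - transition)
    w[core] = 1.0
    rise = (t >= start) & (t < start + transition)
    w[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - start) / transition))
    fall = (t > stop - transition) & (t <= stop)
    w[fall] = 0.5 * (1 - np.cos(np.pi * (stop - t[fall]) / transition))
    return w


def _pink_noise(
    rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
    exponent: float, rms: float, sample_rate: float,
) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power ~ 1/f**exponent."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    current = np.sqrt(np.mean(shaped**2, axis=-1, keepdims=True))
    current[current == 0] = 1.0
    return shaped * (rms / current)


def _amplitude_envelope(cfg: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Steady-state amplitude: linear onset ramp, plateau, short offset fall."""
    env = np.zeros_like(t)
    ramp = (t >= 0) & (t < cfg.onset_ramp_ms)
    env[ramp] = t[ramp] / cfg.onset_ramp_ms
    dur = cfg.stimulus.sound_duration_ms
    env[(t >= cfg.onset_ramp_ms) & (t < dur)] = 1.0
    fall_ms = cfg.stimulus.tone_duration_ms
    fall = (t >= dur) & (t < dur + fall_ms)
    env[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - dur) / fall_ms))
    return cfg.assr_amp_uv * env


def _evoked_template(cfg: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Deterministic per-trial evoked signal: ERPs plus flanker bursts."""
    out = np.zeros_like(t)
    suppression = 1.0 - cfg.pps_percent / 100.0
    for p, pulse in enumerate(cfg.stimulus.pulse_onsets_ms):
        scale = 1.0 if p == 0 else suppression
        for tpl in (cfg.erp_n100, cfg.erp_p200):
            out += (
                scale
                * tpl.amp_uv
                * np.exp(-0.5 * ((t - pulse - tpl.latency_ms) / tpl.width_ms) ** 2)
            )
        fl = cfg.flanker
        envelope = fl.amp_uv * np.exp(
            -0.5 * ((t - pulse - fl.latency_ms) / fl.width_ms) ** 2
        )
        for f in fl.freqs_hz:
            out += envelope * np.cos(2 * np.pi * f * (t - pulse) / 1000.0)
    return out


def simulate_trialset(config: SimulationConfig) -> TrialSet:
    """Generate a :class:`TrialSet` realising the configured ground truth.

    Deterministic under a fixed ``config.seed``; the seed is split into
    named substreams (steady phases, desync redraws, noise) so altering one
    component leaves the others' draws unchanged.
    """
    cfg = config
    t = cfg.times_ms()
    n_samples = t.size
    n_ch = len(cfg.channel_names)
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(0,))
    rng_phase, rng_desync, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    theta = rng_phase.vonmises(0.0, cfg.kappa_steady, size=cfg.n_trials) \
        if cfg.kappa_steady > 0 else rng_phase.uniform(-np.pi, np.pi, cfg.n_trials)

    # per-pulse phase perturbation: redraw with reduced concentration
    omega = 2 * np.pi * cfg.assr_freq_hz / 1000.0
    phase_t = np.broadcast_to(theta[:, None], (cfg.n_trials, n_samples)).copy()
    for pulse in cfg.stimulus.pulse_onsets_ms:
        w0, w1 = cfg.desync.window_post_pulse_ms
        win = _raised_cosine_window(
            t, pulse + w0, pulse + w1, cfg.desync.transition_ms
        )
        k = cfg.desync.kappa
        redraw = (
            rng_desync.vonmises(0.0, k, size=cfg.n_trials)
            if k > 0 else rng_desync.uniform(-np.pi, np.pi, cfg.n_trials)
        )
        delta = _wrap_phase(redraw - theta)
        phase_t += delta[:, None] * win[None, :]

    amp = _amplitude_envelope(cfg, t)
    assr = amp[None, :] * np.cos(omega * t[None, :] + phase_t)
    evoked = _evoked_template(cfg, t)
    signal = assr + evoked[None, :]  # trials x samples

    gains = np.array(
        [DEFAULT_CHANNEL_GAINS.get(ch, 1.0) for ch in cfg.channel_names]
    )
    data = signal[:, None, :] * gains[None, :, None]
    if cfg.noise.rms_uv > 0:
        data = data + _pink_noise(
            rng_noise,
            (cfg.n_trials, n_ch),
            n_samples,
            cfg.noise.exponent,
            cfg.noise.rms_uv,
            cfg.sample_rate,
        )

    schedule = build_event_schedule(cfg.stimulus, cfg.epoch_window_ms)
    return TrialSet(
        data=data,
        times_ms=t,
        channel_names=tuple(cfg.channel_names),
        schedule=schedule,
        truth=cfg,
    )


def inject_artifacts(
    trials: TrialSet, config: SimulationConfig
) -> tuple[TrialSet, tuple[int, ...]]:
    """Contaminate a random subset of trials with blink-like transients.

    Blinks are positive Gaussian bumps with peak ``artifact.peak_uv`` placed
    on frontal/ocular channels at a random latency.  Returns the new trial
    set and the ground-truth indices of contaminated trials, which the
    rejection stage should recover exactly when the peak exceeds the
    rejection threshold and the clean data stays below it.
    """
    art = config.artifact
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1,))
    )
    hit = rng.random(trials.n_trials) < art.probability
    out = trials.copy()
    t = out.times_ms
    frontal_weight = {"Fz": 1.0, "Cz": 0.5, "EOG1": 1.2, "EOG2": 1.2}
    lo, hi = t[0], t[-1]
    for i in np.flatnonzero(hit):
        centre = rng.uniform(lo + 2 * art.width_ms, hi - 2 * art.width_ms)
        bump = np.exp(-0.5 * ((t - centre) / art.width_ms) ** 2)
        for name, w in frontal_weight.items():
            if name in out.channel_names:
                out.data[i, out.channel_index(name), :] += art.peak_uv * w * bump
    idx = tuple(int(i) for i in np.flatnonzero(hit))
    out.artifact_truth = idx
    return out, idx
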