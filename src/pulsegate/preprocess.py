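"""Referencing, artifact rejection, filtering, baseline correction, averaging.

The standard pipeline mirrors the recording conventions of front-central
auditory ERP work: exploring electrodes referenced to linked mastoids,
rejection of any epoch exceeding a +/-100 uV ceiling on any channel,
zero-phase Butterworth band-pass filtering (0.16-100 Hz offline band for
oscillatory analysis, 0.16-35 Hz for evoked potentials), DC-offset removal
using the -200..-100 ms pre-stimulus window, and arithmetic trial averaging
with a minimum-trial bookkeeping flag.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .simulate import TrialSet

__all__ = [
    "PreprocessConfig",
    "EvokedWaveform",
    "TooFewTrialsWarning",
    "rereference_linked_mastoids",
    "reject_artifacts",
    "bandpass",
    "baseline_correct",
    "average_evoked",
    "run_standard_pipeline",
    "write_rejection_log",
]


class TooFewTrialsWarning(UserWarning):
    """Fewer artifact-free trials survived than the configured minimum."""


@dataclass(frozen=True)
class PreprocessConfig:
    reference: tuple[str, str] = ("P9", "P10")
    rejection_threshold_uv: float = 100.0
    min_trials: int = 100
    offline_band_hz: tuple[float, float] = (0.16, 100.0)
    erp_band_hz: tuple[float, float] = (0.16, 35.0)
    dc_offset_window_ms: tuple[float, float] = (-200.0, -100.0)

    def __post_init__(self) -> None:
        if self.rejection_threshold_uv <= 0:
            raise ValueError("rejection threshold must be positive")
        for band in (self.offline_band_hz, self.erp_band_hz):
            if not (0 < band[0] < band[1]):
                raise ValueError(f"invalid band edges {band}")
        if not self.dc_offset_window_ms[0] < self.dc_offset_window_ms[1]:
            raise ValueError("empty DC offset window")


@dataclass
class EvokedWaveform:
    """Across-trial average, channels x samples (uV)."""

    data: np.ndarray
    times_ms: np.ndarray
    channel_names: tuple[str, ...]
    n_trials_averaged: int

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None


def rereference_linked_mastoids(
    trials: TrialSet, config: PreprocessConfig | None = None
) -> TrialSet:
    """Subtract the mean of the two mastoid channels from every channel."""
    config = config or PreprocessConfig()
    for ch in config.reference:
        if ch not in trials.channel_names:
            raise ValueError(f"mastoid channel {ch!r} missing")
    i, j = (trials.channel_index(ch) for ch in config.reference)
    ref = 0.5 * (trials.data[:, i, :] + trials.data[:, j, :])
    out = trials.copy()
    out.data -= ref[:, None, :]
    return out


def reject_artifacts(
    trials: TrialSet, config: PreprocessConfig | None = None
) -> tuple[TrialSet, list[int]]:
    """Drop every trial whose absolute voltage exceeds the threshold anywhere.

    A trial survives iff ``max |v|`` over all channels and samples is at or
    below ``rejection_threshold_uv``.  Surviving trials keep their order and
    their samples are untouched.  If fewer than ``min_trials`` survive a
    :class:`TooFewTrialsWarning` is issued; the caller decides what to do.
    """
    config = config or PreprocessConfig()
    peak = np.abs(trials.data).max(axis=(1, 2))
    bad = peak > config.rejection_threshold_uv
    rejected = [int(i) for i in np.flatnonzero(bad)]
    out = trials.copy()
    out.data = trials.data[~bad]
    out.artifact_truth = None
    if out.n_trials < config.min_trials:
        warnings.warn(
            f"only {out.n_trials} artifact-free trials "
            f"(minimum {config.min_trials})",
            TooFewTrialsWarning,
            stacklevel=2,
        )
    return out, rejected


def _filter_array(
    x: np.ndarray, band_hz: tuple[float, float], sample_rate: float
) -> np.ndarray:
    lo, hi = band_hz
    nyq = sample_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band_hz} invalid for fs={sample_rate}")
    # high-pass and low-pass cascaded: better conditioned than one bandpass
    # SOS when the corners differ by three orders of magnitude
    sos_hp = sps.butter(4, lo, "highpass", fs=sample_rate, output="sos")
    sos_lp = sps.butter(4, hi, "lowpass", fs=sample_rate, output="sos")
    padlen = min(x.shape[-1] - 1, int(3 * sample_rate))
    y = sps.sosfiltfilt(sos_hp, x, axis=-1, padlen=padlen)
    return sps.sosfiltfilt(sos_lp, y, axis=-1, padlen=padlen)


def bandpass(
    x: TrialSet | EvokedWaveform, band_hz: tuple[float, float]
) -> TrialSet | EvokedWaveform:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward).

    Zero phase keeps evoked-peak latencies undistorted, which the latency
    search windows presuppose.
    """
    if isinstance(x, TrialSet):
        out = x.copy()
        out.data = _filter_array(out.data, band_hz, x.sample_rate)
        return out
    fs = 1000.0 / (x.times_ms[1] - x.times_ms[0])
    return EvokedWaveform(
        _filter_array(x.data, band_hz, fs),
        x.times_ms.copy(),
        tuple(x.channel_names),
        x.n_trials_averaged,
    )


def baseline_correct(
    x: TrialSet | EvokedWaveform, window_ms: tuple[float, float] = (-200.0, -100.0)
) -> TrialSet | EvokedWaveform:
    """Subtract the per-trace mean over ``window_ms`` (DC-offset removal)."""
    times = x.times_ms
    mask = (times >= window_ms[0]) & (times <= window_ms[1])
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    if isinstance(x, TrialSet):
        out = x.copy()
        out.data -= out.data[..., mask].mean(axis=-1, keepdims=True)
        return out
    out_ev = EvokedWaveform(
        x.data - x.data[..., mask].mean(axis=-1, keepdims=True),
        x.times_ms.copy(),
        tuple(x.channel_names),
        x.n_trials_averaged,
    )
    return out_ev


def average_evoked(trials: TrialSet) -> EvokedWaveform:
    """Sample-wise arithmetic mean across trials."""
    if trials.n_trials < 1:
        raise ValueError("cannot average an empty trial set")
    return EvokedWaveform(
        trials.data.mean(axis=0),
        trials.times_ms.copy(),
        tuple(trials.channel_names),
        trials.n_trials,
    )


def run_standard_pipeline(
    trials: TrialSet, config: PreprocessConfig | None = None
) -> tuple[TrialSet, EvokedWaveform, list[int]]:
    """Reference -> offline band -> reject -> baseline; plus the ERP average.

    Rejection operates on the offline-band (0.16-100 Hz) data, i.e. at the
    recording/averaging stage, before the narrower ERP filtering.  Returns
    the cleaned offline-band trials (input to the wavelet stage), the
    ERP-band baseline-corrected evoked waveform, and the rejected trial
    indices.
    """
    config = config or PreprocessConfig()
    ref = bandpass(
        rereference_linked_mastoids(trials, config), config.offline_band_hz
    )
    clean, rejected = reject_artifacts(ref, config)
    offline = baseline_correct(clean, config.dc_offset_window_ms)
    evoked = baseline_correct(
        bandpass(average_evoked(clean), config.erp_band_hz),
        config.dc_offset_window_ms,
    )
    return offline, evoked, rejected


def write_rejection_log(
    path: str | Path, trials: TrialSet, config: PreprocessConfig | None = None
) -> None:
    """TSV log of rejected trials: index, worst channel, peak voltage."""
    config = config or PreprocessConfig()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["trial", "channel", "peak_uv"])
        peaks = np.abs(trials.data).max(axis=2)  # trials x channels
        for i in range(trials.n_trials):
            if peaks[i].max() > config.rejection_threshold_uv:
                ch = int(np.argmax(peaks[i]))
                w.writerow(
                    [i, trials.channel_names[ch], f"{peaks[i, ch]:.2f}"]
                )
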