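"""Morlet-wavelet time-frequency decomposition and inter-trial phase coherence.

The decomposition follows the conventional five-cycle complex Morlet
analysis on a 4-100 Hz grid in 2 Hz steps, sampled every 25 ms on a grid
anchored at sound onset (t = 0), so that the pre-stimulus baseline windows
land exactly on grid points.  ITPC at a time-frequency point is the
magnitude of the across-trial mean of the unit-modulus coefficients: 0 for
uniformly random phases, 1 for perfect phase alignment.

Windowed summaries implement the steady-state / pre-pulse / post-pulse
contrast logic: the steady-state mean over 350-850 ms, the pre-stimulus
baseline over -200..-100 ms, and per-pulse contrasts of the windowed
extremum (1100-1350 ms and 1700-1950 ms) against the pre-pulse mean
(850-1000 ms and 1450-1600 ms).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from .simulate import TrialSet

__all__ = [
    "DEFAULT_FREQS_HZ",
    "TIME_STEP_MS",
    "PRE_PULSE_WINDOWS_MS",
    "SEARCH_WINDOWS_MS",
    "STEADY_STATE_WINDOW_MS",
    "PRESTIMULUS_WINDOW_MS",
    "WaveletCoefficients",
    "TFMap",
    "ItpcTimecourse",
    "WindowContrast",
    "morlet_kernel",
    "wavelet_transform",
    "itpc",
    "compute_itpc",
    "band_timecourse",
    "steady_state_summary",
    "prestimulus_baseline",
    "pulse_contrast",
    "write_tfmap_tsv",
]

DEFAULT_FREQS_HZ = tuple(range(4, 101, 2))
TIME_STEP_MS = 25.0
N_CYCLES = 5.0
KERNEL_SUPPORT_SIGMAS = 5.0

# a grid point closer than this many sigma_t to an epoch edge loses >= 1%
# of its kernel's energy to the (zero-padded) outside and is flagged
EDGE_SIGMA_THRESHOLD = 1.65

STEADY_STATE_WINDOW_MS = (350.0, 850.0)
PRESTIMULUS_WINDOW_MS = (-200.0, -100.0)
# indexed by pulse number 1 / 2
PRE_PULSE_WINDOWS_MS = {1: (850.0, 1000.0), 2: (1450.0, 1600.0)}
SEARCH_WINDOWS_MS = {1: (1100.0, 1350.0), 2: (1700.0, 1950.0)}


def morlet_kernel(
    freq_hz: float,
    n_cycles: float = N_CYCLES,
    sample_rate: float = 1000.0,
) -> np.ndarray:
    """Complex Morlet kernel: carrier under a Gaussian envelope.

    The envelope width is ``sigma_t = n_cycles / (2 pi f)`` (19.9 ms for
    five cycles at 40 Hz); support is truncated at +/-5 sigma_t and the
    kernel is L2-normalised so coefficient magnitudes are comparable across
    frequencies.
    """
    if freq_hz <= 0 or n_cycles <= 0:
        raise ValueError("frequency and cycle count must be positive")
    sigma_t = n_cycles / (2 * np.pi * freq_hz)
    half = int(np.ceil(KERNEL_SUPPORT_SIGMAS * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    kernel = np.exp(2j * np.pi * freq_hz * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return kernel / np.linalg.norm(kernel)


@dataclass
class WaveletCoefficients:
    """Per-trial complex coefficients on the (frequency, time) grid."""

    coeffs: np.ndarray  # trials x freqs x grid times, complex
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    edge_flags: np.ndarray  # freqs x times bool: kernel support left the epoch
    channel: str


@dataclass
class TFMap:
    """ITPC on the time-frequency grid, values in [0, 1]."""

    freqs_hz: np.ndarray
    times_ms: np.ndarray
    itpc: np.ndarray  # freqs x times
    n_trials: int
    edge_flags: np.ndarray
    undefined: np.ndarray  # points where every trial's coefficient was zero
    coeffs: WaveletCoefficients | None = None

    def row(self, freq_hz: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.freqs_hz, freq_hz))
        if idx.size == 0:
            raise ValueError(f"{freq_hz} Hz not on the frequency grid")
        return self.itpc[idx[0]]


@dataclass
class ItpcTimecourse:
    """Band-averaged ITPC time series on the 25 ms grid."""

    times_ms: np.ndarray
    values: np.ndarray
    band_hz: tuple[float, float]
    excluded: np.ndarray  # grid points unusable for window statistics

    def window_mean(self, window_ms: tuple[float, float]) -> float:
        mask = self._window_mask(window_ms)
        return float(self.values[mask].mean())

    def _window_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        lo, hi = window_ms
        mask = (self.times_ms >= lo - 1e-9) & (self.times_ms <= hi + 1e-9)
        mask &= ~self.excluded
        if not mask.any():
            raise ValueError(f"window {window_ms} has no usable grid points")
        return mask


@dataclass
class WindowContrast:
    """Extremum-vs-pre-pulse ITPC contrast for one band, electrode, pulse."""

    band_hz: tuple[float, float]
    electrode: str
    pulse_index: int
    pre_window_ms: tuple[float, float]
    search_window_ms: tuple[float, float]
    pre_mean_itpc: float
    extremum_itpc: float
    extremum_kind: Literal["min", "max"]
    extremum_time_ms: float
    delta_itpc: float


def _time_grid(
    times_ms: np.ndarray, step_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Grid times (multiples of step, anchored at 0) and sample indices."""
    t0, t1 = times_ms[0], times_ms[-1]
    first = int(np.ceil(t0 / step_ms - 1e-9))
    last = int(np.floor(t1 / step_ms + 1e-9))
    grid = step_ms * np.arange(first, last + 1)
    dt = times_ms[1] - times_ms[0]
    idx = np.round((grid - t0) / dt).astype(int)
    return grid, idx


def wavelet_transform(
    trials: TrialSet,
    channel: str,
    freqs_hz: Sequence[float] = DEFAULT_FREQS_HZ,
    time_step_ms: float = TIME_STEP_MS,
) -> WaveletCoefficients:
    """Convolve every trial with every Morlet kernel; sample on the grid.

    Epoch edges are zero-padded implicitly by the convolution; grid points
    close enough to an epoch edge that a non-negligible share (>= 1%) of
    the kernel's energy falls outside the recording are flagged as
    edge-contaminated so window statistics can exclude them.
    """
    x = trials.channel(channel)  # trials x samples
    fs = trials.sample_rate
    grid, idx = _time_grid(trials.times_ms, time_step_ms)
    freqs = np.asarray(freqs_hz, dtype=float)
    out = np.empty((trials.n_trials, freqs.size, grid.size), dtype=complex)
    flags = np.zeros((freqs.size, grid.size), dtype=bool)
    t0, t1 = trials.times_ms[0], trials.times_ms[-1]
    for fi, f in enumerate(freqs):
        kernel = morlet_kernel(f, sample_rate=fs)
        conv = sps.fftconvolve(x, kernel[None, :], mode="same", axes=1)
        out[:, fi, :] = conv[:, idx]
        sigma_ms = N_CYCLES / (2 * np.pi * f) * 1000.0
        guard = EDGE_SIGMA_THRESHOLD * sigma_ms
        flags[fi] = (grid - guard < t0 - 1e-9) | (grid + guard > t1 + 1e-9)
    return WaveletCoefficients(out, freqs, grid, flags, channel)


def itpc(coefficients: WaveletCoefficients) -> TFMap:
    """Phase-only across-trial coherence of the complex coefficients.

    At each grid point, trials with an exactly zero coefficient carry no
    phase and are excluded from that point's mean; points where *every*
    trial is zero are undefined (NaN) and flagged.
    """
    c = coefficients.coeffs
    if c.shape[0] < 2:
        raise ValueError("ITPC needs at least 2 trials")
    mag = np.abs(c)
    nonzero = mag > 0
    unit = np.zeros_like(c)
    np.divide(c, mag, out=unit, where=nonzero)
    counts = nonzero.sum(axis=0)
    sums = np.abs(unit.sum(axis=0))
    undefined = counts == 0
    values = np.full(sums.shape, np.nan)
    np.divide(sums, counts, out=values, where=~undefined)
    return TFMap(
        freqs_hz=coefficients.freqs_hz,
        times_ms=coefficients.times_ms,
        itpc=values,
        n_trials=c.shape[0],
        edge_flags=coefficients.edge_flags,
        undefined=undefined,
        coeffs=coefficients,
    )


def compute_itpc(
    trials: TrialSet,
    channel: str,
    freqs_hz: Sequence[float] = DEFAULT_FREQS_HZ,
    keep_coeffs: bool = False,
) -> TFMap:
    """Wavelet transform plus ITPC in one call."""
    tf = itpc(wavelet_transform(trials, channel, freqs_hz))
    if not keep_coeffs:
        tf.coeffs = None
    return tf


def band_timecourse(tf: TFMap, band_hz: tuple[float, float]) -> ItpcTimecourse:
    """Band time series: mean of the ITPC rows at the band's two endpoints.

    On a 2 Hz analysis grid a 2 Hz-wide band label can only contain its two
    endpoint bins, so a band (f, f+2) averages rows f and f+2; a degenerate
    band (f, f) is simply row f.
    """
    rows = [tf.row(f) for f in band_hz]
    f_idx = [int(np.flatnonzero(np.isclose(tf.freqs_hz, f))[0]) for f in band_hz]
    excluded = np.zeros(tf.times_ms.size, dtype=bool)
    for i in f_idx:
        excluded |= tf.edge_flags[i] | tf.undefined[i]
    return ItpcTimecourse(
        times_ms=tf.times_ms.copy(),
        values=np.mean(rows, axis=0),
        band_hz=(float(band_hz[0]), float(band_hz[1])),
        excluded=excluded,
    )


def steady_state_summary(
    tc: ItpcTimecourse, window_ms: tuple[float, float] = STEADY_STATE_WINDOW_MS
) -> float:
    """Mean band ITPC over the late steady-state window (350-850 ms)."""
    return tc.window_mean(window_ms)


def prestimulus_baseline(
    tc: ItpcTimecourse, window_ms: tuple[float, float] = PRESTIMULUS_WINDOW_MS
) -> float:
    """Mean band ITPC over the pre-stimulus window (-200..-100 ms)."""
    return tc.window_mean(window_ms)


def pulse_contrast(
    tc: ItpcTimecourse,
    pulse_index: int,
    kind: Literal["min", "max"],
    electrode: str = "",
) -> WindowContrast:
    """Windowed extremum after a pulse, contrasted with the pre-pulse mean.

    Pulse 1 searches 1100-1350 ms against the 850-1000 ms pre-pulse mean;
    pulse 2 searches 1700-1950 ms against 1450-1600 ms.  ``delta_itpc`` is
    extremum minus pre-pulse mean: negative for a desynchronisation dip,
    positive for a synchronisation burst.
    """
    if pulse_index not in PRE_PULSE_WINDOWS_MS:
        raise ValueError("pulse_index must be 1 or 2")
    if kind not in ("min", "max"):
        raise ValueError("kind must be 'min' or 'max'")
    pre_w = PRE_PULSE_WINDOWS_MS[pulse_index]
    search_w = SEARCH_WINDOWS_MS[pulse_index]
    pre_mean = tc.window_mean(pre_w)
    mask = tc._window_mask(search_w)
    vals = tc.values[mask]
    times = tc.times_ms[mask]
    pos = int(np.argmin(vals) if kind == "min" else np.argmax(vals))
    extremum = float(vals[pos])
    return WindowContrast(
        band_hz=tc.band_hz,
        electrode=electrode,
        pulse_index=pulse_index,
        pre_window_ms=pre_w,
        search_window_ms=search_w,
        pre_mean_itpc=pre_mean,
        extremum_itpc=extremum,
        extremum_kind=kind,
        extremum_time_ms=float(times[pos]),
        delta_itpc=extremum - pre_mean,
    )


def write_tfmap_tsv(path: str | Path, tf: TFMap) -> None:
    """Long-format TSV export: freq_hz, time_ms, itpc, edge flag."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["freq_hz", "time_ms", "itpc", "edge"])
        for fi, f in enumerate(tf.freqs_hz):
            for ti, t in enumerate(tf.times_ms):
                w.writerow(
                    [f"{f:g}", f"{t:g}", f"{tf.itpc[fi, ti]:.6f}",
                     int(tf.edge_flags[fi, ti])]
                )
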