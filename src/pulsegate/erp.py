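"""Change-related N100/P200 measurement and paired-pulse suppression.

An abrupt feature change in an ongoing sound elicits a change-related
response whose N100-like negativity peaks 65-160 ms and whose P200-like
positivity peaks 150-270 ms after the change onset.  To be robust against
baseline shifts the response amplitude is taken peak-to-peak (P200 minus
N100).  Paired-pulse suppression of the second change response is
quantified as (A1 - A2) / A1 * 100.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .preprocess import EvokedWaveform

__all__ = [
    "N100_WINDOW_MS",
    "P200_WINDOW_MS",
    "ChangeResponse",
    "PpsResult",
    "find_peak",
    "measure_change_response",
    "pps_degree",
    "measure_pps",
    "write_erp_tsv",
]

# search windows relative to the change (pulse) onset
N100_WINDOW_MS = (65.0, 160.0)
P200_WINDOW_MS = (150.0, 270.0)


@dataclass(frozen=True)
class ChangeResponse:
    """One change-related response: N100 and P200 peaks plus peak-to-peak."""

    pulse_onset_ms: float
    n100_latency_ms: float
    n100_amp_uv: float
    p200_latency_ms: float
    p200_amp_uv: float

    @property
    def peak_to_peak_uv(self) -> float:
        return self.p200_amp_uv - self.n100_amp_uv


@dataclass(frozen=True)
class PpsResult:
    """Suppression of the second response relative to the first, percent."""

    first_amp_uv: float
    second_amp_uv: float

    @property
    def pps_percent(self) -> float:
        return pps_degree(self.first_amp_uv, self.second_amp_uv)


def find_peak(
    evoked: EvokedWaveform,
    channel: str,
    window_ms: tuple[float, float],
    polarity: Literal["negative", "positive"],
) -> tuple[float, float]:
    """Extremum of the stated polarity within the closed window.

    Returns (latency_ms, amplitude_uv).  Ties are broken by the earliest
    latency, so a flat trace reports the window start.
    """
    if polarity not in ("negative", "positive"):
        raise ValueError("polarity must be 'negative' or 'positive'")
    times = evoked.times_ms
    lo, hi = window_ms
    mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"window {window_ms} outside the epoch")
    trace = evoked.channel(channel)[mask]
    t_win = times[mask]
    pos = int(np.argmin(trace) if polarity == "negative" else np.argmax(trace))
    return float(t_win[pos]), float(trace[pos])


def measure_change_response(
    evoked: EvokedWaveform, channel: str, pulse_onset_ms: float
) -> ChangeResponse:
    """Measure N100 (65-160 ms) and P200 (150-270 ms) after one pulse.

    The windows overlap at 150-160 ms; the overlap is resolved purely by
    polarity (negative extremum vs positive extremum).
    """
    n100_w = (pulse_onset_ms + N100_WINDOW_MS[0], pulse_onset_ms + N100_WINDOW_MS[1])
    p200_w = (pulse_onset_ms + P200_WINDOW_MS[0], pulse_onset_ms + P200_WINDOW_MS[1])
    n_lat, n_amp = find_peak(evoked, channel, n100_w, "negative")
    p_lat, p_amp = find_peak(evoked, channel, p200_w, "positive")
    return ChangeResponse(
        pulse_onset_ms=pulse_onset_ms,
        n100_latency_ms=n_lat,
        n100_amp_uv=n_amp,
        p200_latency_ms=p_lat,
        p200_amp_uv=p_amp,
    )


def pps_degree(first_amp: float, second_amp: float) -> float:
    """(first - second) / first * 100; undefined for nonpositive first."""
    if first_amp <= 0:
        raise ValueError("suppression undefined for nonpositive first amplitude")
    return (first_amp - second_amp) / first_amp * 100.0


def measure_pps(
    evoked: EvokedWaveform,
    channel: str,
    pulse_onsets_ms: Sequence[float] = (1100.0, 1700.0),
) -> tuple[list[ChangeResponse], PpsResult]:
    """Measure both change responses on one channel and their suppression."""
    if len(pulse_onsets_ms) != 2:
        raise ValueError("paired-pulse suppression needs exactly two pulses")
    responses = [
        measure_change_response(evoked, channel, p) for p in pulse_onsets_ms
    ]
    pps = PpsResult(
        first_amp_uv=responses[0].peak_to_peak_uv,
        second_amp_uv=responses[1].peak_to_peak_uv,
    )
    return responses, pps


def write_erp_tsv(
    path: str | Path,
    rows: Sequence[tuple[str, str, list[ChangeResponse], PpsResult]],
    header_lines: Sequence[str] = (),
) -> None:
    """TSV: one row per (subject, electrode, pulse) plus a PPS row each."""
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["subject", "electrode", "pulse", "n100_latency_ms", "n100_amp_uv",
             "p200_latency_ms", "p200_amp_uv", "peak_to_peak_uv", "pps_percent"]
        )
        for subject, electrode, responses, pps in rows:
            for k, r in enumerate(responses, start=1):
                w.writerow(
                    [subject, electrode, k,
                     f"{r.n100_latency_ms:.1f}", f"{r.n100_amp_uv:.4f}",
                     f"{r.p200_latency_ms:.1f}", f"{r.p200_amp_uv:.4f}",
                     f"{r.peak_to_peak_uv:.4f}", ""]
                )
            w.writerow(
                [subject, electrode, "pps", "", "", "", "", "",
                 f"{pps.pps_percent:.2f}"]
            )
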