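"""Trial-set import/export: EDF+ and a compressed array container.

Writing uses a minimal EDF+C encoder (ASCII headers, 16-bit little-endian
samples, one data record per trial, a TAL annotation channel carrying sound
and pulse onsets).  Reading goes through :mod:`mne`, which also serves as an
independent decoder in the round-trip tests: data written here and read
back by mne must agree to EDF's 16-bit quantisation.

The npz container stores the voltage array and time axis losslessly with a
JSON sidecar holding channel names, stimulus parameters and, for simulated
data, the full generating configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np

from .simulate import (
    ArtifactSpec,
    DesyncSpec,
    ErpTemplate,
    FlankerSpec,
    NoiseSpec,
    SimulationConfig,
    TrialSet,
)
from .stimulus import StimulusSpec, build_event_schedule

__all__ = [
    "write_edf",
    "read_edf",
    "save_trialset",
    "load_trialset",
    "config_to_dict",
    "config_from_dict",
]

_ANNOTATION_BYTES = 256  # per record; roomy for onset + pulse TALs


def _ascii(value: Any, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ASCII chars")
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, trials: TrialSet) -> None:
    """Write a trial set as EDF+C, one data record per trial.

    Trials are laid out back to back, so the file is a valid continuous
    recording; a ``sound_onset`` annotation marks each trial's stimulus
    onset and ``pulse`` annotations mark the pressure increments.
    """
    data = trials.data
    n_trials, n_ch, n_samp = data.shape
    fs = trials.sample_rate
    record_dur = n_samp / fs
    phys_max = max(1.0, float(np.ceil(np.abs(data).max())))
    dig_max, dig_min = 32767, -32768

    onset_in_epoch = -trials.times_ms[0] / 1000.0  # sound onset within a record
    pulses_s = [p / 1000.0 for p in trials.schedule.pulse_onsets_ms]

    tals = []
    for i in range(n_trials):
        rec_start = i * record_dur
        tal = f"+{rec_start:.6g}\x14\x14\x00"
        onset = rec_start + onset_in_epoch
        tal += f"+{onset:.6g}\x14sound_onset\x14\x00"
        for p in pulses_s:
            tal += f"+{onset + p:.6g}\x14pulse\x14\x00"
        raw = tal.encode("ascii")
        if len(raw) > _ANNOTATION_BYTES:
            raise ValueError("annotation record overflow")
        tals.append(raw.ljust(_ANNOTATION_BYTES, b"\x00"))

    n_signals = n_ch + 1
    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate 01-JAN-2000 X X X", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (1 + n_signals), 8),
        _ascii("EDF+C", 44),
        _ascii(n_trials, 8),
        _ascii(f"{record_dur:g}", 8),
        _ascii(n_signals, 4),
    ])

    labels = list(trials.channel_names) + ["EDF Annotations"]
    samples_per_rec = [n_samp] * n_ch + [_ANNOTATION_BYTES // 2]

    def col(values: list[Any], width: int) -> bytes:
        return b"".join(_ascii(v, width) for v in values)

    header += col(labels, 16)
    header += col([""] * n_signals, 80)  # transducer
    header += col(["uV"] * n_ch + [""], 8)  # physical dimension
    header += col([f"{-phys_max:g}"] * n_ch + ["-1"], 8)
    header += col([f"{phys_max:g}"] * n_ch + ["1"], 8)
    header += col([dig_min] * n_signals, 8)
    header += col([dig_max] * n_signals, 8)
    header += col([""] * n_signals, 80)  # prefiltering
    header += col(samples_per_rec, 8)
    header += col([""] * n_signals, 32)  # reserved

    # EDF's affine: the full digital span maps onto the physical span
    slope = (dig_max - dig_min) / (2 * phys_max)
    with open(path, "wb") as fh:
        fh.write(header)
        for i in range(n_trials):
            dig = np.clip(
                np.round((data[i] + phys_max) * slope + dig_min),
                dig_min, dig_max,
            ).astype("<i2")
            fh.write(dig.tobytes())
            fh.write(np.frombuffer(tals[i], dtype="<i2").tobytes())


def read_edf(
    path: str | Path,
    stimulus: StimulusSpec | None = None,
    epoch_window_ms: tuple[float, float] = (-200.0, 2300.0),
) -> TrialSet:
    """Read an EDF recording and epoch it around ``sound_onset`` annotations.

    Epochs truncated by the file edges are dropped.  Voltages are returned
    in microvolts; the event schedule is rebuilt from ``stimulus`` (the
    default paradigm when not given).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = raw.info["sfreq"]
    sig = raw.get_data() * 1e6  # mne returns volts
    onsets = [
        ann["onset"] for ann in raw.annotations
        if ann["description"] == "sound_onset"
    ]
    lo, hi = epoch_window_ms
    n_epoch = int(round((hi - lo) / 1000.0 * fs))
    epochs = []
    for onset in onsets:
        start = int(round((onset + lo / 1000.0) * fs))
        stop = start + n_epoch
        if start < 0 or stop > sig.shape[1]:
            continue  # truncated by a file edge
        epochs.append(sig[:, start:stop])
    if not epochs:
        raise ValueError("no complete epochs found in the recording")
    spec = stimulus or StimulusSpec()
    dt = 1000.0 / fs
    times = lo + dt * np.arange(n_epoch)
    return TrialSet(
        data=np.stack(epochs),
        times_ms=times,
        channel_names=tuple(raw.ch_names),
        schedule=build_event_schedule(spec, (lo, hi)),
        truth=None,
    )


# --- npz + JSON sidecar container -------------------------------------------

_NESTED_FIELDS = {
    "stimulus": StimulusSpec,
    "erp_n100": ErpTemplate,
    "erp_p200": ErpTemplate,
    "desync": DesyncSpec,
    "flanker": FlankerSpec,
    "noise": NoiseSpec,
    "artifact": ArtifactSpec,
}


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(d: dict) -> SimulationConfig:
    kwargs = dict(d)
    for name, cls in _NESTED_FIELDS.items():
        if name in kwargs and isinstance(kwargs[name], dict):
            sub = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in kwargs[name].items()
            }
            kwargs[name] = cls(**sub)
    for key, value in kwargs.items():
        if isinstance(value, list):
            kwargs[key] = tuple(value)
    return SimulationConfig(**kwargs)


def save_trialset(path: str | Path, trials: TrialSet) -> None:
    """Save as ``<path>.npz`` (or the given .npz path) plus a JSON sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    np.savez_compressed(path, data=trials.data, times_ms=trials.times_ms)
    spec_fields = dataclasses.asdict(
        StimulusSpec(
            tone_duration_ms=trials.schedule.tone_duration_ms,
            pulse_onsets_ms=trials.schedule.pulse_onsets_ms,
            sound_duration_ms=trials.schedule.sound_duration_ms,
        )
    ) if trials.truth is None else dataclasses.asdict(trials.truth.stimulus)
    meta = {
        "channel_names": list(trials.channel_names),
        "epoch_window_ms": list(trials.schedule.epoch_window_ms),
        "stimulus": spec_fields,
        "truth": config_to_dict(trials.truth) if trials.truth else None,
        "artifact_truth": list(trials.artifact_truth)
        if trials.artifact_truth is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_trialset(path: str | Path) -> TrialSet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    arrays = np.load(path)
    spec = StimulusSpec(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in meta["stimulus"].items()
    })
    truth = config_from_dict(meta["truth"]) if meta.get("truth") else None
    art = meta.get("artifact_truth")
    return TrialSet(
        data=arrays["data"],
        times_ms=arrays["times_ms"],
        channel_names=tuple(meta["channel_names"]),
        schedule=build_event_schedule(spec, tuple(meta["epoch_window_ms"])),
        truth=truth,
        artifact_truth=tuple(art) if art is not None else None,
    )
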