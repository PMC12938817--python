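"""End-to-end orchestration: simulate -> preprocess -> ERP -> TFA -> stats.

Each stage consumes and emits files under one output directory, so stages
can be re-run independently from cached upstream outputs; every table
carries a provenance header (package version, configuration hash, seed).
:func:`run_pipeline` chains all stages and is deterministic for a fixed
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .erp import measure_pps, write_erp_tsv
from .io import config_from_dict, config_to_dict, load_trialset, save_trialset
from .preprocess import PreprocessConfig, run_standard_pipeline
from .simulate import SimulationConfig, TrialSet, inject_artifacts, simulate_trialset
from .stats import build_comparison_table
from .tfa import (
    band_timecourse,
    compute_itpc,
    prestimulus_baseline,
    pulse_contrast,
    steady_state_summary,
)

__all__ = [
    "CohortJitter",
    "RunConfig",
    "run_pipeline",
    "simulate_cohort",
    "load_run_config",
    "save_run_config",
]

log = logging.getLogger("pulsegate")

DEFAULT_BANDS = tuple((lo, lo + 2) for lo in range(30, 51, 2))


@dataclass(frozen=True)
class CohortJitter:
    """Between-subject SDs around the cohort-mean simulation parameters."""

    assr_amp_sd_uv: float = 0.2
    n100_amp_sd_uv: float = 0.8
    p200_amp_sd_uv: float = 0.6
    pps_sd_percent: float = 10.0
    noise_rms_sd_uv: float = 0.15
    kappa_sd: float = 0.1


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    n_subjects: int = 20
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    jitter: CohortJitter = field(default_factory=CohortJitter)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    electrodes: tuple[str, ...] = ("Fz", "Cz")
    bands_hz: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    freqs_hz: tuple[float, ...] = tuple(range(4, 101, 2))
    stats_method: str = "normal_approx"
    seed: int = 0
    make_figures: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(_to_jsonable(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_to_jsonable(v) for v in obj]
    return obj


def save_run_config(path: str | Path, config: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(_to_jsonable(config), sort_keys=False))


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return run_config_from_dict(raw)


def run_config_from_dict(raw: dict) -> RunConfig:
    kwargs = dict(raw)
    if "simulation" in kwargs:
        kwargs["simulation"] = config_from_dict(kwargs["simulation"])
    if "jitter" in kwargs:
        kwargs["jitter"] = CohortJitter(**kwargs["jitter"])
    if "preprocess" in kwargs:
        pp = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in kwargs["preprocess"].items()
        }
        kwargs["preprocess"] = PreprocessConfig(**pp)
    for key in ("electrodes", "freqs_hz"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "bands_hz" in kwargs:
        kwargs["bands_hz"] = tuple(tuple(b) for b in kwargs["bands_hz"])
    return RunConfig(**kwargs)


def _provenance(config: RunConfig) -> list[str]:
    return [
        f"pulsegate={__version__}",
        f"config_hash={config.config_hash()}",
        f"seed={config.seed}",
    ]


def _write_tsv(path: Path, df: pd.DataFrame, header: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def simulate_cohort(
    config: RunConfig, n_subjects: int | None = None
) -> list[TrialSet]:
    """Simulate independent subjects with jittered ground-truth parameters.

    Subject-level parameters are drawn around the cohort means with the
    configured SDs (clipped to valid ranges); each subject gets its own
    seed substream, so per-subject noise is independent.
    """
    n = n_subjects if n_subjects is not None else config.n_subjects
    if n < 1:
        raise ValueError("n_subjects must be >= 1")
    base = config.simulation
    jit = config.jitter
    master = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    subject_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(n + 1)[1:]
    ]
    cohort = []
    for i in range(n):
        cfg_i = replace(
            base,
            assr_amp_uv=max(0.05, base.assr_amp_uv + rng.normal(0, jit.assr_amp_sd_uv)),
            kappa_steady=max(0.0, base.kappa_steady + rng.normal(0, jit.kappa_sd)),
            erp_n100=replace(
                base.erp_n100,
                amp_uv=min(-0.5, base.erp_n100.amp_uv + rng.normal(0, jit.n100_amp_sd_uv)),
            ),
            erp_p200=replace(
                base.erp_p200,
                amp_uv=max(0.5, base.erp_p200.amp_uv + rng.normal(0, jit.p200_amp_sd_uv)),
            ),
            pps_percent=float(np.clip(
                base.pps_percent + rng.normal(0, jit.pps_sd_percent), 0.0, 100.0
            )),
            noise=replace(
                base.noise,
                rms_uv=max(0.1, base.noise.rms_uv + rng.normal(0, jit.noise_rms_sd_uv)),
            ),
            seed=subject_seeds[i],
        )
        trials = simulate_trialset(cfg_i)
        if cfg_i.artifact.probability > 0:
            trials, _ = inject_artifacts(trials, cfg_i)
        cohort.append(trials)
    return cohort


# --- file-based stages ------------------------------------------------------

def stage_simulate(config: RunConfig, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir) / "trials"
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, trials in enumerate(simulate_cohort(config)):
        p = out / f"subject{i:02d}.npz"
        save_trialset(p, trials)
        paths.append(p)
    log.info("simulated %d subjects -> %s", len(paths), out)
    return paths


def stage_preprocess(config: RunConfig, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    clean_dir = out_dir / "clean"
    clean_dir.mkdir(parents=True, exist_ok=True)
    evoked_rows = []
    paths = []
    for p in sorted((out_dir / "trials").glob("subject*.npz")):
        trials = load_trialset(p)
        offline, evoked, rejected = run_standard_pipeline(trials, config.preprocess)
        log.info("%s: rejected %d of %d trials", p.stem, len(rejected), trials.n_trials)
        cp = clean_dir / p.name
        save_trialset(cp, offline)
        np.savez_compressed(
            clean_dir / f"{p.stem}_evoked.npz",
            data=evoked.data,
            times_ms=evoked.times_ms,
            channel_names=np.array(evoked.channel_names),
            n_trials_averaged=evoked.n_trials_averaged,
        )
        for idx in rejected:
            evoked_rows.append({"subject": p.stem, "trial": idx})
        paths.append(cp)
    _write_tsv(
        out_dir / "rejection_log.tsv",
        pd.DataFrame(evoked_rows, columns=["subject", "trial"]),
        _provenance(config),
    )
    return paths


def _load_evoked(path: Path):
    from .preprocess import EvokedWaveform

    z = np.load(path, allow_pickle=False)
    return EvokedWaveform(
        z["data"], z["times_ms"], tuple(str(c) for c in z["channel_names"]),
        int(z["n_trials_averaged"]),
    )


def stage_erp(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    out_dir = Path(out_dir)
    pulses = config.simulation.stimulus.pulse_onsets_ms
    rows, tsv_rows = [], []
    for p in sorted((out_dir / "clean").glob("subject*_evoked.npz")):
        evoked = _load_evoked(p)
        subject = p.stem.replace("_evoked", "")
        for electrode in config.electrodes:
            responses, pps = measure_pps(evoked, electrode, pulses)
            tsv_rows.append((subject, electrode, responses, pps))
            rows.append({
                "subject": subject,
                "electrode": electrode,
                "first_amp": pps.first_amp_uv,
                "second_amp": pps.second_amp_uv,
                "pps_percent": pps.pps_percent,
            })
    df = pd.DataFrame(rows)
    write_erp_tsv(out_dir / "erp_measurements.tsv", tsv_rows, _provenance(config))
    _write_tsv(out_dir / "erp_summary.tsv", df, _provenance(config))
    return df


def stage_tfa(config: RunConfig, out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject ITPC maps -> window contrasts and level summaries."""
    out_dir = Path(out_dir)
    contrast_rows, level_rows = [], []
    maps_dir = out_dir / "itpc"
    maps_dir.mkdir(parents=True, exist_ok=True)
    grand: dict[str, list[np.ndarray]] = {e: [] for e in config.electrodes}
    for p in sorted((out_dir / "clean").glob("subject*.npz")):
        if p.stem.endswith("_evoked"):
            continue
        trials = load_trialset(p)
        for electrode in config.electrodes:
            tf = compute_itpc(trials, electrode, config.freqs_hz)
            grand[electrode].append(tf.itpc)
            np.savez_compressed(
                maps_dir / f"{p.stem}_{electrode}.npz",
                freqs_hz=tf.freqs_hz, times_ms=tf.times_ms, itpc=tf.itpc,
            )
            for band in config.bands_hz:
                tc = band_timecourse(tf, band)
                level_rows.append({
                    "subject": p.stem, "electrode": electrode,
                    "band_lo": band[0], "band_hi": band[1],
                    "baseline": prestimulus_baseline(tc),
                    "steady": steady_state_summary(tc),
                })
                for pulse in (1, 2):
                    for kind in ("min", "max"):
                        c = pulse_contrast(tc, pulse, kind, electrode)
                        contrast_rows.append({
                            "subject": p.stem, "electrode": electrode,
                            "band_lo": band[0], "band_hi": band[1],
                            "pulse": pulse, "kind": kind,
                            "pre_mean": c.pre_mean_itpc,
                            "extremum": c.extremum_itpc,
                            "extremum_time_ms": c.extremum_time_ms,
                            "delta": c.delta_itpc,
                        })
    contrasts = pd.DataFrame(contrast_rows)
    levels = pd.DataFrame(level_rows)
    _write_tsv(out_dir / "window_contrasts.tsv", contrasts, _provenance(config))
    _write_tsv(out_dir / "itpc_levels.tsv", levels, _provenance(config))
    for electrode, maps in grand.items():
        if maps:
            np.savez_compressed(
                maps_dir / f"grand_{electrode}.npz",
                itpc=np.mean(maps, axis=0),
            )
    return contrasts, levels


def stage_stats(config: RunConfig, out_dir: str | Path) -> dict[str, pd.DataFrame]:
    out_dir = Path(out_dir)
    contrasts = pd.read_csv(out_dir / "window_contrasts.tsv", sep="\t", comment="#")
    levels = pd.read_csv(out_dir / "itpc_levels.tsv", sep="\t", comment="#")
    erp = pd.read_csv(out_dir / "erp_summary.tsv", sep="\t", comment="#")
    tables = build_comparison_table(
        contrasts, levels, erp, method=config.stats_method
    )
    for name, df in tables.items():
        _write_tsv(out_dir / f"stats_{name}.tsv", df, _provenance(config))
    return tables


def stage_report(config: RunConfig, out_dir: str | Path) -> list[Path]:
    """Render grand-average figures: evoked waveforms, ITPC map, band curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    fig_dir = out_dir / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    made = []

    evoked_paths = sorted((out_dir / "clean").glob("subject*_evoked.npz"))
    if evoked_paths:
        evs = [_load_evoked(p) for p in evoked_paths]
        times = evs[0].times_ms
        fig, axes = plt.subplots(
            len(config.electrodes), 1, sharex=True, figsize=(8, 5)
        )
        axes = np.atleast_1d(axes)
        for ax, electrode in zip(axes, config.electrodes):
            g = np.mean([e.channel(electrode) for e in evs], axis=0)
            ax.plot(times, g, lw=0.8)
            for p in config.simulation.stimulus.pulse_onsets_ms:
                ax.axvline(p, color="r", ls="--", lw=0.6)
            ax.set_ylabel(f"{electrode} (uV)")
        axes[-1].set_xlabel("time from sound onset (ms)")
        fig.suptitle("Grand-average evoked waveforms")
        path = fig_dir / "evoked.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        made.append(path)

    maps_dir = out_dir / "itpc"
    for electrode in config.electrodes:
        gp = maps_dir / f"grand_{electrode}.npz"
        subj0 = sorted(maps_dir.glob(f"subject*_{electrode}.npz"))
        if not (gp.exists() and subj0):
            continue
        axes_npz = np.load(subj0[0])
        grand_map = np.load(gp)["itpc"]
        fig, ax = plt.subplots(figsize=(8, 4))
        im = ax.pcolormesh(
            axes_npz["times_ms"], axes_npz["freqs_hz"], grand_map,
            shading="nearest", cmap="viridis",
        )
        fig.colorbar(im, ax=ax, label="ITPC")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("frequency (Hz)")
        ax.set_title(f"Grand-average ITPC, {electrode}")
        path = fig_dir / f"itpc_map_{electrode}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        made.append(path)

        fig, ax = plt.subplots(figsize=(8, 4))
        freqs = axes_npz["freqs_hz"]
        for band in config.bands_hz:
            rows = [np.flatnonzero(np.isclose(freqs, f))[0] for f in band]
            ax.plot(
                axes_npz["times_ms"], grand_map[rows].mean(axis=0),
                lw=0.8, label=f"{band[0]:g}-{band[1]:g} Hz",
            )
        ax.legend(fontsize=6, ncols=2)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("ITPC")
        ax.set_title(f"Band ITPC time courses, {electrode}")
        path = fig_dir / f"band_timecourses_{electrode}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        made.append(path)
    return made


_STAGES = ("simulate", "preprocess", "erp", "tfa", "stats", "report")


def run_pipeline(
    config: RunConfig, out_dir: str | Path, stages: Sequence[str] = _STAGES
) -> dict:
    """Run the requested stages in order; returns the collected outputs.

    With the full stage list this produces the five artifact families:
    evoked waveforms, ITPC maps, band time courses, ERP/PPS tables, and
    window-contrast/statistics tables.
    """
    if config.n_subjects < 1 or config.simulation.n_trials < 1:
        raise ValueError("need at least one subject and one trial")
    unknown = set(stages) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_run_config(out_dir / "run_config.yaml", config)
    results: dict = {}
    for stage in _STAGES:
        if stage not in stages:
            continue
        log.info("stage: %s", stage)
        if stage == "simulate":
            results["trials"] = stage_simulate(config, out_dir)
        elif stage == "preprocess":
            results["clean"] = stage_preprocess(config, out_dir)
        elif stage == "erp":
            results["erp"] = stage_erp(config, out_dir)
        elif stage == "tfa":
            results["contrasts"], results["levels"] = stage_tfa(config, out_dir)
        elif stage == "stats":
            results["tables"] = stage_stats(config, out_dir)
        elif stage == "report" and config.make_figures:
            results["figures"] = stage_report(config, out_dir)
    return results
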