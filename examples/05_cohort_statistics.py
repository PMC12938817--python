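"""Cohort-level inference: Wilcoxon comparisons and sample-size planning.

Runs the full pipeline on a small simulated cohort and prints the
group-level oscillation table (pre-pulse mean, windowed extremum, paired
Wilcoxon p-values) plus the a priori sample-size computation used for
paired designs.
"""

import tempfile
from pathlib import Path

from pulsegate import (
    PreprocessConfig,
    RunConfig,
    SimulationConfig,
    run_pipeline,
    sample_size_wilcoxon,
)

cfg = RunConfig(
    n_subjects=8,
    simulation=SimulationConfig(n_trials=60, seed=0),
    preprocess=PreprocessConfig(min_trials=40),
    electrodes=("Fz",),
    bands_hz=((38.0, 40.0), (40.0, 42.0), (48.0, 50.0)),
    freqs_hz=(38.0, 40.0, 42.0, 48.0, 50.0),
    seed=2024,
    make_figures=False,
)

with tempfile.TemporaryDirectory() as out:
    results = run_pipeline(cfg, Path(out),
                           stages=("simulate", "preprocess", "erp", "tfa", "stats"))

osc = results["tables"]["oscillations"]
cols = ["band_lo", "band_hi", "kind", "pre1_mean", "ext1_mean",
        "p_ext_vs_pre_1", "p_delta_1_vs_2"]
print(osc[cols].round(4).to_string(index=False))

erp = results["tables"]["erp"]
print(f"\nERP: first {erp.iloc[0]['first_amp_mean']:.2f} uV vs "
      f"second {erp.iloc[0]['second_amp_mean']:.2f} uV, "
      f"PPS {erp.iloc[0]['pps_mean']:.1f} %, "
      f"Wilcoxon p = {erp.iloc[0]['p_first_vs_second']:.4f}")

plan = sample_size_wilcoxon(0.86, alpha=0.05, power=0.95, tails=2)
print(f"\na priori sample size (d=0.86, alpha=0.05, power=0.95, two-sided, "
      f"ARE 3/pi): n = {plan.n_required} "
      f"(achieved power {plan.achieved_power:.3f})")

# The evoked amplitudes differ sharply between pulses (suppression) and the
# extremum-vs-pre p-values sit at the n = 8 signed-rank floor for the dips
# and bursts.  The desync dips (min) show no pulse-1 vs pulse-2 difference
# -- the phase perturbation is identical at both pulses -- while the max
# contrasts can brush the 5% boundary because the suppressed second-pulse
# ERP transient contributes slightly less phase-locked energy.
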