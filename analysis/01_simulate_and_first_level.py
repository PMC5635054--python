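#!/usr/bin/env python
"""Simulate the demonstration cohort and fit every subject's first level.

Streams the 16 subjects (8 controls with signed alpha/BOLD coupling in two
ground-truth regions, 8 patients with none) one at a time through the full
chain — 5 kHz in-scanner EEG synthesis, decimation, gradient and pulse
artifact subtraction, filtering, ICA cleanup, occipital pooling, complex
demodulation, HRF regressor construction, BOLD preprocessing and the
voxel-wise GLM — then writes the per-subject coupling maps to scratch/ (for
the group stage) and a first-level summary table to results/.
"""

import sys
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from alphabold import io, pipeline, synth

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "first_level"
RESULTS = ROOT / "results"
SEED = 1


def main() -> int:
    warnings.filterwarnings("ignore")
    config = pipeline.StudyConfig(sim=synth.demo_config(n_per_group=8),
                                  seed=SEED)
    region_a, region_b = synth.demo_regions(config.sim.grid_shape)
    plan = synth.cohort_plan(config.sim, SEED)
    cov = synth.cohort_covariates(config.sim, SEED)
    RESULTS.mkdir(exist_ok=True)
    cov.to_csv(RESULTS / "covariates.tsv", sep="\t", index=False)

    rows = []
    for sid, grp, sseed in plan:
        t0 = time.time()
        subject = synth.simulate_subject(config.sim, grp, sid, sseed)
        res = pipeline.run_first_level(subject, config)
        sdir = SCRATCH / sid
        for band in res.beta_maps:
            io.write_nifti(res.beta_maps[band], sdir / f"beta_{band}.nii.gz")
            io.write_nifti(res.t_pos[band].values, sdir / f"tpos_{band}.nii.gz")
        io.write_json({"subject_id": sid, "group": grp, "df": res.df,
                       "relative_power": res.relative_power, **res.report},
                      sdir / "report.json")
        t_a = float(np.nanmean(res.t_pos["total_alpha"].values[region_a]))
        t_b = float(np.nanmean(res.t_pos["total_alpha"].values[region_b]))
        rows.append(dict(subject_id=sid, group=grp, df=res.df,
                         rel_alpha_power=res.relative_power["total_alpha"],
                         mean_t_region_a=t_a, mean_t_region_b=t_b,
                         n_r_peaks=res.report.get("n_r_peaks"),
                         seconds=round(time.time() - t0, 1)))
        print(f"{sid} ({grp}): mean t in coupled region A = {t_a:+.1f}, "
              f"region B = {t_b:+.1f}  [{rows[-1]['seconds']} s]")
        del subject

    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "first_level_summary.tsv", sep="\t", index=False)
    hc = table[table.group == "HC"]
    ad = table[table.group == "AD"]
    print(f"\nControls: mean t in region A {hc.mean_t_region_a.mean():+.1f} "
          f"(patients {ad.mean_t_region_a.mean():+.1f}) — the generator's "
          "positive coupling is visible only in the control group.")
    print(f"Summary written to {RESULTS / 'first_level_summary.tsv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
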