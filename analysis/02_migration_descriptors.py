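#!/usr/bin/env python
"""Migration descriptors of the simulated phenotypes.

For each ensemble written by ``01_simulate_phenotypes.py``: pooled
step-length branch fits (exponential vs half-Gaussian on the semi-log
histogram), the recovered motion class, and the turning-angle histogram with
circular statistics.  Outputs under ``results/02_descriptors``.
"""

import json
from pathlib import Path

import matplotlib.pyplot as plt
import pandas as pd

from ooctrack import descriptors, plotting, synth
from ooctrack.io import read_tracks

root = Path(__file__).resolve().parent.parent / "results"
in_dir = root / "01_phenotypes"
out_dir = root / "02_descriptors"
out_dir.mkdir(parents=True, exist_ok=True)

summary = {}
for label in synth.PHENOTYPE_LABELS:
    tracks = read_tracks(in_dir / f"tracks_{label}.csv")
    steps = descriptors.pool_steps(tracks)
    fits = descriptors.fit_all_branches(steps)
    motion = descriptors.classify_motion(fits)
    hist = descriptors.turning_histogram(steps.dtheta)

    pd.DataFrame(
        [
            {"axis": f.axis, "sign": f.sign, "model": f.model, "scale_um": f.scale,
             "scale_se": f.scale_se, "r2_exponential": f.r2_exponential,
             "r2_gaussian": f.r2_gaussian, "n": f.n_points}
            for f in fits.values()
        ]
    ).to_csv(out_dir / f"branch_fits_{label}.csv", index=False)

    axes = plotting.plot_step_distributions(steps)
    axes[0, 0].figure.suptitle(f"{label}: semi-log step-length branches")
    axes[0, 0].figure.savefig(out_dir / f"steps_{label}.png", dpi=150)
    plt.close(axes[0, 0].figure)

    ax = plotting.plot_turning_polar(hist)
    ax.set_title(f"{label}: turning angles")
    ax.figure.savefig(out_dir / f"turning_{label}.png", dpi=150)
    plt.close(ax.figure)

    summary[label] = {
        "recovered_class": motion.label,
        "branch_models": motion.branch_models,
        "resultant_length": hist.resultant_length,
        "peak_frequency": hist.peak_frequency,
        "n_steps": int(len(steps.dx)),
    }
    print(f"{label}: recovered {motion.label}, "
          f"resultant length {hist.resultant_length:.3f}")

(out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
print(f"outputs in {out_dir}")
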