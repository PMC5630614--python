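#!/usr/bin/env python
"""Simulate the three migration phenotypes and archive their tracks.

Generates one ensemble per phenotype (strong drift in x and y, drift along x
only, isotropic) with the package's default generator parameters, writes the
track CSVs and a trajectory figure per ensemble under ``results/01_phenotypes``.
"""

from pathlib import Path

import matplotlib.pyplot as plt

from ooctrack import plotting, synth
from ooctrack.io import write_tracks

SEED = 0
N_CELLS = 30
N_STEPS = 200

out_dir = Path(__file__).resolve().parent.parent / "results" / "01_phenotypes"
out_dir.mkdir(parents=True, exist_ok=True)

for label in synth.PHENOTYPE_LABELS:
    params = synth.PhenotypeParams(label=label)
    walks = synth.simulate_phenotype_walks(params, N_CELLS, N_STEPS, seed=SEED)
    write_tracks(walks, out_dir / f"tracks_{label}.csv")

    ax = plotting.plot_trajectories(walks)
    ax.set_title(f"phenotype: {label} (n={N_CELLS}, {N_STEPS} frames)")
    ax.figure.savefig(out_dir / f"trajectories_{label}.png", dpi=150)
    plt.close(ax.figure)
    print(f"{label}: wrote {N_CELLS} tracks ({N_STEPS} frames each)")

print(f"outputs in {out_dir}")
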