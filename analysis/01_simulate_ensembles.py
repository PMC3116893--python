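#!/usr/bin/env python
"""Materialize the synthetic study systems for inspection.

The systems themselves are defined once, as seeded pure generators, in
``_common.py`` — a 60-residue pseudo-helical chain, a 200-frame Gaussian
ensemble drawn from its elastic network, blocked/shuffled two-state
trajectories (8 Å between states, 0.4 Å jitter), AR(1) free-energy
component tables (2400 snapshots at 20-ps spacing, lag-1 correlation 0.6)
and the cavity fixture. This driver writes them under scratch/ (they are
bulky and fully regenerable) and a summary row per system to
results/systems.tsv.
"""

import numpy as np
import pandas as pd

from modescope import energetics as en
from modescope.structio import write_structure

import _common as cc

cc.SCRATCH.mkdir(exist_ok=True)
cc.RESULTS.mkdir(exist_ok=True)

rows = []

c = cc.chain()
write_structure(c, cc.SCRATCH / "chain.pdb")
rows.append({"system": "chain", "atoms": c.n_atoms, "frames": 1})

_, ens = cc.gaussian_ensemble()
write_structure(ens, cc.SCRATCH / "ensemble.pdb")
rows.append({"system": "enm_gaussian_ensemble", "atoms": ens.topology.n_atoms,
             "frames": ens.n_frames})

for layout in ("blocked", "shuffled"):
    traj = cc.two_state(layout)
    write_structure(traj, cc.SCRATCH / f"two_state_{layout}.pdb")
    rows.append({"system": f"two_state_{layout}",
                 "atoms": traj.topology.n_atoms, "frames": traj.n_frames})

for label in ("wt", "mut"):
    series = cc.energy_series(label)
    en.write_energy_table(series, cc.SCRATCH / f"energy_{label}.tsv")
    rows.append({"system": f"energy_{label}", "atoms": 0,
                 "frames": series.n_frames})

cav = cc.cavity()
write_structure(cav, cc.SCRATCH / "cavity.pdb")
rows.append({"system": "cavity", "atoms": cav.n_atoms, "frames": 1})

table = pd.DataFrame(rows)
table.to_csv(cc.RESULTS / "systems.tsv", sep="\t", index=False)
print(table.to_string(index=False))
print(f"\nheavy files under {cc.SCRATCH} (regenerable; seed {cc.SEED})")
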