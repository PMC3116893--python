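"""Shared study-system definitions for the analysis drivers.

Every driver rebuilds its inputs from these seeded, pure generator calls,
so the drivers can run independently and in any order; 01 additionally
materializes the systems under scratch/ for inspection.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from modescope import energetics as en
from modescope import nma
from modescope import synthetic_data as sd

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 2024

N_RESIDUES = 60          # chain length of the ENM substrate
N_FRAMES = 200           # ensemble size for PCA/convergence stages
STATE_RMSD = 8.0         # two-state separation, Å (well above the jitter)
JITTER = 0.4             # within-state thermal jitter, Å
N_ENERGY_FRAMES = 2400   # snapshots at 20-ps spacing in the energy tables


def chain():
    return sd.make_toy_chain(N_RESIDUES, seed=SEED)


def chain_modes(structure=None):
    return nma.compute_enm_modes(structure or chain(), cutoff=12.0,
                                 n_modes=None)


def gaussian_ensemble():
    c = chain()
    return c, sd.sample_enm_ensemble(c, chain_modes(c), scale=1.0,
                                     n_frames=N_FRAMES, seed=SEED + 1)


def two_state(layout):
    c = chain()
    other = sd.make_deformed_state(c, STATE_RMSD, seed=SEED + 2)
    return sd.make_two_state_trajectory(c, other, 100, layout=layout,
                                        jitter=JITTER, seed=SEED + 3)


def energy_series(label):
    i = ("wt", "mut").index(label)
    comp = {}
    for j, col in enumerate(en.ENTHALPY_COLUMNS + en.ENTROPY_COLUMNS):
        comp[col] = sd.make_ar1_series(
            mean=-120.0 + 15.0 * j + 4.0 * i, sigma=4.0, phi=0.6,
            n=N_ENERGY_FRAMES, seed=SEED + 10 * (i + 1) + j)
    return en.EnergySeries(
        times=np.arange(1.0, N_ENERGY_FRAMES + 1.0) * 20.0,
        components=pd.DataFrame(comp), label=label)


def cavity():
    return sd.make_cavity_structure(8.0, 40.0, 200, seed=SEED + 4)
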