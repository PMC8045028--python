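"""Plain-text export of trajectories and observables.

Frames go out as multi-model XYZ (one model per frame, species as atom
names), the final frame optionally as a minimal PDB, energy and observable
series as CSV.  These are convenience exports for visualization; analysis
should use the in-memory objects.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .energy import SystemState
from .mc import Trajectory

_ELEMENT = {"TPP": "P", "PP": "P", "citrate": "C", "Na": "Na", "Cl": "Cl"}


def _atom_name(species: str) -> str:
    return _ELEMENT.get(species, species[:2])


def write_xyz(traj: Trajectory, path: str | os.PathLike) -> None:
    """Multi-frame XYZ: one model per sampled frame."""
    with open(path, "w") as fh:
        for k, frame in enumerate(traj.frames):
            fh.write(f"{frame.n_sites}\n")
            fh.write(f"frame {k} energy_kT {traj.energies[k]:.6f}\n")
            for sp, xyz in zip(frame.species, frame.coords):
                fh.write(f"{_atom_name(str(sp)):<4s} "
                         f"{xyz[0]:12.4f} {xyz[1]:12.4f} {xyz[2]:12.4f}\n")


def write_pdb(state: SystemState, path: str | os.PathLike) -> None:
    """Minimal PDB of one frame (CA records for beads, HETATM for ions)."""
    with open(path, "w") as fh:
        fh.write(f"CRYST1{state.box_length:9.3f}{state.box_length:9.3f}"
                 f"{state.box_length:9.3f}  90.00  90.00  90.00 P 1           1\n")
        serial = 1
        for i in range(state.n_sites):
            sp = str(state.species[i])
            is_ion = state.chain_id[i] < 0
            record = "HETATM" if is_ion else "ATOM  "
            resname = sp[:3].upper() if is_ion else f"  {sp}"
            chain = "I" if is_ion else chr(ord("A") + int(state.chain_id[i]) % 26)
            x, y, z = state.coords[i]
            fh.write(f"{record}{serial:>5d}  CA {resname:>3s} {chain}{serial:>4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n")
            serial += 1
        fh.write("END\n")


def write_energy_csv(traj: Trajectory, path: str | os.PathLike) -> None:
    pd.DataFrame({"frame": np.arange(traj.n_frames), "energy_kT": traj.energies}) \
        .to_csv(path, index=False)


def write_observable_csv(name: str, values, path: str | os.PathLike) -> None:
    values = np.asarray(values, float)
    pd.DataFrame({"frame": np.arange(len(values)), name: values}).to_csv(path, index=False)
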