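"""Plain-text file formats: COLVAR / HILLS dialect tables, FES tables and
contact-frequency TSVs.

COLVAR-style files are whitespace-separated numeric tables with a single
``#! FIELDS name1 name2 ...`` header line; readers tolerate any number of
``#!`` comment lines. Values are written with 17 significant digits so
round trips are lossless for float64.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .metadynamics import FES, Hill, HillLog, MetadynamicsConfig
from .pulling import ContactFrequencyTable, PullTrajectory, ResidueZone
from .engine import Trajectory

__all__ = [
    "write_fields_table", "read_fields_table",
    "write_colvar", "read_colvar",
    "write_hills", "read_hills",
    "write_fes", "read_fes",
    "write_pull_trajectory", "read_pull_trajectory",
    "write_contact_table", "read_contact_table",
]

_FMT = "%.17g"


def write_fields_table(path, fields: Sequence[str], columns: Sequence[np.ndarray]) -> None:
    arr = np.column_stack([np.asarray(c, dtype=float) for c in columns])
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        np.savetxt(fh, arr, fmt=_FMT)


def read_fields_table(path) -> Dict[str, np.ndarray]:
    fields = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#!"):
                tokens = line.split()
                if len(tokens) >= 2 and tokens[1] == "FIELDS":
                    fields = tokens[2:]
            else:
                break
    if fields is None:
        raise ValueError(f"no '#! FIELDS' header in {path}")
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.size and data.shape[1] != len(fields):
        raise ValueError(f"column count mismatch in {path}")
    if not data.size:
        data = data.reshape(0, len(fields))
    return {name: data[:, i] for i, name in enumerate(fields)}


# -- trajectories -----------------------------------------------------------

def write_colvar(traj: Trajectory, path, stride: int = 1) -> None:
    """Write a trajectory record as `#! FIELDS time dz bias force`."""
    s = slice(None, None, stride)
    write_fields_table(path, ["time", "dz", "bias", "force"],
                       [traj.time[s], traj.z[s], traj.bias_energy[s],
                        traj.total_force[s]])


def read_colvar(path) -> Dict[str, np.ndarray]:
    return read_fields_table(path)


# -- hills ------------------------------------------------------------------

def write_hills(log: HillLog, path) -> None:
    """PLUMED-style HILLS text: time dz sigma_dz height biasf."""
    t, c, s, h = log.arrays()
    bf = np.full(t.size, log.config.biasfactor)
    write_fields_table(path, ["time", "dz", "sigma_dz", "height", "biasf"],
                       [t, c, s, h, bf])


def read_hills(path, config: MetadynamicsConfig) -> HillLog:
    d = read_fields_table(path)
    hills = [Hill(time=t, center=c, sigma=s, height=h, biasfactor=b)
             for t, c, s, h, b in zip(d["time"], d["dz"], d["sigma_dz"],
                                      d["height"], d["biasf"])]
    return HillLog(hills=hills, config=config)


# -- FES --------------------------------------------------------------------

def write_fes(fes: FES, path) -> None:
    df = pd.DataFrame({"z": fes.z_grid, "free_energy": fes.free_energy,
                       "sampled": fes.region_sampled.astype(int)})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_fes(path) -> FES:
    df = pd.read_csv(path, sep="\t")
    return FES(z_grid=df["z"].to_numpy(), free_energy=df["free_energy"].to_numpy(),
               region_sampled=df["sampled"].to_numpy().astype(bool))


# -- pulling ----------------------------------------------------------------

def write_pull_trajectory(traj: PullTrajectory, path) -> None:
    """`#! FIELDS time z center force <zone labels...>` with 0/1 contacts."""
    fields = ["time", "z", "center", "force"] + [z.residue_label for z in traj.zones]
    cols = [traj.time, traj.z, traj.restraint_center, traj.pull_force]
    cols += [traj.contacts[j].astype(float) for j in range(len(traj.zones))]
    write_fields_table(path, fields, cols)


def read_pull_trajectory(path, halfwidths: Dict[str, float] | None = None,
                         centers: Dict[str, float] | None = None,
                         seed: int = -1) -> PullTrajectory:
    d = read_fields_table(path)
    zone_labels = [k for k in d if k not in ("time", "z", "center", "force")]
    zones = [ResidueZone(lab,
                         (centers or {}).get(lab, 0.0),
                         (halfwidths or {}).get(lab, 0.1))
             for lab in zone_labels]
    contacts = np.array([d[lab] > 0.5 for lab in zone_labels]).reshape(len(zones), -1)
    t = d["time"]
    spacing = float(t[1] - t[0]) if t.size > 1 else 1.0
    return PullTrajectory(time=t, z=d["z"], restraint_center=d["center"],
                          pull_force=d["force"], contacts=contacts, zones=zones,
                          frame_spacing=spacing, seed=seed)


# -- contact tables ---------------------------------------------------------

def write_contact_table(table: ContactFrequencyTable, path) -> None:
    """TSV with `# key=value` metadata header lines."""
    with open(path, "w") as fh:
        for k in sorted(table.metadata):
            v = table.metadata[k]
            if isinstance(v, (tuple, list)):
                v = ",".join(map(str, v))
            fh.write(f"# {k}={v}\n")
        table.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_contact_table(path) -> ContactFrequencyTable:
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    for k in ("replicate", "seed", "transported"):
        if k in meta:
            meta[k] = int(meta[k])
    return ContactFrequencyTable(table=df, metadata=meta)


def contact_tables_from_dir(directory) -> list:
    """All `*.tsv` contact tables under a directory, sorted by name."""
    paths = sorted(Path(directory).glob("*.tsv"))
    if not paths:
        raise ValueError(f"no contact tables in {directory}")
    return [read_contact_table(p) for p in paths]
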