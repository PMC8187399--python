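"""Multi-frame peptide/ligand structures and their plain-text formats.

A :class:`Trajectory` is the container every structural analysis consumes:
coordinates in nanometres, frames x atoms x 3, plus a per-atom topology
table (atom name, element, residue index/name, group tag, proton flag).
Structures round-trip through multi-model PDB or XYZ text with a CSV
topology sidecar, so no binary trajectory formats are ever needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TOPOLOGY_COLUMNS = ("atom_name", "element", "res_index", "res_name", "group", "is_proton")

GROUPS = ("peptide", "ligand", "other")


class TopologyError(ValueError):
    """Raised when a trajectory's topology violates its contract."""


@dataclass
class Trajectory:
    """Conformational ensemble: coordinates (nm) plus per-atom topology.

    Parameters
    ----------
    coords
        Array of shape (n_frames, n_atoms, 3), nanometres.
    topology
        DataFrame with columns ``atom_name, element, res_index, res_name,
        group, is_proton``; one row per atom. ``group`` is one of
        ``peptide``, ``ligand``, ``other``. Residue indices are 0-based
        and non-decreasing.
    frame_times
        Optional per-frame times in picoseconds.
    ground_truth
        Optional generator metadata (per-frame state labels, contact
        flags, input parameters). Empty for structures read from disk.
    """

    coords: np.ndarray
    topology: pd.DataFrame
    frame_times: np.ndarray | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError("coords must have shape (n_frames, n_atoms, 3)")
        missing = [c for c in TOPOLOGY_COLUMNS if c not in self.topology.columns]
        if missing:
            raise TopologyError(f"topology missing columns: {missing}")
        if len(self.topology) != self.coords.shape[1]:
            raise TopologyError(
                f"topology has {len(self.topology)} atoms but coords have "
                f"{self.coords.shape[1]}"
            )
        bad = set(self.topology["group"]) - set(GROUPS)
        if bad:
            raise TopologyError(f"unknown group tags: {sorted(bad)}")
        res_idx = self.topology["res_index"].to_numpy()
        if len(res_idx) and np.any(np.diff(res_idx) < 0):
            raise TopologyError("residue indices must be non-decreasing")
        if not np.all(np.isfinite(self.coords)):
            raise TopologyError("coordinates must be finite")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise TopologyError("frame_times length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def peptide_residues(self) -> np.ndarray:
        """Sorted unique residue indices belonging to the peptide group."""
        mask = self.topology["group"] == "peptide"
        return np.unique(self.topology.loc[mask, "res_index"].to_numpy())

    def atom_indices(
        self,
        group: str | None = None,
        names: list[str] | tuple[str, ...] | None = None,
        protons_only: bool = False,
        res_index: int | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching all the given filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if group is not None:
            mask &= (self.topology["group"] == group).to_numpy()
        if names is not None:
            mask &= self.topology["atom_name"].isin(names).to_numpy()
        if protons_only:
            mask &= self.topology["is_proton"].to_numpy().astype(bool)
        if res_index is not None:
            mask &= (self.topology["res_index"] == res_index).to_numpy()
        return np.flatnonzero(mask)


def backbone_indices(traj: Trajectory, residue: int) -> dict[str, int]:
    """Map N/CA/C atom names to atom indices for one peptide residue.

    Raises :class:`TopologyError` naming the residue if any backbone atom
    is missing.
    """
    out: dict[str, int] = {}
    for name in ("N", "CA", "C"):
        idx = traj.atom_indices(group="peptide", names=[name], res_index=residue)
        if idx.size != 1:
            raise TopologyError(
                f"residue {residue} lacks a unique backbone atom {name!r}"
            )
        out[name] = int(idx[0])
    return out


# ---------------------------------------------------------------------------
# Text formats


def write_topology_csv(traj: Trajectory, path) -> None:
    traj.topology.loc[:, list(TOPOLOGY_COLUMNS)].to_csv(path, index=False)


def read_topology_csv(path) -> pd.DataFrame:
    top = pd.read_csv(path)
    top["is_proton"] = top["is_proton"].astype(bool)
    return top


def write_xyz(traj: Trajectory, path) -> None:
    """Write all frames as concatenated XYZ blocks (coordinates in nm)."""
    names = traj.topology["atom_name"].tolist()
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\nframe {f}\n")
            for name, (x, y, z) in zip(names, traj.coords[f]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path, topology: pd.DataFrame) -> Trajectory:
    frames = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + n
    return Trajectory(np.asarray(frames), topology)


def write_pdb(traj: Trajectory, path) -> None:
    """Write a multi-model PDB (coordinates converted nm -> Angstrom)."""
    top = traj.topology
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[f, a] * 10.0
                fh.write(
                    "ATOM  {serial:5d} {name:<4s}{res:>4s} A{resi:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n".format(
                        serial=a + 1,
                        name=top["atom_name"].iat[a][:4],
                        res=top["res_name"].iat[a][:4],
                        resi=int(top["res_index"].iat[a]) + 1,
                        x=x,
                        y=y,
                        z=z,
                        el=top["element"].iat[a][:2],
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb(path, topology: pd.DataFrame | None = None) -> Trajectory:
    """Read a multi-model PDB written by :func:`write_pdb` (Angstrom -> nm).

    If no topology table is supplied, a minimal one is reconstructed from
    the ATOM records (group inferred from the residue name ``OLA`` for the
    ligand; protons flagged by element H).
    """
    frames: list[list[list[float]]] = []
    cur: list[list[float]] = []
    records: list[tuple[str, str, int, str]] = []
    first = True
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("MODEL"):
                cur = []
            elif ln.startswith("ATOM"):
                cur.append(
                    [float(ln[30:38]) / 10.0, float(ln[38:46]) / 10.0, float(ln[46:54]) / 10.0]
                )
                if first:
                    records.append(
                        (
                            ln[12:16].strip(),
                            ln[76:78].strip() or ln[12:16].strip()[0],
                            int(ln[22:26]) - 1,
                            ln[17:21].strip(),
                        )
                    )
            elif ln.startswith("ENDMDL"):
                frames.append(cur)
                first = False
    if topology is None:
        topology = pd.DataFrame(
            {
                "atom_name": [r[0] for r in records],
                "element": [r[1] for r in records],
                "res_index": [r[2] for r in records],
                "res_name": [r[3] for r in records],
                "group": ["ligand" if r[3] == "OLA" else "peptide" for r in records],
                "is_proton": [r[1] == "H" for r in records],
            }
        )
    return Trajectory(np.asarray(frames), topology)
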