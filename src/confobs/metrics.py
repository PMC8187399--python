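"""Geometric ensemble metrics: pairwise RMSD, GROMOS neighbour-count
clustering, dihedral secondary-structure propensity, and peptide-ligand
contact probability.

Secondary structure here is a backbone-dihedral region classifier rather
than a hydrogen-bond assignment: a residue is helical (H) when its
(phi, psi) falls in the alpha-region window, extended (E) in the
beta-region window, other (O) elsewhere. The three-letter grouping used
throughout (3_10/alpha/pi helices -> H; beta sheet and isolated bridge
-> E; rest -> O) is also applied verbatim to externally computed DSSP
label streams via :func:`group_ss_labels`, so real DSSP output can be
aggregated into the same propensity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

# helical / extended windows of the (phi, psi) classifier, degrees
HELIX_PHI_DEG = (-100.0, -30.0)
HELIX_PSI_DEG = (-80.0, -5.0)
SHEET_PHI_DEG = (-180.0, -90.0)
SHEET_PSI_DEG = (90.0, 180.0)
SHEET_PSI_WRAP_DEG = (-180.0, -170.0)  # psi near +180 wrapped to -180

#: DSSP single-letter codes grouped to H / E / O
DSSP_GROUPING = {"G": "H", "H": "H", "I": "H", "E": "E", "B": "E"}

#: default peptide-ligand contact cutoff, nm (contact := distance < cutoff)
CONTACT_CUTOFF_NM = 0.55


@dataclass
class ClusterResult:
    """GROMOS clustering output: cluster ids are 0-based and ordered by
    decreasing cluster size (ties broken by earlier central frame)."""

    labels: np.ndarray  # per-frame cluster id
    centers: np.ndarray  # per-cluster central frame index
    cutoff_nm: float
    selection: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


@dataclass
class SSMatrix:
    """Per-frame, per-residue secondary-structure labels and the derived
    per-residue helical propensity (mean over frames of label == H)."""

    labels: np.ndarray  # frames x residues, dtype '<U1', in {H, E, O}
    residues: np.ndarray  # residue indices the columns refer to

    @property
    def helical_propensity(self) -> np.ndarray:
        return (self.labels == "H").mean(axis=0)


@dataclass
class ContactProfile:
    """Per-residue contact probabilities plus the any-residue aggregate."""

    residues: np.ndarray
    probability: np.ndarray  # per residue, in [0, 1]
    any_contact: float  # fraction of frames with at least one residue in contact
    cutoff_nm: float
    group_pair: tuple[str, str]


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets after optimal
    superposition (least-squares rotation + translation, Kabsch/SVD)."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(xc.T @ yc)
    sign = np.sign(np.linalg.det(u @ vt))
    s = s.copy()
    s[-1] *= sign
    msd = (np.sum(xc**2) + np.sum(yc**2) - 2.0 * np.sum(s)) / len(x)
    return float(np.sqrt(max(msd, 0.0)))


def pairwise_rmsd(traj: Trajectory, selection: np.ndarray | None = None) -> np.ndarray:
    """Symmetric frame-by-frame RMSD matrix (nm) after per-pair optimal
    superposition on the selected atoms (default: backbone N/CA/C)."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if selection is None:
        selection = traj.atom_indices(group="peptide", names=["N", "CA", "C"])
    selection = np.asarray(selection)
    if selection.size < 3:
        raise ValueError("superposition needs at least 3 atoms")
    xyz = traj.coords[:, selection, :]
    n = traj.n_frames
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = kabsch_rmsd(xyz[i], xyz[j])
    return out


def gromos_cluster(
    traj: Trajectory,
    cutoff_nm: float = 0.2,
    selection: np.ndarray | None = None,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterResult:
    """Iterative neighbour-count (GROMOS/Daura) clustering.

    Repeatedly take the unassigned frame with the most unassigned
    neighbours within ``cutoff_nm`` (ties: lowest frame index) as a
    cluster centre, assign it and its neighbours to one cluster, and
    remove them. Clusters are then renumbered by decreasing size.
    """
    if selection is None:
        selection = traj.atom_indices(group="peptide", names=["N", "CA", "C"])
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd(traj, selection)
    n = rmsd_matrix.shape[0]
    neighbor = rmsd_matrix < cutoff_nm
    np.fill_diagonal(neighbor, True)
    unassigned = np.ones(n, dtype=bool)
    raw_labels = np.full(n, -1)
    raw_centers = []
    while unassigned.any():
        counts = (neighbor & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = neighbor[center] & unassigned
        raw_labels[members] = len(raw_centers)
        raw_centers.append(center)
        unassigned &= ~members
    sizes = np.bincount(raw_labels)
    order = sorted(range(len(raw_centers)), key=lambda c: (-sizes[c], raw_centers[c]))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in raw_labels])
    centers = np.array([raw_centers[old] for old in order])
    return ClusterResult(labels=labels, centers=centers, cutoff_nm=cutoff_nm,
                         selection=np.asarray(selection))


def classify_phi_psi(phi_rad: np.ndarray, psi_rad: np.ndarray) -> np.ndarray:
    """Label backbone (phi, psi) pairs as H (helix), E (sheet) or O."""
    phi = np.rad2deg(np.asarray(phi_rad))
    psi = np.rad2deg(np.asarray(psi_rad))
    out = np.full(phi.shape, "O", dtype="<U1")
    sheet = (
        (phi >= SHEET_PHI_DEG[0]) & (phi <= SHEET_PHI_DEG[1])
        & (
            ((psi >= SHEET_PSI_DEG[0]) & (psi <= SHEET_PSI_DEG[1]))
            | ((psi >= SHEET_PSI_WRAP_DEG[0]) & (psi <= SHEET_PSI_WRAP_DEG[1]))
        )
    )
    out[sheet] = "E"
    helix = (
        (phi >= HELIX_PHI_DEG[0]) & (phi <= HELIX_PHI_DEG[1])
        & (psi >= HELIX_PSI_DEG[0]) & (psi <= HELIX_PSI_DEG[1])
    )
    out[helix] = "H"
    return out


def group_ss_labels(labels: np.ndarray) -> np.ndarray:
    """Collapse DSSP-style single-letter labels to the H/E/O grouping
    (3_10, alpha and pi helices -> H; sheet and isolated bridge -> E)."""
    arr = np.asarray(labels, dtype="<U1")
    out = np.full(arr.shape, "O", dtype="<U1")
    for code, grp in DSSP_GROUPING.items():
        out[arr == code] = grp
    return out


def ss_propensity(dihedrals) -> SSMatrix:
    """Per-residue secondary-structure labels from a dihedral time series.

    Accepts a :class:`~confobs.dpca.DihedralSeries`; propensity is the
    per-residue mean of the H indicator over frames.
    """
    phi, psi = dihedrals.phi_psi()
    return SSMatrix(labels=classify_phi_psi(phi, psi), residues=dihedrals.residues)


def contact_probability(
    traj: Trajectory,
    group_a: np.ndarray | None = None,
    group_b: np.ndarray | None = None,
    cutoff_nm: float = CONTACT_CUTOFF_NM,
    group_pair: tuple[str, str] = ("sidechain-H", "ligand"),
) -> ContactProfile:
    """Per-residue contact probability between two atom groups.

    For each residue represented in ``group_a`` (default: peptide
    side-chain protons) and each frame, the minimum distance to any
    ``group_b`` atom (default: ligand) is computed; a contact is strictly
    ``distance < cutoff_nm``. ``any_contact`` is the fraction of frames
    in which at least one residue is in contact.
    """
    if group_a is None:
        group_a = traj.atom_indices(group="peptide", protons_only=True)
    if group_b is None:
        group_b = traj.atom_indices(group="ligand")
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("both contact groups must be non-empty")
    res_of_a = traj.topology["res_index"].to_numpy()[group_a]
    residues = np.unique(res_of_a)
    xa = traj.coords[:, group_a, :]
    xb = traj.coords[:, group_b, :]
    # frames x nA x nB distance tensor; fine at desk scale
    d = np.linalg.norm(xa[:, :, None, :] - xb[:, None, :, :], axis=3)
    min_over_b = d.min(axis=2)  # frames x nA
    prob = np.empty(residues.size)
    per_res_contact = np.zeros((traj.n_frames, residues.size), dtype=bool)
    for k, r in enumerate(residues):
        cols = res_of_a == r
        per_res_contact[:, k] = min_over_b[:, cols].min(axis=1) < cutoff_nm
        prob[k] = per_res_contact[:, k].mean()
    return ContactProfile(
        residues=residues,
        probability=prob,
        any_contact=float(per_res_contact.any(axis=1).mean()),
        cutoff_nm=cutoff_nm,
        group_pair=group_pair,
    )
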