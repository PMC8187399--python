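"""Dihedral principal component analysis and free-energy surfaces.

Backbone phi/psi angles are periodic, so PCA is performed on their
(cos, sin) embedding: each frame's angle vector theta of length m maps to
(cos theta_1, sin theta_1, ..., cos theta_m, sin theta_m) and the
covariance of that 2m-dimensional representation is eigendecomposed.
This is the standard dPCA transform; because dihedrals are invariant
under rigid rotation/translation of the frames, so is the whole
analysis.

The free-energy surface over the first two components is the binned
Boltzmann inversion F_i = -RT ln(P_i / P_o), with P_i the population of
bin i and P_o that of the most populated bin, so F >= 0 everywhere, the
modal bin sits exactly at F = 0, and empty bins are masked (F undefined)
rather than capped. Minima basins are extracted by an ascending-F
watershed with persistence merging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory, backbone_indices

#: gas constant, kJ/(mol K)
R_GAS_KJ = 0.0083145


@dataclass
class DihedralSeries:
    """Backbone phi/psi time series: frames x (2 * n_internal_residues),
    radians, ordered (phi_i, psi_i) by residue."""

    angles: np.ndarray
    residues: np.ndarray  # internal residue indices, one per (phi, psi) pair

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] % 2:
            raise ValueError("angles must be frames x even column count")
        if self.angles.shape[1] != 2 * len(self.residues):
            raise ValueError("column count must be twice the residue count")
        if np.any(self.angles <= -np.pi) or np.any(self.angles > np.pi):
            raise ValueError("angles must lie in (-pi, pi]")

    def phi_psi(self) -> tuple[np.ndarray, np.ndarray]:
        """Split into (phi, psi) arrays, each frames x residues."""
        return self.angles[:, 0::2], self.angles[:, 1::2]


@dataclass
class PCModel:
    """Principal components of the sin/cos-embedded dihedral matrix."""

    mean: np.ndarray
    eigenvectors: np.ndarray  # columns, orthonormal
    eigenvalues: np.ndarray  # non-increasing

    def transform(self, dihedrals: DihedralSeries, k: int = 2) -> np.ndarray:
        emb = embed_angles(dihedrals.angles)
        return (emb - self.mean) @ self.eigenvectors[:, :k]


@dataclass
class FESGrid:
    """2-D binned free-energy surface over the leading two components."""

    counts: np.ndarray
    free_energy: np.ma.MaskedArray  # kJ/mol; masked where counts == 0
    xedges: np.ndarray
    yedges: np.ndarray
    temperature: float
    reference_index: tuple[int, int]
    frame_bins: np.ndarray  # flat bin index per frame
    r_gas: float = R_GAS_KJ

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class Basin:
    """Connected free-energy minimum: member bins (flat indices), the
    frames falling in them, and a representative frame."""

    bins: np.ndarray
    min_free_energy: float
    min_bin: int
    frame_indices: np.ndarray
    representative_frame: int
    members_labelled: dict = field(default_factory=dict)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Torsion angle (rad, in (-pi, pi]) of four points; vectorised over
    leading axes."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(b1n, n1)  # IUPAC sign: atan2((n1 x n2).b^, n1.n2)
    x = np.einsum("...i,...i", n1, n2)
    y = np.einsum("...i,...i", m1, n2)
    ang = np.arctan2(y, x)
    # map -pi to +pi so the half-open convention holds
    return np.where(ang <= -np.pi, ang + 2 * np.pi, ang)


def dihedral_timeseries(traj: Trajectory) -> DihedralSeries:
    """phi/psi series for internal peptide residues (termini excluded).

    phi_i uses C(i-1)-N(i)-CA(i)-C(i); psi_i uses N(i)-CA(i)-C(i)-N(i+1).
    Raises a topology error naming the residue if backbone atoms are
    missing.
    """
    residues = traj.peptide_residues()
    if residues.size < 3:
        raise ValueError("need at least 3 peptide residues for internal dihedrals")
    bb = {r: backbone_indices(traj, int(r)) for r in residues}
    internal = residues[1:-1]
    cols = []
    x = traj.coords
    for k, r in enumerate(internal):
        prev_r, next_r = residues[k], residues[k + 2]
        phi = dihedral(x[:, bb[prev_r]["C"]], x[:, bb[r]["N"]],
                       x[:, bb[r]["CA"]], x[:, bb[r]["C"]])
        psi = dihedral(x[:, bb[r]["N"]], x[:, bb[r]["CA"]],
                       x[:, bb[r]["C"]], x[:, bb[next_r]["N"]])
        cols.extend([phi, psi])
    return DihedralSeries(np.stack(cols, axis=1), internal)


def embed_angles(angles: np.ndarray) -> np.ndarray:
    """Interleaved (cos, sin) embedding, frames x 2m."""
    out = np.empty((angles.shape[0], 2 * angles.shape[1]))
    out[:, 0::2] = np.cos(angles)
    out[:, 1::2] = np.sin(angles)
    return out


def fit_dpca(dihedrals: DihedralSeries, k: int = 2) -> tuple[PCModel, np.ndarray]:
    """Eigendecompose the covariance of the embedded dihedral matrix.

    Returns the model and the projections onto the top ``k`` components.
    Constant columns simply yield zero eigenvalues.
    """
    emb = embed_angles(dihedrals.angles)
    if emb.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    mean = emb.mean(axis=0)
    cov = np.cov(emb, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    model = PCModel(mean=mean, eigenvectors=vecs, eigenvalues=vals)
    return model, (emb - mean) @ vecs[:, :k]


def build_fes(
    projections: np.ndarray,
    bins: int = 64,
    temperature: float = 300.0,
) -> FESGrid:
    """Boltzmann-inverted 2-D histogram of the first two projections.

    F_i = -RT ln(P_i/P_o) with the reference P_o at the most populated
    bin (ties: lowest flat index); empty bins are masked.
    """
    p = np.asarray(projections, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2:
        raise ValueError("projections must be frames x >=2")
    if bins < 2:
        raise ValueError("need at least 2 bins per axis")
    x, y = p[:, 0], p[:, 1]
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    ref_flat = int(np.argmax(counts))
    ref = np.unravel_index(ref_flat, counts.shape)
    with np.errstate(divide="ignore"):
        f = -R_GAS_KJ * temperature * np.log(counts / counts[ref])
    fes = np.ma.masked_array(f, mask=counts == 0)
    ix = np.clip(np.searchsorted(xe, x, side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(ye, y, side="right") - 1, 0, bins - 1)
    frame_bins = ix * bins + iy
    return FESGrid(
        counts=counts, free_energy=fes, xedges=xe, yedges=ye,
        temperature=temperature, reference_index=(int(ref[0]), int(ref[1])),
        frame_bins=frame_bins,
    )


def _neighbors(idx: int, shape: tuple[int, int]):
    i, j = divmod(idx, shape[1])
    if i > 0:
        yield idx - shape[1]
    if i < shape[0] - 1:
        yield idx + shape[1]
    if j > 0:
        yield idx - 1
    if j < shape[1] - 1:
        yield idx + 1


def locate_basins(
    fes: FESGrid,
    depth_cutoff: float = 2.0,
    traj: Trajectory | None = None,
    selection: np.ndarray | None = None,
) -> list[Basin]:
    """Free-energy minima basins by ascending-F watershed.

    Bins are visited in increasing F (ties: lowest flat index). A bin
    with no visited 4-neighbour seeds a new basin; otherwise it joins the
    deepest adjacent basin, and any other adjacent basin whose minimum
    lies within ``depth_cutoff`` of the meeting level is merged into it
    (persistence criterion). Basin membership is limited to bins within
    ``depth_cutoff`` of the basin minimum, so ``depth_cutoff=0`` reduces
    basins to their minimum bins. The representative frame is the RMSD
    medoid of the basin's frames when a trajectory is supplied, else the
    frame nearest the basin minimum in component space.
    """
    f = fes.free_energy
    shape = f.shape
    flat_f = f.filled(np.inf).ravel()
    valid = np.flatnonzero(~f.mask.ravel()) if np.ma.is_masked(f) else np.arange(flat_f.size)
    valid = valid[np.isfinite(flat_f[valid])]
    if valid.size == 0:
        return []
    order = valid[np.lexsort((valid, flat_f[valid]))]

    parent: list[int] = []
    min_f: list[float] = []
    min_bin: list[int] = []
    members: list[list[int]] = []
    owner = np.full(flat_f.size, -1)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for b in order:
        fb = flat_f[b]
        adjacent = {find(owner[nb]) for nb in _neighbors(b, shape) if owner[nb] >= 0}
        if not adjacent:
            bid = len(parent)
            parent.append(bid)
            min_f.append(fb)
            min_bin.append(int(b))
            members.append([int(b)])
            owner[b] = bid
            continue
        deepest = min(adjacent, key=lambda i: (min_f[i], min_bin[i]))
        for other in adjacent:
            if other != deepest and fb - min_f[other] <= depth_cutoff:
                parent[other] = deepest
                members[deepest].extend(members[other])
                members[other] = []
        owner[b] = deepest
        if fb <= min_f[deepest] + depth_cutoff:
            members[deepest].append(int(b))

    basins: list[Basin] = []
    for bid in range(len(parent)):
        if parent[bid] != bid or not members[bid]:
            continue
        # enforce the membership cap after merging
        keep = np.array(sorted(m for m in set(members[bid])
                               if flat_f[m] <= min_f[bid] + depth_cutoff))
        bin_set = set(keep.tolist())
        frames = np.flatnonzero(np.isin(fes.frame_bins, keep))
        rep = _representative(fes, frames, min_bin[bid], traj, selection)
        basins.append(Basin(
            bins=keep,
            min_free_energy=float(min_f[bid]),
            min_bin=int(min_bin[bid]),
            frame_indices=frames,
            representative_frame=rep,
        ))
    basins.sort(key=lambda b: (b.min_free_energy, b.min_bin))
    return basins


def _representative(
    fes: FESGrid,
    frames: np.ndarray,
    min_bin: int,
    traj: Trajectory | None,
    selection: np.ndarray | None,
) -> int:
    if frames.size == 0:
        return -1
    if traj is not None and frames.size > 1:
        from .metrics import pairwise_rmsd  # local to avoid cost when unused

        sub = Trajectory(traj.coords[frames], traj.topology)
        mat = pairwise_rmsd(sub, selection)
        return int(frames[np.argmin(mat.sum(axis=1))])
    # fall back: frame whose bin is the basin minimum, else first member
    in_min = frames[fes.frame_bins[frames] == min_bin]
    return int(in_min[0]) if in_min.size else int(frames[0])
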