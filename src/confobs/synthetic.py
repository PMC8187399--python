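"""Synthetic two-state peptide ensembles and spectrometer decays with
known ground truth.

The conformer generator emulates the statistical structure of a
helix/coil peptide ensemble with a fatty-acid-like ligand cluster: each
frame is drawn whole from a helical mode (backbone phi/psi around
(-60, -45) degrees) with probability ``helix_fraction``, otherwise from a
broad extended/coil mode, and the ligand pseudo-atoms sit within contact
range (< 0.55 nm) of a randomly chosen side-chain proton in a
``contact_fraction`` share of frames and > 1 nm away otherwise.
Coordinates are built from the sampled dihedrals by standard peptide
geometry (fixed bond lengths and angles, trans peptide bonds, one
pseudo-proton side chain per residue), which is sufficient for RMSD,
clustering and contact statistics at desk scale. Every generator records
its ground truth on the returned object so downstream estimators can be
tested as round trips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import HELIX_PHI_DEG, HELIX_PSI_DEG
from .nmr import DecayCurve, PeakTable, st_kernel, GAMMA_1H, HALF_SINE_SHAPE
from .trajectory import Trajectory

# idealised backbone geometry (nm / degrees), trans peptide bond
BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_CA_HB = 0.20  # pseudo side-chain proton, stands in for the whole side chain
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.7
ANGLE_C_N_CA = 121.9
ANGLE_N_CA_HB = 109.5

HELIX_PHI_MEAN = -60.0
HELIX_PSI_MEAN = -45.0
# coil mode: uniform over an extended-region box disjoint from the
# helical classifier window, so class labels are unambiguous
COIL_PHI_RANGE = (-180.0, -105.0)
COIL_PSI_RANGE = (90.0, 175.0)


@dataclass
class EnsembleSpec:
    """Parameters of the two-state helix/coil + ligand generator."""

    n_residues: int = 10
    n_frames: int = 500
    helix_fraction: float = 0.5
    n_ligand: int = 4
    contact_fraction: float = 0.5
    noise_sd: float = 0.0
    kappa: float = 100.0  # von Mises concentration of the helical mode
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.helix_fraction <= 1.0):
            raise ValueError("helix_fraction must be in [0, 1]")
        if not (0.0 <= self.contact_fraction <= 1.0):
            raise ValueError("contact_fraction must be in [0, 1]")
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues for backbone dihedrals")
        if self.n_frames < 1 or self.n_ligand < 0:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
          angle_deg: float, torsion_rad: np.ndarray | float) -> np.ndarray:
    """Place one atom per frame from three reference atoms (natural
    extension reference frame): bond length c-new, angle b-c-new and
    torsion a-b-c-new."""
    theta = np.deg2rad(angle_deg)
    phi = np.asarray(torsion_rad, dtype=float)
    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d = np.stack(
        [
            -bond * np.cos(theta) * np.ones_like(phi),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ],
        axis=-1,
    )
    rot = np.stack([bc, m, n], axis=-1)  # columns are the local frame
    return c + np.einsum("...ij,...j->...i", rot, d)


def _sample_helix_angles(rng: np.random.Generator, size: int, mean_deg: float,
                         window_deg: tuple[float, float], kappa: float) -> np.ndarray:
    """Von Mises draws around the helical mean, rejection-truncated to the
    helical classifier window so the class label is exact by construction."""
    lo, hi = np.deg2rad(window_deg[0]), np.deg2rad(window_deg[1])
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.vonmises(np.deg2rad(mean_deg), kappa, size=todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def gen_conformer_ensemble(spec: EnsembleSpec) -> Trajectory:
    """Generate a two-state helix/coil ensemble with a ligand cluster.

    Each frame's state (helix vs coil) is one Bernoulli(helix_fraction)
    draw applied to every residue, so the ensemble has exactly two
    conformational modes; per-frame state and contact labels are recorded
    in ``ground_truth``. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    nf, nr = spec.n_frames, spec.n_residues

    helix_frame = rng.random(nf) < spec.helix_fraction
    phi = np.empty((nf, nr))
    psi = np.empty((nf, nr))
    # coil draws for everything, then overwrite helix frames
    phi[:] = rng.uniform(*np.deg2rad(COIL_PHI_RANGE), size=(nf, nr))
    psi[:] = rng.uniform(*np.deg2rad(COIL_PSI_RANGE), size=(nf, nr))
    n_h = int(helix_frame.sum())
    if n_h:
        phi[helix_frame] = _sample_helix_angles(
            rng, n_h * nr, HELIX_PHI_MEAN, HELIX_PHI_DEG, spec.kappa
        ).reshape(n_h, nr)
        psi[helix_frame] = _sample_helix_angles(
            rng, n_h * nr, HELIX_PSI_MEAN, HELIX_PSI_DEG, spec.kappa
        ).reshape(n_h, nr)

    # build backbone N, CA, C (+ pseudo side-chain proton HB) per residue
    coords = np.zeros((nf, nr * 4, 3))
    th = np.deg2rad(ANGLE_N_CA_C)
    n_prev = np.zeros((nf, 3))
    ca_prev = np.tile([BOND_N_CA, 0.0, 0.0], (nf, 1))
    c_prev = ca_prev + np.array([-BOND_CA_C * np.cos(th), BOND_CA_C * np.sin(th), 0.0])
    for i in range(nr):
        if i == 0:
            n_i, ca_i, c_i = n_prev, ca_prev, c_prev
        else:
            n_i = _nerf(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi[:, i - 1])
            ca_i = _nerf(ca_prev, c_prev, n_i, BOND_N_CA, ANGLE_C_N_CA, np.pi)
            c_i = _nerf(c_prev, n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi[:, i])
        hb_i = _nerf(c_i, n_i, ca_i, BOND_CA_HB, ANGLE_N_CA_HB, np.deg2rad(-120.0))
        coords[:, 4 * i] = n_i
        coords[:, 4 * i + 1] = ca_i
        coords[:, 4 * i + 2] = c_i
        coords[:, 4 * i + 3] = hb_i
        n_prev, ca_prev, c_prev = n_i, ca_i, c_i

    # ligand pseudo-atoms: near a random side-chain proton in contact
    # frames, well clear of the whole peptide otherwise
    contact_frame = rng.random(nf) < spec.contact_fraction
    contact_res = rng.integers(0, nr, size=nf)
    lig = np.zeros((nf, spec.n_ligand, 3))
    if spec.n_ligand:
        centroid = coords.mean(axis=1)
        rmax = np.linalg.norm(coords - centroid[:, None], axis=2).max(axis=1)
        for f in range(nf):
            if contact_frame[f]:
                anchor = coords[f, 4 * contact_res[f] + 3]
                dirs = rng.normal(size=(spec.n_ligand, 3))
                dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
                dist = rng.uniform(0.30, 0.50, size=spec.n_ligand)
                lig[f] = anchor + dirs * dist[:, None]
            else:
                dirs = rng.normal(size=(spec.n_ligand, 3))
                dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
                dist = rmax[f] + 1.5 + rng.uniform(0.0, 0.5, size=spec.n_ligand)
                lig[f] = centroid[f] + dirs * dist[:, None]
        coords = np.concatenate([coords, lig], axis=1)

    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)

    rows = []
    for i in range(nr):
        for name, el, proton in (("N", "N", False), ("CA", "C", False),
                                 ("C", "C", False), ("HB", "H", True)):
            rows.append((name, el, i, "ALA", "peptide", proton))
    for j in range(spec.n_ligand):
        rows.append(("OLP", "H", nr + j, "OLA", "ligand", True))
    topology = pd.DataFrame(rows, columns=[
        "atom_name", "element", "res_index", "res_name", "group", "is_proton"])

    return Trajectory(
        coords,
        topology,
        ground_truth={
            "frame_is_helix": helix_frame,
            "frame_in_contact": contact_frame,
            "contact_residue": contact_res,
            "phi": phi,
            "psi": psi,
            "spec": spec,
        },
    )


def gen_pfg_decay(
    d_coeff: float,
    gradients: np.ndarray,
    delta: float,
    big_delta: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    i0: float = 1.0,
    gamma: float = GAMMA_1H,
    shape_factor: float = HALF_SINE_SHAPE,
) -> DecayCurve:
    """Pulsed-field-gradient decay I(g) = I0 exp(-D k(g)) with
    multiplicative Gaussian noise of relative size ``noise_sd``."""
    if d_coeff <= 0:
        raise ValueError("diffusion coefficient must be positive")
    g = np.asarray(gradients, dtype=float)
    rng = np.random.default_rng(seed)
    clean = i0 * np.exp(-d_coeff * st_kernel(g, delta, big_delta, gamma, shape_factor))
    noisy = clean * (1.0 + noise_sd * rng.standard_normal(g.size)) if noise_sd > 0 else clean
    return DecayCurve(
        g, noisy, kind="pfg", delta=delta, big_delta=big_delta,
        ground_truth={"D": d_coeff, "I0": i0, "gamma": gamma, "shape_factor": shape_factor},
    )


def gen_cpmg_decay(
    t2: float,
    delays: np.ndarray,
    i0: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DecayCurve:
    """CPMG decay I(t) = I0 exp(-t/T2) with multiplicative noise."""
    if t2 <= 0:
        raise ValueError("T2 must be positive")
    t = np.asarray(delays, dtype=float)
    rng = np.random.default_rng(seed)
    clean = i0 * np.exp(-t / t2)
    noisy = clean * (1.0 + noise_sd * rng.standard_normal(t.size)) if noise_sd > 0 else clean
    return DecayCurve(t, noisy, kind="cpmg", ground_truth={"T2": t2, "I0": i0})


def gen_peak_table(stoich: float, seed: int = 0, noise_sd: float = 0.0) -> PeakTable:
    """Peak-area table whose proton-normalised ligand/peptide area ratio
    equals ``stoich`` (up to optional multiplicative noise).

    Regions mimic well-resolved 1D 1H windows: two peptide regions
    (aromatic, methyl) and two ligand regions (olefinic, methylene).
    """
    if stoich <= 0:
        raise ValueError("stoichiometry must be positive")
    rng = np.random.default_rng(seed)
    scale = 100.0  # arbitrary intensity units per proton of the peptide
    regions = [
        ("peptide", "aromatic", 10, 1.0),
        ("peptide", "methyl", 12, 1.0),
        ("ligand", "olefinic", 2, stoich),
        ("ligand", "methylene", 20, stoich),
    ]
    rows = []
    for species, region, protons, mols in regions:
        area = scale * protons * mols
        if noise_sd > 0:
            area *= 1.0 + noise_sd * rng.standard_normal()
        rows.append((species, region, area, protons))
    frame = pd.DataFrame(rows, columns=["species", "region", "area", "protons_per_molecule"])
    return PeakTable(frame, ground_truth={"stoichiometry": stoich})
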