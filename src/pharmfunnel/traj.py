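"""Trajectory analytics: RMSD/RMSF, hydrogen bonds, contacts, PCA, FEL.

All analyses operate on the :class:`~pharmfunnel.chemio.Trajectory`
container (frames in Angstrom).  Superposition is least-squares Kabsch;
hydrogen bonds use the geometric donor-acceptor distance / H-D-A angle
criterion; the free-energy landscape is the Boltzmann inversion
``G_i = -k_B T ln(P_i / P_max)`` of a 2D histogram over collective
coordinates (by default the first two principal components of the
coordinate covariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemio import Trajectory

#: Boltzmann constant, kcal/mol/K
KB = 0.0019872

DEFAULT_TEMPERATURE = 300.0
HBOND_DISTANCE_CUTOFF = 3.5   # donor-acceptor, A
HBOND_ANGLE_CUTOFF = 30.0     # H-D-A, degrees
CONTACT_CUTOFF = 4.0          # A


class TrajAnalysisError(Exception):
    pass


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    ref: np.ndarray, mobile: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``ref``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to ``ref``.
    The rotation is proper (determinant +1).  Requires >= 3 atoms and a
    non-degenerate (non-collinear) geometry.
    """
    ref = np.asarray(ref, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if ref.shape != mobile.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise TrajAnalysisError("coordinate sets must both be (n, 3)")
    n = len(ref)
    if n < 3:
        raise TrajAnalysisError("superposition needs at least 3 atoms")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mobile - mobile.mean(axis=0)
    # collinearity check: rank of either centered cloud < 2
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise TrajAnalysisError("degenerate (collinear) reference selection")
    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = ref.mean(axis=0) - rot @ mobile.mean(axis=0)
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def _apply_fit(frame, ref, fit_idx):
    rot, trans, _ = kabsch_superpose(ref[fit_idx], frame[fit_idx])
    return frame @ rot.T + trans


def rmsd_series(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    ref_frame: int = 0,
    fit_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD of ``selection`` after fitting on ``fit_selection``.

    Defaults measure every atom and fit on every atom, mirroring the
    usual "ligand RMSD after receptor fit" when selections are given.
    """
    xyz = traj.xyz()
    n_atoms = traj.n_atoms
    sel = np.arange(n_atoms) if selection is None else np.asarray(selection)
    fit = np.arange(n_atoms) if fit_selection is None else np.asarray(fit_selection)
    if len(sel) == 0 or len(fit) == 0:
        raise TrajAnalysisError("empty selection")
    ref = xyz[ref_frame]
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(xyz):
        moved = _apply_fit(frame, ref, fit)
        out[i] = np.sqrt(np.mean(np.sum((moved[sel] - ref[sel]) ** 2, axis=1)))
    return out


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation after per-frame fitting.

    RMSF_i = sqrt(<|x_i(t) - <x_i>|^2>) with frames first superposed on
    ``fit_selection`` against frame 0.
    """
    xyz = traj.xyz()
    n_atoms = traj.n_atoms
    sel = np.arange(n_atoms) if selection is None else np.asarray(selection)
    fit = np.arange(n_atoms) if fit_selection is None else np.asarray(fit_selection)
    if len(sel) == 0 or len(fit) == 0:
        raise TrajAnalysisError("empty selection")
    ref = xyz[0]
    fitted = np.stack([_apply_fit(f, ref, fit) for f in xyz])
    mean_pos = fitted[:, sel].mean(axis=0)
    dev2 = np.sum((fitted[:, sel] - mean_pos) ** 2, axis=2)
    return np.sqrt(dev2.mean(axis=0))


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    da_distance: float
    ha_distance: float
    hda_angle: float


def _donor_hydrogens(coords, elements, donors, max_dh=1.25):
    """Hydrogens covalently attached to each donor, by proximity."""
    h_idx = [i for i, e in enumerate(elements) if e == "H"]
    if not h_idx:
        raise TrajAnalysisError(
            "no hydrogens present; run a normalization pass that adds "
            "explicit hydrogens before hydrogen-bond analysis"
        )
    pairs = []
    for d in donors:
        for h in h_idx:
            if np.linalg.norm(coords[h] - coords[d]) <= max_dh:
                pairs.append((d, h))
    return pairs


def hydrogen_bonds_frame(
    coords: np.ndarray,
    elements: list[str],
    donors: np.ndarray,
    acceptors: np.ndarray,
    d_cut: float = HBOND_DISTANCE_CUTOFF,
    angle_cut: float = HBOND_ANGLE_CUTOFF,
) -> list[HBond]:
    """Geometric hydrogen bonds in one frame.

    A bond requires donor-acceptor distance <= ``d_cut`` and H-D-A angle
    <= ``angle_cut`` (the GROMACS convention).  Both the D-A and H...A
    distances are reported since published tables are ambiguous about
    which is printed.
    """
    coords = np.asarray(coords, dtype=float)
    dh_pairs = _donor_hydrogens(coords, elements, donors)
    bonds = []
    for d, h in dh_pairs:
        for a in acceptors:
            if a == d or a == h:
                continue
            da = np.linalg.norm(coords[a] - coords[d])
            if da > d_cut:
                continue
            v_dh = coords[h] - coords[d]
            v_da = coords[a] - coords[d]
            cosang = np.dot(v_dh, v_da) / (
                np.linalg.norm(v_dh) * np.linalg.norm(v_da)
            )
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle <= angle_cut:
                ha = float(np.linalg.norm(coords[a] - coords[h]))
                bonds.append(HBond(int(d), int(h), int(a), float(da), ha, angle))
    return bonds


def hydrogen_bonds(
    traj: Trajectory,
    donors: np.ndarray,
    acceptors: np.ndarray,
    d_cut: float = HBOND_DISTANCE_CUTOFF,
    angle_cut: float = HBOND_ANGLE_CUTOFF,
) -> tuple[np.ndarray, list[list[HBond]]]:
    """Per-frame hydrogen-bond counts and bond lists over a trajectory."""
    elements = [m.element for m in traj.meta]
    per_frame = [
        hydrogen_bonds_frame(f, elements, donors, acceptors, d_cut, angle_cut)
        for f in traj.frames
    ]
    counts = np.array([len(b) for b in per_frame])
    return counts, per_frame


def hbond_residue_table(traj: Trajectory, bonds_per_frame) -> "object":
    """Aggregate bonds by (donor residue, acceptor residue).

    Returns a DataFrame with occupancy (fraction of frames), mean D-A and
    H...A distances and mean H-D-A angle per residue pair.
    """
    import pandas as pd

    rows: dict[tuple, list] = {}
    for frame_bonds in bonds_per_frame:
        for b in frame_bonds:
            dm, am = traj.meta[b.donor], traj.meta[b.acceptor]
            key = (
                f"{dm.residue_name}{dm.residue_number}",
                f"{am.residue_name}{am.residue_number}",
            )
            rows.setdefault(key, []).append((b.da_distance, b.ha_distance, b.hda_angle))
    out = []
    n_frames = traj.n_frames
    for (dres, ares), vals in sorted(rows.items()):
        arr = np.array(vals)
        out.append(
            {
                "donor_residue": dres,
                "acceptor_residue": ares,
                "occupancy": len(vals) / n_frames,
                "mean_da_distance": arr[:, 0].mean(),
                "mean_ha_distance": arr[:, 1].mean(),
                "mean_hda_angle": arr[:, 2].mean(),
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# distances and contacts
# ---------------------------------------------------------------------------

def _check_groups(group_a, group_b):
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if len(a) == 0 or len(b) == 0:
        raise TrajAnalysisError("empty atom group")
    if set(a.tolist()) & set(b.tolist()):
        raise TrajAnalysisError("atom groups overlap")
    return a, b


def min_distance_series(
    traj: Trajectory, group_a: np.ndarray, group_b: np.ndarray
) -> np.ndarray:
    """Per-frame minimum distance over all cross pairs, A."""
    a, b = _check_groups(group_a, group_b)
    out = np.empty(traj.n_frames)
    for i, f in enumerate(traj.frames):
        d = f[a][:, None, :] - f[b][None, :, :]
        out[i] = np.sqrt(np.sum(d * d, axis=-1)).min()
    return out


def contact_count_series(
    traj: Trajectory,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = CONTACT_CUTOFF,
) -> np.ndarray:
    """Per-frame count of cross atom pairs within ``cutoff`` A."""
    a, b = _check_groups(group_a, group_b)
    out = np.empty(traj.n_frames, dtype=int)
    for i, f in enumerate(traj.frames):
        d = f[a][:, None, :] - f[b][None, :, :]
        out[i] = int(np.sum(np.sum(d * d, axis=-1) <= cutoff * cutoff))
    return out


# ---------------------------------------------------------------------------
# covariance PCA
# ---------------------------------------------------------------------------

def pca_covariance(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    superpose: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decomposition of the coordinate covariance.

    Frames are optionally superposed on frame 0 first.  Returns
    ``(eigenvalues, eigenvectors, explained_fractions)`` with eigenpairs
    sorted descending; eigenvectors are columns over the 3N selected
    coordinates.
    """
    if traj.n_frames < 3:
        raise TrajAnalysisError("PCA needs at least 3 frames")
    sel = (
        np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    )
    if len(sel) == 0:
        raise TrajAnalysisError("empty selection")
    xyz = traj.xyz()
    if superpose:
        ref = xyz[0]
        xyz = np.stack([_apply_fit(f, ref, sel) for f in xyz])
    flat = xyz[:, sel].reshape(traj.n_frames, -1)
    centered = flat - flat.mean(axis=0)
    cov = centered.T @ centered / (traj.n_frames - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    total = vals.sum()
    fractions = vals / total if total > 0 else np.zeros_like(vals)
    return vals, vecs, fractions


def project(
    traj: Trajectory,
    eigenvectors: np.ndarray,
    selection: np.ndarray | None = None,
    n_components: int = 2,
    superpose: bool = True,
) -> np.ndarray:
    """Project each frame onto the top eigenvectors -> (n_frames, k)."""
    sel = (
        np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    )
    xyz = traj.xyz()
    if superpose:
        ref = xyz[0]
        xyz = np.stack([_apply_fit(f, ref, sel) for f in xyz])
    flat = xyz[:, sel].reshape(traj.n_frames, -1)
    centered = flat - flat.mean(axis=0)
    return centered @ eigenvectors[:, :n_components]


# ---------------------------------------------------------------------------
# free-energy landscape
# ---------------------------------------------------------------------------

@dataclass
class FELGrid:
    """Boltzmann-inverted 2D free-energy surface over (PC1, PC2)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    G: np.ndarray            # kcal/mol, min exactly 0 at the modal bin
    temperature: float

    @property
    def minimum_bin(self) -> tuple[int, int]:
        return tuple(np.unravel_index(np.argmax(self.counts), self.counts.shape))


def free_energy_landscape(
    points: np.ndarray,
    bins: int | tuple[int, int] = 32,
    temperature: float = DEFAULT_TEMPERATURE,
) -> FELGrid:
    """G_i = -k_B T ln(P_i / P_max) from a 2D histogram of ``points``.

    Empty bins are capped at max(G over occupied bins) + 1 k_B T so the
    surface stays finite.  The global minimum is exactly 0 at the most
    populated bin.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 1:
        raise TrajAnalysisError("need an (n, 2) array with n >= 1")
    if isinstance(bins, int):
        if bins < 1:
            raise TrajAnalysisError("bin count must be >= 1")
        bins = (bins, bins)
    elif min(bins) < 1:
        raise TrajAnalysisError("bin count must be >= 1")
    counts, x_edges, y_edges = np.histogram2d(
        points[:, 0], points[:, 1], bins=bins
    )
    kt = KB * temperature
    p_max = counts.max()
    occupied = counts > 0
    G = np.zeros_like(counts)
    G[occupied] = -kt * np.log(counts[occupied] / p_max)
    cap = G[occupied].max() + kt
    G[~occupied] = cap
    return FELGrid(x_edges, y_edges, counts, G, temperature)
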