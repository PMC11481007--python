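"""Synthetic inputs with controlled ground truth.

Every stage of the screening funnel can be exercised without proprietary
software or external databases: this module generates

* feature-embedded active/decoy libraries for the pharmacophore matcher
  (abstract feature clouds with exact geometric control, each paired
  with a small real scaffold SMILES for end-to-end smoke tests),
* EC50 activity tables with a planted structure-activity rule
  (carboxylic acid + at least two aromatic rings => potent),
* ligand-in-pocket toy trajectories with Gaussian wobble, linear drift
  or planted collective modes,
* toy receptor-ligand complexes with per-atom nonbonded parameters so
  interaction energies have brute-force closed-form oracles.

Every generator is a pure function of its spec (seed included); there is
no global random state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chemio import Atom, AtomMeta, Molecule, Residue, Structure, Trajectory
from .energetics import ToyForceField
from .pharmacophore import (
    FeatureCloud,
    FeaturePoint,
    PharmModel,
    match_bruteforce,
)


class GenerationError(Exception):
    pass


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def embed_from_distances(model: PharmModel) -> np.ndarray:
    """Classical MDS embedding of a model's complete distance matrix.

    Requires every feature pair to be constrained; raises if the matrix
    is incomplete or not embeddable in 3D (triangle-inequality
    violations show up as strongly negative Gram eigenvalues).
    """
    n = model.n_features
    dmat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = model.constraint(i, j)
        if d is None:
            raise GenerationError(
                "embedding needs a complete pairwise distance matrix"
            )
        dmat[i, j] = dmat[j, i] = d
    d2 = dmat ** 2
    j_mat = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j_mat @ d2 @ j_mat
    vals, vecs = np.linalg.eigh(gram)
    if vals.min() < -1e-6 * max(vals.max(), 1.0) - 1e-8:
        if abs(vals.min()) > 0.05 * vals.max():
            raise GenerationError(
                "distance constraints are not embeddable in 3D "
                "(triangle inequality violated)"
            )
    top = np.argsort(vals)[::-1][:3]
    coords = vecs[:, top] * np.sqrt(np.clip(vals[top], 0.0, None))
    return coords


# ---------------------------------------------------------------------------
# feature library
# ---------------------------------------------------------------------------

@dataclass
class LibrarySpec:
    """Recipe for a synthetic active/decoy feature library."""

    n_actives: int
    n_decoys: int
    model: PharmModel
    geometric_noise_sd: float = 0.0
    seed: int = 0
    reference_points: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_actives < 0 or self.n_decoys < 0:
            raise GenerationError("counts must be nonnegative")
        if self.geometric_noise_sd < 0:
            raise GenerationError("noise sd must be nonnegative")
        if self.model.n_features < 2:
            raise GenerationError("model needs at least 2 features")


# small real scaffolds drawn from the same template space as the activity
# tables: rule-positive ones carry a carboxylic acid + >= 2 aromatic rings
# and a hydrophobic chain; rule-negative ones break the rule
_ACTIVE_SCAFFOLDS = (
    "OC(=O)Cc1ccc(-c2ccccc2)cc1CCCC",
    "OC(=O)CCc1ccc(Cc2ccccc2)cc1CCC",
    "OC(=O)Cc1ccc(Oc2ccc(F)cc2)cc1CC",
    "OC(=O)CCc1ccc(-c2ccccc2)cc1OC",
)
_DECOY_SCAFFOLDS = (
    "OCCc1ccccc1",
    "CCOC(=O)Cc1ccc(-c2ccccc2)cc1",
    "NC(=O)CC1CCCCC1",
    "OCCC1CCCCC1C",
    "CCOC(=O)CC1CCCCC1",
    "NC(=O)Cc1ccccc1C",
)


def _cloud_from_points(
    mol_id: str, kinds: Sequence[str], pts: np.ndarray, scaffold: str
) -> FeatureCloud:
    points = [FeaturePoint(k, p) for k, p in zip(kinds, pts)]
    return FeatureCloud(mol_id, points, {"scaffold_smiles": scaffold})


def make_feature_library(
    spec: LibrarySpec,
) -> tuple[list[FeatureCloud], dict[str, bool]]:
    """Generate actives/decoys as feature clouds with ground-truth labels.

    Actives are the model's reference geometry plus i.i.d. Gaussian noise
    (sd ``geometric_noise_sd`` per coordinate) under a random rigid
    motion.  Decoys displace both required features far outside their
    constraints (>2x tolerance) and are rejection-checked to admit no
    k-of-n match.  Ids sort actives before decoys; labels map id->True
    for actives.
    """
    model = spec.model
    ref = (
        np.asarray(spec.reference_points, dtype=float)
        if spec.reference_points is not None
        else embed_from_distances(model)
    )
    if ref.shape != (model.n_features, 3):
        raise GenerationError("reference points must be (n_features, 3)")
    kinds = [f.kind for f in model.features]
    rng = np.random.default_rng(spec.seed)
    width = len(str(max(spec.n_actives + spec.n_decoys, 1)))

    clouds: list[FeatureCloud] = []
    labels: dict[str, bool] = {}

    for k in range(spec.n_actives):
        pts = ref + rng.normal(scale=spec.geometric_noise_sd, size=ref.shape)
        rot = _random_rotation(rng)
        pts = pts @ rot.T + rng.uniform(-20, 20, size=3)
        mol_id = f"act_{k:0{width}d}"
        scaffold = _ACTIVE_SCAFFOLDS[k % len(_ACTIVE_SCAFFOLDS)]
        clouds.append(_cloud_from_points(mol_id, kinds, pts, scaffold))
        labels[mol_id] = True

    # displace at least two features far enough that each broken feature
    # violates every constraint it participates in by > 2x tolerance
    n_break = max(2, sum(1 for f in model.features if f.required))
    max_d = max(model.distances.values())
    for k in range(spec.n_decoys):
        for _attempt in range(50):
            pts = ref + rng.normal(scale=spec.geometric_noise_sd, size=ref.shape)
            required_idx = [
                i for i, f in enumerate(model.features) if f.required
            ]
            others = [i for i in range(model.n_features) if i not in required_idx]
            rng.shuffle(others)
            broken = (required_idx + others)[:n_break]
            for b in broken:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                shift = max_d * (2.0 + 3.0 * (1.0 + model.tolerance)) \
                    + rng.uniform(0, 5)
                pts[b] = pts[b] + direction * shift
            rot = _random_rotation(rng)
            cand = pts @ rot.T + rng.uniform(-20, 20, size=3)
            cloud = _cloud_from_points(
                f"dec_{k:0{width}d}", kinds, cand,
                _DECOY_SCAFFOLDS[k % len(_DECOY_SCAFFOLDS)],
            )
            if match_bruteforce(model, cloud) is None:
                break
        else:  # pragma: no cover - overwhelmingly unlikely
            raise GenerationError("could not generate a non-matching decoy")
        clouds.append(cloud)
        labels[cloud.id] = False

    return clouds, labels


# ---------------------------------------------------------------------------
# activity tables
# ---------------------------------------------------------------------------

@dataclass
class ActivityTableSpec:
    """Recipe for an EC50 activity table with a planted descriptor rule.

    The rule: molecules bearing a carboxylic acid and >= 2 aromatic rings
    are potent (base EC50 ~ 100 nM), all others weak (~ 31.6 uM).  Log-
    normal noise of ``ec50_noise_sd`` log10 units multiplies the base
    potency, mirroring how potency measurements scatter.
    """

    n: int = 2000
    active_fraction: float = 0.5
    ec50_noise_sd: float = 0.3
    seed: int = 0
    active_log10_nM: float = 2.0   # 100 nM
    inactive_log10_nM: float = 4.5  # ~31.6 uM

    def __post_init__(self) -> None:
        if not (0.0 <= self.active_fraction <= 1.0):
            raise GenerationError("active_fraction must lie in [0, 1]")
        if self.n < 1:
            raise GenerationError("n must be >= 1")


_HEADS = {
    # head SMILES fragment -> satisfies the acid part of the rule
    "OC(=O)C": True,
    "OC(=O)CC": True,
    "CCOC(=O)C": False,   # ester
    "OCC": False,         # alcohol
    "NC(=O)C": False,     # amide
}
_RING_BLOCKS = {
    # aromatic block -> ring count contributed
    "c1ccc(-c2ccccc2)cc1": 2,
    "c1ccc(Cc2ccccc2)cc1": 2,
    "c1ccc(Oc2ccc(F)cc2)cc1": 2,
    "c1ccccc1": 1,
    "C1CCCCC1": 0,
}
_TAILS = ("", "C", "CC", "CCC", "CCCC", "CCCCC", "OC", "N(C)C")
_SUBS = ("", "C", "F", "OC")


def _assemble_smiles(head: str, ring: str, tail: str, sub: str) -> str:
    # linear concatenation: head attaches to the ring block, tail and a
    # small substituent extend the chain on the far side
    return head + ring + tail + sub


def _rule_positive(head: str, ring: str) -> bool:
    return _HEADS[head] and _RING_BLOCKS[ring] >= 2


def make_activity_table(spec: ActivityTableSpec):
    """Generate an activity table as a DataFrame (id, smiles, ec50_nM).

    Potency labels derive from EC50 <= 1000 nM downstream; the planted
    rule determines the base potency exactly at noise 0.  The realized
    rule-positive fraction is binomial around ``active_fraction``.
    """
    import pandas as pd
    from rdkit import Chem

    rng = np.random.default_rng(spec.seed)
    pos_combos = []
    neg_combos = []
    for head, ring, tail, sub in itertools.product(
        _HEADS, _RING_BLOCKS, _TAILS, _SUBS
    ):
        (pos_combos if _rule_positive(head, ring) else neg_combos).append(
            (head, ring, tail, sub)
        )

    rows = []
    width = len(str(spec.n))
    for i in range(spec.n):
        is_pos = bool(rng.random() < spec.active_fraction)
        pool = pos_combos if is_pos else neg_combos
        head, ring, tail, sub = pool[rng.integers(len(pool))]
        smi = _assemble_smiles(head, ring, tail, sub)
        rd = Chem.MolFromSmiles(smi)
        if rd is None:  # pragma: no cover - templates are all valid
            raise GenerationError(f"template produced invalid SMILES {smi!r}")
        base = spec.active_log10_nM if is_pos else spec.inactive_log10_nM
        log_ec50 = base + rng.normal(scale=spec.ec50_noise_sd)
        rows.append(
            {
                "id": f"cmpd_{i:0{width}d}",
                "smiles": Chem.MolToSmiles(rd),
                "ec50_nM": float(10.0 ** log_ec50),
                "rule_positive": is_pos,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def make_trajectory(
    pose: Structure,
    n_frames: int,
    wobble_sd: float,
    drift: float | np.ndarray | None = None,
    seed: int = 0,
    dt_ps: float = 1.0,
) -> Trajectory:
    """Frames = pose + i.i.d. Gaussian wobble + optional linear drift.

    ``drift`` may be a scalar (A/frame along +x) or a 3-vector; wobble is
    independent per atom, per frame and per coordinate, so for two
    independently perturbed copies E[RMSD^2] = 6 * wobble_sd^2.
    """
    if n_frames < 2:
        raise GenerationError("a trajectory needs at least 2 frames")
    base, meta = _structure_arrays(pose)
    rng = np.random.default_rng(seed)
    if drift is None:
        drift_vec = np.zeros(3)
    elif np.isscalar(drift):
        drift_vec = np.array([float(drift), 0.0, 0.0])
    else:
        drift_vec = np.asarray(drift, dtype=float)
    frames = [
        base + i * drift_vec + rng.normal(scale=wobble_sd, size=base.shape)
        if wobble_sd > 0
        else base + i * drift_vec
        for i in range(n_frames)
    ]
    return Trajectory(frames, meta, dt_ps)


def make_mode_trajectory(
    pose: Structure,
    n_frames: int,
    amplitudes: Sequence[float] = (3.0, 1.5),
    noise_sd: float = 0.01,
    seed: int = 0,
    dt_ps: float = 1.0,
) -> Trajectory:
    """Plant collective motions: orthonormal random modes with sinusoidal
    time courses at incommensurate frequencies, plus tiny isotropic noise.

    With K amplitudes the first K principal components of the coordinate
    covariance capture essentially all variance.
    """
    if n_frames < 2:
        raise GenerationError("a trajectory needs at least 2 frames")
    base, meta = _structure_arrays(pose)
    n_dof = base.size
    rng = np.random.default_rng(seed)
    k = len(amplitudes)
    raw = rng.normal(size=(n_dof, k))
    modes, _ = np.linalg.qr(raw)  # orthonormal columns
    freqs = 2.0 * np.pi * (0.8 + 0.61803 * np.arange(k)) / n_frames * 7.0
    phases = rng.uniform(0, 2 * np.pi, size=k)
    frames = []
    for t in range(n_frames):
        disp = sum(
            amplitudes[m] * np.sin(freqs[m] * t + phases[m]) * modes[:, m]
            for m in range(k)
        )
        frame = base + disp.reshape(base.shape)
        if noise_sd > 0:
            frame = frame + rng.normal(scale=noise_sd, size=base.shape)
        frames.append(frame)
    return Trajectory(frames, meta, dt_ps)


def _structure_arrays(pose: Structure) -> tuple[np.ndarray, list[AtomMeta]]:
    coords = []
    meta = []
    for chain_id, res, name, atom in pose.iter_atoms():
        coords.append(atom.coords)
        meta.append(AtomMeta(name, atom.element, res.name, res.number, chain_id))
    if not coords:
        raise GenerationError("pose has no atoms")
    return np.array(coords, dtype=float), meta


# ---------------------------------------------------------------------------
# toy complexes
# ---------------------------------------------------------------------------

def make_toy_complex(
    n_receptor_atoms: int,
    n_ligand_atoms: int,
    ff: ToyForceField | None = None,
    seed: int = 0,
    min_separation: float = 2.2,
) -> tuple[Structure, ToyForceField]:
    """Random receptor+ligand point complex with nonbonded parameters.

    Receptor atoms fill a cube, ligand atoms an adjacent pocket; all
    pair distances exceed ``min_separation`` so LJ/Coulomb sums are
    finite.  When ``ff`` is None, per-atom parameters are drawn:
    sigma ~ U(2.5, 3.5) A, epsilon ~ U(0.05, 0.2) kcal/mol,
    q ~ U(-0.5, 0.5) e.
    """
    if n_receptor_atoms < 1 or n_ligand_atoms < 1:
        raise GenerationError("complex needs at least 1 atom on each side")
    rng = np.random.default_rng(seed)
    n = n_receptor_atoms + n_ligand_atoms
    coords: list[np.ndarray] = []
    box = max(8.0, (n * 30.0) ** (1.0 / 3.0))
    for i in range(n):
        offset = np.zeros(3) if i < n_receptor_atoms else np.array([box + 2.0, 0, 0])
        for _ in range(2000):
            p = rng.uniform(0, box, size=3) + offset
            if all(np.linalg.norm(p - c) >= min_separation for c in coords):
                coords.append(p)
                break
        else:  # pragma: no cover
            raise GenerationError("could not place atoms without overlap")
    coords_arr = np.array(coords)
    if ff is None:
        ff = ToyForceField(
            sigma=rng.uniform(2.5, 3.5, size=n),
            epsilon=rng.uniform(0.05, 0.2, size=n),
            q=rng.uniform(-0.5, 0.5, size=n),
        )
    rec_atoms = [Atom("C", c) for c in coords_arr[:n_receptor_atoms]]
    lig_atoms = [Atom("C", c) for c in coords_arr[n_receptor_atoms:]]
    s = Structure(id="toy_complex")
    s.chains["R"] = [
        Residue("REC", 1, rec_atoms, [f"C{i+1}" for i in range(n_receptor_atoms)])
    ]
    s.chains["L"] = [
        Residue(
            "LIG", 1, lig_atoms,
            [f"C{i+1}" for i in range(n_ligand_atoms)], is_ligand=True,
        )
    ]
    return s, ff


def make_pocket_pose(
    n_receptor_atoms: int = 30, n_ligand_atoms: int = 10, seed: int = 0
) -> Structure:
    """A compact ligand-in-pocket pose for trajectory fixtures.

    Receptor atoms form a loose shell around a central ligand cluster,
    so ligand-receptor contacts and minimum distances are nontrivial.
    """
    rng = np.random.default_rng(seed)
    lig = rng.normal(scale=1.5, size=(n_ligand_atoms, 3))
    shell_dirs = rng.normal(size=(n_receptor_atoms, 3))
    shell_dirs /= np.linalg.norm(shell_dirs, axis=1, keepdims=True)
    rec = shell_dirs * rng.uniform(5.0, 8.0, size=(n_receptor_atoms, 1))
    s = Structure(id="pocket")
    s.chains["R"] = [
        Residue(
            "ALA", i + 1, [Atom("C", rec[i])], ["CA"]
        )
        for i in range(n_receptor_atoms)
    ]
    s.chains["L"] = [
        Residue(
            "LIG", 1, [Atom("C", c) for c in lig],
            [f"C{i+1}" for i in range(n_ligand_atoms)], is_ligand=True,
        )
    ]
    return s
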