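"""Five-feature pharmacophore models: perception, matching, screening.

A pharmacophore here is a set of typed feature points (aromatic,
hydrophobic, H-bond acceptor/donor, anionic, cationic) with pairwise
Euclidean distance constraints and a fractional tolerance.  A molecule
matches when at least ``min_required`` features can be assigned
injectively to perceived feature points of the same kind such that every
constrained pair among the matched features satisfies
``|r_ij - d_ij| <= tau_ij * d_ij``.

The default model geometry mirrors the GPR40 agonist-site arrangement:
three aromatic rings (pi-stacking partners for Phe87/Tyr91, Phe142 and
Trp174), one hydrophobic group in the lipid-facing groove, and one
acceptor (the carboxylate engaging Arg183/Tyr2240).  The acceptor and
hydrophobic features are required by default; one aromatic may be
dropped (4-of-5 matching).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .chemio import Molecule

logger = logging.getLogger("pharmfunnel")

FEATURE_KINDS = ("aromatic", "hydrophobic", "acceptor", "donor", "anionic", "cationic")

#: default fractional distance tolerance — midpoint of the 10-15% range
DEFAULT_TOLERANCE = 0.125

#: weight of the RMS fractional-deviation penalty in the match score
DEVIATION_PENALTY = 1.0


class PharmacophoreError(Exception):
    pass


class DegenerateModelError(PharmacophoreError):
    """Two picked feature centroids coincide."""


@dataclass(frozen=True)
class PharmFeature:
    label: str
    kind: str
    weight: float = 1.0
    required: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise PharmacophoreError(f"unknown feature kind {self.kind!r}")
        if self.weight < 0:
            raise PharmacophoreError("feature weight must be nonnegative")


@dataclass(frozen=True)
class FeaturePoint:
    """A perceived feature: kind, centroid (A), contributing atom indices."""

    kind: str
    centroid: np.ndarray
    atom_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "centroid", np.asarray(self.centroid, dtype=float)
        )


@dataclass
class FeatureCloud:
    """An abstract molecule: labeled feature points only, no chemistry.

    The synthetic library generator emits these so the matcher can be
    exercised with exact geometric control.
    """

    id: str
    points: list[FeaturePoint]
    properties: dict = field(default_factory=dict)


@dataclass
class PharmModel:
    """Typed feature points with pairwise distance constraints.

    ``distances[(i, j)]`` (i < j, feature indices) gives the target
    distance in Angstrom; ``tolerances`` the fractional tolerance per
    constrained pair (defaulting to ``tolerance``).
    """

    features: list[PharmFeature]
    distances: dict[tuple[int, int], float]
    tolerance: float = DEFAULT_TOLERANCE
    tolerances: dict[tuple[int, int], float] = field(default_factory=dict)
    min_required: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.tolerance < 0.5):
            raise PharmacophoreError("tolerance must lie in (0, 0.5)")
        if self.min_required > len(self.features):
            raise PharmacophoreError("min_required exceeds feature count")
        norm = {}
        for (i, j), d in self.distances.items():
            if i == j:
                raise PharmacophoreError("self-distance constraint")
            if d <= 0:
                raise DegenerateModelError(f"constraint d({i},{j}) = {d} <= 0")
            norm[(min(i, j), max(i, j))] = float(d)
        self.distances = norm
        self.tolerances = {
            (min(i, j), max(i, j)): float(t) for (i, j), t in self.tolerances.items()
        }

    def tau(self, i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        return self.tolerances.get(key, self.tolerance)

    def constraint(self, i: int, j: int) -> float | None:
        return self.distances.get((min(i, j), max(i, j)))

    @property
    def n_features(self) -> int:
        return len(self.features)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "features": [
                {"label": f.label, "kind": f.kind, "weight": f.weight,
                 "required": f.required}
                for f in self.features
            ],
            "distances": [
                {"i": i, "j": j, "d": d, "tau": self.tau(i, j)}
                for (i, j), d in sorted(self.distances.items())
            ],
            "min_required": self.min_required,
            "tolerance": self.tolerance,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PharmModel":
        doc = yaml.safe_load(Path(path).read_text())
        feats = [
            PharmFeature(f["label"], f["kind"], f.get("weight", 1.0),
                         f.get("required", False))
            for f in doc["features"]
        ]
        tol = float(doc.get("tolerance", DEFAULT_TOLERANCE))
        distances = {}
        tolerances = {}
        for c in doc.get("distances", []):
            key = (int(c["i"]), int(c["j"]))
            distances[key] = float(c["d"])
            if "tau" in c:
                tolerances[key] = float(c["tau"])
        return cls(feats, distances, tol, tolerances,
                   int(doc.get("min_required", 4)))


@dataclass
class MatchResult:
    """Best feature assignment for one molecule.

    ``deviation`` is the RMS of ``|r_ij - d_ij| / d_ij`` over constrained
    matched pairs; ``score`` is the summed weight of matched features
    minus ``DEVIATION_PENALTY * deviation``.
    """

    mol_id: str
    mapping: dict[int, FeaturePoint]
    matched_count: int
    conformer_index: int
    deviation: float
    score: float


# ---------------------------------------------------------------------------
# perception
# ---------------------------------------------------------------------------

_ACCEPTOR_SMARTS = "[$([O;-1]),$([OX1]=[C,S,P]),$([OX2H0]),$([OX2H1]),$([nX2]),$([NX3;H0;!$(N=O);!$(N[O-])]),$([NX2H0])]"
_DONOR_SMARTS = "[$([N;!H0]),$([O;!H0]),$([S;!H0])]"
_ANIONIC_SMARTS = "[-1,-2]"
_CATIONIC_SMARTS = "[+1,+2]"

_MIN_HYDROPHOBIC_SIZE = 3


def perceive_features(mol: Molecule, conformer_index: int = 0) -> list[FeaturePoint]:
    """Perceive pharmacophore feature points on one conformer.

    Rules: each 5/6-membered aromatic ring yields an aromatic point at
    the ring-carbon centroid; each N/O with a lone pair and non-positive
    formal charge yields an acceptor point (carboxylate oxygens each emit
    one); each maximal connected group of >= 3 non-aromatic carbons
    yields a hydrophobic point; donors and charged groups come from
    SMARTS rules.
    """
    if mol.rdkit_mol is None:
        raise PharmacophoreError(f"{mol.id}: perception needs chemistry")
    if not mol.conformers:
        raise PharmacophoreError(f"{mol.id}: no conformer to perceive on")
    if conformer_index >= len(mol.conformers):
        raise PharmacophoreError(f"{mol.id}: conformer {conformer_index} missing")
    from rdkit import Chem

    rd = mol.rdkit_mol
    coords = mol.conformers[conformer_index]
    points: list[FeaturePoint] = []

    ring_info = rd.GetRingInfo()
    for ring in ring_info.AtomRings():
        if len(ring) in (5, 6) and all(
            rd.GetAtomWithIdx(i).GetIsAromatic() for i in ring
        ):
            centroid = coords[list(ring)].mean(axis=0)
            points.append(FeaturePoint("aromatic", centroid, tuple(sorted(ring))))

    patt = Chem.MolFromSmarts(_ACCEPTOR_SMARTS)
    seen: set[int] = set()
    for (idx,) in rd.GetSubstructMatches(patt):
        atom = rd.GetAtomWithIdx(idx)
        if atom.GetFormalCharge() > 0 or idx in seen:
            continue
        seen.add(idx)
        points.append(FeaturePoint("acceptor", coords[idx], (idx,)))

    # hydrophobic: connected components of non-aromatic carbons
    carbon = [
        a.GetIdx()
        for a in rd.GetAtoms()
        if a.GetSymbol() == "C" and not a.GetIsAromatic()
    ]
    carbon_set = set(carbon)
    unvisited = set(carbon)
    while unvisited:
        start = min(unvisited)
        comp = {start}
        stack = [start]
        while stack:
            i = stack.pop()
            for nb in rd.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in carbon_set and j not in comp:
                    comp.add(j)
                    stack.append(j)
        unvisited -= comp
        if len(comp) >= _MIN_HYDROPHOBIC_SIZE:
            idxs = sorted(comp)
            points.append(
                FeaturePoint("hydrophobic", coords[idxs].mean(axis=0), tuple(idxs))
            )

    for smarts, kind in (
        (_DONOR_SMARTS, "donor"),
        (_ANIONIC_SMARTS, "anionic"),
        (_CATIONIC_SMARTS, "cationic"),
    ):
        patt = Chem.MolFromSmarts(smarts)
        for match in rd.GetSubstructMatches(patt):
            idx = match[0]
            points.append(FeaturePoint(kind, coords[idx], (idx,)))

    return points


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def build_model_from_reference(
    ligand: Molecule,
    feature_picks: Sequence[tuple[str, Sequence[int]]],
    tolerance: float = DEFAULT_TOLERANCE,
    min_required: int | None = None,
    required_kinds: Sequence[str] = ("acceptor", "hydrophobic"),
    conformer_index: int = 0,
) -> PharmModel:
    """Build a model from a reference pose.

    ``feature_picks`` lists ``(kind, atom_indices)``; each feature centroid
    is the mean of the picked atoms in the reference conformer, and every
    pairwise centroid distance becomes a constraint.  Features whose kind
    is in ``required_kinds`` are marked required.
    """
    if not ligand.conformers:
        raise PharmacophoreError(f"{ligand.id}: reference has no conformer")
    coords = ligand.conformers[conformer_index]
    n_atoms = len(ligand.atoms)
    centroids = []
    features = []
    counters: dict[str, int] = {}
    label_prefix = {
        "aromatic": "R", "hydrophobic": "Hy", "acceptor": "A",
        "donor": "D", "anionic": "N", "cationic": "P",
    }
    for kind, idxs in feature_picks:
        idxs = list(idxs)
        if any(i >= n_atoms for i in idxs):
            raise PharmacophoreError("feature pick references a missing atom")
        counters[kind] = counters.get(kind, 0) + 1
        label = f"{label_prefix.get(kind, 'F')}{counters[kind]}"
        features.append(
            PharmFeature(label, kind, 1.0, required=kind in required_kinds)
        )
        centroids.append(coords[idxs].mean(axis=0))
    distances = {}
    for i, j in itertools.combinations(range(len(features)), 2):
        d = float(np.linalg.norm(centroids[i] - centroids[j]))
        if d < 1e-6:
            raise DegenerateModelError(
                f"features {features[i].label} and {features[j].label} coincide"
            )
        distances[(i, j)] = d
    if min_required is None:
        min_required = max(len(features) - 1, 1)
    return PharmModel(features, distances, tolerance, {}, min_required)


def default_gpr40_model(
    tolerance: float = DEFAULT_TOLERANCE, min_required: int = 4
) -> tuple[PharmModel, np.ndarray]:
    """The packaged 5-feature agonist-site model and its reference geometry.

    Returns ``(model, reference_points)`` where ``reference_points`` is a
    ``(5, 3)`` array of feature centroids (A) in the order R1, R2, R3,
    Hy1, A1.  The geometry is an idealized arrangement of an elongated
    acid-headed agonist: three aromatic centers spaced along the scaffold,
    a hydrophobic tail centroid, and the carboxylate acceptor at the
    opposite end.
    """
    ref = np.array(
        [
            [0.0, 0.0, 0.0],     # R1 (near the acid head)
            [4.8, 1.2, 0.6],     # R2 (central biaryl)
            [8.9, 0.4, -0.8],    # R3 (distal aromatic)
            [12.4, 1.8, 0.9],    # Hy1 (lipophilic tail)
            [-3.6, 0.8, -0.4],   # A1 (carboxylate oxygen region)
        ]
    )
    features = [
        PharmFeature("R1", "aromatic"),
        PharmFeature("R2", "aromatic"),
        PharmFeature("R3", "aromatic"),
        PharmFeature("Hy1", "hydrophobic", required=True),
        PharmFeature("A1", "acceptor", required=True),
    ]
    distances = {
        (i, j): float(np.linalg.norm(ref[i] - ref[j]))
        for i, j in itertools.combinations(range(5), 2)
    }
    return PharmModel(features, distances, tolerance, {}, min_required), ref


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _points_of(mol: Molecule | FeatureCloud, conformer_index: int):
    if isinstance(mol, FeatureCloud):
        return mol.points
    return perceive_features(mol, conformer_index)


def _evaluate(model: PharmModel, assignment: dict[int, FeaturePoint]):
    """Score a complete candidate assignment; None if any constraint fails."""
    devs = []
    for i, j in itertools.combinations(sorted(assignment), 2):
        d = model.constraint(i, j)
        if d is None:
            continue
        r = float(np.linalg.norm(assignment[i].centroid - assignment[j].centroid))
        frac = abs(r - d) / d
        if frac > model.tau(i, j) + 1e-12:
            return None
        devs.append(frac)
    deviation = float(np.sqrt(np.mean(np.square(devs)))) if devs else 0.0
    weight = sum(model.features[i].weight for i in assignment)
    return deviation, weight - DEVIATION_PENALTY * deviation


def _required_ok(model: PharmModel, matched: set[int]) -> bool:
    return all(
        i in matched for i, f in enumerate(model.features) if f.required
    )


def _match_conformer(
    model: PharmModel, points: Sequence[FeaturePoint]
) -> tuple[int, float, float, dict[int, FeaturePoint]] | None:
    """Backtracking search over injective kind-respecting assignments.

    Features are assigned in index order; each may be mapped to an unused
    point of its kind or skipped.  Distance feasibility against already-
    placed features prunes the search.  Returns the assignment maximizing
    (weighted matched score, then lowest deviation), or None.
    """
    by_kind: dict[str, list[int]] = {}
    for p_idx, p in enumerate(points):
        by_kind.setdefault(p.kind, []).append(p_idx)

    n = model.n_features
    best: list | None = None  # [weight_score, deviation, mapping]

    def recurse(f_idx: int, assignment: dict[int, int], used: set[int]) -> None:
        nonlocal best
        if f_idx == n:
            if len(assignment) < model.min_required:
                return
            if not _required_ok(model, set(assignment)):
                return
            mapped = {i: points[p] for i, p in assignment.items()}
            res = _evaluate(model, mapped)
            if res is None:
                return
            deviation, score = res
            if best is None or (score, -deviation) > (best[0], -best[1]):
                best = [score, deviation, dict(assignment)]
            return
        # prune: even matching everything remaining cannot reach min_required
        remaining = n - f_idx
        if len(assignment) + remaining < model.min_required:
            return
        feat = model.features[f_idx]
        for p_idx in by_kind.get(feat.kind, []):
            if p_idx in used:
                continue
            ok = True
            for placed, placed_p in assignment.items():
                d = model.constraint(placed, f_idx)
                if d is None:
                    continue
                r = float(
                    np.linalg.norm(
                        points[placed_p].centroid - points[p_idx].centroid
                    )
                )
                if abs(r - d) > model.tau(placed, f_idx) * d + 1e-12:
                    ok = False
                    break
            if ok:
                assignment[f_idx] = p_idx
                used.add(p_idx)
                recurse(f_idx + 1, assignment, used)
                del assignment[f_idx]
                used.remove(p_idx)
        if not feat.required:
            recurse(f_idx + 1, assignment, used)

    recurse(0, {}, set())
    if best is None:
        return None
    score, deviation, assignment = best
    mapping = {i: points[p] for i, p in assignment.items()}
    return len(assignment), deviation, score, mapping


def match(model: PharmModel, mol: Molecule | FeatureCloud) -> MatchResult | None:
    """Best match of ``model`` against all conformers of ``mol``.

    Exactly one conformer is reported per molecule: the one whose best
    assignment maximizes (score, -deviation), earlier conformer winning
    ties.  Returns None when no conformer admits a valid assignment.
    """
    if isinstance(mol, FeatureCloud):
        n_conf = 1
    else:
        if not mol.conformers:
            raise PharmacophoreError(f"{mol.id}: no conformers to match")
        n_conf = len(mol.conformers)
    best: MatchResult | None = None
    for c in range(n_conf):
        points = _points_of(mol, c)
        res = _match_conformer(model, points)
        if res is None:
            continue
        count, deviation, score, mapping = res
        cand = MatchResult(mol.id, mapping, count, c, deviation, score)
        if best is None or (cand.score, -cand.deviation) > (best.score, -best.deviation):
            best = cand
    return best


def match_bruteforce(
    model: PharmModel, mol: Molecule | FeatureCloud
) -> MatchResult | None:
    """Exhaustive-enumeration matcher (oracle; exponential, small inputs only).

    Enumerates every subset of features of size >= min_required containing
    all required features, and every injective kind-respecting assignment
    of that subset to points, over every conformer.
    """
    if isinstance(mol, FeatureCloud):
        n_conf = 1
    else:
        n_conf = len(mol.conformers)
    best: MatchResult | None = None
    n = model.n_features
    for c in range(n_conf):
        points = list(_points_of(mol, c))
        for size in range(model.min_required, n + 1):
            for subset in itertools.combinations(range(n), size):
                if not _required_ok(model, set(subset)):
                    continue
                pools = [
                    [i for i, p in enumerate(points)
                     if p.kind == model.features[f].kind]
                    for f in subset
                ]
                for choice in itertools.product(*pools):
                    if len(set(choice)) != len(choice):
                        continue
                    mapped = {
                        f: points[p] for f, p in zip(subset, choice)
                    }
                    res = _evaluate(model, mapped)
                    if res is None:
                        continue
                    deviation, score = res
                    cand = MatchResult(mol.id, mapped, size, c, deviation, score)
                    if best is None or (cand.score, -cand.deviation) > (
                        best.score, -best.deviation
                    ):
                        best = cand
    return best


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def screen(
    model: PharmModel, library: Sequence[Molecule | FeatureCloud]
):
    """Screen a library; returns a DataFrame of hits.

    Columns: id, matched_count, score, deviation, conformer_index.  Hits
    are sorted by score descending, ties broken lexicographically by id.
    """
    import pandas as pd

    if len(library) == 0:
        raise PharmacophoreError("cannot screen an empty library")
    rows = []
    for mol in library:
        res = match(model, mol)
        if res is None:
            continue
        rows.append(
            {
                "id": res.mol_id,
                "matched_count": res.matched_count,
                "score": res.score,
                "deviation": res.deviation,
                "conformer_index": res.conformer_index,
            }
        )
    df = pd.DataFrame(
        rows, columns=["id", "matched_count", "score", "deviation", "conformer_index"]
    )
    if len(df):
        df = df.sort_values(
            ["score", "id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
    hit_fraction = len(df) / len(library)
    logger.info(
        "screen: %d/%d hits (%.2f%% of library)",
        len(df), len(library), 100.0 * hit_fraction,
    )
    return df
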