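"""Molecular I/O and the shared data model.

Provides lightweight containers — :class:`Atom`, :class:`Molecule`,
:class:`Structure`, :class:`Trajectory` — plus readers/writers for the
plain-text formats the pipeline consumes: SDF (V2000), SMILES tables,
PDB (single- and multi-model) and multi-frame XYZ.  RDKit does the
chemistry (SDF/SMILES parsing, conformer embedding); Bio.PDB does the
PDB parsing.  All coordinates are stored in Angstrom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

logger = logging.getLogger("pharmfunnel")

RDLogger.DisableLog("rdApp.*")

#: heavy-atom RMSD below which two conformers count as duplicates, Angstrom
CONFORMER_DEDUP_RMSD = 0.5

_RECOGNIZED_ELEMENTS = frozenset(
    Chem.GetPeriodicTable().GetElementSymbol(z) for z in range(1, 104)
)


class ChemIOError(Exception):
    """Base error for molecular I/O failures."""


class EmptyLibraryError(ChemIOError):
    """A file yielded zero parseable records."""


class ConformerGenerationError(ChemIOError):
    """3D embedding failed for a molecule."""


class TrajectoryConsistencyError(ChemIOError):
    """Frames of a trajectory disagree on atom count or ordering."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """A single atom: element symbol, coordinates (A), charges (e)."""

    element: str
    coords: np.ndarray
    formal_charge: int = 0
    partial_charge: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be a finite 3-vector")
        if self.element not in _RECOGNIZED_ELEMENTS:
            raise ValueError(f"unrecognized element symbol {self.element!r}")


@dataclass
class Molecule:
    """A small molecule with bonds, 0+ conformers and named properties.

    ``bonds`` entries are ``(i, j, order, aromatic)`` with atom indices into
    ``atoms``.  ``conformers`` is a list of ``(n_atoms, 3)`` coordinate sets;
    ``atoms[i].coords`` mirrors conformer 0 when present.
    """

    id: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int, float, bool]] = field(default_factory=list)
    conformers: list[np.ndarray] = field(default_factory=list)
    properties: dict = field(default_factory=dict)
    rdkit_mol: Chem.Mol | None = None  # kept for featurization / writing

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, *_ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
        clean = []
        for conf in self.conformers:
            conf = np.asarray(conf, dtype=float)
            if conf.shape != (n, 3):
                raise ValueError("conformer length must equal atom count")
            clean.append(conf)
        self.conformers = clean

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def smiles(self) -> str | None:
        if self.rdkit_mol is not None:
            return Chem.MolToSmiles(self.rdkit_mol)
        return self.properties.get("smiles")


@dataclass
class Residue:
    name: str
    number: int
    atoms: list[Atom]
    atom_names: list[str]
    is_ligand: bool = False


@dataclass
class Structure:
    """Chains of residues of atoms, as read from a PDB file."""

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def iter_atoms(self) -> Iterable[tuple[str, Residue, str, Atom]]:
        for chain_id, residues in self.chains.items():
            for res in residues:
                for name, atom in zip(res.atom_names, res.atoms):
                    yield chain_id, res, name, atom

    def coords(self) -> np.ndarray:
        return np.array([a.coords for *_, a in self.iter_atoms()], dtype=float)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for rs in self.chains.values() for r in rs)


@dataclass
class AtomMeta:
    """Per-atom metadata carried by a trajectory."""

    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str


@dataclass
class Trajectory:
    """Frame-indexed coordinates (A) over a fixed atom list."""

    frames: list[np.ndarray]
    meta: list[AtomMeta]
    dt_ps: float = 1.0

    def __post_init__(self) -> None:
        n = len(self.meta)
        clean = []
        for k, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise TrajectoryConsistencyError(
                    f"frame {k} has shape {f.shape}, expected ({n}, 3)"
                )
            clean.append(f)
        self.frames = clean

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.meta)

    def xyz(self) -> np.ndarray:
        """All coordinates as an ``(n_frames, n_atoms, 3)`` array."""
        return np.stack(self.frames)

    def select(self, predicate) -> np.ndarray:
        """Indices of atoms whose :class:`AtomMeta` satisfies ``predicate``."""
        return np.array(
            [i for i, m in enumerate(self.meta) if predicate(m)], dtype=int
        )


# ---------------------------------------------------------------------------
# RDKit bridge
# ---------------------------------------------------------------------------

def mol_from_rdkit(rd: Chem.Mol, mol_id: str) -> Molecule:
    """Convert an RDKit molecule (with any number of conformers) to ours."""
    atoms = []
    has_conf = rd.GetNumConformers() > 0
    conf0 = rd.GetConformer(0) if has_conf else None
    for a in rd.GetAtoms():
        xyz = (
            np.array(conf0.GetAtomPosition(a.GetIdx()))
            if conf0 is not None
            else np.zeros(3)
        )
        atoms.append(Atom(a.GetSymbol(), xyz, a.GetFormalCharge()))
    bonds = [
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            b.GetBondTypeAsDouble(),
            b.GetIsAromatic(),
        )
        for b in rd.GetBonds()
    ]
    conformers = [
        np.array(rd.GetConformer(c.GetId()).GetPositions(), dtype=float)
        for c in rd.GetConformers()
    ]
    props = {k: rd.GetProp(k) for k in rd.GetPropNames()}
    return Molecule(mol_id, atoms, bonds, conformers, props, rdkit_mol=rd)


def _record_id(rd: Chem.Mol, index: int) -> str:
    if rd.HasProp("_Name") and rd.GetProp("_Name").strip():
        return rd.GetProp("_Name").strip()
    return f"mol_{index}"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_sdf(path: str | Path) -> tuple[list[Molecule], int]:
    """Read an SDF (V2000) file.

    Returns ``(molecules, n_skipped)``.  Individually malformed records are
    skipped with a logged warning; a file with zero parseable records raises
    :class:`EmptyLibraryError`.  V3000 records are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    text = path.read_text()
    if "V3000" in text:
        raise ChemIOError(f"{path}: V3000 SDF records are not supported")
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mols: list[Molecule] = []
    skipped = 0
    for i, rd in enumerate(supplier):
        if rd is None:
            skipped += 1
            logger.warning("read_sdf: skipping malformed record %d in %s", i, path)
            continue
        mols.append(mol_from_rdkit(rd, _record_id(rd, i)))
    if not mols:
        raise EmptyLibraryError(f"{path}: no parseable SDF records")
    return mols, skipped


def read_smiles_table(
    path: str | Path,
    smiles_column: str = "smiles",
    id_column: str | None = "id",
    sep: str = ",",
) -> tuple[list[Molecule], int]:
    """Read molecules from a delimited table with a SMILES column.

    Unparseable SMILES rows are skipped and counted.  Raises a schema error
    if ``smiles_column`` is missing from the header.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=sep)
    if smiles_column not in df.columns:
        raise ChemIOError(f"{path}: missing SMILES column {smiles_column!r}")
    use_id = id_column if id_column in df.columns else None
    mols: list[Molecule] = []
    skipped = 0
    for i, row in df.iterrows():
        rd = Chem.MolFromSmiles(str(row[smiles_column]))
        if rd is None:
            skipped += 1
            logger.warning("read_smiles_table: bad SMILES at row %d", i)
            continue
        mol_id = str(row[use_id]) if use_id else f"mol_{i}"
        m = mol_from_rdkit(rd, mol_id)
        m.properties.update(
            {c: row[c] for c in df.columns if c not in (smiles_column,)}
        )
        m.properties["smiles"] = str(row[smiles_column])
        mols.append(m)
    return mols, skipped


def generate_conformers(
    mol: Molecule, max_conformers: int = 3, seed: int = 0
) -> Molecule:
    """Embed up to ``max_conformers`` distinct 3D conformers.

    Distinctness means pairwise heavy-atom RMSD above
    :data:`CONFORMER_DEDUP_RMSD`.  Deterministic for a fixed seed.
    """
    if mol.rdkit_mol is None:
        raise ConformerGenerationError(f"{mol.id}: no chemistry available")
    rd = Chem.AddHs(Chem.Mol(mol.rdkit_mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.pruneRmsThresh = CONFORMER_DEDUP_RMSD
    n_request = max(max_conformers * 4, 8)
    ids = AllChem.EmbedMultipleConfs(rd, numConfs=n_request, params=params)
    if len(ids) == 0:
        raise ConformerGenerationError(f"{mol.id}: 3D embedding failed")
    AllChem.MMFFOptimizeMoleculeConfs(rd, maxIters=200)
    rd_noh = Chem.RemoveHs(rd)
    # greedy dedup on heavy-atom RMSD, keeping embed order
    kept: list[int] = []
    for cid in [c.GetId() for c in rd_noh.GetConformers()]:
        dup = False
        for prev in kept:
            rms = AllChem.GetConformerRMS(rd_noh, prev, cid, prealigned=False)
            if rms < CONFORMER_DEDUP_RMSD:
                dup = True
                break
        if not dup:
            kept.append(cid)
        if len(kept) >= max_conformers:
            break
    out = Chem.Mol(rd_noh)
    out.RemoveAllConformers()
    for cid in kept:
        out.AddConformer(rd_noh.GetConformer(cid), assignId=True)
    for k in mol.rdkit_mol.GetPropNames():
        out.SetProp(k, mol.rdkit_mol.GetProp(k))
    new = mol_from_rdkit(out, mol.id)
    new.properties.update(mol.properties)
    return new


def _parse_pdb(path: Path) -> list[Structure]:
    """Parse a PDB file into one Structure per MODEL via Bio.PDB."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio = parser.get_structure(path.stem, str(path))
    structures: list[Structure] = []
    for model in bio:
        s = Structure(id=path.stem)
        for chain in model:
            residues = []
            for res in chain:
                het = res.id[0].strip() != ""
                atoms = []
                names = []
                for at in res:
                    atoms.append(
                        Atom(
                            element=at.element.capitalize() or "C",
                            coords=np.asarray(at.coord, dtype=float),
                        )
                    )
                    names.append(at.get_name())
                residues.append(
                    Residue(res.get_resname(), res.id[1], atoms, names, is_ligand=het)
                )
            s.chains[chain.id] = residues
        structures.append(s)
    return structures


def read_structure(path: str | Path) -> Structure:
    """Read a single-model PDB file into a :class:`Structure`."""
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    structures = _parse_pdb(path)
    if not structures:
        raise ChemIOError(f"{path}: no models found")
    return structures[0]


def structure_to_frame(s: Structure) -> tuple[np.ndarray, list[AtomMeta]]:
    coords = []
    meta = []
    for chain_id, res, name, atom in s.iter_atoms():
        coords.append(atom.coords)
        meta.append(AtomMeta(name, atom.element, res.name, res.number, chain_id))
    return np.array(coords, dtype=float), meta


def read_trajectory(path: str | Path, dt_ps: float = 1.0) -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ file as a trajectory.

    Atom ordering must be constant across frames; differing atom counts
    raise :class:`TrajectoryConsistencyError`.
    """
    path = Path(path)
    if not path.exists():
        raise ChemIOError(f"no such file: {path}")
    if path.suffix.lower() == ".xyz":
        return _read_xyz(path, dt_ps)
    structures = _parse_pdb(path)
    if not structures:
        raise ChemIOError(f"{path}: no models found")
    frame0, meta = structure_to_frame(structures[0])
    frames = [frame0]
    for s in structures[1:]:
        coords, m = structure_to_frame(s)
        if len(m) != len(meta):
            raise TrajectoryConsistencyError(
                f"{path}: frame atom counts differ ({len(m)} vs {len(meta)})"
            )
        frames.append(coords)
    return Trajectory(frames, meta, dt_ps)


def _read_xyz(path: Path, dt_ps: float) -> Trajectory:
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    meta: list[AtomMeta] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        elems = []
        coords = []
        for ln in block:
            parts = ln.split()
            elems.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        if meta is None:
            meta = [AtomMeta(e, e, "MOL", 1, "A") for e in elems]
        elif len(elems) != len(meta):
            raise TrajectoryConsistencyError(f"{path}: inconsistent frame sizes")
        frames.append(np.array(coords))
        i += 2 + n
    if meta is None:
        raise ChemIOError(f"{path}: empty XYZ file")
    return Trajectory(frames, meta, dt_ps)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_sdf(mols: Sequence[Molecule], path: str | Path) -> None:
    """Write molecules (with conformer 0 if present) as SDF V2000."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for m in mols:
        rd = m.rdkit_mol
        if rd is None:
            raise ChemIOError(f"{m.id}: cannot write without chemistry")
        rd = Chem.Mol(rd)
        rd.SetProp("_Name", m.id)
        for k, v in m.properties.items():
            rd.SetProp(str(k), str(v))
        writer.write(rd)
    writer.close()


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (3-decimal coordinates)."""
    with open(path, "w") as fh:
        for k, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {k:4d}\n")
            serial = 1
            for m, xyz in zip(traj.meta, frame):
                record = "HETATM" if m.residue_name in ("LIG", "UNL") else "ATOM  "
                name = m.name[:4]
                fh.write(
                    f"{record}{serial:5d} {name:<4s}{m.residue_name:>4s} "
                    f"{m.chain:1s}{m.residue_number:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {m.element:>2s}\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_structure_pdb(s: Structure, path: str | Path) -> None:
    coords, meta = structure_to_frame(s)
    write_trajectory_pdb(Trajectory([coords], meta), path)
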