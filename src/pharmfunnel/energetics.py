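"""MM-PBSA-style energy bookkeeping and toy-system energetics.

An :class:`EnergyLedger` holds the per-compound binding free-energy
decomposition used by end-point (MM-GB/PBSA) scoring:

* gas phase:  ``dG_gas  = dE_vdW + dE_elec``
* solvation:  ``dG_solv = dE_GB  + dE_surf``
* total:      ``dG_total = dG_gas + dG_solv``  (kcal/mol throughout)

The polar GB term is ingested from an external solver's output, never
computed here; the nonpolar term follows ``E_surf = gamma * SASA + beta``.
Toy Lennard-Jones / Coulomb energetics and a Shrake-Rupley SASA are
provided with closed-form oracles so the bookkeeping and the ingestion
path can be validated without a molecular-dynamics engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Coulomb constant, kcal*A/(mol*e^2)
COULOMB_CONSTANT = 332.0637

#: default surface tension for the nonpolar solvation term, kcal/mol/A^2
DEFAULT_GAMMA = 0.0072

#: additive identity tolerance covering 2-decimal rounding of components
LEDGER_TOLERANCE = 0.015

#: Bondi-style van der Waals radii (A) for SASA
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

DEFAULT_PROBE_RADIUS = 1.4


class EnergeticsError(Exception):
    pass


@dataclass(frozen=True)
class EnergyLedger:
    """Component decomposition of one compound's binding free energy."""

    id: str
    vdw: float
    eel: float
    egb: float
    esurf: float
    ggas: float
    gsolv: float
    total: float


@dataclass
class ToyForceField:
    """Per-atom nonbonded parameters for toy complexes.

    sigma (A) and epsilon (kcal/mol) feed a 6-12 Lennard-Jones potential
    with Lorentz-Berthelot combination; q (e) feeds a screened Coulomb
    term with relative dielectric eps_r.  gamma/beta parameterize the
    SASA-proportional nonpolar solvation term.
    """

    sigma: np.ndarray
    epsilon: np.ndarray
    q: np.ndarray
    eps_r: float = 1.0
    gamma: float = DEFAULT_GAMMA
    beta: float = 0.0

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if np.any(self.sigma < 0) or np.any(self.epsilon < 0):
            raise EnergeticsError("sigma and epsilon must be nonnegative")
        if self.eps_r < 1:
            raise EnergeticsError("relative dielectric must be >= 1")


# ---------------------------------------------------------------------------
# ledger assembly and verification
# ---------------------------------------------------------------------------

def assemble_ledger(
    vdw: float, eel: float, egb: float, esurf: float, id: str = ""
) -> EnergyLedger:
    """Build a ledger from the four components; sums computed, not given."""
    parts = (vdw, eel, egb, esurf)
    if not all(np.isfinite(parts)):
        raise ValueError(f"{id}: non-finite energy component in {parts}")
    ggas = vdw + eel
    gsolv = egb + esurf
    return EnergyLedger(id, vdw, eel, egb, esurf, ggas, gsolv, ggas + gsolv)


def verify_ledger(
    ledger: EnergyLedger, tol: float = LEDGER_TOLERANCE
) -> tuple[bool, dict[str, float]]:
    """Check the three additive identities of a (possibly ingested) ledger.

    Returns ``(passed, residuals)`` with residuals for gas, solvation and
    total sums.  The default tolerance absorbs 2-decimal rounding of
    independently printed components.
    """
    residuals = {
        "ggas": abs(ledger.ggas - (ledger.vdw + ledger.eel)),
        "gsolv": abs(ledger.gsolv - (ledger.egb + ledger.esurf)),
        "total": abs(ledger.total - (ledger.ggas + ledger.gsolv)),
    }
    return max(residuals.values()) <= tol, residuals


def read_ledger_csv(path) -> list[EnergyLedger]:
    """Ingest a 7-component ledger CSV (id,vdw,eel,egb,esurf,ggas,gsolv,total)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"id", "vdw", "eel", "egb", "esurf", "ggas", "gsolv", "total"}
    missing = required - set(df.columns)
    if missing:
        raise EnergeticsError(f"ledger CSV missing columns: {sorted(missing)}")
    return [
        EnergyLedger(
            str(r.id), float(r.vdw), float(r.eel), float(r.egb),
            float(r.esurf), float(r.ggas), float(r.gsolv), float(r.total),
        )
        for r in df.itertuples()
    ]


def rank_against_control(
    ledgers: Sequence[EnergyLedger], control: EnergyLedger
) -> tuple[list[EnergyLedger], list[EnergyLedger]]:
    """Order ledgers by total (ascending, most favorable first).

    Returns ``(ranked, better_than_control)`` where the subset holds
    ledgers with total strictly below the control's.  Ties order
    lexicographically by id.
    """
    ranked = sorted(ledgers, key=lambda l: (l.total, l.id))
    better = [l for l in ranked if l.total < control.total]
    return ranked, better


# ---------------------------------------------------------------------------
# toy gas-phase terms
# ---------------------------------------------------------------------------

def _split_complex(structure) -> tuple[np.ndarray, np.ndarray]:
    """Receptor and ligand atom index arrays of a Structure."""
    rec, lig = [], []
    idx = 0
    for chain in structure.chains.values():
        for res in chain:
            for _ in res.atoms:
                (lig if res.is_ligand else rec).append(idx)
                idx += 1
    return np.array(rec, dtype=int), np.array(lig, dtype=int)


def _pair_distances(coords, rec, lig):
    d = coords[rec][:, None, :] - coords[lig][None, :, :]
    r = np.sqrt(np.sum(d * d, axis=-1))
    if np.any(r < 1e-9):
        raise EnergeticsError("overlapping atoms (r = 0) in complex")
    return r


def lj_energy(structure, ff: ToyForceField) -> float:
    """Receptor-ligand Lennard-Jones 6-12 energy, kcal/mol.

    ``sum 4 eps_ij [(sigma_ij/r)^12 - (sigma_ij/r)^6]`` over all
    intermolecular pairs, Lorentz-Berthelot combination, no cutoff.
    """
    rec, lig = _split_complex(structure)
    coords = structure.coords()
    r = _pair_distances(coords, rec, lig)
    sig = 0.5 * (ff.sigma[rec][:, None] + ff.sigma[lig][None, :])
    eps = np.sqrt(ff.epsilon[rec][:, None] * ff.epsilon[lig][None, :])
    s6 = (sig / r) ** 6
    return float(np.sum(4.0 * eps * (s6 * s6 - s6)))


def coulomb_energy(structure, ff: ToyForceField) -> float:
    """Receptor-ligand screened Coulomb energy, kcal/mol."""
    rec, lig = _split_complex(structure)
    coords = structure.coords()
    r = _pair_distances(coords, rec, lig)
    qq = ff.q[rec][:, None] * ff.q[lig][None, :]
    return float(np.sum(COULOMB_CONSTANT * qq / (ff.eps_r * r)))


def born_ion_energy(q: float, radius: float, eps_r: float = 78.5) -> float:
    """Single-ion Born solvation energy (kcal/mol): -166 q^2 / R * (1 - 1/eps_r).

    Provided as a closed-form oracle for the GB ingestion path; the
    package never computes GB energies for real systems.
    """
    return -166.0 * q * q / radius * (1.0 - 1.0 / eps_r)


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def sasa(
    structure_or_coords,
    elements: Sequence[str] | None = None,
    probe: float = DEFAULT_PROBE_RADIUS,
    n_points: int = 960,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Accepts either a Structure (elements taken from its atoms) or an
    ``(n, 3)`` coordinate array plus an ``elements`` list.  Returns
    ``(per_atom_area, total_area)`` in A^2.  The sampling sphere is a
    deterministic golden-spiral point set, so results are reproducible
    for a fixed ``n_points``.
    """
    if elements is None:
        coords = structure_or_coords.coords()
        elements = [a.element for *_, a in structure_or_coords.iter_atoms()]
    else:
        coords = np.asarray(structure_or_coords, dtype=float)
    try:
        radii = np.array([VDW_RADII[e] for e in elements]) + probe
    except KeyError as exc:
        raise EnergeticsError(f"no van der Waals radius for element {exc}") from exc
    n = len(coords)
    unit = _sphere_points(n_points)
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas, float(areas.sum())


def esurf_from_sasa(
    total_area: float, gamma: float = DEFAULT_GAMMA, beta: float = 0.0
) -> float:
    """Nonpolar solvation term: gamma * SASA + beta, kcal/mol."""
    return gamma * total_area + beta


# ---------------------------------------------------------------------------
# reference data: GPR40 candidate decomposition (worked example / fixtures)
# ---------------------------------------------------------------------------

#: Published MM-GBSA decomposition (kcal/mol) for the ten GPR40 agonist
#: candidates and the TAK-875 control, as printed to 2 decimals:
#: (vdw, eel, egb, esurf, ggas, gsolv, total).  The sums are kept verbatim
#: so the internal consistency of the published rows can be audited with
#: :func:`verify_ledger`; note that the molecule "3" row is internally
#: inconsistent as printed (its component sums disagree with its printed
#: totals by far more than rounding).
GPR40_CANDIDATE_TABLE: dict[str, tuple[float, ...]] = {
    "1": (-65.71, -46.92, 59.63, -10.30, -112.63, 49.34, -63.29),
    "2": (-44.26, -26.04, 37.07, -7.04, -70.29, 30.04, -40.26),
    "3": (-55.26, -21.45, 34.37, -8.84, -57.67, 29.07, -47.60),
    "4": (-53.93, -55.64, 57.82, -8.12, -109.58, 49.70, -59.87),
    "5": (-56.76, -19.40, 40.30, -8.31, -76.16, 31.99, -44.17),
    "6": (-54.69, -71.14, 80.23, -9.18, -125.83, 71.05, -54.77),
    "7": (-50.97, -17.73, 38.13, -7.66, -68.70, 30.47, -38.24),
    "8": (-41.37, -6.33, 25.58, -5.41, -47.70, 20.17, -27.53),
    "9": (-47.59, -6.12, 31.13, -6.21, -53.70, 24.92, -28.78),
    "10": (-62.65, -20.85, 47.13, -8.79, -83.50, 38.34, -45.16),
    "Control": (-53.54, -23.06, 41.58, -7.43, -76.60, 34.15, -42.45),
}


def gpr40_printed_ledgers() -> tuple[list[EnergyLedger], EnergyLedger]:
    """Ledgers carrying the published rows verbatim (candidates, control)."""
    ledgers = [
        EnergyLedger(mol_id, *row)
        for mol_id, row in GPR40_CANDIDATE_TABLE.items()
        if mol_id != "Control"
    ]
    control = EnergyLedger("Control", *GPR40_CANDIDATE_TABLE["Control"])
    return ledgers, control


def gpr40_candidate_ledgers() -> tuple[list[EnergyLedger], EnergyLedger]:
    """Ledgers re-assembled from the four published components per compound.

    Sums are recomputed by :func:`assemble_ledger`, never copied from the
    published table.
    """
    ledgers = [
        assemble_ledger(*row[:4], id=mol_id)
        for mol_id, row in GPR40_CANDIDATE_TABLE.items()
        if mol_id != "Control"
    ]
    control = assemble_ledger(*GPR40_CANDIDATE_TABLE["Control"][:4], id="Control")
    return ledgers, control
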