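"""Tanimoto fingerprint similarity and novelty flagging.

Candidate compounds are compared against a reference set of known
actives with both MACCS (166-bit) and Morgan radius-2 (2048-bit)
fingerprints.  A candidate whose maximum Tanimoto coefficient to any
reference reaches 0.85 is flagged "known-like" (structurally similar
compounds have about a 30% chance of sharing activity at that
threshold); anything below is "novel".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

SCHEMES = {"MACCS-166": 167, "Morgan-r2-2048": 2048}

#: similarity at or above which a compound counts as known-like
NOVELTY_THRESHOLD = 0.85


class SimilarityError(Exception):
    pass


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length bit vector under a named scheme."""

    scheme: str
    bits: tuple[int, ...]  # sorted indices of set bits

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise SimilarityError(f"unknown scheme {self.scheme!r}")
        length = SCHEMES[self.scheme]
        bits = tuple(sorted(set(int(b) for b in self.bits)))
        if bits and (bits[0] < 0 or bits[-1] >= length):
            raise SimilarityError("bit index out of range for scheme")
        object.__setattr__(self, "bits", bits)

    @property
    def popcount(self) -> int:
        return len(self.bits)


def fingerprint_from_smiles(smiles: str, scheme: str) -> Fingerprint:
    """Compute a MACCS or Morgan fingerprint via RDKit."""
    from rdkit import Chem
    from rdkit.Chem import AllChem, MACCSkeys

    rd = Chem.MolFromSmiles(smiles)
    if rd is None:
        raise SimilarityError(f"unparseable SMILES {smiles!r}")
    if scheme == "MACCS-166":
        bv = MACCSkeys.GenMACCSKeys(rd)
    elif scheme == "Morgan-r2-2048":
        gen = AllChem.GetMorganGenerator(radius=2, fpSize=2048)
        bv = gen.GetFingerprint(rd)
    else:
        raise SimilarityError(f"unknown scheme {scheme!r}")
    return Fingerprint(scheme, tuple(bv.GetOnBits()))


def tanimoto(fp1: Fingerprint, fp2: Fingerprint) -> float:
    """c / (a + b - c) over set bits; 0/0 defined as 0."""
    if fp1.scheme != fp2.scheme:
        raise SimilarityError(
            f"scheme mismatch: {fp1.scheme} vs {fp2.scheme}"
        )
    a, b = fp1.popcount, fp2.popcount
    c = len(set(fp1.bits) & set(fp2.bits))
    denom = a + b - c
    return c / denom if denom else 0.0


def max_similarity(
    query: Fingerprint, references: Sequence[tuple[str, Fingerprint]]
) -> tuple[float, str]:
    """Maximum Tanimoto over a non-empty reference set.

    ``references`` are ``(id, fingerprint)`` pairs; ties resolve to the
    lexicographically smallest reference id.
    """
    if not references:
        raise SimilarityError("reference set is empty")
    best_val, best_id = -1.0, ""
    for ref_id, ref_fp in references:
        v = tanimoto(query, ref_fp)
        if v > best_val or (v == best_val and ref_id < best_id):
            best_val, best_id = v, ref_id
    return best_val, best_id


def novelty_flag(
    values: Iterable[float], threshold: float = NOVELTY_THRESHOLD
) -> str:
    """"known-like" iff any similarity value reaches the threshold
    (inclusive); an empty value list is vacuously "novel"."""
    values = list(values)
    if any(not (0.0 <= v <= 1.0) for v in values):
        raise SimilarityError("similarity values must lie in [0, 1]")
    if values and max(values) >= threshold:
        return "known-like"
    return "novel"


def similarity_report(
    candidates: Sequence[tuple[str, str]],
    references: Sequence[tuple[str, str]],
    threshold: float = NOVELTY_THRESHOLD,
):
    """Per-candidate MACCS and Morgan similarity against a reference set.

    Both ``candidates`` and ``references`` are ``(id, smiles)`` pairs.
    Returns a DataFrame (id, tanimoto_maccs, tanimoto_morgan,
    nearest_reference, flag); the flag uses the maximum of the two
    schemes' values.
    """
    import pandas as pd

    ref_fps = {
        scheme: [(rid, fingerprint_from_smiles(smi, scheme))
                 for rid, smi in references]
        for scheme in SCHEMES
    }
    rows = []
    for cid, smi in candidates:
        vals = {}
        nearest = {}
        for scheme in SCHEMES:
            q = fingerprint_from_smiles(smi, scheme)
            vals[scheme], nearest[scheme] = max_similarity(q, ref_fps[scheme])
        best_scheme = max(SCHEMES, key=lambda s: vals[s])
        rows.append(
            {
                "id": cid,
                "tanimoto_maccs": vals["MACCS-166"],
                "tanimoto_morgan": vals["Morgan-r2-2048"],
                "nearest_reference": nearest[best_scheme],
                "flag": novelty_flag(vals.values(), threshold),
            }
        )
    return pd.DataFrame(rows)


def random_fingerprint(
    rng: np.random.Generator, scheme: str, density: float = 0.1
) -> Fingerprint:
    """Random fingerprint with i.i.d. set bits (test/benchmark helper)."""
    length = SCHEMES[scheme]
    bits = tuple(np.flatnonzero(rng.random(length) < density))
    return Fingerprint(scheme, bits)
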