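"""Staged screening funnel: pharmacophore -> ML triage -> docking ingestion
-> novelty filter -> energetics ranking.

Each stage discards candidates before a more expensive evaluation.
Docking scores and MM-GB/PBSA ledgers are external by design (the
scorers are proprietary or engine-bound): they enter as CSV and pass
through the same bookkeeping as everything computed in-package.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import ml_triage, pharmacophore, similarity
from .energetics import EnergyLedger, rank_against_control
from .synth import ActivityTableSpec, LibrarySpec, make_activity_table, make_feature_library

logger = logging.getLogger("pharmfunnel")


class FunnelError(Exception):
    pass


@dataclass
class FunnelRecord:
    """One compound's passage through the funnel."""

    id: str
    pharm_hit: bool = False
    ml_active: bool = False
    docking_score: float | None = None
    novelty: str | None = None
    mmpbsa_total: float | None = None
    notes: list[str] = field(default_factory=list)


@dataclass
class FunnelReport:
    seed: int
    stage_counts: dict[str, int]
    retention_pct: dict[str, float]
    records: dict[str, FunnelRecord]
    table: pd.DataFrame

    def summary(self) -> str:
        lines = [f"Screening funnel (seed {self.seed})"]
        for stage, count in self.stage_counts.items():
            pct = self.retention_pct.get(stage)
            extra = f"  ({pct:.2f}% of library)" if pct is not None else ""
            lines.append(f"  {stage:<14s} {count:6d}{extra}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# external-score ingestion
# ---------------------------------------------------------------------------

def ingest_docking_scores(path, id_column="id", score_column="score") -> pd.DataFrame:
    """Read an external docking-score CSV; duplicate ids are an error."""
    df = pd.read_csv(path)
    for col in (id_column, score_column):
        if col not in df.columns:
            raise FunnelError(f"docking CSV missing column {col!r}")
    df = df.rename(columns={id_column: "id", score_column: "score"})
    df["id"] = df["id"].astype(str)
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise FunnelError(f"duplicate ids in docking CSV: {dups}")
    return df[["id", "score"]]


def select_better_than_control(
    scores: pd.DataFrame, control_score: float, strict: bool = False
) -> pd.DataFrame:
    """Rows scoring at least as well as the control (lower = better).

    Non-strict (default) keeps ties with the control, the reading that
    reproduces the published 10-molecule docking cut; ``strict=True``
    requires a strictly better score.
    """
    if strict:
        keep = scores["score"] < control_score
    else:
        keep = scores["score"] <= control_score
    out = scores[keep].sort_values(["score", "id"], kind="mergesort")
    logger.info(
        "docking cut: %d/%d at %s control %.3f",
        len(out), len(scores), "<" if strict else "<=", control_score,
    )
    return out.reset_index(drop=True)


#: Published Glide XP docking scores (kcal/mol) for the ten GPR40
#: candidates and the TAK-875 control redock (worked-example fixture).
GPR40_DOCKING_SCORES: dict[str, float] = {
    "1": -13.9, "2": -13.9, "3": -13.5, "4": -13.4, "5": -13.4,
    "6": -12.9, "7": -12.7, "8": -12.3, "9": -12.1, "10": -12.1,
    "Control": -12.1,
}


# ---------------------------------------------------------------------------
# final report
# ---------------------------------------------------------------------------

def final_report(records: Sequence[FunnelRecord]) -> pd.DataFrame:
    """Ranked table: docking score then MM-PBSA total, missing as blank."""
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "docking_score": r.docking_score,
                "mmpbsa_total": r.mmpbsa_total,
                "novelty": r.novelty if r.novelty is not None else "",
            }
        )
    df = pd.DataFrame(rows, columns=["id", "docking_score", "mmpbsa_total", "novelty"])
    if len(df):
        df = df.sort_values(
            ["docking_score", "mmpbsa_total", "id"],
            kind="mergesort", na_position="last",
        ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_funnel(config: dict, outdir: str | Path | None = None) -> FunnelReport:
    """Run the staged funnel on a synthetic or user-supplied library.

    Config keys (all optional except the library stage):

    * ``seed`` — master seed for every stochastic stage.
    * ``library`` — either ``{"synthetic": {n_actives, n_decoys, noise_sd}}``
      or ``{"smiles_csv": path}``.
    * ``pharmacophore`` — ``{"model_yaml": path}`` or ``{"default": true}``.
    * ``triage`` — ``{"activity_csv": path}`` or
      ``{"synthetic": {n, active_fraction, ec50_noise_sd}}``; absent skips.
    * ``docking`` — ``{"scores_csv": path, "control_id": id, "strict": bool}``.
    * ``novelty`` — ``{"references": [[id, smiles], ...], "threshold": 0.85}``.
    * ``energetics`` — ``{"ledger_csv": path, "control_id": id}``.

    Every stage logs input/output counts; intermediates are written under
    ``outdir`` when given.  Deterministic for a fixed config.
    """
    seed = int(config.get("seed", 0))
    outdir = Path(outdir) if outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    stage_counts: dict[str, int] = {}
    retention: dict[str, float] = {}
    t0 = time.time()

    # ---- stage 0: library -------------------------------------------------
    lib_cfg = config.get("library")
    if not lib_cfg:
        raise FunnelError("configuration error: missing stage input 'library'")
    truth: dict[str, bool] | None = None
    if "synthetic" in lib_cfg:
        syn = lib_cfg["synthetic"]
        model, ref = pharmacophore.default_gpr40_model()
        spec = LibrarySpec(
            n_actives=int(syn.get("n_actives", 100)),
            n_decoys=int(syn.get("n_decoys", 900)),
            model=model,
            geometric_noise_sd=float(syn.get("noise_sd", 0.0)),
            seed=seed,
            reference_points=ref,
        )
        library, truth = make_feature_library(spec)
    elif "smiles_csv" in lib_cfg:
        from .chemio import generate_conformers, read_smiles_table

        mols, _ = read_smiles_table(lib_cfg["smiles_csv"])
        library = [generate_conformers(m, seed=seed) for m in mols]
        model = None
    else:
        raise FunnelError("configuration error: library needs 'synthetic' or 'smiles_csv'")
    n_library = len(library)
    stage_counts["library"] = n_library
    retention["library"] = 100.0
    records = {m.id: FunnelRecord(id=m.id) for m in library}
    logger.info("stage library: %d molecules (%.1fs)", n_library, time.time() - t0)

    # ---- stage 1: pharmacophore screen ------------------------------------
    ph_cfg = config.get("pharmacophore", {"default": True})
    if "model_yaml" in ph_cfg:
        model = pharmacophore.PharmModel.from_yaml(ph_cfg["model_yaml"])
    elif model is None:
        model, _ = pharmacophore.default_gpr40_model()
    hits_df = pharmacophore.screen(model, library)
    hit_ids = set(hits_df["id"])
    for mid in hit_ids:
        records[mid].pharm_hit = True
    survivors = [m for m in library if m.id in hit_ids]
    stage_counts["pharmacophore"] = len(survivors)
    retention["pharmacophore"] = round(100.0 * len(survivors) / n_library, 2)
    if outdir:
        hits_df.to_csv(outdir / "pharm_hits.csv", index=False)

    # ---- stage 2: ML triage ----------------------------------------------
    tri_cfg = config.get("triage")
    if tri_cfg and survivors:
        if "activity_csv" in tri_cfg:
            table = pd.read_csv(tri_cfg["activity_csv"])
        else:
            syn = tri_cfg.get("synthetic", {})
            table = make_activity_table(
                ActivityTableSpec(
                    n=int(syn.get("n", 1500)),
                    active_fraction=float(syn.get("active_fraction", 0.5)),
                    ec50_noise_sd=float(syn.get("ec50_noise_sd", 0.3)),
                    seed=seed + 1,
                )
            )
        labeled = ml_triage.label_activities(table)
        X, ok = ml_triage.featurize_smiles(labeled["smiles"].tolist())
        y = labeled.loc[ok, "label"].to_numpy()
        _, best_report, best_clf, _ = ml_triage.split_sweep(X, y, seed=seed)
        kept, pct, _ = ml_triage.classify_library(best_clf, survivors)
        for m in kept:
            records[m.id].ml_active = True
        survivors = kept
        stage_counts["ml_triage"] = len(survivors)
        retention["ml_triage"] = round(100.0 * len(survivors) / n_library, 2)
        logger.info(
            "stage ml_triage: kept %d (%s acc %.3f)",
            len(survivors), best_report.name, best_report.accuracy,
        )

    # ---- stage 3: docking ingestion ---------------------------------------
    dock_cfg = config.get("docking")
    if dock_cfg and survivors:
        scores = ingest_docking_scores(dock_cfg["scores_csv"])
        control_id = str(dock_cfg.get("control_id", "Control"))
        row = scores[scores["id"] == control_id]
        if row.empty:
            raise FunnelError(f"configuration error: docking control {control_id!r} absent")
        control_score = float(row["score"].iloc[0])
        candidates = scores[scores["id"] != control_id]
        passed = select_better_than_control(
            candidates, control_score, strict=bool(dock_cfg.get("strict", False))
        )
        passed_ids = set(passed["id"])
        for _, r in candidates.iterrows():
            if r["id"] in records:
                records[r["id"]].docking_score = float(r["score"])
        survivors = [m for m in survivors if m.id in passed_ids]
        stage_counts["docking"] = len(survivors)
        retention["docking"] = round(100.0 * len(survivors) / n_library, 2)

    # ---- stage 4: novelty filter -------------------------------------------
    nov_cfg = config.get("novelty")
    if nov_cfg and survivors:
        refs = [(str(i), s) for i, s in nov_cfg["references"]]
        threshold = float(nov_cfg.get("threshold", similarity.NOVELTY_THRESHOLD))
        cands = []
        for m in survivors:
            smi = getattr(m, "smiles", None) or m.properties.get("scaffold_smiles")
            if smi:
                cands.append((m.id, smi))
        rep = similarity.similarity_report(cands, refs, threshold)
        flag_by_id = dict(zip(rep["id"], rep["flag"]))
        for m in survivors:
            records[m.id].novelty = flag_by_id.get(m.id, "novel")
        survivors = [m for m in survivors if flag_by_id.get(m.id, "novel") == "novel"]
        stage_counts["novelty"] = len(survivors)
        retention["novelty"] = round(100.0 * len(survivors) / n_library, 2)
        if outdir:
            rep.to_csv(outdir / "novelty.csv", index=False)

    # ---- stage 5: energetics ranking ---------------------------------------
    en_cfg = config.get("energetics")
    if en_cfg and survivors:
        from .energetics import read_ledger_csv

        ledgers = read_ledger_csv(en_cfg["ledger_csv"])
        control_id = str(en_cfg.get("control_id", "Control"))
        control = next((l for l in ledgers if l.id == control_id), None)
        if control is None:
            raise FunnelError(f"configuration error: energetics control {control_id!r} absent")
        candidates = [l for l in ledgers if l.id != control_id]
        _, better = rank_against_control(candidates, control)
        better_ids = set(l.id for l in better)
        for l in candidates:
            if l.id in records:
                records[l.id].mmpbsa_total = l.total
        survivors = [m for m in survivors if m.id in better_ids]
        stage_counts["energetics"] = len(survivors)
        retention["energetics"] = round(100.0 * len(survivors) / n_library, 2)

    table = final_report([records[m.id] for m in survivors])
    if outdir:
        table.to_csv(outdir / "final_report.csv", index=False)
    report = FunnelReport(seed, stage_counts, retention, records, table)
    logger.info("funnel complete in %.1fs\n%s", time.time() - t0, report.summary())
    return report
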