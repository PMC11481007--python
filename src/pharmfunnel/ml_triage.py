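"""EC50-thresholded machine-learning triage of screening hits.

Compounds with EC50 <= 1000 nM (1 uM, inclusive) are labeled active.
Molecules are featurized with RDKit physicochemical descriptors plus
MACCS (166 bits) and Morgan radius-2 (2048 bits) fingerprints; a
leaderboard of classifier families (gradient-boosted trees, random
forest, extra trees, AdaBoost, decision tree, bagging, SVM, ...) is
trained over a sweep of train/test ratios from 80/20 to 70/30 and the
best (ratio, model) pair by test accuracy is selected.  The chosen model
then filters a compound library, reporting the retention percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("pharmfunnel")

#: activity threshold, nM (1 uM, inclusive)
ACTIVITY_THRESHOLD_NM = 1000.0

#: 2D descriptor block computed per molecule
_DESCRIPTOR_NAMES = (
    "MolWt", "MolLogP", "TPSA", "NumHAcceptors", "NumHDonors",
    "NumRotatableBonds", "NumAromaticRings", "RingCount", "FractionCSP3",
    "HeavyAtomCount", "NumAliphaticRings", "NOCount", "NHOHCount",
)


class TriageError(Exception):
    pass


class EmptyDatasetError(TriageError):
    pass


class StratificationError(TriageError):
    pass


@dataclass
class ModelReport:
    """Held-out evaluation of one classifier family."""

    name: str
    accuracy: float
    roc_auc: float
    f1: float
    confusion: tuple[int, int, int, int]  # tn, fp, fn, tp
    precision_active: float
    recall_active: float
    precision_inactive: float
    recall_inactive: float
    cv_scores: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------

def label_activities(
    records: pd.DataFrame, threshold_nM: float = ACTIVITY_THRESHOLD_NM
) -> pd.DataFrame:
    """Label records active iff EC50 <= threshold; clean duplicates.

    Rows with missing/non-positive EC50 are dropped; duplicate ids keep
    the lowest EC50 (logged).  Raises :class:`EmptyDatasetError` when
    nothing survives.
    """
    df = records.copy()
    df["ec50_nM"] = pd.to_numeric(df["ec50_nM"], errors="coerce")
    df = df[df["ec50_nM"].notna() & (df["ec50_nM"] > 0)]
    n_dup = df.duplicated("id").sum()
    if n_dup:
        logger.info("label_activities: collapsing %d duplicate ids", n_dup)
        df = df.sort_values(["id", "ec50_nM"], kind="mergesort")
        df = df.drop_duplicates("id", keep="first")
    df = df.reset_index(drop=True)
    if df.empty:
        raise EmptyDatasetError("no rows with a defined positive EC50")
    df["label"] = (df["ec50_nM"] <= threshold_nM).astype(int)
    return df


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def featurize_smiles(
    smiles: list[str],
    use_descriptors: bool = True,
    use_maccs: bool = True,
    n_morgan_bits: int = 2048,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix for a SMILES list.

    Returns ``(X, ok_mask)`` — rows of descriptors + MACCS + Morgan bits
    for parseable SMILES; ``ok_mask`` marks which inputs featurized.
    Constant columns are retained here and dropped at fit time.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem, Descriptors, MACCSkeys

    desc_fns = {n: getattr(Descriptors, n) for n in _DESCRIPTOR_NAMES}
    rows = []
    ok = np.zeros(len(smiles), dtype=bool)
    gen = AllChem.GetMorganGenerator(radius=2, fpSize=n_morgan_bits)
    for i, smi in enumerate(smiles):
        rd = Chem.MolFromSmiles(smi)
        if rd is None:
            continue
        parts = []
        if use_descriptors:
            parts.append(np.array([f(rd) for f in desc_fns.values()], dtype=float))
        if use_maccs:
            parts.append(
                np.frombuffer(
                    MACCSkeys.GenMACCSKeys(rd).ToBitString().encode(), dtype="S1"
                ).astype(float)
            )
        if n_morgan_bits:
            fp = gen.GetFingerprint(rd)
            parts.append(
                np.frombuffer(fp.ToBitString().encode(), dtype="S1").astype(float)
            )
        rows.append(np.concatenate(parts))
        ok[i] = True
    if not rows:
        return np.zeros((0, 0)), ok
    X = np.vstack(rows)
    X = np.nan_to_num(X, nan=0.0, posinf=0.0, neginf=0.0)
    return X, ok


# ---------------------------------------------------------------------------
# model families
# ---------------------------------------------------------------------------

def default_model_families(seed: int = 0) -> dict:
    """>= 7 representative classifier families with fixed hyperparameters."""
    from lightgbm import LGBMClassifier
    from sklearn.ensemble import (
        AdaBoostClassifier,
        BaggingClassifier,
        ExtraTreesClassifier,
        RandomForestClassifier,
    )
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "adaboost": AdaBoostClassifier(n_estimators=100, random_state=seed),
        "bagging": BaggingClassifier(n_estimators=50, random_state=seed),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
        "extra_trees": ExtraTreesClassifier(n_estimators=200, random_state=seed),
        "gradient_boosted": LGBMClassifier(
            n_estimators=200, random_state=seed, verbosity=-1
        ),
        "random_forest": RandomForestClassifier(n_estimators=200, random_state=seed),
        "svm": SVC(kernel="rbf", random_state=seed),
    }


def _drop_constant(X_train: np.ndarray, X_test: np.ndarray):
    keep = X_train.std(axis=0) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.debug("dropping %d constant feature columns", n_dropped)
    return X_train[:, keep], X_test[:, keep], keep


def _evaluate_model(name, clf, X_test, y_test) -> ModelReport:
    from sklearn.metrics import (
        confusion_matrix,
        f1_score,
        precision_score,
        recall_score,
        roc_auc_score,
    )

    y_pred = clf.predict(X_test)
    if hasattr(clf, "predict_proba"):
        scores = clf.predict_proba(X_test)[:, 1]
    else:
        scores = clf.decision_function(X_test)
    tn, fp, fn, tp = confusion_matrix(y_test, y_pred, labels=[0, 1]).ravel()
    return ModelReport(
        name=name,
        accuracy=float((tp + tn) / max(len(y_test), 1)),
        roc_auc=float(roc_auc_score(y_test, scores)),
        f1=float(f1_score(y_test, y_pred, zero_division=0)),
        confusion=(int(tn), int(fp), int(fn), int(tp)),
        precision_active=float(precision_score(y_test, y_pred, zero_division=0)),
        recall_active=float(recall_score(y_test, y_pred, zero_division=0)),
        precision_inactive=float(
            precision_score(y_test, y_pred, pos_label=0, zero_division=0)
        ),
        recall_inactive=float(
            recall_score(y_test, y_pred, pos_label=0, zero_division=0)
        ),
    )


def train_compare(
    X_train, y_train, X_test, y_test, families: dict | None = None, seed: int = 0
) -> tuple[list[ModelReport], dict]:
    """Fit each family; return reports (sorted by accuracy desc, name asc)
    and the fitted estimators keyed by name.  A family whose fit raises is
    logged and skipped."""
    if families is None:
        families = default_model_families(seed)
    X_train, X_test, keep = _drop_constant(np.asarray(X_train), np.asarray(X_test))
    reports = []
    fitted = {}
    for name in sorted(families):
        clf = families[name]
        try:
            clf.fit(X_train, y_train)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("train_compare: %s failed (%s); skipped", name, exc)
            continue
        clf._feature_mask_ = keep  # so classify_library can re-featurize
        reports.append(_evaluate_model(name, clf, X_test, y_test))
        fitted[name] = clf
    reports.sort(key=lambda r: (-r.accuracy, r.name))
    return reports, fitted


def split_sweep(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    ratios: tuple[float, ...] = (0.80, 0.78, 0.76, 0.74, 0.72, 0.70),
    families: dict | None = None,
):
    """Stratified train/test split sweep from 80/20 to 70/30 (step 0.02).

    Fits every family at every ratio; selects the (ratio, model) with
    highest test accuracy, ties resolved toward the larger training
    fraction and then lexicographic model name.  Returns
    ``(best_ratio, best_report, best_estimator, leaderboard)`` where
    leaderboard maps ratio -> list of ModelReport.
    """
    from sklearn.model_selection import train_test_split

    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 20:
        raise StratificationError(
            "split sweep needs >= 20 rows per class"
        )
    leaderboard = {}
    best = None  # (acc, train_fraction, name) maximized
    for ratio in ratios:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=ratio, random_state=seed, shuffle=True, stratify=y
        )
        if len(np.unique(y_te)) < 2:  # pragma: no cover
            raise StratificationError(f"class absent from test split at {ratio}")
        reports, fitted = train_compare(
            X_tr, y_tr, X_te, y_te,
            families=dict(families) if families else None, seed=seed,
        )
        leaderboard[ratio] = reports
        for r in reports:
            key = (r.accuracy, ratio, _neg_name(r.name))
            if best is None or key > best[0]:
                best = (key, ratio, r, fitted[r.name])
    _, best_ratio, best_report, best_clf = best
    logger.info(
        "split_sweep: selected %s at train fraction %.2f (accuracy %.3f)",
        best_report.name, best_ratio, best_report.accuracy,
    )
    return best_ratio, best_report, best_clf, leaderboard


class _neg_name(str):
    """Orders lexicographically reversed so max() prefers earlier names."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def cross_validate(model, X, y, k: int = 20, seed: int = 0) -> list[float]:
    """Stratified k-fold accuracy scores (fold assignment seeded)."""
    from sklearn.base import clone
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    y = np.asarray(y)
    minority = np.bincount(y).min()
    if k > minority:
        raise TriageError(f"k={k} exceeds minority-class count {minority}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = cross_val_score(clone(model), X, y, cv=skf, scoring="accuracy")
    return [float(s) for s in scores]


# ---------------------------------------------------------------------------
# library filtering
# ---------------------------------------------------------------------------

def classify_library(model, molecules, smiles: list[str] | None = None):
    """Apply a trained classifier to a molecule list.

    ``molecules`` may be Molecule/FeatureCloud objects (SMILES pulled
    from chemistry or the ``scaffold_smiles`` property) or plain ids when
    ``smiles`` is given.  Returns ``(kept, retention_pct, n_skipped)``
    with input order preserved and retention reported to 2 decimals.
    """
    if smiles is None:
        smiles = []
        for m in molecules:
            smi = getattr(m, "smiles", None) or m.properties.get("scaffold_smiles")
            smiles.append(smi if smi else "")
    X, ok = featurize_smiles(smiles)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("classify_library: %d molecules not featurizable", n_skipped)
    kept = []
    if len(X):
        mask = getattr(model, "_feature_mask_", None)
        if mask is not None:
            X = X[:, mask]
        preds = model.predict(X)
        ok_idx = np.flatnonzero(ok)
        for idx, pred in zip(ok_idx, preds):
            if pred == 1:
                kept.append(molecules[idx])
    retention = retention_percentage(len(kept), len(molecules))
    return kept, retention, n_skipped


def retention_percentage(n_kept: int, n_total: int) -> float:
    """100 * kept / total, rounded to 2 decimals (0 for an empty input)."""
    if n_total == 0:
        return 0.0
    return round(100.0 * n_kept / n_total, 2)
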