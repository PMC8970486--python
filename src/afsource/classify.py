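"""Classifiers for AF mechanism detection and their evaluation.

Three binary tasks are defined over the four episode categories
(driver-type focal source, initiator-type focal source, FS-induced AF,
reentrant AF):

* ``fs_presence`` — is a focal source present? positive = driver-type or
  initiator-type FS;
* ``af_sustainability`` — is there an arrhythmogenic substrate that
  sustains AF without the focal discharges? positive = FS-induced AF,
  reentrant AF, or initiator-type FS; negative = driver-type FS;
* ``fs_location`` — for FS-driven episodes only, is the focal site on the
  right atrium (positive) rather than the left atrium / pulmonary veins?

Training balances classes with SMOTE oversampling and fits a 200-tree
random forest; generalization across anatomies is measured by nested
leave-one-patient-out cross-validation, with the number of extracted
sources K selected on inner one-patient validation folds. Signal-level
classifier outputs map to one of six mechanisms, which aggregate to a
patient-level mechanism call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "AtrialSite",
    "EpisodeLabel",
    "TaskSpec",
    "TASKS",
    "MechanismCall",
    "PatientMechanism",
    "Mechanism",
    "smote_balance",
    "train_task",
    "nested_lopo_cv",
    "evaluate",
    "auroc",
    "predict_mechanism",
    "aggregate_patient",
]

CATEGORIES = ("driver_fs", "initiator_fs", "fs_induced_af", "reentrant_af")
FS_CATEGORIES = ("driver_fs", "initiator_fs")


@dataclass(frozen=True)
class AtrialSite:
    """Focal site in universal atrial coordinates (alpha, beta) or a PV id."""

    chamber: str  # LA | RA | PV
    alpha: float | None = None
    beta: float | None = None
    vein: str | None = None

    def __post_init__(self):
        if self.chamber not in ("LA", "RA", "PV"):
            raise ValueError(f"chamber must be LA, RA or PV, got {self.chamber!r}")
        if self.chamber == "PV":
            if self.vein is None:
                raise ValueError("PV site needs a vein id")
        else:
            if self.alpha is None or self.beta is None:
                raise ValueError("grid site needs (alpha, beta)")


@dataclass(frozen=True)
class EpisodeLabel:
    """Ground truth for one analyzed segment."""

    category: str
    patient_id: str
    segment_id: str
    focal_site: AtrialSite | None = None
    focal_cl_ms: float | None = None
    ach: bool = False
    parent_segment_id: str | None = None  # FS-induced AF -> its initiator FS

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        has_focus = self.focal_site is not None and self.focal_cl_ms is not None
        if self.category in FS_CATEGORIES and not has_focus:
            raise ValueError(f"{self.category} episode needs focal_site and focal_cl_ms")
        if self.category not in FS_CATEGORIES and (
            self.focal_site is not None or self.focal_cl_ms is not None
        ):
            raise ValueError(f"{self.category} episode must not carry focal info")


@dataclass(frozen=True)
class TaskSpec:
    """Binary task: which segments are eligible and which are positive."""

    name: str
    eligible: Callable[[EpisodeLabel], bool]
    positive: Callable[[EpisodeLabel], bool]


TASKS: Mapping[str, TaskSpec] = {
    "fs_presence": TaskSpec(
        name="fs_presence",
        eligible=lambda lab: True,
        positive=lambda lab: lab.category in FS_CATEGORIES,
    ),
    "af_sustainability": TaskSpec(
        name="af_sustainability",
        eligible=lambda lab: True,
        positive=lambda lab: lab.category != "driver_fs",
    ),
    "fs_location": TaskSpec(
        name="fs_location",
        eligible=lambda lab: lab.category in FS_CATEGORIES,
        positive=lambda lab: lab.focal_site is not None
        and lab.focal_site.chamber == "RA",
    ),
}


# ---------------------------------------------------------------------------
# SMOTE


def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    seed: int | np.random.Generator = 0,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts by SMOTE oversampling.

    Every minority class is topped up to the majority count with synthetic
    rows: each new row is a uniform convex combination of a random class
    member and one of its k nearest within-class neighbors. Original rows
    are preserved verbatim. ``k_neighbors`` is reduced automatically (with
    a warning) when a class is smaller than k+1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("SMOTE needs at least two classes")
    if counts.min() < 2:
        raise ValueError("SMOTE needs >= 2 examples per class")
    target = int(counts.max())
    out_X, out_y = [X], [y]
    for cls, n in zip(classes, counts):
        need = target - int(n)
        if need == 0:
            continue
        Xc = X[y == cls]
        k = min(k_neighbors, int(n) - 1)
        if k < k_neighbors:
            warnings.warn(
                f"class {cls!r} has only {n} rows; SMOTE k reduced to {k}",
                stacklevel=2,
            )
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # column 0 is the point itself
        base = rng.integers(0, Xc.shape[0], size=need)
        nb = idx[base, rng.integers(1, k + 1, size=need)]
        gap = rng.random((need, 1))
        synth = Xc[base] + gap * (Xc[nb] - Xc[base])
        out_X.append(synth)
        out_y.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(out_X), np.concatenate(out_y)


# ---------------------------------------------------------------------------
# Training and evaluation


def _task_rows(labels: Sequence[EpisodeLabel], task: TaskSpec):
    idx = [i for i, lab in enumerate(labels) if task.eligible(lab)]
    yb = np.array([task.positive(labels[i]) for i in idx], dtype=int)
    return np.array(idx, dtype=int), yb


def train_task(
    features: np.ndarray,
    labels: Sequence[EpisodeLabel],
    task: TaskSpec | str,
    n_trees: int = 200,
    seed: int = 0,
) -> RandomForestClassifier:
    """SMOTE-balance the eligible rows and fit a 200-tree random forest."""
    if isinstance(task, str):
        task = TASKS[task]
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    idx, yb = _task_rows(labels, task)
    if idx.size == 0:
        raise ValueError(f"no eligible segments for task {task.name!r}")
    Xb, yb = smote_balance(features[idx], yb, seed=seed)
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    model.fit(Xb, yb)
    return model


def evaluate(
    preds: np.ndarray,
    truth: np.ndarray,
    labels: Sequence[EpisodeLabel] | None = None,
    restrict_to_fs: bool = False,
) -> dict:
    """Accuracy, precision and recall of binary predictions.

    ``restrict_to_fs`` scores only segments whose category is a focal
    source (the "evaluated on FS-driven episodes" setting); it requires
    the aligned ``labels``. Precision with no predicted positives (and
    recall with no true positives) is NaN with a warning.
    """
    preds = np.asarray(preds, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if preds.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    mask = np.ones(preds.size, dtype=bool)
    if restrict_to_fs:
        if labels is None:
            raise ValueError("restrict_to_fs requires the episode labels")
        mask = np.array([lab.category in FS_CATEGORIES for lab in labels])
    p, t = preds[mask], truth[mask]
    tp = int(np.sum((p == 1) & (t == 1)))
    fp = int(np.sum((p == 1) & (t == 0)))
    fn = int(np.sum((p == 0) & (t == 1)))
    acc = float(np.mean(p == t)) if p.size else float("nan")
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision undefined", stacklevel=2)
        prec = float("nan")
    else:
        prec = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no true positives; recall undefined", stacklevel=2)
        rec = float("nan")
    else:
        rec = tp / (tp + fn)
    return {"accuracy": acc, "precision": prec, "recall": rec, "n": int(p.size)}


def auroc(scores, binary_truth) -> float:
    """Rank-based AUROC with midrank tie handling."""
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=float)
    t = np.asarray(binary_truth, dtype=int)
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes in the truth")
    r = rankdata(s)
    return float((r[t == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Nested leave-one-patient-out cross-validation


@dataclass
class FoldResult:
    test_patient: str
    chosen_K: int
    metrics: dict
    n_test: int


def nested_lopo_cv(
    features_by_k: Mapping[int, np.ndarray],
    labels: Sequence[EpisodeLabel],
    task: TaskSpec | str,
    seed: int = 0,
    n_trees: int = 200,
) -> dict:
    """Nested leave-one-patient-out cross-validation with K selection.

    The outer loop holds out one patient as the test set. The inner loop
    cycles one further patient out of the remainder as a validation set
    and picks the K (key of ``features_by_k``) with the highest mean
    inner accuracy (ties broken toward the smallest K — cheaper
    extraction). The model is then retrained with the chosen K on the
    full training+validation rows and scored on the held-out patient.

    Returns per-fold results plus mean and s.d. of accuracy, precision
    and recall across folds.
    """
    if isinstance(task, str):
        task = TASKS[task]
    k_grid = sorted(features_by_k)
    n_rows = len(labels)
    for K, F in features_by_k.items():
        if np.asarray(F).shape[0] != n_rows:
            raise ValueError(f"feature matrix for K={K} has wrong row count")
    patients = sorted({lab.patient_id for lab in labels})
    if len(patients) < 3:
        raise ValueError("nested LOPO needs >= 3 patients")
    elig_idx, y_all = _task_rows(labels, task)
    elig_patients = np.array([labels[i].patient_id for i in elig_idx])

    folds: list[FoldResult] = []
    for test_p in patients:
        test_mask = elig_patients == test_p
        if not np.any(test_mask):
            warnings.warn(f"patient {test_p} has no eligible segments; fold skipped",
                          stacklevel=2)
            continue
        pool_mask = ~test_mask
        pool_patients = sorted(set(elig_patients[pool_mask]))

        # inner loop: one-patient validation for each candidate K
        mean_acc = {}
        for K in k_grid:
            F = np.asarray(features_by_k[K], dtype=float)[elig_idx]
            accs = []
            for val_p in pool_patients:
                val_mask = pool_mask & (elig_patients == val_p)
                trn_mask = pool_mask & (elig_patients != val_p)
                y_trn = y_all[trn_mask]
                if np.unique(y_trn).size < 2 or np.min(np.bincount(y_trn)) < 2:
                    continue  # inner fold lacks a trainable class split
                Xb, yb = smote_balance(F[trn_mask], y_trn, seed=seed)
                m = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
                m.fit(Xb, yb)
                accs.append(float(np.mean(m.predict(F[val_mask]) == y_all[val_mask])))
            mean_acc[K] = float(np.mean(accs)) if accs else -np.inf
        best_K = max(k_grid, key=lambda K: (mean_acc[K], -K))

        # retrain on the full pool with the chosen K, score on the test patient
        F = np.asarray(features_by_k[best_K], dtype=float)[elig_idx]
        y_pool = y_all[pool_mask]
        if np.unique(y_pool).size < 2:
            warnings.warn(f"training pool for patient {test_p} is single-class; "
                          "fold skipped", stacklevel=2)
            continue
        Xb, yb = smote_balance(F[pool_mask], y_pool, seed=seed)
        m = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        m.fit(Xb, yb)
        preds = m.predict(F[test_mask])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny test folds may lack a class
            metrics = evaluate(preds, y_all[test_mask])
        folds.append(
            FoldResult(
                test_patient=test_p,
                chosen_K=best_K,
                metrics=metrics,
                n_test=int(test_mask.sum()),
            )
        )

    summary = {}
    for key in ("accuracy", "precision", "recall"):
        vals = np.array([f.metrics[key] for f in folds], dtype=float)
        ok = vals[np.isfinite(vals)]
        summary[f"{key}_mean"] = float(ok.mean()) if ok.size else float("nan")
        summary[f"{key}_sd"] = float(ok.std(ddof=1)) if ok.size > 1 else 0.0
    return {"folds": folds, "summary": summary, "task": task.name}


# ---------------------------------------------------------------------------
# Mechanism mapping (signal level) and patient aggregation


class Mechanism:
    INITIATOR_LA_PV = "initiator_fs_la_pv"
    INITIATOR_RA = "initiator_fs_ra"
    DRIVER_LA_PV = "driver_fs_la_pv"
    DRIVER_RA = "driver_fs_ra"
    SUSTAINED_AF_NO_FS = "sustained_af_without_fs"
    NEITHER = "neither_af_nor_fs"


@dataclass(frozen=True)
class MechanismCall:
    """Signal-level mechanism derived from the three classifier outputs."""

    signal_level: str
    fs_presence: bool
    af_sustainability: bool
    fs_location: bool | None  # True = RA; ignored when fs_presence is negative


@dataclass(frozen=True)
class PatientMechanism:
    patient_id: str
    mechanisms: frozenset
    group: str  # group1 = single-atrial initiator-type FS; group2 = other


def predict_mechanism(
    fs_presence: bool,
    af_sustainability: bool,
    fs_location: bool | None = None,
) -> MechanismCall:
    """Map (FS presence, AF sustainability, FS-on-RA) outputs to a mechanism.

    When FS presence is negative the location output is irrelevant and may
    be omitted; when positive it is required.
    """
    if fs_presence:
        if fs_location is None:
            raise ValueError("fs_location output required when FS presence is positive")
        if af_sustainability:
            mech = Mechanism.INITIATOR_RA if fs_location else Mechanism.INITIATOR_LA_PV
        else:
            mech = Mechanism.DRIVER_RA if fs_location else Mechanism.DRIVER_LA_PV
    else:
        mech = Mechanism.SUSTAINED_AF_NO_FS if af_sustainability else Mechanism.NEITHER
    return MechanismCall(
        signal_level=mech,
        fs_presence=fs_presence,
        af_sustainability=af_sustainability,
        fs_location=fs_location if fs_presence else None,
    )


def aggregate_patient(patient_id: str, calls: Sequence[MechanismCall]) -> PatientMechanism:
    """Union the signal-level mechanisms and assign the survival group.

    Group 1: at least one initiator-type FS call and all initiator-type
    calls originate from the same atrium. Group 2: everything else.
    """
    if not calls:
        raise ValueError("need at least one mechanism call")
    mechs = frozenset(c.signal_level for c in calls)
    has_la = Mechanism.INITIATOR_LA_PV in mechs
    has_ra = Mechanism.INITIATOR_RA in mechs
    group = "group1" if (has_la != has_ra) else "group2"
    return PatientMechanism(patient_id=patient_id, mechanisms=mechs, group=group)
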