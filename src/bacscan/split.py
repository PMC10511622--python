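"""Patient-level stratified train/validation/test splitting.

BAC cohorts are strongly age-structured (prevalence rises steeply with age),
so positives are split within age-quartile classes to preserve the BAC+ age
distribution across subsets; negatives are split globally.  All four views of
a patient travel together (view cohesion), and the training subset is
rebalanced by randomly undersampling negatives to a target patient-level BAC+
prevalence (default 30%) while validation and test keep the natural
prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SplitConfig", "SplitAssignment", "age_classes", "class_of_age",
           "stratified_split", "undersample_training_negatives",
           "assignment_to_frame"]

SUBSETS = ("train", "val", "test")


@dataclass(frozen=True)
class SplitConfig:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    target_train_prevalence: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if not 0.0 < self.target_train_prevalence <= 1.0:
            raise ValueError("target_train_prevalence must be in (0, 1]")


@dataclass
class SplitAssignment:
    subset_of: dict[str, str]              # patient_id -> train/val/test
    retained: dict[str, bool]              # False for undersampled-away patients
    quartiles: tuple[float, float, float]  # (Q1, Q2, Q3) in years
    degenerate_classes: bool               # True when quartiles coincide
    counts: pd.DataFrame = field(repr=False)

    def patients(self, subset: str, retained_only: bool = True) -> list[str]:
        return [p for p, s in self.subset_of.items()
                if s == subset and (self.retained[p] or not retained_only)]


def age_classes(ages) -> tuple[float, float, float]:
    """Age-quartile thresholds (Q1, Q2, Q3) by linear interpolation.

    Classes are [min, Q1], (Q1, Q2], (Q2, Q3], (Q3, max].
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 4:
        raise ValueError("need at least 4 ages to form quartile classes")
    q1, q2, q3 = np.percentile(ages, [25, 50, 75])
    return float(q1), float(q2), float(q3)


def class_of_age(age: float, quartiles: tuple[float, float, float]) -> int:
    return int(np.searchsorted(np.asarray(quartiles), age, side="left"))


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Apportion n into integer parts closest to n*fractions.

    Remaining units go to the largest fractional remainders; ties are broken
    by subset order (train first).
    """
    quotas = [n * f for f in fractions]
    parts = [int(np.floor(q)) for q in quotas]
    short = n - sum(parts)
    remainders = [q - p for q, p in zip(quotas, parts)]
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        parts[i] += 1
    return parts


def _patient_table(cohort: pd.DataFrame) -> pd.DataFrame:
    required = {"patient_id", "age", "label"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    pt = (cohort.groupby("patient_id")
                .agg(age=("age", "first"), label=("label", "max"))
                .reset_index()
                .sort_values("patient_id", kind="stable")
                .reset_index(drop=True))
    return pt


def stratified_split(cohort: pd.DataFrame, config: SplitConfig) -> SplitAssignment:
    """Assign patients to train/val/test.

    Positives are shuffled and split by the configured fractions within each
    age class (largest-remainder rounding); negatives are split globally.
    Patients are canonically sorted by id before shuffling, so the assignment
    is invariant to the row order of the input table.
    """
    config.validate()
    pt = _patient_table(cohort)
    quartiles = age_classes(pt["age"].to_numpy())
    degenerate = len(set(quartiles)) < 3

    rng = np.random.default_rng(config.seed)
    subset_of: dict[str, str] = {}

    pos = pt[pt["label"] > 0]
    for cls in range(4):
        ids = [pid for pid, age in zip(pos["patient_id"], pos["age"])
               if class_of_age(age, quartiles) == cls]
        if 0 < len(ids) < 3:
            warnings.warn(f"age class {cls} has only {len(ids)} BAC+ patients; "
                          "some subsets may be empty", stacklevel=2)
        ids = sorted(ids)
        perm = rng.permutation(len(ids))
        parts = _largest_remainder(len(ids), config.fractions)
        cursor = 0
        for subset, k in zip(SUBSETS, parts):
            for j in perm[cursor:cursor + k]:
                subset_of[ids[j]] = subset
            cursor += k

    neg_ids = sorted(pt[pt["label"] == 0]["patient_id"])
    perm = rng.permutation(len(neg_ids))
    parts = _largest_remainder(len(neg_ids), config.fractions)
    cursor = 0
    for subset, k in zip(SUBSETS, parts):
        for j in perm[cursor:cursor + k]:
            subset_of[neg_ids[j]] = subset
        cursor += k

    retained = {pid: True for pid in subset_of}
    counts = _audit_counts(pt, subset_of, retained, quartiles)
    return SplitAssignment(subset_of=subset_of, retained=retained,
                           quartiles=quartiles, degenerate_classes=degenerate,
                           counts=counts)


def undersample_training_negatives(assignment: SplitAssignment,
                                   cohort: pd.DataFrame,
                                   config: SplitConfig,
                                   rng: np.random.Generator | None = None
                                   ) -> SplitAssignment:
    """Undersample BAC- training patients to the target BAC+ prevalence.

    Keeps all positives and n_neg = round(n_pos * (1 - p) / p) negatives;
    discarded patients stay mapped to 'train' but are flagged retained=False.
    Validation and test subsets are untouched.  If the target prevalence is
    at or below the natural one, the assignment is returned unchanged with a
    warning.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    pt = _patient_table(cohort)
    label_of = dict(zip(pt["patient_id"], pt["label"]))

    train_ids = sorted(p for p, s in assignment.subset_of.items() if s == "train")
    pos_ids = [p for p in train_ids if label_of[p] > 0]
    neg_ids = [p for p in train_ids if label_of[p] == 0]
    if not pos_ids:
        raise ValueError("training subset has no BAC+ patients")
    p = config.target_train_prevalence
    n_keep = int(np.floor(len(pos_ids) * (1.0 - p) / p + 0.5))
    retained = dict(assignment.retained)
    if n_keep >= len(neg_ids):
        warnings.warn("target prevalence at or below the natural training "
                      "prevalence; undersampling is a no-op", stacklevel=2)
    else:
        keep = set(np.asarray(neg_ids)[rng.permutation(len(neg_ids))[:n_keep]])
        for pid in neg_ids:
            retained[pid] = pid in keep

    counts = _audit_counts(pt, assignment.subset_of, retained,
                           assignment.quartiles)
    return SplitAssignment(subset_of=dict(assignment.subset_of),
                           retained=retained,
                           quartiles=assignment.quartiles,
                           degenerate_classes=assignment.degenerate_classes,
                           counts=counts)


def _audit_counts(pt: pd.DataFrame, subset_of: dict[str, str],
                  retained: dict[str, bool],
                  quartiles: tuple[float, float, float]) -> pd.DataFrame:
    rows = []
    for subset in SUBSETS:
        ids = [p for p, s in subset_of.items() if s == subset and retained[p]]
        sub = pt[pt["patient_id"].isin(ids)]
        row = {"subset": subset,
               "n_patients": len(sub),
               "n_pos": int((sub["label"] > 0).sum()),
               "n_neg": int((sub["label"] == 0).sum())}
        for cls in range(4):
            in_cls = sub["age"].map(lambda a: class_of_age(a, quartiles) == cls)
            row[f"pos_class{cls}"] = int((sub["label"][in_cls] > 0).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def assignment_to_frame(assignment: SplitAssignment) -> pd.DataFrame:
    ids = sorted(assignment.subset_of)
    return pd.DataFrame({
        "patient_id": ids,
        "subset": [assignment.subset_of[p] for p in ids],
        "retained": [bool(assignment.retained[p]) for p in ids],
    })
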