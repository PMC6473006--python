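"""Symptom questionnaire encoding, cohort consistency screen, and the
variable-vs-class correlation screen.

Each subject answers seven yes/no symptom questions (loss of
consciousness, headache, nausea/vomiting, light sensitivity, sound
sensitivity, confusion, memory dysfunction) and rates each endorsed
symptom's severity on a 0–6 scale.  The analysis uses 8 variables: the
seven binary answers plus the average severity over all seven items.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SingleClassError, ValidationError

SYMPTOM_ITEMS = [
    "loss_of_consciousness",
    "headache",
    "nausea_vomiting",
    "light_sensitivity",
    "sound_sensitivity",
    "confusion",
    "memory_dysfunction",
]

SYMPTOM_VARIABLES = SYMPTOM_ITEMS + ["severity_avg"]

__all__ = [
    "SYMPTOM_ITEMS",
    "SYMPTOM_VARIABLES",
    "SymptomReport",
    "encode_symptoms",
    "consistency_screen",
    "variable_class_correlation",
]


@dataclass
class SymptomReport:
    """Raw questionnaire: 7 yes/no answers and 7 severities in 0..6.

    A severity must be 0 whenever its item was answered "no"; an
    endorsed item may still carry severity 0 (present but negligible).
    """

    answers: dict[str, bool]
    severities: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [i for i in SYMPTOM_ITEMS if i not in self.answers]
        if missing:
            raise ValidationError(f"missing answers for {missing}")
        self.severities = {i: int(self.severities.get(i, 0)) for i in SYMPTOM_ITEMS}
        for item, sev in self.severities.items():
            if not 0 <= sev <= 6:
                raise ValidationError(f"{item}: severity {sev} outside 0..6")
            if sev > 0 and not self.answers[item]:
                raise ValidationError(
                    f"{item}: severity {sev} reported for a 'no' answer"
                )

    @property
    def n_yes(self) -> int:
        return sum(bool(self.answers[i]) for i in SYMPTOM_ITEMS)


def encode_symptoms(
    report: SymptomReport, severity_denominator: str = "all"
) -> pd.Series:
    """Encode a report into the 8 analysis variables.

    Yes/no answers map to 1/0; ``severity_avg`` divides the severity sum
    by all 7 items (default) or, with ``severity_denominator=
    "endorsed"``, by the number of endorsed items (0 if none).
    """
    binaries = [int(bool(report.answers[i])) for i in SYMPTOM_ITEMS]
    total = sum(report.severities[i] for i in SYMPTOM_ITEMS)
    if severity_denominator == "all":
        avg = total / len(SYMPTOM_ITEMS)
    elif severity_denominator == "endorsed":
        n = sum(binaries)
        avg = total / n if n else 0.0
    else:
        raise ValueError(f"unknown severity_denominator {severity_denominator!r}")
    return pd.Series(binaries + [avg], index=SYMPTOM_VARIABLES, dtype=float)


def symptom_table(subjects, severity_denominator: str = "all") -> pd.DataFrame:
    """Cohort-level symptom variable table from synthetic subjects.

    Index = subject_id; columns = label + the 8 symptom variables.
    """
    rows = {}
    labels = {}
    for s in subjects:
        rows[s.subject_id] = encode_symptoms(s.symptoms, severity_denominator)
        labels[s.subject_id] = s.label
    df = pd.DataFrame(rows).T
    df.insert(0, "label", pd.Series(labels))
    df.index.name = "subject_id"
    return df


def consistency_screen(
    table: pd.DataFrame,
    control_min_yes: int = 5,
    mtbi_max_yes: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove subjects whose questionnaire contradicts their class.

    Controls endorsing ``>= control_min_yes`` symptoms and mTBI subjects
    endorsing ``<= mtbi_max_yes`` symptoms are dropped.  ``table`` needs
    a ``label`` column (``mtbi``/``control``) and the 7 item columns.
    Returns ``(retained, removed)``; ``removed`` gains a ``reason``
    column.  The screen is idempotent.
    """
    if len(table) == 0:
        removed = table.copy()
        removed["reason"] = pd.Series(dtype=object)
        return table.copy(), removed
    n_yes = table[SYMPTOM_ITEMS].sum(axis=1)
    is_control = table["label"] == "control"
    is_mtbi = table["label"] == "mtbi"
    drop_control = is_control & (n_yes >= control_min_yes)
    drop_mtbi = is_mtbi & (n_yes <= mtbi_max_yes)
    removed = table[drop_control | drop_mtbi].copy()
    removed["reason"] = np.where(
        drop_control[drop_control | drop_mtbi],
        f"control with >= {control_min_yes} symptoms",
        f"mtbi with <= {mtbi_max_yes} symptoms",
    )
    retained = table[~(drop_control | drop_mtbi)].copy()
    return retained, removed


def variable_class_correlation(
    features: pd.DataFrame, labels
) -> pd.DataFrame:
    """Point-biserial correlation of each variable with the class vector.

    ``labels`` may be strings (``mtbi`` = positive) or ±1 / 0-1 codes.
    Returns a DataFrame indexed by variable with columns ``r``, ``p``
    and ``constant`` (True where the column has zero variance, leaving
    r and p undefined).  p-values come from the exact t transform with
    n−2 degrees of freedom (two-sided).
    """
    y = _class_vector(labels)
    if len(y) < 3:
        raise ValidationError("need at least 3 subjects for the screen")
    if y.min() == y.max():
        raise SingleClassError("both classes must be present")
    out = []
    for col in features.columns:
        x = np.asarray(features[col], dtype=float)
        if np.ptp(x) == 0:
            out.append((col, np.nan, np.nan, True))
            continue
        r, p = stats.pearsonr(x, y)
        out.append((col, r, p, False))
    df = pd.DataFrame(out, columns=["variable", "r", "p", "constant"])
    return df.set_index("variable")


def _class_vector(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "UOS":
        return (labels == "mtbi").astype(float)
    arr = labels.astype(float)
    return (arr > 0).astype(float)
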