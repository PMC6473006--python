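"""ROC analysis over held-out boosting scores.

Because the class priors of a deployed concussion screen are unknown,
no single operating weighting is privileged: the classifier is re-run
under a sweep of relative class weights, each run's held-out scores
yield one ROC member, and the family is summarized by vertical
averaging (mean/min/max true-positive rate at fixed false-positive
rate) together with the member AUCs.  Integer weight ratios 1..10 on
either arm — {1:k} ∪ {k:1}, k = 1..10 — give the 19 distinct settings.

Also here: ordered score listings, per-class score distributions, and
the randomization control that destroys the EEG–symptom row pairing to
show the EEG contribution is carried by within-subject correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics

from .boost import BoostConfig, CVResult, FeatureMatrix, loocv
from .errors import SingleClassError

__all__ = [
    "ROCCurve",
    "ROCFamily",
    "ScoreDistribution",
    "roc_curve",
    "weight_settings",
    "roc_family",
    "ordered_scores",
    "score_distributions",
    "randomization_control",
]


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


@dataclass
class ROCFamily:
    settings: list[tuple[float, float]]          # (w_pos, w_neg) per member
    curves: dict[tuple[float, float], ROCCurve]
    cv: dict[tuple[float, float], CVResult]
    fpr_grid: np.ndarray
    tpr_mean: np.ndarray
    tpr_min: np.ndarray
    tpr_max: np.ndarray
    member_aucs: np.ndarray
    auc_mean: float
    auc_min: float
    auc_max: float
    auc_of_mean_curve: float
    failed: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.curves)


def roc_curve(scores, labels) -> ROCCurve:
    """ROC by threshold sweep; AUC equals the Mann–Whitney statistic.

    ``labels`` are ±1 (or truthy for the positive class).  Tied scores
    step diagonally.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    y01 = (y > 0).astype(int)
    if y01.min() == y01.max():
        raise SingleClassError("ROC needs both classes")
    fpr, tpr, thr = metrics.roc_curve(y01, scores)
    return ROCCurve(fpr, tpr, thr, float(metrics.auc(fpr, tpr)))


def weight_settings(grid=range(1, 11)) -> list[tuple[float, float]]:
    """Distinct class-weight ratios {1:k} ∪ {k:1} over an integer grid.

    For the default grid 1..10 this yields the 19 settings, ordered
    from control-heavy (1:10) through 1:1 to mTBI-heavy (10:1).
    """
    ks = sorted(set(int(k) for k in grid))
    left = [(1.0, float(k)) for k in reversed(ks)]          # 1:10 ... 1:1
    right = [(float(k), 1.0) for k in ks if k != 1]         # 2:1 ... 10:1
    return left + right


def roc_family(
    fm: FeatureMatrix,
    config: BoostConfig = BoostConfig(),
    grid=range(1, 11),
    n_grid: int = 101,
) -> ROCFamily:
    """LOOCV once per class-weight setting; aggregate the member ROCs.

    Aggregation is vertical: each member's TPR is linearly interpolated
    onto a common ``n_grid``-point FPR grid and the pointwise mean, min
    and max taken.  ``auc_mean``/``auc_min``/``auc_max`` summarize the
    member AUCs; the AUC of the mean curve is reported separately.
    """
    settings = weight_settings(grid)
    curves, cvs, failed = {}, {}, []
    for w_pos, w_neg in settings:
        try:
            res = loocv(fm.with_weights(w_pos, w_neg), config)
            ok = np.isfinite(res.scores)
            curves[(w_pos, w_neg)] = roc_curve(res.scores[ok], res.y[ok])
            cvs[(w_pos, w_neg)] = res
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(
                f"weight setting {w_pos}:{w_neg} failed ({exc}); excluded",
                stacklevel=2,
            )
            failed.append((w_pos, w_neg))
    if not curves:
        raise SingleClassError("no ROC member could be computed")
    fpr_grid = np.linspace(0, 1, n_grid)
    tprs = np.vstack(
        [np.interp(fpr_grid, c.fpr, c.tpr) for c in curves.values()]
    )
    aucs = np.array([c.auc for c in curves.values()])
    tpr_mean = tprs.mean(axis=0)
    return ROCFamily(
        settings=settings,
        curves=curves,
        cv=cvs,
        fpr_grid=fpr_grid,
        tpr_mean=tpr_mean,
        tpr_min=tprs.min(axis=0),
        tpr_max=tprs.max(axis=0),
        member_aucs=aucs,
        auc_mean=float(aucs.mean()),
        auc_min=float(aucs.min()),
        auc_max=float(aucs.max()),
        auc_of_mean_curve=float(np.trapezoid(tpr_mean, fpr_grid)),
        failed=failed,
    )


def ordered_scores(scores, labels) -> pd.DataFrame:
    """Scores sorted ascending with class tags (zero = class boundary)."""
    df = pd.DataFrame({"score": np.asarray(scores, dtype=float),
                       "label": np.asarray(labels)})
    return df.sort_values("score", kind="stable").reset_index(drop=True)


@dataclass
class ScoreDistribution:
    mean_pos: float
    sd_pos: float
    mean_neg: float
    sd_neg: float
    separation: float  # mean_pos − mean_neg


def score_distributions(scores, labels) -> ScoreDistribution:
    """Per-class score mean/SD and the between-class mean separation."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos, neg = scores[y > 0], scores[~(y > 0)]
    if len(pos) == 0 or len(neg) == 0:
        raise SingleClassError("score distributions need both classes")

    def sd(a):
        return float(np.std(a, ddof=1)) if len(a) > 1 else 0.0

    return ScoreDistribution(
        mean_pos=float(pos.mean()),
        sd_pos=sd(pos),
        mean_neg=float(neg.mean()),
        sd_neg=sd(neg),
        separation=float(pos.mean() - neg.mean()),
    )


@dataclass
class RandomizationResult:
    combined_auc: float             # unpermuted combined family mean AUC
    symptom_auc: float              # symptoms-only family mean AUC
    permuted_aucs: np.ndarray       # combined mean AUC per EEG-row permutation


def randomization_control(
    eeg: pd.DataFrame,
    sym: pd.DataFrame,
    labels,
    n_perm: int = 20,
    seed: int = 0,
    config: BoostConfig = BoostConfig(),
    grid=range(1, 11),
) -> RandomizationResult:
    """Destroy the EEG–subject pairing and re-measure the combined AUC.

    Whole EEG feature rows are permuted across subjects (jointly, so
    within-EEG correlations survive) while symptoms and labels stay
    put; the combined-model family AUC is recomputed per permutation.
    If the EEG block helps only through its within-subject correlation
    with class and symptoms, the permuted combined AUC should fall back
    to the symptoms-only AUC.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    from .boost import assemble

    rng = np.random.default_rng(seed)
    combined = roc_family(assemble(eeg, sym, labels, "combined"), config, grid)
    sym_only = roc_family(assemble(None, sym, labels, "symptoms_only"),
                          config, grid)
    permuted = []
    for _ in range(n_perm):
        perm = rng.permutation(len(eeg))
        eeg_p = pd.DataFrame(
            eeg.to_numpy()[perm], index=eeg.index, columns=eeg.columns
        )
        fam = roc_family(assemble(eeg_p, sym, labels, "combined"), config, grid)
        permuted.append(fam.auc_mean)
    return RandomizationResult(
        combined_auc=combined.auc_mean,
        symptom_auc=sym_only.auc_mean,
        permuted_aucs=np.array(permuted),
    )
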