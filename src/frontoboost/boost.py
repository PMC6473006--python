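"""Totally-corrective boosting (TotalBoost) with decision stumps.

Unlike AdaBoost's single-constraint update, a totally-corrective
booster re-solves the whole weight problem each round: after selecting
the stump with the largest weighted edge, the example distribution is
projected (in relative entropy, with the class-weighted prior as the
reference measure) onto the set of distributions under which *every*
stump chosen so far has edge at most ``γ_min − ν``, where ``γ_min`` is
the smallest best-edge seen and ``ν`` a slack parameter.  The Lagrange
multipliers of that projection are the nonnegative stump coefficients,
and as rounds proceed they converge to the margin-maximizing convex
combination of stumps.

The projection is solved on its convex dual

    minimize  log Σ_i d0_i exp(−(Uᵀα)_i) + bound · Σ_t α_t ,   α ≥ 0

(U rows are the signed stump/label agreement vectors), which is smooth
and low-dimensional; the primal distribution is the softmax of
``log d0 − Uᵀα``.  Class priors enter through the reference
distribution ``d0`` — this is how the ROC stage sweeps class weights.

Weak learners are axis-aligned depth-1 stumps with thresholds at the
midpoints of sorted unique values, which keeps the hypothesis space
exactly enumerable.  The fit is fully deterministic: equal-edge ties
break lexicographically by (variable index, threshold).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SingleClassError, ValidationError

__all__ = [
    "BoostConfig",
    "Stump",
    "BoostModel",
    "FeatureMatrix",
    "CVResult",
    "fit",
    "score",
    "loocv",
    "subset_search",
    "assemble",
]


@dataclass(frozen=True)
class BoostConfig:
    max_learners: int = 200
    nu: float = 0.01          # edge slack; larger = softer margin, faster stop
    tol: float = 1e-8         # allowed constraint violation in the projection
    tie_policy: str = "positive"  # score exactly 0 -> mTBI (fail-safe)


@dataclass(frozen=True)
class Stump:
    """Predicts ``polarity`` where ``x[var] >= threshold``, else ``-polarity``."""

    var: int
    threshold: float
    polarity: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(
            X[:, self.var] >= self.threshold, self.polarity, -self.polarity
        )


@dataclass
class BoostModel:
    stumps: list[Stump]
    alphas: np.ndarray              # nonnegative coefficients, one per stump
    feature_names: list[str]
    config: BoostConfig
    converged: str = "max_learners"  # "edge", "margin_converged", ...
    n_rounds: int = 0
    trace: list[float] | None = None  # per-round training error (optional)

    def votes(self, X: np.ndarray) -> np.ndarray:
        if not self.stumps:
            return np.zeros((len(X), 0))
        return np.column_stack([s.predict(X) for s in self.stumps])

    def score(self, X) -> np.ndarray:
        """Normalized ensemble vote Σ α h(x) / Σ α, in [−1, +1]."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"expected {len(self.feature_names)} variables, got {X.shape[1]}"
            )
        total = self.alphas.sum()
        if not self.stumps or total <= 0:
            return np.zeros(len(X))
        return self.votes(X) @ self.alphas / total

    def predict(self, X) -> np.ndarray:
        s = self.score(X)
        tie = 1 if self.config.tie_policy == "positive" else -1
        return np.where(s > 0, 1, np.where(s < 0, -1, tie))

    def to_json(self) -> dict:
        return {
            "stumps": [
                {"var": s.var, "threshold": s.threshold, "polarity": s.polarity}
                for s in self.stumps
            ],
            "alphas": self.alphas.tolist(),
            "feature_names": list(self.feature_names),
            "config": {
                "max_learners": self.config.max_learners,
                "nu": self.config.nu,
                "tol": self.config.tol,
                "tie_policy": self.config.tie_policy,
            },
            "converged": self.converged,
            "n_rounds": self.n_rounds,
        }


@dataclass
class FeatureMatrix:
    """Subjects × variables with labels and class weights.

    ``y`` is ±1 (+1 = mTBI).  ``w_pos``/``w_neg`` weight the classes in
    the boosting reference distribution (relative values only).
    """

    X: np.ndarray
    names: list[str]
    groups: list[str]  # "eeg" | "symptom" per column
    y: np.ndarray
    w_pos: float = 1.0
    w_neg: float = 1.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValidationError("X rows must match label count")
        if self.X.shape[1] != len(self.names):
            raise ValidationError("column metadata must match X width")
        if np.isnan(self.X).any():
            raise ValidationError("missing entries in the feature matrix")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValidationError("labels must be ±1")

    @property
    def n(self) -> int:
        return len(self.y)

    def with_weights(self, w_pos: float, w_neg: float) -> "FeatureMatrix":
        return replace(self, w_pos=w_pos, w_neg=w_neg)

    def subset_rows(self, idx) -> "FeatureMatrix":
        return replace(self, X=self.X[idx], y=self.y[idx])


def assemble(
    eeg: pd.DataFrame | None,
    sym: pd.DataFrame | None,
    labels,
    case: str = "combined",
    symptom_subset: tuple[str, ...] | None = None,
) -> FeatureMatrix:
    """Build a FeatureMatrix for one of the standard variable sets.

    ``case`` is ``eeg_only`` (12 variables), ``symptoms_only`` (8), or
    ``combined`` (20).  ``symptom_subset`` restricts the symptom block
    to the named columns (used by the subset search).
    """
    blocks, names, groups = [], [], []
    if case in ("eeg_only", "combined"):
        blocks.append(np.asarray(eeg, dtype=float))
        names += list(eeg.columns)
        groups += ["eeg"] * eeg.shape[1]
    if case in ("symptoms_only", "combined"):
        s = sym if symptom_subset is None else sym.loc[:, list(symptom_subset)]
        blocks.append(np.asarray(s, dtype=float))
        names += list(s.columns)
        groups += ["symptom"] * s.shape[1]
    if not blocks:
        raise ValidationError(f"unknown case {case!r}")
    labels = np.asarray(labels)
    y = np.where(labels == "mtbi", 1, -1) if labels.dtype.kind in "UOS" \
        else labels.astype(int)
    return FeatureMatrix(np.hstack(blocks), names, groups, y)


# ---------------------------------------------------------------------------
# candidate stump enumeration
# ---------------------------------------------------------------------------

def _candidate_stumps(X: np.ndarray):
    """All midpoint-threshold stumps (positive polarity) as a matrix.

    Returns (H, var_idx, thresholds): H[k, i] = sign(x_i[var_k] -
    thr_k) ∈ {−1, +1}.  Candidates are ordered lexicographically by
    (variable, threshold), which fixes tie-breaking.
    """
    n, d = X.shape
    rows, var_idx, thrs = [], [], []
    for j in range(d):
        u = np.unique(X[:, j])
        if len(u) < 2:
            continue
        mids = 0.5 * (u[:-1] + u[1:])
        preds = np.where(X[None, :, j] >= mids[:, None], 1, -1)
        rows.append(preds)
        var_idx.extend([j] * len(mids))
        thrs.extend(mids.tolist())
    if not rows:
        return np.zeros((0, n), dtype=np.int8), np.array([], int), np.array([])
    return (
        np.vstack(rows).astype(np.int8),
        np.array(var_idx, dtype=int),
        np.array(thrs),
    )


# ---------------------------------------------------------------------------
# entropy projection (dual)
# ---------------------------------------------------------------------------

def _dual_fg(alpha, ln_d0, U, bound):
    """Dual objective/gradient; also returns the implied distribution."""
    z = ln_d0 - U.T @ alpha
    zmax = z.max()
    ez = np.exp(z - zmax)
    s = ez.sum()
    d = ez / s
    f = zmax + np.log(s) + bound * alpha.sum()
    return f, bound - U @ d, d


def _project(ln_d0, U, bound, alpha0, tol):
    """Min-relative-entropy projection onto {d : U d <= bound}.

    The dual (smooth, convex, dimension = number of stumps) is solved
    by a damped projected-Newton iteration with the explicit t×t
    Hessian ``U diag(d) Uᵀ − (Ud)(Ud)ᵀ``, warm-started from the
    previous round, with an L-BFGS-B fall-back if Newton stalls.
    Returns ``(alpha, d, feasible)``; primal infeasibility shows up as
    diverging multipliers / a dual objective running to −∞.
    """
    t = U.shape[0]
    alpha = np.asarray(alpha0, dtype=float).copy()
    f, g, d = _dual_fg(alpha, ln_d0, U, bound)
    feasible = True
    converged = False
    for _it in range(100):
        if f < -60.0 or alpha.max(initial=0.0) > 1e6:
            feasible = False
            break
        # KKT: free coords need g ~ 0; coords at 0 need g >= 0
        at_zero = alpha <= 1e-14
        kkt = np.where(at_zero, np.minimum(g, 0.0), g)
        if np.max(np.abs(kkt)) <= max(tol, 1e-10):
            converged = True
            break
        free = ~(at_zero & (g >= 0.0))
        if not free.any():
            converged = True
            break
        Uf = U[free]
        Ud = Uf @ d
        Hf = (Uf * d) @ Uf.T - np.outer(Ud, Ud)
        Hf[np.diag_indices_from(Hf)] += 1e-12
        try:
            step_f = np.linalg.solve(Hf, g[free])
        except np.linalg.LinAlgError:
            step_f = g[free]
        step = np.zeros(t)
        step[free] = -step_f
        # backtracking line search with projection onto alpha >= 0
        s = 1.0
        for _ls in range(30):
            cand = np.maximum(alpha + s * step, 0.0)
            fc, gc, dc = _dual_fg(cand, ln_d0, U, bound)
            if fc <= f - 1e-12 or fc < -60.0:
                alpha, f, g, d = cand, fc, gc, dc
                break
            s *= 0.5
        else:
            # no descent along the Newton direction: try steepest descent
            s = 1.0
            improved = False
            for _ls in range(30):
                cand = np.maximum(alpha - s * g, 0.0)
                fc, gc, dc = _dual_fg(cand, ln_d0, U, bound)
                if fc <= f - 1e-12:
                    alpha, f, g, d = cand, fc, gc, dc
                    improved = True
                    break
                s *= 0.5
            if not improved:
                break  # numerically stationary
    if feasible and not converged:
        alpha, d, feasible = _project_lbfgs(ln_d0, U, bound, alpha)

    f, _, d = _dual_fg(alpha, ln_d0, U, bound)
    if f < -60.0:
        feasible = False
    if feasible:
        viol = float(np.max(U @ d - bound)) if t else 0.0
        feasible = viol < max(tol, 1e-8) * 10 + 1e-6
    return alpha, d, feasible


def _project_lbfgs(ln_d0, U, bound, alpha0):
    """General-solver fallback for the dual projection (L-BFGS-B)."""
    from scipy import optimize

    def fg(alpha):
        f, g, _ = _dual_fg(alpha, ln_d0, U, bound)
        return f, g

    res = optimize.minimize(
        fg, alpha0, jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * U.shape[0],
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    alpha = np.maximum(res.x, 0.0)
    f, _, d = _dual_fg(alpha, ln_d0, U, bound)
    feasible = f > -60.0 and alpha.max(initial=0.0) < 1e6
    return alpha, d, feasible


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit(
    fm: FeatureMatrix,
    config: BoostConfig = BoostConfig(),
    record_trace: bool = False,
) -> BoostModel:
    """Fit the totally-corrective stump ensemble.

    Stops at ``max_learners`` rounds, when no stump has edge above the
    slack ``ν`` (no weak learner), when the best edge no longer
    violates the accumulated constraints (optimality), or on an
    infeasible projection (partial model returned with a warning).
    """
    y = fm.y.astype(float)
    if len(np.unique(fm.y)) < 2:
        raise SingleClassError("training data contains a single class")
    H, var_idx, thrs = _candidate_stumps(fm.X)
    w = np.where(fm.y > 0, fm.w_pos, fm.w_neg).astype(float)
    d0 = w / w.sum()
    ln_d0 = np.log(d0)
    d = d0.copy()

    Hy = H * y[None, :]  # Hy[k] = y_i * h_k(x_i)
    stumps: list[Stump] = []
    stump_index: dict[tuple[int, float, int], int] = {}
    U_rows: list[np.ndarray] = []
    alpha = np.zeros(0)
    gamma_min = np.inf
    converged = "max_learners"

    # The bound γ_min − ν tightens by at least ν whenever the best edge
    # fails to violate the current constraints, so the loop needs a few
    # extra tightening iterations beyond the learner budget.
    max_iter = config.max_learners + int(np.ceil(2.0 / config.nu)) + 10
    trace: list[float] = []
    tie = 1 if config.tie_policy == "positive" else -1
    if len(Hy) == 0:
        converged = "no_candidates"
    for _round in range(max_iter):
        if len(Hy) == 0:
            break
        edges = Hy @ d
        abs_edges = np.abs(edges)
        best = abs_edges.max()
        # deterministic tie-break: first candidate in (var, threshold) order
        k = int(np.flatnonzero(abs_edges >= best - 1e-12)[0])
        best = float(abs_edges[k])
        if best <= config.nu:
            converged = "edge"
            break
        polarity = 1 if edges[k] >= 0 else -1
        key = (int(var_idx[k]), float(thrs[k]), polarity)
        is_new = key not in stump_index
        if is_new and len(stumps) >= config.max_learners:
            converged = "max_learners"
            break
        gamma_min = min(gamma_min, best)
        if is_new:
            stump_index[key] = len(stumps)
            stumps.append(Stump(*key))
            U_rows.append(polarity * Hy[k].astype(float))
            alpha = np.append(alpha, 0.0)
        U = np.vstack(U_rows)
        alpha_new, d_new, feasible = _project(
            ln_d0, U, gamma_min - config.nu, alpha, config.tol
        )
        if not feasible:
            # The chosen stumps certify that no distribution keeps all
            # their edges below the bound — the bound has crossed the
            # achievable margin, and the last feasible dual solution is
            # the margin-maximizing coefficient vector.  This is the
            # normal TotalBoost termination.
            converged = "margin_converged"
            if alpha.sum() <= 0 and len(stumps) == 1:
                # a perfectly separating stump (edge 1) makes even the
                # first projection infeasible; that stump alone is the
                # margin-maximizing ensemble
                alpha = np.ones(1)
            if record_trace and alpha.sum() > 0:
                margin = alpha @ np.vstack(U_rows)
                err = (margin < 0) | ((margin == 0) & (fm.y != tie))
                trace.append(float(np.mean(err)))
            if alpha.sum() <= 0:
                warnings.warn(
                    "projection infeasible before any coefficient was "
                    "assigned; returning a partial model",
                    stacklevel=2,
                )
                converged = "infeasible"
            break
        alpha, d = alpha_new, d_new
        if record_trace:
            margin = alpha @ np.vstack(U_rows)  # y_i * f(x_i), unnormalized
            err = (margin < 0) | ((margin == 0) & (fm.y != tie))
            trace.append(float(np.mean(err)))
    else:
        converged = "iteration_cap"

    return BoostModel(
        stumps=stumps,
        alphas=alpha if len(stumps) else np.zeros(0),
        feature_names=list(fm.names),
        config=config,
        converged=converged,
        n_rounds=len(stumps),
        trace=trace if record_trace else None,
    )


def score(model: BoostModel, x) -> np.ndarray:
    """Module-level alias for :meth:`BoostModel.score`."""
    return model.score(x)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    scores: np.ndarray          # held-out score per subject
    predictions: np.ndarray     # held-out ±1 per subject
    y: np.ndarray
    accuracy: float
    resubstitution_accuracy: float
    skipped_folds: list[int] = field(default_factory=list)

    def to_frame(self, subject_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "label": self.y,
                "score": self.scores,
                "prediction": self.predictions,
                "fold": np.arange(len(self.y)),
            }
        )
        if subject_ids is not None:
            df.insert(0, "subject_id", list(subject_ids))
        return df


def loocv(fm: FeatureMatrix, config: BoostConfig = BoostConfig()) -> CVResult:
    """Leave-one-out cross-validation plus resubstitution accuracy.

    One fold per subject; folds whose training half loses a class
    entirely are skipped with a warning (their prediction is NaN and
    they count as errors).  The procedure is deterministic and
    independent of subject order.
    """
    n = fm.n
    if n < 3:
        raise ValidationError("LOOCV needs at least 3 subjects")
    if len(np.unique(fm.y)) < 2:
        raise SingleClassError("LOOCV requires both classes")
    scores = np.full(n, np.nan)
    preds = np.zeros(n)
    skipped = []
    for i in range(n):
        keep = np.arange(n) != i
        if len(np.unique(fm.y[keep])) < 2:
            warnings.warn(f"fold {i}: training set single-class; skipped",
                          stacklevel=2)
            skipped.append(i)
            continue
        model = fit(fm.subset_rows(keep), config)
        scores[i] = model.score(fm.X[i : i + 1])[0]
        preds[i] = model.predict(fm.X[i : i + 1])[0]
    evaluated = ~np.isin(np.arange(n), skipped)
    acc = float(np.mean(preds[evaluated] == fm.y[evaluated])) if evaluated.any() else 0.0
    full = fit(fm, config)
    resub = float(np.mean(full.predict(fm.X) == fm.y))
    return CVResult(scores, preds, fm.y.copy(), acc, resub, skipped)


# ---------------------------------------------------------------------------
# exhaustive symptom-subset search
# ---------------------------------------------------------------------------

def subset_search(
    eeg: pd.DataFrame,
    sym: pd.DataFrame,
    labels,
    config: BoostConfig = BoostConfig(),
    cardinality=None,
) -> pd.DataFrame:
    """LOOCV accuracy for every symptom subset joined to all EEG variables.

    Enumerates the full power set of the symptom columns (2^8 = 256 for
    the standard 8), including the empty set (EEG only) and the full
    set.  ``cardinality`` optionally restricts subset sizes (e.g.
    ``[3, 4]``).  Returns a DataFrame ranked by accuracy (descending),
    ties broken by smaller subsets first, then lexicographically.
    """
    cols = list(sym.columns)
    rows = []
    for r in range(len(cols) + 1):
        if cardinality is not None and r not in cardinality:
            continue
        for combo in itertools.combinations(cols, r):
            fm = assemble(eeg, sym, labels, "combined", symptom_subset=combo) \
                if combo else assemble(eeg, None, labels, "eeg_only")
            res = loocv(fm, config)
            rows.append(
                {
                    "subset": combo,
                    "n_symptoms": r,
                    "loocv_accuracy": res.accuracy,
                    "resubstitution_accuracy": res.resubstitution_accuracy,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["loocv_accuracy", "n_symptoms", "subset"],
        ascending=[False, True, True],
    ).reset_index(drop=True)
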