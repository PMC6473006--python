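"""Totally-corrective boosting: contracts, invariants, and equivalence
with an exhaustive-stump + generic-convex-solver oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from frontoboost import boost
from frontoboost.boost import BoostConfig, FeatureMatrix, fit, loocv
from frontoboost.errors import SingleClassError, ValidationError


def _fm(X, y, **kw):
    X = np.asarray(X, dtype=float)
    names = [f"v{j}" for j in range(X.shape[1])]
    return FeatureMatrix(X, names, ["eeg"] * X.shape[1], np.asarray(y), **kw)


# ---------------------------------------------------------------------------
# independent oracle: plain-loop stump enumeration, SLSQP dual projection
# ---------------------------------------------------------------------------

def _oracle_stumps(X):
    out = []
    for j in range(X.shape[1]):
        vals = sorted(set(X[:, j]))
        for a, b in zip(vals, vals[1:]):
            out.append((j, (a + b) / 2.0))
    return out


def _oracle_project(d0, U, bound):
    """Dual of the entropy projection via a generic solver (SLSQP)."""
    U = np.asarray(U, dtype=float)
    t = len(U)

    def f(alpha):
        z = np.log(d0) - U.T @ alpha
        m = z.max()
        return m + np.log(np.sum(np.exp(z - m))) + bound * alpha.sum()

    res = optimize.minimize(
        f, np.zeros(t), method="SLSQP",
        bounds=[(0.0, 1e4)] * t,
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    alpha = np.maximum(res.x, 0.0)
    z = np.log(d0) - U.T @ alpha
    d = np.exp(z - z.max())
    d /= d.sum()
    infeasible = f(alpha) < -60.0 or alpha.max(initial=0.0) > 1e4 - 1e-6
    return alpha, d, infeasible


def oracle_totalboost(X, y, nu=0.01, max_learners=200):
    """Reference implementation on exhaustively enumerated stumps."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    cand = _oracle_stumps(X)
    d0 = np.full(n, 1.0 / n)
    d = d0.copy()
    chosen, U = [], []
    alpha = np.zeros(0)
    gamma_min = np.inf
    for _ in range(max_learners + int(np.ceil(2.0 / nu)) + 10):
        best_edge, best = 0.0, None
        for j, thr in cand:  # lexicographic (variable, threshold) order
            h = np.where(X[:, j] >= thr, 1.0, -1.0)
            e = float(np.sum(d * y * h))
            if abs(e) > best_edge + 1e-12:
                best_edge, best = abs(e), (j, thr, 1 if e >= 0 else -1)
        if best is None or best_edge <= nu:
            break
        gamma_min = min(gamma_min, best_edge)
        if best not in chosen:
            if len(chosen) >= max_learners:
                break
            chosen.append(best)
            j, thr, pol = best
            U.append(pol * y * np.where(X[:, j] >= thr, 1.0, -1.0))
        a_new, d_new, infeasible = _oracle_project(d0, U, gamma_min - nu)
        if infeasible:
            if alpha.sum() <= 0 and len(chosen) == 1:
                alpha = np.ones(1)  # a perfect stump is the whole model
            break
        alpha, d = a_new, d_new
    alpha = alpha if len(alpha) == len(chosen) else np.zeros(len(chosen))

    def predict(Xq):
        if not chosen or alpha.sum() <= 0:
            return np.ones(len(Xq))
        s = np.zeros(len(Xq))
        for (j, thr, pol), a in zip(chosen, alpha):
            s += a * pol * np.where(Xq[:, j] >= thr, 1.0, -1.0)
        return np.where(s > 0, 1, np.where(s < 0, -1, 1))

    return predict


class TestFitContracts:
    def test_separable_singleton_one_stump(self):
        fm = _fm([[0.0], [0.0], [1.0], [1.0]], [-1, -1, 1, 1])
        model = fit(fm)
        assert len(model.stumps) == 1
        assert np.all(model.predict(fm.X) == fm.y)
        assert model.score(fm.X).min() >= -1
        assert model.score(fm.X).max() <= 1

    def test_xor_is_not_stump_separable(self):
        """Axis stumps produce additive scores, so parity labels defeat
        them: every stump has zero edge and the ensemble stays empty."""
        X = [[0, 0], [1, 1], [0, 1], [1, 0]]
        y = [1, 1, -1, -1]
        model = fit(_fm(X, y))
        assert model.n_rounds == 0
        assert np.mean(model.predict(np.asarray(X, float)) == y) == 0.5
        oracle = oracle_totalboost(np.asarray(X, float), y)
        np.testing.assert_array_equal(
            model.predict(np.asarray(X, float)),
            oracle(np.asarray(X, float)),
        )

    def test_contradictory_duplicates_bound_resubstitution(self):
        X = [[1.0, 2.0], [1.0, 2.0], [0.0, 1.0], [0.0, 1.0]]
        y = [1, -1, 1, -1]
        model = fit(_fm(X, y))
        assert np.mean(model.predict(np.asarray(X, float)) == y) < 1.0

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            fit(_fm([[0.0], [1.0]], [1, 1]))

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError):
            _fm([[np.nan], [1.0]], [1, -1])

    def test_training_error_nonincreasing(self, informative_tables):
        eeg, sym, labels = informative_tables
        fm = boost.assemble(eeg, sym, labels, "combined")
        model = fit(fm, record_trace=True)
        errs = model.trace
        assert len(errs) >= 1
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))


class TestScore:
    def test_unanimous_vote_saturates(self):
        fm = _fm([[0.0], [1.0]], [-1, 1])
        model = fit(fm)
        assert model.score(np.array([[5.0]]))[0] == pytest.approx(1.0)
        assert model.score(np.array([[-5.0]]))[0] == pytest.approx(-1.0)

    def test_scores_match_brute_force_votes(self, small_tables):
        eeg, sym, labels = small_tables
        fm = boost.assemble(eeg, sym, labels, "combined")
        model = fit(fm)
        s = model.score(fm.X)
        brute = np.zeros(fm.n)
        for stump, a in zip(model.stumps, model.alphas):
            brute += a * np.where(
                fm.X[:, stump.var] >= stump.threshold, stump.polarity,
                -stump.polarity,
            )
        np.testing.assert_allclose(s, brute / model.alphas.sum(), atol=1e-12)
        assert np.all(np.abs(s) <= 1 + 1e-12)

    def test_variable_mismatch_rejected(self, small_tables):
        eeg, sym, labels = small_tables
        model = fit(boost.assemble(eeg, sym, labels, "combined"))
        with pytest.raises(ValidationError):
            model.score(np.zeros((1, 3)))


class TestOracleEquivalence:
    """Resubstitution predictions match the exhaustive-stump oracle on
    small instances (n <= 8, d <= 2)."""

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        X = rng.normal(size=(n, 2))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.normal(size=n) > 0,
                     1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        model = fit(_fm(X, y))
        oracle = oracle_totalboost(X, y)
        np.testing.assert_array_equal(model.predict(X), oracle(X))


class TestLOOCV:
    def test_one_prediction_per_subject(self, small_tables):
        eeg, sym, labels = small_tables
        fm = boost.assemble(eeg, sym, labels, "combined")
        res = loocv(fm)
        assert len(res.predictions) == fm.n
        assert len(res.scores) == fm.n
        assert np.isfinite(res.scores).all()
        assert 0.0 <= res.accuracy <= 1.0

    def test_separable_cohort_perfect_loocv(self):
        """A cleanly separated construction is classified perfectly."""
        rng = np.random.default_rng(1)
        n = 20
        y = np.array([1] * 10 + [-1] * 10)
        X = np.column_stack([
            y * 2.0 + 0.3 * rng.normal(size=n),
            rng.normal(size=n),
        ])
        res = loocv(_fm(X, y))
        assert res.accuracy == 1.0
        assert res.resubstitution_accuracy == 1.0

    def test_permuted_labels_give_chance(self, small_tables):
        eeg, sym, labels = small_tables
        accs = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            y = rng.permutation(np.where(labels == "mtbi", 1, -1))
            fm = _fm(np.asarray(pd.concat([eeg, sym], axis=1)), y)
            accs.append(loocv(fm, BoostConfig(max_learners=40)).accuracy)
        assert 0.2 <= np.mean(accs) <= 0.8

    def test_subject_order_invariance(self, small_tables):
        eeg, sym, labels = small_tables
        fm = boost.assemble(eeg, sym, labels, "combined")
        res = loocv(fm)
        rng = np.random.default_rng(3)
        perm = rng.permutation(fm.n)
        res_p = loocv(fm.subset_rows(perm))
        assert res_p.accuracy == pytest.approx(res.accuracy)
        assert res_p.resubstitution_accuracy == pytest.approx(
            res.resubstitution_accuracy)
        # scores agree to solver tolerance (summation order perturbs the
        # projection by ~1e-7, not enough to move any prediction)
        np.testing.assert_allclose(res_p.scores, res.scores[perm], atol=1e-5)
        np.testing.assert_array_equal(res_p.predictions, res.predictions[perm])

    def test_resubstitution_dominates_loocv_on_average(self):
        from conftest import cohort_tables
        from frontoboost.synthetic import CohortSpec, generate_cohort

        diffs = []
        for seed in range(5):
            spec = CohortSpec(n_mtbi=7, n_control=7, duration_s=8.0,
                              seed=seed)
            eeg, sym, labels = cohort_tables(generate_cohort(spec))
            fm = boost.assemble(eeg, sym, labels, "combined")
            res = loocv(fm, BoostConfig(max_learners=60))
            diffs.append(res.resubstitution_accuracy - res.accuracy)
        assert np.mean(diffs) >= 0.0


class TestSubsetSearch:
    def test_enumerates_power_set(self, small_tables):
        eeg, sym, labels = small_tables
        keep = slice(0, 12)  # 8 mTBI + 4 controls: enough for enumeration
        eeg, sym, labels = eeg.iloc[keep], sym.iloc[keep], labels[keep]
        cfg = BoostConfig(max_learners=10, nu=0.05)
        table = boost.subset_search(eeg, sym, labels, cfg)
        assert len(table) == 256
        subsets = list(table["subset"])
        assert subsets.count(()) == 1
        assert subsets.count(tuple(sym.columns)) == 1
        assert len(set(subsets)) == 256

    def test_cardinality_filter(self, small_tables):
        eeg, sym, labels = small_tables
        keep = slice(0, 12)
        eeg, sym, labels = eeg.iloc[keep], sym.iloc[keep], labels[keep]
        cfg = BoostConfig(max_learners=10, nu=0.05)
        table = boost.subset_search(eeg, sym.iloc[:, :3], labels, cfg)
        assert len(table) == 8
        limited = boost.subset_search(eeg, sym, labels, cfg,
                                      cardinality=[3, 4])
        from math import comb
        assert len(limited) == comb(8, 3) + comb(8, 4)
        assert set(limited["n_symptoms"]) == {3, 4}
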