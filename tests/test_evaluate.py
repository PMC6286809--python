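"""Reconstruction metrics and the GGM partial-correlation baseline."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import lyapnet as ln
from lyapnet.pipeline import ReplicateDataset


class TestGScore:
    @pytest.mark.parametrize(
        "tpr,fpr,expected",
        [
            (0.66, 0.08, 0.78),
            (0.69, 0.29, 0.70),
            (0.76, 0.12, 0.82),
            (0.95, 0.13, 0.91),
            (0.73, 0.16, 0.78),
            (0.75, 0.08, 0.83),
            (0.79, 0.31, 0.74),
        ],
    )
    def test_reference_values(self, tpr, fpr, expected):
        assert round(ln.g_score(tpr, fpr), 2) == expected

    def test_extremes(self):
        assert ln.g_score(1, 0) == 1.0
        assert ln.g_score(0, 0.3) == 0.0
        assert ln.g_score(0, 1) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ln.g_score(1.2, 0.1)
        with pytest.raises(ValueError):
            ln.g_score(0.5, -0.1)

    @given(
        st.floats(0.01, 0.99), st.floats(0.01, 0.99), st.floats(0.001, 0.009)
    )
    def test_monotone_in_tpr_and_fpr(self, tpr, fpr, eps):
        up_tpr = ln.g_score(min(tpr + eps, 1.0), fpr)
        up_fpr = ln.g_score(tpr, min(fpr + eps, 1.0))
        base = ln.g_score(tpr, fpr)
        assert up_tpr > base
        assert up_fpr < base


class TestTprFpr:
    def test_perfect_prediction(self):
        truth = np.array([[1, 0], [1, 1]], bool)
        ev = ln.tpr_fpr(truth, truth)
        assert (ev.tpr, ev.fpr, ev.g_score) == (1.0, 0.0, 1.0)

    def test_complement_prediction(self):
        truth = np.array([[1, 0], [1, 1]], bool)
        ev = ln.tpr_fpr(~truth, truth)
        assert (ev.tpr, ev.fpr) == (0.0, 1.0)

    def test_hand_counted_three_by_three(self):
        truth = np.zeros((3, 3), bool)
        truth[0, 0] = truth[1, 1] = truth[2, 2] = True  # 3 positives
        pred = np.zeros((3, 3), bool)
        pred[0, 0] = pred[1, 1] = True  # TP=2, FN=1
        pred[0, 1] = True  # FP=1, TN=5
        ev = ln.tpr_fpr(pred, truth)
        assert ev.tpr == pytest.approx(2 / 3)
        assert ev.fpr == pytest.approx(1 / 6)

    def test_exclude_diagonal(self):
        truth = np.eye(3, dtype=bool)
        truth[0, 1] = True
        pred = np.zeros((3, 3), bool)
        pred[0, 1] = True
        ev = ln.tpr_fpr(pred, truth, include_diagonal=False)
        assert ev.positions_evaluated == 6
        assert ev.tpr == 1.0 and ev.fpr == 0.0

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            ln.tpr_fpr(np.ones((2, 2), bool), np.ones((2, 2), bool))
        with pytest.raises(ValueError):
            ln.tpr_fpr(np.zeros((2, 2), bool), np.zeros((2, 2), bool))


class TestSparsity:
    def test_limits_and_arithmetic(self):
        assert ln.sparsity_of(np.zeros((4, 4))) == 1.0
        assert ln.sparsity_of(np.ones((4, 4))) == 0.0
        s = np.zeros((13, 13))
        s.reshape(-1)[:84] = 1
        assert ln.sparsity_of(s) == pytest.approx((169 - 84) / 169)


def make_dataset(values, names=None):
    values = np.asarray(values, float)
    names = names or [f"M{i+1}" for i in range(values.shape[1])]
    return ReplicateDataset(values=values, names=names)


class TestGGM:
    def test_chain_partial_correlation_vanishes(self):
        """X → Y → Z: corr(X,Z) is large but partial corr(X,Z | Y) ≈ 0."""
        rng = np.random.default_rng(0)
        m = 20_000
        x = rng.standard_normal(m)
        y = 0.9 * x + 0.4 * rng.standard_normal(m)
        z = 0.9 * y + 0.4 * rng.standard_normal(m)
        data = make_dataset(np.column_stack([x, y, z]))
        adj, pcor, _ = ln.ggm_infer(data)
        assert abs(np.corrcoef(x, z)[0, 1]) > 0.5
        assert abs(pcor[0, 2]) < 0.05
        assert adj[0, 1] and adj[1, 2] and not adj[0, 2]

    def test_tridiagonal_precision_recovered(self):
        """Gaussian with tridiagonal precision: recovered edges = the chain."""
        n, m = 4, 10_000
        P = np.eye(n) * 2.0
        for i in range(n - 1):
            P[i, i + 1] = P[i + 1, i] = -0.8
        cov = np.linalg.inv(P)
        rng = np.random.default_rng(1)
        X = rng.multivariate_normal(np.zeros(n), cov, size=m)
        adj, _, _ = ln.ggm_infer(make_dataset(X))
        expected = np.zeros((n, n), bool)
        for i in range(n - 1):
            expected[i, i + 1] = expected[i + 1, i] = True
        np.testing.assert_array_equal(adj, expected)

    def test_null_calibration(self):
        """Independent Gaussians: the false-edge rate tracks the p cutoff."""
        rng = np.random.default_rng(2)
        hits = total = 0
        for _ in range(40):
            X = rng.standard_normal((2000, 6))
            adj, _, _ = ln.ggm_infer(make_dataset(X), p_cutoff=0.01)
            iu = np.triu_indices(6, 1)
            hits += int(adj[iu].sum())
            total += len(iu[0])
        rate = hits / total
        assert 0.0005 < rate < 0.03  # ≈ 0.01 within Monte-Carlo error

    def test_invariant_to_per_metabolite_rescaling(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((500, 5)) @ rng.normal(size=(5, 5))
        d1 = make_dataset(X)
        scale = rng.uniform(0.1, 10, size=5)
        shift = rng.normal(size=5)
        d2 = make_dataset(X * scale + shift)
        adj1, _, p1 = ln.ggm_infer(d1)
        adj2, _, p2 = ln.ggm_infer(d2)
        np.testing.assert_array_equal(adj1, adj2)
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_matches_pingouin_partial_correlation(self):
        """Cross-check full-order partial correlations and p-values against
        an independent implementation."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 4)) @ rng.normal(size=(4, 4))
        _, pcor, pvals = ln.ggm_infer(make_dataset(X))
        df = pd.DataFrame(X, columns=list("abcd"))
        out = pingouin.partial_corr(
            df, x="a", y="b", covar=["c", "d"], method="pearson"
        )
        assert pcor[0, 1] == pytest.approx(float(out["r"].iloc[0]), abs=1e-10)
        assert pvals[0, 1] == pytest.approx(float(out["p_val"].iloc[0]), rel=1e-6)

    def test_needs_enough_replicates(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="replicates"):
            ln.ggm_infer(make_dataset(rng.standard_normal((6, 5))))


class TestValueAgreement:
    def _candidate(self, J):
        from lyapnet.ga import CandidateSolution

        vecJ = J.reshape(-1, order="F")
        support = np.flatnonzero(vecJ)
        return CandidateSolution(
            structure=vecJ != 0,
            zero_count=int((vecJ == 0).sum()),
            j_values=vecJ[support],
            residual=0.0,
            fitness=0.0,
        )

    def test_exact_values_give_rho_one(self):
        rng = np.random.default_rng(0)
        J = np.where(rng.random((4, 4)) < 0.4, rng.normal(size=(4, 4)), 0.0)
        J[0, 0] = 1.0
        results, med = ln.jacobian_value_agreement([self._candidate(J)], J)
        assert results[0][0] == pytest.approx(1.0)
        assert med == pytest.approx(1.0)

    def test_rank_reversal_gives_minus_one(self):
        J = np.diag([1.0, 2.0, 3.0, 4.0])
        cand = self._candidate(np.diag([4.0, 3.0, 2.0, 1.0]))
        results, _ = ln.jacobian_value_agreement([cand], J)
        assert results[0][0] == pytest.approx(-1.0)

    def test_monotone_transform_preserves_rho(self):
        J = np.diag([0.5, 1.0, 2.0, 4.0])
        cand = self._candidate(np.diag([0.5, 1.0, 2.0, 4.0]) ** 3)
        results, _ = ln.jacobian_value_agreement([cand], J)
        assert results[0][0] == pytest.approx(1.0)

    def test_too_few_positions_rejected(self):
        J = np.zeros((2, 2))
        J[0, 0] = 1.0
        with pytest.raises(ValueError, match="positions"):
            ln.jacobian_value_agreement([self._candidate(J)], J)


class TestReproducibility:
    def test_against_truth(self):
        truth = np.array([1, 0, 1], bool)
        runs = [truth] * 19 + [np.array([1, 1, 1], bool)]
        assert ln.reproducibility(runs, truth=truth) == pytest.approx(0.95)

    def test_all_identical(self):
        s = np.array([0, 1], bool)
        assert ln.reproducibility([s, s.copy(), s.copy()]) == 1.0

    def test_all_distinct_modal_fraction(self):
        runs = [np.array(b, bool) for b in ([1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0])]
        assert ln.reproducibility(runs) == pytest.approx(0.25)
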