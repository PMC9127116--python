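"""The scatter-matrix categorization index against independent oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import f_oneway

from itpopcode import (
    Condition,
    ci_1d,
    ci_of_matrix,
    ci_single_unit,
    closed_form_ci_two_class,
    normalized_contrast,
    scatter_decomposition,
)
from itpopcode.io import trials_to_frame
from itpopcode.core import TrialRecord

# the worked 2-neuron, 4-trial example: two body rows, two non-body rows
X4 = np.array([[0.0, 1.0], [2.0, 0.0], [4.0, 0.0], [6.0, 1.0]])
L4 = np.array(["body", "body", "nonbody", "nonbody"])


def brute_force_scatters(x, labels):
    """Direct summation of the scatter definitions, no linear algebra."""
    cats = sorted(set(labels))
    n = len(x)
    m = x.mean(axis=0)
    s_w = np.zeros((x.shape[1], x.shape[1]))
    s_b = np.zeros_like(s_w)
    for c in cats:
        rows = x[labels == c]
        mi = rows.mean(axis=0)
        for r in rows:
            s_w += np.outer(r - mi, r - mi)
        s_b += len(rows) * np.outer(mi - m, mi - m)
    return s_w, s_b


class TestWorkedExample:
    def test_scatter_matrices_exact(self):
        dec = scatter_decomposition(X4, L4, ridge=0.0)
        np.testing.assert_array_equal(dec.within_scatter, [[4.0, 0.0], [0.0, 1.0]])
        np.testing.assert_array_equal(dec.between_scatter, [[16.0, 0.0], [0.0, 0.0]])
        assert dec.ci == pytest.approx(4.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        s_w, s_b = brute_force_scatters(X4, L4)
        dec = scatter_decomposition(X4, L4, ridge=0.0)
        np.testing.assert_allclose(dec.within_scatter, s_w)
        np.testing.assert_allclose(dec.between_scatter, s_b)

    def test_closed_form_agrees(self):
        assert closed_form_ci_two_class(X4, L4, ridge=0.0) == pytest.approx(4.0)

    def test_default_ridge_barely_perturbs(self):
        assert ci_of_matrix(X4, L4) == pytest.approx(4.0, abs=1e-4)


class TestScatterProperties:
    def test_identical_distributions_give_zero_ci(self, rng):
        rows = rng.normal(size=(12, 3))
        x = np.vstack([rows, rows])
        labels = np.repeat(["body", "nonbody"], 12)
        dec = scatter_decomposition(x, labels, ridge=0.0)
        np.testing.assert_allclose(dec.between_scatter, 0, atol=1e-9)
        assert dec.ci == pytest.approx(0.0, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.integers(2, 4), st.integers(2, 5))
    def test_within_plus_between_equals_total_scatter(self, seed, c, dim):
        rng = np.random.default_rng(seed)
        n_per = rng.integers(3, 10)
        x = rng.normal(size=(c * n_per, dim))
        labels = np.repeat([f"g{i}" for i in range(c)], n_per)
        dec = scatter_decomposition(x, labels, ridge=0.0)
        centered = x - x.mean(axis=0)
        total = centered.T @ centered
        np.testing.assert_allclose(dec.total_scatter, total, atol=1e-9)

    def test_affine_invariance(self, rng):
        """trace(S_W^-1 S_B) is unchanged by invertible linear maps."""
        x = rng.normal(size=(60, 8)) + np.repeat([0, 1.5], 30)[:, None]
        labels = np.repeat(["body", "nonbody"], 30)
        a = rng.normal(size=(8, 8)) + 2 * np.eye(8)
        before = ci_of_matrix(x, labels, ridge=0.0)
        after = ci_of_matrix(x @ a, labels, ridge=0.0)
        assert after == pytest.approx(before, rel=1e-8)

    def test_trace_identity_and_rank(self, rng):
        x = rng.normal(size=(50, 6)) + np.repeat([0, 1.0], 25)[:, None]
        labels = np.repeat(["body", "nonbody"], 25)
        dec = scatter_decomposition(x, labels, ridge=0.0)
        trace_path = np.trace(np.linalg.solve(dec.within_scatter, dec.between_scatter))
        assert dec.eigenvalues.sum() == pytest.approx(trace_path, abs=1e-8)
        # two categories: exactly one nonzero eigenvalue
        assert dec.eigenvalues[0] > 1e-6
        assert np.all(dec.eigenvalues[1:] < 1e-10 * max(dec.eigenvalues[0], 1.0))

    def test_category_with_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2 rows"):
            scatter_decomposition(np.eye(3), np.array(["a", "b", "b"]))

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="2 categories"):
            scatter_decomposition(np.eye(3), np.array(["a", "a", "a"]))

    def test_pinv_fallback_when_rank_deficient(self, rng):
        """More neurons than pseudo-trials still yields a finite CI."""
        x = rng.normal(size=(10, 25)) + np.repeat([0, 1.0], 5)[:, None]
        labels = np.repeat(["body", "nonbody"], 5)
        ci = ci_of_matrix(x, labels)
        assert np.isfinite(ci) and ci >= 0


class TestOneDimensional:
    def test_hand_example_and_f_statistic(self):
        vals = np.array([1.0, 3.0, 5.0, 7.0])
        labels = np.array(["body", "body", "nonbody", "nonbody"])
        ci = ci_1d(vals, labels)
        assert ci == pytest.approx(4.0)
        f = f_oneway(vals[:2], vals[2:]).statistic
        assert f == pytest.approx(8.0)
        n, c = 4, 2
        assert ci == pytest.approx(f * (c - 1) / (n - c))

    def test_zero_within_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ci_1d(np.array([1.0, 1.0, 2.0, 2.0]), np.array(["a", "a", "b", "b"]))

    def test_single_unit_ci_from_trials(self):
        """1-D population CI of a neuron's spike counts, evoked window."""
        def trial(count, cat, sub):
            times = np.linspace(160, 340, count) if count else np.empty(0)
            return TrialRecord(
                neuron_id="n0", session_id="s", task="passive", stimulus_id=f"{cat}{count}",
                category=cat, subcategory=sub, signal_level=90, outcome="none",
                choice="none", preceding_category="none", spike_times=times,
            )

        df = trials_to_frame(
            [trial(1, "body", "human"), trial(3, "body", "human"),
             trial(5, "nonbody", "car"), trial(7, "nonbody", "car")]
        )
        res = ci_single_unit(df, Condition("passive", 90), n_reps=50, seed=0)
        assert res.ci == pytest.approx(4.0)
        assert res.ci_baseline == 0.0


class TestEnhancementArithmetic:
    def test_direct_values(self):
        assert normalized_contrast(3.0, 1.0) == pytest.approx(0.5)
        assert normalized_contrast(2.0, 2.0) == 0.0

    def test_undefined_denominator(self):
        with pytest.raises(ZeroDivisionError):
            normalized_contrast(0.0, 0.0)

    def test_bounds(self, rng):
        for _ in range(100):
            c, p = rng.uniform(0, 10, size=2)
            if c + p > 0:
                assert -1.0 <= normalized_contrast(c, p) <= 1.0
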