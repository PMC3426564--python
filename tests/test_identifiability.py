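"""Confidence intervals, collinearity index, subset screening."""

import itertools

import numpy as np
import pytest
from scipy import stats

from gapcircuit.identifiability import (SensitivityMatrix, collinearity_index,
                                        confidence_intervals,
                                        finite_difference_jacobian,
                                        flag_subsets, sensitivity,
                                        subset_table, wildtype_only_analysis)


def sens(S, wt_rows=None, labels=None):
    n, m = S.shape
    return SensitivityMatrix(
        S, labels or [f"p{j}" for j in range(m)],
        np.ones(n, bool) if wt_rows is None else wt_rows)


class TestFiniteDifferences:
    def test_linear_model_exact(self, rng):
        X = rng.normal(size=(30, 6))
        J = finite_difference_jacobian(lambda th: X @ th, np.zeros(6),
                                       np.full(6, 1e-4))
        assert np.allclose(J, X, atol=1e-6)

    def test_central_beats_forward(self, rng):
        def f(th):
            return np.array([np.sin(th[0]) + th[1] ** 3,
                             np.exp(0.1 * th[0] * th[1])])
        th = np.array([0.7, 1.3])
        exact = np.array([
            [np.cos(th[0]), 3 * th[1] ** 2],
            [0.1 * th[1] * np.exp(0.1 * th[0] * th[1]),
             0.1 * th[0] * np.exp(0.1 * th[0] * th[1])]])
        ec = np.abs(finite_difference_jacobian(f, th, 1e-4) - exact).max()
        ef = np.abs(finite_difference_jacobian(f, th, 1e-4,
                                               scheme="forward")
                    - exact).max()
        assert ec < 1e-7 and ec < ef


class TestConfidenceIntervals:
    def test_matches_closed_form_ols(self, rng):
        """Oracle: statsmodels OLS gives [(X'X)^-1]_jj s^2 via bse; the
        joint-projection interval is estimate +/- sqrt(m F) * bse."""
        import statsmodels.api as sm
        n, m = 60, 5
        X = rng.normal(size=(n, m))
        beta = rng.normal(size=m)
        y = X @ beta + rng.normal(scale=0.3, size=n)
        est = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = X @ est - y
        cis = confidence_intervals(sens(X), resid, est, alpha=0.05)
        ols = sm.OLS(y, X).fit()
        half_ref = np.sqrt(m * stats.f.ppf(0.95, m, n - m)) * ols.bse
        for j, ci in enumerate(cis):
            assert ci.upper - ci.estimate == pytest.approx(half_ref[j],
                                                           abs=1e-8)
            assert ci.estimate - ci.lower == pytest.approx(half_ref[j],
                                                           abs=1e-8)

    def test_near_duplicate_columns_blow_up(self, rng):
        n = 50
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        X_ind = np.column_stack([x, z])
        X_dup = np.column_stack([x, x + 1e-4 * rng.normal(size=n)])
        y = x + rng.normal(scale=0.1, size=n)
        for X in (X_ind, X_dup):
            est = np.linalg.lstsq(X, y, rcond=None)[0]
            resid = X @ est - y
            cis = confidence_intervals(sens(X), resid, est)
            width = cis[0].upper - cis[0].lower
            if X is X_ind:
                w_ind = width
            else:
                w_dup = width
        assert w_dup > 10 * w_ind

    def test_zero_residuals_zero_width(self, rng):
        X = rng.normal(size=(20, 3))
        est = rng.normal(size=3)
        cis = confidence_intervals(sens(X), np.zeros(20), est)
        for ci in cis:
            assert ci.lower == ci.upper == ci.estimate

    def test_width_shrinks_like_sqrt_n(self, rng):
        widths = {}
        for n in (80, 320):
            X = rng.standard_normal((n, 4))
            y = X @ np.ones(4) + rng.normal(scale=0.5, size=n)
            est = np.linalg.lstsq(X, y, rcond=None)[0]
            cis = confidence_intervals(sens(X), X @ est - y, est)
            widths[n] = np.mean([c.upper - c.lower for c in cis])
        assert widths[80] / widths[320] == pytest.approx(2.0, rel=0.3)

    def test_sign_identifiability_flag(self, rng):
        X = rng.normal(size=(40, 2)) * [5.0, 0.01]
        y = X @ np.array([1.0, 1.0]) + rng.normal(scale=0.5, size=40)
        est = np.linalg.lstsq(X, y, rcond=None)[0]
        cis = confidence_intervals(sens(X), X @ est - y, est)
        assert cis[0].sign_identifiable
        assert not cis[1].sign_identifiable


class TestCollinearityIndex:
    def test_orthogonal_is_one(self):
        S = np.eye(6)[:, :2]
        assert collinearity_index(S, [0, 1]) == pytest.approx(1.0)

    def test_cosine_099_gives_ten(self):
        u = np.zeros(10)
        u[0] = 1.0
        w = np.zeros(10)
        w[1] = 1.0
        c = 0.99
        v = c * u + np.sqrt(1 - c * c) * w
        gamma = collinearity_index(np.column_stack([u, v]), [0, 1])
        assert gamma == pytest.approx(10.0, abs=1e-9)

    def test_identical_columns_infinite(self):
        x = np.arange(1.0, 9.0)
        assert collinearity_index(np.column_stack([x, x]), [0, 1]) == np.inf

    def test_zero_column_infinite(self):
        x = np.arange(1.0, 9.0)
        S = np.column_stack([x, np.zeros(8)])
        assert collinearity_index(S, [0, 1]) == np.inf

    def test_scale_invariance(self, rng):
        S = rng.normal(size=(30, 4))
        g1 = collinearity_index(S, [0, 1, 2])
        S2 = S.copy()
        S2[:, 1] *= 1e3
        assert collinearity_index(S2, [0, 1, 2]) == pytest.approx(g1,
                                                                  rel=1e-10)

    def test_monotone_under_superset(self, rng):
        for _ in range(20):
            S = rng.normal(size=(25, 5))
            g2 = collinearity_index(S, [0, 1])
            g3 = collinearity_index(S, [0, 1, 2])
            assert g3 >= g2 - 1e-12


def brute_force_flags(S, kmax, threshold):
    """Independent oracle: SVD-based gamma over exhaustive subsets, then
    the containment rule."""
    m = S.shape[1]
    norms = np.linalg.norm(S, axis=0)
    Sn = S / norms
    out = []
    flagged = []
    for k in range(2, kmax + 1):
        for combo in itertools.combinations(range(m), k):
            if any(set(f) <= set(combo) for f in flagged):
                continue
            smin = np.linalg.svd(Sn[:, combo], compute_uv=False)[-1]
            gamma = np.inf if smin == 0 else 1.0 / smin
            if gamma > threshold:
                out.append((combo, gamma))
                flagged.append(combo)
    return out


class TestFlagSubsets:
    def test_matches_brute_force_random(self, rng):
        for trial in range(3):
            S = rng.normal(size=(20, 10))
            # plant a near-duplicate pair
            S[:, 7] = S[:, 2] + 0.05 * rng.normal(size=20)
            got = flag_subsets(S, kmax=3, threshold=7.0)
            ref = brute_force_flags(S, 3, 7.0)
            got_sets = {tuple(f.indices) for f in got}
            ref_sets = {c for c, _ in ref}
            assert got_sets == ref_sets
            ref_g = dict(ref)
            for f in got:
                assert f.gamma == pytest.approx(ref_g[tuple(f.indices)],
                                                rel=1e-9)

    def test_single_planted_pair(self, rng):
        S = rng.normal(size=(40, 10))
        q, _ = np.linalg.qr(S)          # orthonormal columns: no accidents
        S = q
        S[:, 5] = S[:, 1] + 0.01 * S[:, 2]
        flags = flag_subsets(S, kmax=2, threshold=7.0)
        assert len(flags) == 1
        assert set(flags[0].indices) == {1, 5}

    def test_infinite_threshold_empty(self, rng):
        S = rng.normal(size=(15, 6))
        assert flag_subsets(S, threshold=np.inf) == []

    def test_three_way_dependency_flagged_at_dim3(self):
        e = np.eye(12)
        col1, col2 = e[:, 0], e[:, 1]
        col3 = (col1 + col2) / np.sqrt(2)   # pairwise cosine 0.707
        S = np.column_stack([col1, col2, col3, e[:, 3], e[:, 4]])
        flags = flag_subsets(S, kmax=3, threshold=7.0)
        dims = {len(f.labels) for f in flags}
        assert dims == {3}
        assert any(set(f.indices) == {0, 1, 2} for f in flags)

    def test_sorted_descending(self, rng):
        S = rng.normal(size=(30, 8))
        S[:, 3] = S[:, 0] + 1e-3 * rng.normal(size=30)
        S[:, 6] = S[:, 1] + 1e-2 * rng.normal(size=30)
        flags = flag_subsets(S, kmax=2, threshold=5.0)
        gammas = [f.gamma for f in flags]
        assert gammas == sorted(gammas, reverse=True)


@pytest.fixture(scope="module")
def S_truth(truth, clean_dataset):
    return sensitivity(truth.params, clean_dataset, transform=False)


class TestCircuitSensitivity:
    def test_shape_and_rows(self, S_truth, clean_dataset):
        assert S_truth.S.shape == (clean_dataset.n_observations, 40)
        assert S_truth.wt_rows.sum() == clean_dataset.wt_mask.sum()

    def test_kr_block_zero_on_mutant_rows(self, S_truth):
        """Kr-target parameters only touch the Kr channel, which is absent
        from the mutant genotype: their sensitivities live on wild-type
        rows only."""
        kr_cols = [j for j, lab in enumerate(S_truth.labels)
                   if lab.startswith("K") or lab.endswith("_Kr")]
        assert len(kr_cols) == 10
        mut = ~S_truth.wt_rows
        assert np.abs(S_truth.S[mut][:, kr_cols]).max() < 1e-9
        # and they do affect the wild-type rows
        assert np.abs(S_truth.S[S_truth.wt_rows][:, kr_cols]).max() > 1e-3

    def test_wildtype_only_flags_at_least_as_many(self, S_truth):
        res = wildtype_only_analysis(S_truth, kmax=2, threshold=7.0)
        assert res["n_wildtype_only"] >= res["n_full"]

    def test_no_mutant_rows_identical(self, S_truth):
        restricted = S_truth.restricted(S_truth.wt_rows)
        res = wildtype_only_analysis(restricted, kmax=2, threshold=7.0)
        assert ({f.labels for f in res["wildtype_only"]}
                == {f.labels for f in res["full"]})


class TestSubsetTable:
    def test_circuit_counts(self, rng):
        S1 = rng.normal(size=(20, 6))
        S1[:, 4] = S1[:, 0] + 1e-3 * rng.normal(size=20)
        S2 = rng.normal(size=(20, 6))
        S2[:, 4] = S2[:, 0] + 1e-3 * rng.normal(size=20)
        flags = [flag_subsets(S, kmax=2, threshold=7.0) for S in (S1, S2)]
        df = subset_table(flags)
        row = df[df.parameters == "4-0"] if len(
            df[df.parameters == "4-0"]) else df[df.parameters == "0-4"]
        assert int(row.circuit_count.iloc[0]) == 2
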