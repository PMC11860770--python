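import numpy as np
import pytest

from airsom.pmf import (
    UncertaintyModel,
    bootstrap_pmf,
    build_uncertainties,
    concentration_codebook,
    factor_cluster_crosstab,
    fit_pmf,
    match_factors,
    q_expected,
    select_factor_count,
    species_percent_profile,
    top_nodes_per_factor,
)
from airsom.preprocess import ScalingModel
from airsom.som import Codebook


def planted(rng, n=60, k=3, noise=0.0):
    """Nonnegative rank-k data with strong anchor rows for each factor."""
    F = np.array(
        [
            [8.0, 1.0, 0.2, 0.1, 0.1],
            [0.2, 0.1, 9.0, 1.0, 0.3],
            [0.1, 0.5, 0.2, 0.4, 7.0],
        ]
    )[:k]
    F = F / F.sum(axis=1, keepdims=True)
    G = rng.uniform(0.05, 0.4, size=(n, k))
    G[np.arange(n) % k == np.arange(k)[:, None].T.flatten()[0]] += 0  # keep simple
    for j in range(k):  # anchor rows: nearly pure in each factor
        G[j * (n // k) : j * (n // k) + n // (2 * k), j] += 5.0
    X = G @ F
    if noise:
        X = X * np.exp(rng.normal(0, noise, X.shape))
    return X, G, F


def cosine_rows(A, B):
    return np.array(
        [a @ b / (np.linalg.norm(a) * np.linalg.norm(b)) for a, b in zip(A, B)]
    )


class TestUncertainties:
    def test_relative_uncertainty_example(self):
        model = UncertaintyModel(rel=[0.062], floor=[0.0])
        U = build_uncertainties(np.array([[100.0]]), model)
        assert np.isclose(U[0, 0], 6.2)

    def test_floor_active_at_zero(self):
        model = UncertaintyModel(rel=[0.1], floor=[0.1])
        U = build_uncertainties(np.array([[0.0]]), model)
        assert U[0, 0] == 0.1

    def test_strictly_positive(self, rng):
        X = np.abs(rng.standard_normal((20, 5)))
        X[0] = 0.0
        model = UncertaintyModel.from_data(X, rel=[0.1] * 5)
        assert (build_uncertainties(X, model) > 0).all()

    def test_negative_data_rejected(self):
        model = UncertaintyModel(rel=[0.1], floor=[0.1])
        with pytest.raises(ValueError, match="inverse_autoscale"):
            build_uncertainties(np.array([[-1.0]]), model)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            UncertaintyModel(rel=[0.0], floor=[0.1])
        with pytest.raises(ValueError):
            UncertaintyModel(rel=[0.1], floor=[-1.0])

    def test_default_table_by_variable_name(self):
        X = np.abs(np.random.default_rng(0).standard_normal((30, 5))) + 0.1
        model = UncertaintyModel.from_data(
            X, variable_names=("Ben", "Tol", "PM10", "NO", "NO2")
        )
        assert np.allclose(model.rel, [0.109, 0.109, 0.10, 0.062, 0.062])


def test_concentration_codebook_clips_negatives():
    cb = Codebook(np.array([[-2.0, 1.0], [0.5, 2.0]]), ("a", "b"), scale="autoscaled")
    scaling = ScalingModel(means=[1.0, 1.0], sds=[1.0, 1.0])
    out = concentration_codebook(cb, scaling)
    assert out.scale == "concentration"
    assert out.M.min() == 0.0  # -2 + 1 = -1 clipped
    assert np.isclose(out.M[1, 1], 3.0)


class TestQExpected:
    def test_reference_arithmetic(self):
        assert q_expected(902, 5, 4) == 882
        with pytest.raises(ValueError):
            q_expected(902, 5, 5)

    def test_k_zero(self):
        assert q_expected(10, 5, 0) == 50

    def test_monotone_decreasing_in_k(self):
        values = [q_expected(100, 8, k) for k in range(0, 7)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestFitPmf:
    def test_planted_recovery(self, rng):
        X, G0, F0 = planted(rng)
        U = 0.05 * X + 0.01
        sol = fit_pmf(X, U, 3, n_starts=5, seed=0)
        assert sol.Q / q_expected(*X.shape, 3) < 0.01
        perm = match_factors(sol.F, F0)
        assert cosine_rows(sol.F[perm], F0).min() >= 0.99

    def test_rank1(self, rng):
        g = rng.uniform(1, 2, size=40)
        f = np.array([1.0, 3.0, 0.5, 2.0, 0.1])
        X = np.outer(g, f)
        sol = fit_pmf(X, 0.1 * X + 0.01, 1, n_starts=3, seed=0)
        assert cosine_rows(sol.F, [f / f.sum()]).min() >= 0.999

    def test_q_trace_nonincreasing(self, rng):
        X = np.abs(rng.standard_normal((30, 5))) + 0.1
        U = 0.1 * X + 0.05
        sol = fit_pmf(X, U, 3, n_starts=4, seed=1)
        q = sol.q_trace
        assert (np.diff(q) <= q[:-1] * 1e-10 + 1e-12).all()

    def test_nonnegativity_and_row_normalization(self, rng):
        X = np.abs(rng.standard_normal((25, 5))) + 0.1
        sol = fit_pmf(X, 0.1 * X + 0.05, 2, n_starts=3, seed=0)
        assert (sol.G >= 0).all() and (sol.F >= 0).all()
        assert np.allclose(sol.F.sum(axis=1), 1.0)

    def test_q_matches_independent_reevaluation(self, rng):
        X = np.abs(rng.standard_normal((25, 5))) + 0.1
        U = 0.1 * X + 0.05
        sol = fit_pmf(X, U, 3, n_starts=3, seed=0)
        q_direct = float(np.sum(((X - sol.G @ sol.F) / U) ** 2))
        assert abs(sol.Q - q_direct) <= 1e-8 * max(q_direct, 1e-30)

    def test_deterministic(self, rng):
        X = np.abs(rng.standard_normal((20, 5))) + 0.1
        U = 0.1 * X + 0.05
        s1 = fit_pmf(X, U, 2, n_starts=4, seed=9)
        s2 = fit_pmf(X, U, 2, n_starts=4, seed=9)
        assert (s1.G == s2.G).all() and (s1.F == s2.F).all() and s1.Q == s2.Q

    def test_input_validation(self, rng):
        X = np.abs(rng.standard_normal((10, 5)))
        with pytest.raises(ValueError):
            fit_pmf(-X - 1, 0.1 * X + 1, 2)
        with pytest.raises(ValueError):
            fit_pmf(X, np.zeros_like(X), 2)
        with pytest.raises(ValueError):
            fit_pmf(X, 0.1 * X + 1, 11)


class TestSelectFactorCount:
    def test_planted_two_sources_scan_1_to_4(self, rng):
        X, _, _ = planted(rng, n=80, k=2, noise=0.05)
        U = 0.05 * X + 0.01 * X.mean()
        scan = select_factor_count(X, U, 1, 4, n_starts=4, seed=0, n_boot=15)
        assert scan.chosen_k == 2
        assert len(scan.table) == 4
        assert np.isfinite(scan.table["Q"]).all()

    def test_table_bookkeeping(self, rng):
        X, _, _ = planted(rng, n=40, k=3, noise=0.05)
        U = 0.05 * X + 0.01 * X.mean()
        scan = select_factor_count(X, U, 2, 4, n_starts=3, seed=0, n_boot=10)
        assert list(scan.table["k"]) == [2, 3, 4]
        assert set(scan.solutions) == {2, 3, 4}

    def test_invalid_range(self, rng):
        X = np.abs(rng.standard_normal((10, 5))) + 0.1
        with pytest.raises(ValueError):
            select_factor_count(X, 0.1 * X + 1, 3, 2)


class TestBootstrap:
    def test_noiseless_self_consistency(self, rng):
        X, _, _ = planted(rng, n=60, k=3)
        U = 0.05 * X + 0.01
        base = fit_pmf(X, U, 3, n_starts=4, seed=0)
        rep = bootstrap_pmf(X, U, base, n_boot=30, seed=0)
        assert rep.unmapped == 0
        assert (rep.mapping_fraction == 1.0).all()

    def test_conservation(self, rng):
        X = np.abs(rng.standard_normal((40, 5))) + 0.1
        U = 0.1 * X + 0.05
        base = fit_pmf(X, U, 3, n_starts=3, seed=0)
        rep = bootstrap_pmf(X, U, base, n_boot=25, seed=1)
        assert rep.mapping_counts.sum() + rep.unmapped == rep.n_boot * 3
        assert rep.n_boot + rep.n_skipped == 25

    def test_validation(self, rng):
        X = np.abs(rng.standard_normal((20, 5))) + 0.1
        U = 0.1 * X + 0.05
        base = fit_pmf(X, U, 2, n_starts=2, seed=0)
        with pytest.raises(ValueError):
            bootstrap_pmf(X, U, base, n_boot=1)
        with pytest.raises(ValueError):
            bootstrap_pmf(X, U, base, n_boot=5, r_threshold=1.5)


class TestSpeciesPercentProfile:
    def test_single_factor_all_hundred(self, rng):
        X = np.abs(rng.standard_normal((20, 5))) + 0.1
        sol = fit_pmf(X, 0.1 * X + 0.05, 1, n_starts=2, seed=0)
        assert np.allclose(species_percent_profile(sol), 100.0)

    def test_columns_sum_to_hundred(self, rng):
        X = np.abs(rng.standard_normal((30, 5))) + 0.1
        sol = fit_pmf(X, 0.1 * X + 0.05, 3, n_starts=3, seed=0)
        pct = species_percent_profile(sol)
        assert np.allclose(pct.sum(axis=0), 100.0, atol=1e-6)

    def test_disjoint_support_block_identity(self, rng):
        # disjoint species support covering all five variables
        F = np.array(
            [
                [0.5, 0.5, 0.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.0, 0.0],
                [0.0, 0.0, 0.0, 0.5, 0.5],
            ]
        )
        G = rng.uniform(0.02, 0.1, size=(40, 3))
        for j in range(3):  # anchor rows make the factorization identifiable
            G[j * 10 : j * 10 + 5, j] += 6.0
        X = G @ F
        sol = fit_pmf(X, 0.05 * X + 0.01, 3, n_starts=4, seed=0)
        pct = species_percent_profile(sol)
        perm = match_factors(sol.F, F)
        for i, j in [(0, 0), (1, 2), (2, 3)]:  # a species from each factor's block
            assert pct[perm[i], j] >= 95.0


class TestTopNodes:
    def test_pure_node_in_its_factor_only(self):
        G = np.full((20, 3), 0.2)
        G[7] = [0.0, 5.0, 0.0]
        sol = _solution_with(G)
        sets = top_nodes_per_factor(sol, q=0.9)
        assert 7 in sets[1]
        assert all(7 not in s for i, s in enumerate(sets) if i != 1)

    def test_set_sizes_near_quantile(self, rng):
        G = rng.random((200, 4))
        sol = _solution_with(G)
        for s in top_nodes_per_factor(sol, q=0.9):
            assert abs(len(s) - 20) <= 3

    def test_q_validation(self, rng):
        sol = _solution_with(rng.random((10, 2)))
        with pytest.raises(ValueError):
            top_nodes_per_factor(sol, q=1.0)


def _solution_with(G):
    """Minimal PmfSolution carrying a given G (for node-set operations)."""
    from airsom.pmf import PmfSolution

    k = G.shape[1]
    F = np.full((k, 5), 0.2)
    return PmfSolution(
        G=np.asarray(G, float),
        F=F,
        Q=0.0,
        Q_expected=np.nan,
        scaled_residuals=np.zeros((G.shape[0], 5)),
        n_starts=1,
        seed=0,
        converged=True,
    )


class TestCrosstab:
    def test_single_cluster_all_mass_there(self, rng):
        sol = _solution_with(rng.random((30, 3)))
        labels = np.ones(30, dtype=int)
        pct = factor_cluster_crosstab(sol, labels, normalize=True)
        assert np.allclose(pct.to_numpy()[:, 0], 100.0)

    def test_row_sums_equal_set_sizes(self, rng):
        sol = _solution_with(rng.random((50, 3)))
        labels = rng.integers(1, 4, size=50)
        counts = factor_cluster_crosstab(sol, labels)
        sizes = [len(s) for s in top_nodes_per_factor(sol, q=0.9)]
        assert counts.sum(axis=1).tolist() == sizes

    def test_planted_block_design_diagonal(self, rng):
        G = np.full((60, 3), 0.05)
        labels = np.repeat([1, 2, 3], 20)
        for c in range(3):  # jitter avoids an exactly tied quantile cut
            G[labels == c + 1, c] = 5.0 + rng.random(20)
        sol = _solution_with(G)
        counts = factor_cluster_crosstab(sol, labels).to_numpy()
        assert (counts.argmax(axis=1) == np.arange(3)).all()

    def test_misaligned_rejected(self, rng):
        sol = _solution_with(rng.random((10, 2)))
        with pytest.raises(ValueError):
            factor_cluster_crosstab(sol, np.ones(9, dtype=int))


def test_match_factors_identity_permutation(rng):
    F = np.abs(rng.standard_normal((4, 5))) + 0.1
    perm = rng.permutation(4)
    # match_factors returns the inverse permutation: F[perm][result[i]] == F[i]
    assert (match_factors(F[perm], F) == np.argsort(perm)).all()
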