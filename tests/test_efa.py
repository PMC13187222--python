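"""EFA machinery: KMO, Bartlett, parallel analysis, PAF, oblimin, fit, scores."""

import numpy as np
import pytest

from scalenet.efa import (
    bartlett_sphericity,
    efa_fit,
    factor_scores,
    fit_efa,
    kmo,
    oblimin_rotate,
    paf,
    parallel_analysis,
    score_reliability,
    smc,
)
from scalenet.synthetic import SimulationConfig, default_thresholds, generate_responses


def _equicorrelated(p, r):
    corr = np.full((p, p), r)
    np.fill_diagonal(corr, 1.0)
    return corr


def _two_factor_population(loading=0.7, phi=0.5, p1=6, p2=6):
    lam = np.zeros((p1 + p2, 2))
    lam[:p1, 0] = loading
    lam[p1:, 1] = loading
    phi_m = np.array([[1.0, phi], [phi, 1.0]])
    pop = lam @ phi_m @ lam.T
    np.fill_diagonal(pop, 1.0)
    return pop, lam, phi_m


class TestKmo:
    def test_matches_partial_correlation_oracle(self, rng):
        z = rng.normal(size=(200, 5))
        z[:, 1] += z[:, 0]
        z[:, 3] += 0.5 * z[:, 2]
        z -= z.mean(axis=0)  # center so the residual identity is exact
        corr = np.corrcoef(z, rowvar=False)
        overall, per_item = kmo(corr)
        # oracle: partial correlations via regression residuals per pair
        p = 5
        q2_sum, r2_sum = 0.0, 0.0
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                others = [k for k in range(p) if k not in (i, j)]
                xi = z[:, i] - z[:, others] @ np.linalg.lstsq(
                    z[:, others], z[:, i], rcond=None
                )[0]
                xj = z[:, j] - z[:, others] @ np.linalg.lstsq(
                    z[:, others], z[:, j], rcond=None
                )[0]
                q2_sum += np.corrcoef(xi, xj)[0, 1] ** 2
                r2_sum += corr[i, j] ** 2
        assert overall == pytest.approx(r2_sum / (r2_sum + q2_sum), abs=1e-10)

    def test_identity_is_zero_by_convention(self):
        overall, per_item = kmo(np.eye(4))
        assert overall == 0.0
        assert np.all(per_item == 0.0)

    def test_strong_one_factor_high(self):
        overall, _ = kmo(_equicorrelated(10, 0.8))
        assert overall > 0.9

    def test_singular_matrix_error(self):
        corr = np.ones((3, 3))
        with pytest.raises(ValueError, match="singular|ridge"):
            kmo(corr)


class TestBartlett:
    def test_identity(self):
        chi2, df, p = bartlett_sphericity(np.eye(6), 100)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_direct_formula(self):
        corr = _equicorrelated(5, 0.3)
        n = 100
        chi2, df, p = bartlett_sphericity(corr, n)
        expected = -(n - 1 - (2 * 5 + 5) / 6) * np.log(np.linalg.det(corr))
        assert chi2 == pytest.approx(expected, abs=1e-10)
        assert df == 10

    def test_monotone_in_shrinkage(self):
        corr = _equicorrelated(5, 0.5)
        stats = [
            bartlett_sphericity((1 - a) * corr + a * np.eye(5), 80)[0]
            for a in [0.0, 0.3, 0.6, 0.9]
        ]
        assert all(x > y for x, y in zip(stats, stats[1:]))


class TestParallelAnalysis:
    def test_pure_noise_zero_factors(self, rng):
        data = rng.integers(1, 8, size=(500, 10))
        res = parallel_analysis(data, n_resamples=200, seed=11)
        assert res.n_factors == 0

    def test_two_factor_data_detected(self):
        lam = np.zeros((12, 2))
        lam[:6, 0] = 0.7
        lam[6:, 1] = 0.7
        cfg = SimulationConfig(
            n_per_group=(250, 250),
            loadings=lam,
            factor_correlation=np.array([[1.0, 0.5], [0.5, 1.0]]),
            group_shift=np.zeros(12),
            thresholds=default_thresholds(12),
            seed=42,
        )
        data = generate_responses(cfg).values
        res = parallel_analysis(data, n_resamples=300, seed=5)
        assert res.n_factors == 2

    def test_group_shift_masks_within_group_structure(self):
        """A large uniform between-group shift yields one factor on the
        combined sample while each group separately shows two factors: the
        between-group variance dominates and blurs the content factors."""
        from scalenet.synthetic import induce_d_profile

        lam = np.zeros((18, 2))
        lam[:12, 0] = 0.55
        lam[12:, 1] = 0.55
        base = SimulationConfig(
            n_per_group=(196, 196),
            loadings=lam,
            factor_correlation=np.array([[1.0, 0.58], [0.58, 1.0]]),
            group_shift=np.zeros(18),
            thresholds=default_thresholds(18),
            reverse_items=frozenset(),
            seed=3,
        )
        cfg = induce_d_profile(np.full(18, 2.4), base)
        m = generate_responses(cfg)
        combined = parallel_analysis(m.values, n_resamples=200, seed=3)
        case = parallel_analysis(m.values[m.group == "case"], n_resamples=200, seed=3)
        comp = parallel_analysis(
            m.values[m.group == "comparison"], n_resamples=200, seed=3
        )
        assert combined.n_factors == 1
        assert case.n_factors == 2
        assert comp.n_factors == 2

    def test_deterministic_and_quantile_monotone(self, rng):
        data = rng.integers(1, 8, size=(300, 8))
        a = parallel_analysis(data, n_resamples=150, seed=3)
        b = parallel_analysis(data, n_resamples=150, seed=3)
        assert np.array_equal(a.reference_eigenvalues, b.reference_eigenvalues)
        k_low = parallel_analysis(data, n_resamples=150, quantile=0.5, seed=3).n_factors
        k_high = parallel_analysis(data, n_resamples=150, quantile=0.99, seed=3).n_factors
        assert k_high <= k_low

    def test_more_items_than_rows_error(self, rng):
        with pytest.raises(ValueError):
            parallel_analysis(rng.integers(1, 8, size=(5, 10)), n_resamples=100)


class TestPaf:
    def test_one_factor_analytic_solution(self):
        corr = _equicorrelated(6, 0.64)
        lam, h2, heywood = paf(corr, 1)
        assert not heywood
        assert np.allclose(lam[:, 0], 0.8, atol=1e-6)
        assert np.allclose(h2, 0.64, atol=1e-6)

    def test_two_factor_congruence(self):
        pop, lam_true, phi = _two_factor_population()
        lam, h2, _ = paf(pop, 2)
        rot, phi_hat = oblimin_rotate(lam)
        # Tucker congruence per factor after alignment
        for f in range(2):
            congruences = [
                abs(rot[:, g] @ lam_true[:, f])
                / np.sqrt((rot[:, g] ** 2).sum() * (lam_true[:, f] ** 2).sum())
                for g in range(2)
            ]
            assert max(congruences) > 0.99

    def test_population_cross_structure_recovery(self):
        pop, lam_true, phi_true = _two_factor_population(loading=0.6, phi=0.4)
        lam, h2, _ = paf(pop, 2)
        implied = lam @ lam.T
        off = ~np.eye(12, dtype=bool)
        assert np.allclose(implied[off], pop[off], atol=1e-6)


class TestOblimin:
    def test_perfect_simple_structure_fixed_point(self):
        lam = np.zeros((8, 2))
        lam[:4, 0] = 0.8
        lam[4:, 1] = 0.6
        rot, phi = oblimin_rotate(lam)
        # same structure up to column permutation/sign
        recovered = np.abs(rot)
        assert np.allclose(np.sort(recovered.max(axis=1)), np.sort(lam.max(axis=1)),
                           atol=1e-6)
        assert np.allclose(recovered.min(axis=1), 0, atol=1e-6)

    def test_beats_random_oblique_rotations(self, rng):
        lam = rng.normal(size=(8, 2))
        rot, phi = oblimin_rotate(lam, seed=0)

        def quartimin(l):
            l2 = l**2
            return (l2[:, 0] * l2[:, 1]).sum() / 2.0  # sum over factor pairs

        best_random = np.inf
        for _ in range(1000):
            t = rng.normal(size=(2, 2))
            t /= np.sqrt((t**2).sum(axis=0))
            cand = lam @ np.linalg.inv(t).T
            best_random = min(best_random, quartimin(cand))
        assert quartimin(rot) <= best_random + 1e-8

    def test_model_implied_matrix_preserved(self, rng):
        lam = rng.normal(size=(10, 3))
        rot, phi = oblimin_rotate(lam, seed=1)
        assert np.allclose(rot @ phi @ rot.T, lam @ lam.T, atol=1e-8)

    def test_needs_two_factors(self):
        with pytest.raises(ValueError):
            oblimin_rotate(np.ones((5, 1)))


class TestEfaFit:
    def test_chi_square_equals_df_zero_rmsea(self):
        fit = efa_fit(50.0, 50, 200, 500.0, 60)
        assert fit["rmsea"] == 0.0

    def test_direct_formula_values(self):
        fit = efa_fit(100.0, 50, 201, 1000.0, 60)
        assert fit["rmsea"] == pytest.approx(np.sqrt(50 / (50 * 200)), abs=1e-12)
        expected_tli = (1000 / 60 - 100 / 50) / (1000 / 60 - 1)
        assert fit["tli"] == pytest.approx(expected_tli, abs=1e-12)

    def test_hand_formula_oracle_random_tuples(self, rng):
        for _ in range(20):
            df = int(rng.integers(5, 80))
            chi2 = float(df * rng.uniform(0.5, 4.0))
            n = int(rng.integers(df + 10, 1000))
            df_b = df + int(rng.integers(1, 40))
            chi2_b = float(df_b * rng.uniform(5.0, 30.0))
            fit = efa_fit(chi2, df, n, chi2_b, df_b)
            rmsea_ref = np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))
            tli_ref = (chi2_b / df_b - chi2 / df) / (chi2_b / df_b - 1.0)
            assert fit["rmsea"] == pytest.approx(rmsea_ref, abs=1e-10)
            assert fit["tli"] == pytest.approx(tli_ref, abs=1e-10)

    def test_rmsea_ci_brackets_point(self):
        fit = efa_fit(150.0, 50, 300, 900.0, 60)
        lo, hi = fit["rmsea_ci90"]
        assert lo <= fit["rmsea"] <= hi

    def test_baseline_df_validation(self):
        with pytest.raises(ValueError):
            efa_fit(100.0, 50, 200, 900.0, 50)


class TestFactorScores:
    def test_single_perfect_indicator(self, rng):
        from scalenet.efa import FactorSolution

        z = rng.normal(size=(200, 2))
        corr = np.corrcoef(z, rowvar=False)
        sol = FactorSolution(
            loadings=np.array([[1.0], [0.0]]),
            phi=np.eye(1),
            communalities=np.array([1.0, 0.0]),
            variance_explained=np.array([0.5]),
            total_variance_explained=0.5,
        )
        rel = score_reliability(np.eye(2), sol.loadings, sol.phi)
        assert rel["multiple_r2"][0] == pytest.approx(1.0)

    def test_population_r2_identity(self):
        pop, lam, phi = _two_factor_population(loading=0.7, phi=0.5)
        rel = score_reliability(pop, lam, phi)
        # oracle: explicit regression of the factor on the items at population
        # level; cov(f, items) = structure column, R^2 = s' R^-1 s
        structure = lam @ phi
        for f in range(2):
            s = structure[:, f]
            r2_ref = s @ np.linalg.solve(pop, s)
            assert rel["multiple_r2"][f] == pytest.approx(r2_ref, abs=1e-8)

    def test_estimated_scores_track_true_factors(self):
        lam = np.zeros((12, 2))
        lam[:6, 0] = 0.75
        lam[6:, 1] = 0.75
        phi = np.array([[1.0, 0.5], [0.5, 1.0]])
        rng = np.random.default_rng(7)
        n = 2000
        f = rng.multivariate_normal([0, 0], phi, size=n)
        resid = rng.normal(size=(12,)) * 0  # build continuous indicators
        e = rng.normal(size=(n, 12)) * np.sqrt(1 - 0.75**2)
        data = f @ lam.T + e
        sol = fit_efa(data, n_factors=2)
        scores, rel = factor_scores(data, sol)
        for j in range(2):
            best = max(
                abs(np.corrcoef(scores[:, g], f[:, j])[0, 1]) for g in range(2)
            )
            assert best >= np.sqrt(rel["multiple_r2"].min()) - 0.05


def test_fit_efa_end_to_end_variance_and_phi():
    lam = np.zeros((12, 2))
    lam[:6, 0] = 0.7
    lam[6:, 1] = 0.7
    cfg = SimulationConfig(
        n_per_group=(500, 500),
        loadings=lam,
        factor_correlation=np.array([[1.0, 0.6], [0.6, 1.0]]),
        group_shift=np.zeros(12),
        thresholds=default_thresholds(12),
        seed=9,
    )
    data = generate_responses(cfg).values
    sol = fit_efa(data, n_factors=2)
    assert abs(sol.phi[0, 1] - 0.6) < 0.1
    assert 0.2 < sol.total_variance_explained < 0.8
    assert np.all(sol.communalities <= 1.0)


def test_smc_matches_regression(rng):
    z = rng.normal(size=(300, 4))
    z[:, 0] += z[:, 1]
    corr = np.corrcoef(z, rowvar=False)
    vals = smc(corr)
    for i in range(4):
        others = [k for k in range(4) if k != i]
        beta = np.linalg.solve(corr[np.ix_(others, others)], corr[others, i])
        assert vals[i] == pytest.approx(corr[i, others] @ beta, abs=1e-10)
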