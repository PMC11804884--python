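import numpy as np
import pytest

from mbiselect import (
    ModelSpec,
    PanelData,
    SolverConfig,
    SourcePartition,
    detect_layout,
    empirical_vcov,
    enumerate_combos,
    fit,
    fit_path,
    impute_all,
)
from mbiselect.objective import _weight_from_scores
from mbiselect.scores import basis_matrices, build_problem, get_link
from mbiselect.solver import _penalty, _ridge_init, lqa_diag, newton_step


def problem_of(panel, partition, corr="exchangeable", link="identity"):
    layout = detect_layout(panel, partition)
    imputed = impute_all(panel, partition, layout, enumerate_combos(layout))
    return build_problem(
        imputed,
        panel,
        partition,
        layout,
        basis_matrices(corr, panel.m),
        get_link(link),
    )


class TestLqaDiag:
    def test_at_zero_magnitude(self):
        d = lqa_diag(np.array([0.0]), lam=1.0, a=3.7, epsilon=1e-6)
        assert d[0] == pytest.approx(1e6)

    def test_flat_region_gives_zero(self):
        d = lqa_diag(np.array([5.0]), lam=1.0, a=3.7, epsilon=1e-6)
        assert d[0] == 0.0

    def test_lambda_zero_gives_zero(self):
        d = lqa_diag(np.array([0.0, 0.5, 3.0]), lam=0.0, a=3.7, epsilon=1e-6)
        np.testing.assert_array_equal(d, 0.0)


class TestNewtonStep:
    def test_unpenalized_complete_data_reaches_gee_solution(self, rng):
        """Identity link, independence basis, K=1: the unpenalized fit
        coincides with pooled least squares (normal-equations oracle)
        within two steps."""
        n, m, p = 20, 3, 3
        x = rng.standard_normal((n, m, p))
        beta0 = np.array([1.0, 0.0, -2.0])
        y = x @ beta0 + 0.5 * rng.standard_normal((n, m))
        panel = PanelData(y=y, x=x, subject_id=np.arange(n))
        partition = SourcePartition([range(p)])
        problem = problem_of(panel, partition, corr="independence")
        config = SolverConfig()
        beta = np.zeros(p)
        state = None
        for _ in range(2):
            beta, _, state, _, _ = newton_step(
                beta, problem, 0.0, 3.7, config, state
            )
        xf = x.reshape(-1, p)
        expect = np.linalg.lstsq(xf, y.reshape(-1), rcond=None)[0]
        np.testing.assert_allclose(beta, expect, atol=1e-8)

    def test_stationary_point_is_fixed(self, rng):
        """At an unpenalized stationary point the update returns beta
        unchanged (zero step)."""
        n, m, p = 15, 3, 3
        x = rng.standard_normal((n, m, p))
        y = x @ np.array([1.0, -0.5, 0.0]) + 0.3 * rng.standard_normal((n, m))
        panel = PanelData(y=y, x=x, subject_id=np.arange(n))
        problem = problem_of(panel, SourcePartition([range(p)]), "independence")
        config = SolverConfig()
        beta = np.zeros(p)
        state = None
        for _ in range(30):
            beta_new, _, state, d, _ = newton_step(
                beta, problem, 0.0, 3.7, config, state
            )
            beta = beta_new
            if d < 1e-12:
                break
        beta_next, _, _, dnorm, _ = newton_step(
            beta, problem, 0.0, 3.7, config, state
        )
        assert dnorm < 1e-9
        np.testing.assert_allclose(beta_next, beta, atol=1e-9)

    def test_single_step_minimizes_fixed_weight_quadratic(self, rng):
        """With the weight held at the current iterate and no penalty, one
        Newton step lands on the exact minimizer of the fixed-weight
        quadratic (analytic normal-equations solution)."""
        n, m, p = 12, 3, 3
        x = rng.standard_normal((n, m, p))
        y = x @ np.array([0.5, 1.0, 0.0]) + rng.standard_normal((n, m))
        panel = PanelData(y=y, x=x, subject_id=np.arange(n))
        problem = problem_of(panel, SourcePartition([range(p)]))
        beta_t = rng.normal(size=p)
        g, scores = problem.moments(beta_t)
        c = _weight_from_scores(scores)
        jac = problem.jacobian(beta_t)
        a_mat = jac.T @ c.apply_pinv(jac)
        expect = beta_t - np.linalg.solve(a_mat, jac.T @ c.apply_pinv(g))
        got, *_ = newton_step(beta_t, problem, 0.0, 3.7, SolverConfig())
        np.testing.assert_allclose(got, expect, atol=1e-8)

    def test_descent_of_line_search_surrogate(self, canonical3):
        """Every accepted step does not increase the surrogate it was
        line-searched on (fixed-weight objective + SCAD penalty)."""
        problem = problem_of(canonical3["panel"], canonical3["partition"])
        config = SolverConfig()
        lam = 0.3
        beta = _ridge_init(problem, config)
        state = None
        for _ in range(25):
            g, scores = problem.moments(beta)
            c = (
                state[1]
                if state is not None
                else _weight_from_scores(
                    scores, config.weight_shrinkage
                )
            )
            s_before = float(g @ c.apply_pinv(g)) + _penalty(beta, lam, 3.7)
            beta_new, s_after, state, dnorm, accepted = newton_step(
                beta, problem, lam, 3.7, config, state
            )
            if accepted:
                assert s_after <= s_before + 1e-9
            beta = beta_new
            if dnorm < config.tol or not accepted:
                break


class TestFitPath:
    def test_single_lambda_grid(self, canonical3):
        problem = problem_of(canonical3["panel"], canonical3["partition"])
        config = SolverConfig(lambda_grid=np.array([0.25]))
        res = fit_path(problem, ModelSpec(), config)
        assert res.lambda_star == 0.25
        assert len(res.ebic_path) == 1

    def test_ebic_path_covers_grid_and_ties_prefer_sparser(self, canonical3):
        problem = problem_of(canonical3["panel"], canonical3["partition"])
        config = SolverConfig(n_lambda=8)
        res = fit_path(problem, ModelSpec(), config)
        assert len(res.ebic_path) == 8
        ebics = [e["ebic"] for e in res.ebic_path]
        best = min(ebics)
        # path is descending in lambda; the selected entry is the first
        # (largest-lambda) entry attaining the minimum
        first_idx = ebics.index(best)
        assert res.lambda_star == res.ebic_path[first_idx]["lam"]

    def test_support_respects_zero_threshold(self, canonical3):
        problem = problem_of(canonical3["panel"], canonical3["partition"])
        model = ModelSpec()
        res = fit_path(problem, model, SolverConfig(n_lambda=8))
        nz = np.abs(res.beta_hat) >= model.zero_threshold
        assert set(res.support) == set(np.where(nz)[0])
        assert not np.any(
            (np.abs(res.beta_hat) > 0)
            & (np.abs(res.beta_hat) < model.zero_threshold)
        )

    def test_pure_noise_selects_empty_support(self):
        """Under a global null (all coefficients zero) the selected support
        is empty in nearly all replicates."""
        rng_global = np.random.default_rng(7)
        empty = 0
        reps = 20
        for _ in range(reps):
            n, m, p = 400, 3, 10
            x = rng_global.standard_normal((n, m, p))
            y = rng_global.standard_normal((n, m))
            panel = PanelData(y=y, x=x, subject_id=np.arange(n))
            problem = problem_of(panel, SourcePartition([range(p)]))
            res = fit_path(problem, ModelSpec(), SolverConfig(n_lambda=15))
            empty += len(res.support) == 0
        assert empty >= int(0.9 * reps)

    def test_signal_recovery_end_to_end(self, rng):
        """On an easy synthetic panel the full pipeline recovers the true
        support exactly."""
        from conftest import make_three_source_panel

        beta = np.zeros(6)
        beta[0], beta[2] = 2.0, -1.5
        panel, partition, _, _ = make_three_source_panel(
            rng, n_k=(30, 60, 60), beta=beta, noise=0.5
        )
        res = fit(panel, partition, ModelSpec())
        assert set(res.support) == {0, 2}
        assert res.converged


class TestPenaltyExclusion:
    def test_excluded_column_not_forced_to_zero(self, rng):
        """A column listed in penalty_exclude keeps its (small) estimate
        instead of being selected away."""
        n, m, p = 80, 3, 5
        x = rng.standard_normal((n, m, p))
        beta = np.array([0.05, 1.0, 0.0, 0.0, 0.0])
        y = x @ beta + 0.5 * rng.standard_normal((n, m))
        panel = PanelData(y=y, x=x, subject_id=np.arange(n))
        part = SourcePartition([range(p)])
        penalized = fit(panel, part, ModelSpec())
        free = fit(panel, part, ModelSpec(penalty_exclude=(0,)))
        assert penalized.beta_hat[0] == 0.0
        assert free.beta_hat[0] != 0.0
        assert 1 in free.support  # the real signal is still found


class TestEmpiricalVcov:
    def test_complete_data_matches_gmm_covariance_oracle(self, rng):
        """K=1 (Omega=I): the estimate equals inv(H C^+ H')/n computed
        densely from scratch."""
        n, m, p = 40, 3, 3
        x = rng.standard_normal((n, m, p))
        beta = np.array([1.0, -0.5, 0.8])
        y = x @ beta + rng.standard_normal((n, m))
        panel = PanelData(y=y, x=x, subject_id=np.arange(n))
        problem = problem_of(panel, SourcePartition([range(p)]))
        support = np.arange(p)
        got = empirical_vcov(problem, beta, support, shrinkage="none")
        g, scores = problem.moments(beta)
        c = scores[0].T @ scores[0] / n
        h = problem.jacobian(beta).T
        expect = np.linalg.inv(h @ np.linalg.pinv(c, hermitian=True) @ h.T) / n
        np.testing.assert_allclose(got, expect, rtol=1e-6)

    def test_inverse_n_scaling(self, rng):
        """Duplicating the dataset roughly halves the coefficient
        covariance (asymptotic 1/n behaviour)."""
        n, m, p = 60, 3, 3
        x = rng.standard_normal((n, m, p))
        beta = np.array([1.0, -0.5, 0.8])
        y = x @ beta + rng.standard_normal((n, m))
        panel = PanelData(y=y, x=x, subject_id=np.arange(n))
        problem = problem_of(panel, SourcePartition([range(p)]))
        v1 = empirical_vcov(problem, beta, np.arange(p), shrinkage="none")
        doubled = PanelData(
            y=np.concatenate([y, y]),
            x=np.concatenate([x, x]),
            subject_id=np.arange(2 * n),
        )
        problem2 = problem_of(doubled, SourcePartition([range(p)]))
        v2 = empirical_vcov(problem2, beta, np.arange(p), shrinkage="none")
        np.testing.assert_allclose(np.diag(v2), np.diag(v1) / 2, rtol=0.1)

    def test_empty_support_rejected(self, complete_panel):
        panel, partition, beta = complete_panel
        problem = problem_of(panel, partition)
        with pytest.raises(ValueError, match="support"):
            empirical_vcov(problem, beta, np.array([], dtype=int))
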