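"""Dense reference solvers, uniformization series, and the low-rank iteration."""

import math

import numpy as np
import pytest

from htmarginal.models import (
    InitialState,
    ThetaMatrix,
    build_generator_cp,
    gamma_bound,
    generator_dense,
    mhn_to_san,
)
from htmarginal.tree import balanced_tree
from htmarginal.httensor import TruncationControl, cp_to_ht, ht_to_dense, ht_unit, CPTensor
from htmarginal.solver import (
    ConvergenceBound,
    SolverConfig,
    StructureError,
    dense_marginal,
    dense_splitting_marginal,
    neumann_partial_sums,
    partial_sum_mass,
    relative_residual,
    solve_marginal_lowrank,
    upper_approx,
)

from conftest import random_theta


def mhn_dense(theta_matrix):
    spec = mhn_to_san(theta_matrix)
    q = generator_dense(spec)
    p0 = InitialState.all_zero(spec.d).dense(spec.sizes)
    return spec, q, p0


class TestDenseMarginal:
    @pytest.mark.parametrize("theta,expected", [(1.0, [0.5, 0.5]), (3.0, [0.25, 0.75])])
    def test_two_state_closed_form(self, theta, expected):
        # p = (1/(1+theta), theta/(1+theta)) for a single event
        _, q, p0 = mhn_dense(ThetaMatrix(theta=np.array([[theta]])))
        np.testing.assert_allclose(dense_marginal(q, p0), expected, atol=1e-14)

    def test_neutral_two_event_network(self):
        _, q, p0 = mhn_dense(ThetaMatrix(theta=np.ones((2, 2))))
        np.testing.assert_allclose(
            dense_marginal(q, p0), [1 / 3, 1 / 6, 1 / 6, 1 / 3], atol=1e-14
        )

    def test_result_is_distribution(self, rng):
        _, q, p0 = mhn_dense(random_theta(rng, 4))
        p = dense_marginal(q, p0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert p.min() >= -1e-14


class TestSplittingMarginal:
    def test_two_state_chain(self):
        _, q, p0 = mhn_dense(ThetaMatrix(theta=np.array([[1.0]])))
        np.testing.assert_allclose(dense_splitting_marginal(q, p0), [0.5, 0.5], atol=1e-14)

    def test_matches_direct_solve(self, rng):
        _, q, p0 = mhn_dense(random_theta(rng, 3))
        p_direct = dense_marginal(q, p0)
        p_split = dense_splitting_marginal(q, p0)
        assert np.linalg.norm(p_split - p_direct) <= 1e-10 * np.linalg.norm(p_direct)

    def test_non_progressive_chain_rejected(self):
        # a reversible 2-state chain is not triangular under any event order
        q = np.array([[-1.0, 1.0], [1.0, -1.0]])
        with pytest.raises(StructureError):
            dense_splitting_marginal(q, np.array([1.0, 0.0]))


class TestPartialSumMass:
    @pytest.mark.parametrize(
        "k,gamma,expected",
        [(0, 1.0, 1.0), (0, 7.3, 1.0), (1, 1.0, 1.5), (1, 2.0, 5 / 3)],
    )
    def test_closed_form_values(self, k, gamma, expected):
        assert partial_sum_mass(k, gamma) == pytest.approx(expected, abs=1e-14)

    def test_large_k_no_overflow(self):
        val = partial_sum_mass(10_000, 50.0)
        assert 0.0 < val <= 51.0

    def test_converges_to_one_plus_gamma(self):
        assert partial_sum_mass(5_000, 2.0) == pytest.approx(3.0, rel=1e-12)


class TestNeumannPartialSums:
    def test_k0_recovers_initial_distribution(self, rng):
        _, q, p0 = mhn_dense(random_theta(rng, 3))
        _, pnorm = neumann_partial_sums(q, p0, 0, gamma_bound(mhn_to_san(random_theta(rng, 3))) + 5)
        np.testing.assert_allclose(pnorm[0], p0, atol=1e-14)

    def test_converges_to_marginal(self):
        spec, q, p0 = mhn_dense(ThetaMatrix(theta=np.array([[1.0]])))
        _, pnorm = neumann_partial_sums(q, p0, 50, gamma_bound(spec))
        np.testing.assert_allclose(pnorm[-1], [0.5, 0.5], atol=1e-10)

    def test_masses_match_closed_form_exactly(self, rng):
        # closed-form mass identity of the untruncated partial sums
        theta = random_theta(rng, 4)
        spec, q, p0 = mhn_dense(theta)
        gamma = gamma_bound(spec)
        ptilde, pnorm = neumann_partial_sums(q, p0, 30, gamma)
        for m, (pt, pn) in enumerate(zip(ptilde, pnorm)):
            assert (1 + gamma) * pt.sum() == pytest.approx(
                partial_sum_mass(m, gamma), abs=1e-12
            )
            assert pn.sum() == pytest.approx(1.0, abs=1e-12)

    def test_lowrank_mode_matches_dense_mode(self, rng):
        theta = random_theta(rng, 3)
        spec = mhn_to_san(theta)
        gamma = gamma_bound(spec)
        qd = generator_dense(spec)
        p0d = InitialState.all_zero(3).dense(spec.sizes)
        tree = balanced_tree(3)
        q = build_generator_cp(spec)
        p0 = ht_unit(tree, spec.sizes, (0,) * 3)
        ptilde_d, pnorm_d = neumann_partial_sums(qd, p0d, 4, gamma)
        ptilde_h, pnorm_h = neumann_partial_sums(q, p0, 4, gamma)
        for ref, low in zip(ptilde_d, ptilde_h):
            np.testing.assert_allclose(ht_to_dense(low).ravel(), ref, atol=1e-12)
        for ref, low in zip(pnorm_d, pnorm_h):
            np.testing.assert_allclose(ht_to_dense(low).ravel(), ref, atol=1e-12)

    def test_lower_bound_monotone_below_marginal(self, rng):
        spec, q, p0 = mhn_dense(random_theta(rng, 3))
        gamma = gamma_bound(spec)
        p = dense_marginal(q, p0)
        ptilde, _ = neumann_partial_sums(q, p0, 25, gamma)
        prev = np.full_like(p, -np.inf)
        for pt in ptilde:
            assert np.all(pt <= p + 1e-12)
            assert np.all(pt >= prev - 1e-12)
            prev = pt


class TestUpperApprox:
    def test_sandwich_between_bounds(self):
        spec, q, p0 = mhn_dense(ThetaMatrix(theta=np.array([[1.0]])))
        gamma = gamma_bound(spec)
        p = dense_marginal(q, p0)
        ptilde, _ = neumann_partial_sums(q, p0, 3, gamma)
        phat = upper_approx(ptilde[3], 3, gamma)
        assert np.all(ptilde[3] <= p + 1e-14)
        assert np.all(p <= phat + 1e-14)

    def test_deficit_value_at_k0(self):
        # deficit = (gamma/(1+gamma))^(k+1) = 1/2 for k=0, gamma=1
        phat = upper_approx(np.zeros(4), 0, 1.0)
        np.testing.assert_allclose(phat, 0.5)

    def test_deficit_vanishes_for_large_k(self):
        phat = upper_approx(np.zeros(2), 500, 1.0)
        np.testing.assert_allclose(phat, 0.0, atol=1e-100)


class TestRelativeResidual:
    def test_exact_solution_has_tiny_residual(self, rng):
        theta = random_theta(rng, 4)
        spec, qd, p0d = mhn_dense(theta)
        p = dense_marginal(qd, p0d)
        tree = balanced_tree(4)
        # embed the dense solution in HT exactly (one CP term per state block)
        p_ht = cp_to_ht(_dense_to_cp(p.reshape([2] * 4)), tree)
        q = build_generator_cp(spec)
        p0 = ht_unit(tree, spec.sizes, (0,) * 4)
        assert relative_residual(q, p_ht, p0) <= 1e-8

    def test_initial_state_residual_closed_form(self):
        theta = ThetaMatrix(theta=np.array([[1.0]]))
        spec = mhn_to_san(theta)
        q = build_generator_cp(spec)
        tree = balanced_tree(1)
        p0 = ht_unit(tree, [2], (0,))
        # (Id - Q) p0 - p0 = -Q p0 = (1, -1): norm sqrt(2)
        assert relative_residual(q, p0, p0) == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_matches_dense_residual(self, rng):
        theta = random_theta(rng, 6)
        spec, qd, p0d = mhn_dense(theta)
        tree = balanced_tree(6)
        q = build_generator_cp(spec)
        p0 = ht_unit(tree, spec.sizes, (0,) * 6)
        cfg = SolverConfig(gamma=gamma_bound(spec), tol=1e-5, residual_stride=5)
        res = solve_marginal_lowrank(q, p0, cfg)
        dense_res = np.linalg.norm(
            (np.eye(64) - qd) @ ht_to_dense(res.p).ravel() - p0d
        ) / np.linalg.norm(p0d)
        lowrank_res = relative_residual(q, res.p, p0)
        assert lowrank_res == pytest.approx(dense_res, abs=1e-6)


def _dense_to_cp(t):
    """Exact CP representation of a small dense tensor (one term per slice)."""
    d = t.ndim
    sizes = list(t.shape)
    terms = []
    flat = t.reshape(t.shape[0], -1)
    for i0 in range(t.shape[0]):
        sub = flat[i0].reshape(sizes[1:]) if d > 1 else None
        e0 = np.zeros(sizes[0])
        e0[i0] = 1.0
        if d == 1:
            terms.append([np.array([t[i0]]) * 0 + t[i0] * e0])
            continue
        for idx in np.ndindex(*sizes[1:-1]) if d > 2 else [()]:
            vec = sub[idx] if d > 2 else sub
            term = [e0]
            for k, j in enumerate(idx):
                e = np.zeros(sizes[1 + k])
                e[j] = 1.0
                term.append(e)
            term.append(np.asarray(vec, dtype=float))
            terms.append(term)
    return CPTensor(sizes=sizes, terms=terms)


class TestLowRankSolver:
    def test_two_state_chain_converges(self):
        theta = ThetaMatrix(theta=np.array([[1.0]]))
        spec = mhn_to_san(theta)
        q = build_generator_cp(spec)
        tree = balanced_tree(1)
        p0 = ht_unit(tree, [2], (0,))
        res = solve_marginal_lowrank(q, p0, SolverConfig(gamma=1.0, tol=1e-6))
        assert res.converged
        np.testing.assert_allclose(ht_to_dense(res.p).ravel(), [0.5, 0.5], atol=1e-5)
        assert res.final_mass == pytest.approx(1.0, abs=1e-12)

    def test_matches_dense_oracle_d8_block_design(self):
        from htmarginal.synthetic import BlockDesign, sample_theta

        theta = sample_theta(BlockDesign(d=8, n_blocks=2, seed=42))
        spec, qd, p0d = mhn_dense(theta)
        tree = balanced_tree(8)
        q = build_generator_cp(spec)
        p0 = ht_unit(tree, spec.sizes, (0,) * 8)
        cfg = SolverConfig(gamma=gamma_bound(spec), tol=1e-4, residual_stride=5)
        res = solve_marginal_lowrank(q, p0, cfg)
        p_ref = dense_marginal(qd, p0d)
        dist = np.linalg.norm(ht_to_dense(res.p).ravel() - p_ref)
        assert dist <= 1e-3 * np.linalg.norm(p_ref)
        assert res.final_mass == pytest.approx(1.0, abs=1e-12)

    def test_every_recorded_mass_is_one(self, rng):
        theta = random_theta(rng, 5)
        spec = mhn_to_san(theta)
        tree = balanced_tree(5)
        q = build_generator_cp(spec)
        p0 = ht_unit(tree, spec.sizes, (0,) * 5)
        cfg = SolverConfig(gamma=gamma_bound(spec), tol=1e-4)
        res = solve_marginal_lowrank(q, p0, cfg)
        for mass in res.masses:
            assert mass == pytest.approx(1.0, abs=1e-12)

    def test_max_iter_flagged_unconverged(self, rng):
        theta = random_theta(rng, 4)
        spec = mhn_to_san(theta)
        q = build_generator_cp(spec)
        p0 = ht_unit(balanced_tree(4), spec.sizes, (0,) * 4)
        cfg = SolverConfig(gamma=gamma_bound(spec), tol=1e-12, max_iter=3)
        res = solve_marginal_lowrank(q, p0, cfg)
        assert not res.converged
        assert res.iterations == 3


class TestConvergenceEnvelope:
    def test_theorem_bound_holds_every_iteration(self, rng):
        theta = random_theta(rng, 4)
        spec, q, p0 = mhn_dense(theta)
        gamma = gamma_bound(spec)
        p = dense_marginal(q, p0)
        bound = ConvergenceBound.from_dense(gamma, p0, p)
        assert 0.0 < bound.rate < 1.0
        _, pnorm = neumann_partial_sums(q, p0, 60, gamma)
        for k, pk in enumerate(pnorm):
            assert np.linalg.norm(pk - p) <= bound.envelope(k) * (1 + 1e-10)

    def test_log_residual_slope_matches_rate(self, rng):
        theta = random_theta(rng, 4)
        spec, q, p0 = mhn_dense(theta)
        gamma = gamma_bound(spec)
        p = dense_marginal(q, p0)
        _, pnorm = neumann_partial_sums(q, p0, 80, gamma)
        errs = np.array([np.linalg.norm(pk - p) for pk in pnorm])
        keep = errs > 1e-13
        ks = np.arange(len(errs))[keep]
        slope = np.polyfit(ks, np.log(errs[keep]), 1)[0]
        assert slope <= math.log(gamma / (1 + gamma)) + 0.1
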