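"""Inference pipeline: gene harmonization, sampling, decoding, uncertainty."""

import numpy as np
import pytest

from disco.bgnn import DenoiserParams, tiny_config
from disco.diffusion import EdgeCategorical, make_schedule
from disco.inference import (assignment_cost, decode_assignment, deconvolve,
                             deconvolve_best_of, estimate_uncertainty,
                             harmonize_genes, proportions_from_assignment,
                             reconstruct_and_score)
from disco.oracle import AssignmentMatrix


class TestHarmonizeGenes:
    def test_identity_when_lists_match_below_capacity(self):
        X = np.arange(12.0).reshape(3, 4)
        Y = np.arange(6.0).reshape(3, 2)
        ids = ["a", "b", "c"]
        Xh, Yh, plan = harmonize_genes(X, Y, ids, ids, capacity=2000)
        np.testing.assert_array_equal(Xh, X)
        np.testing.assert_array_equal(Yh, Y)
        assert plan.mode == "first_d_weights"
        assert plan.d == 3

    def test_small_shared_set_uses_first_d_weights(self):
        rng = np.random.default_rng(0)
        ids = [f"g{i}" for i in range(160)]
        X = rng.random((160, 5))
        Y = rng.random((160, 4))
        _, _, plan = harmonize_genes(X, Y, ids, ids, capacity=2000)
        assert plan.mode == "first_d_weights"
        assert plan.d == 160

    def test_capacity_triggers_hvg_selection(self):
        rng = np.random.default_rng(1)
        n = 50
        ids = [f"g{i}" for i in range(n)]
        X = rng.poisson(2.0, size=(n, 30)).astype(float)
        Y = rng.poisson(6.0, size=(n, 10)).astype(float)
        Xh, Yh, plan = harmonize_genes(X, Y, ids, ids, capacity=20)
        assert plan.mode == "hvg_top20"
        assert Xh.shape == (20, 30) and Yh.shape == (20, 10)
        assert len(plan.shared_ids) == 20

    def test_order_follows_reference(self):
        X = np.array([[1.0], [2.0], [3.0]])
        Y = np.array([[10.0], [20.0]])
        Xh, Yh, plan = harmonize_genes(X, Y, ["a", "b", "c"], ["c", "a"],
                                       capacity=100)
        assert plan.shared_ids == ["a", "c"]
        np.testing.assert_array_equal(Xh[:, 0], [1.0, 3.0])
        np.testing.assert_array_equal(Yh[:, 0], [20.0, 10.0])

    def test_disjoint_lists_rejected(self):
        with pytest.raises(ValueError):
            harmonize_genes(np.ones((2, 2)), np.ones((2, 2)), ["a", "b"],
                            ["c", "d"])


class TestDecodeAssignment:
    def test_one_hot_rows_unchanged(self):
        soft = EdgeCategorical(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_array_equal(decode_assignment(soft).entries,
                                      [[0, 1], [1, 0]])

    def test_argmax_and_tie_break(self):
        soft = EdgeCategorical(np.array([[0.2, 0.7, 0.1],
                                         [0.4, 0.4, 0.4]]))
        A = decode_assignment(soft)
        np.testing.assert_array_equal(A.entries, [[0, 1, 0], [1, 0, 0]])
        assert A.is_feasible()


class TestProportionsFromAssignment:
    def test_one_cell_per_spot(self):
        A = AssignmentMatrix(np.eye(3))
        q = proportions_from_assignment(A, np.array([0, 1, 2]), 3)
        np.testing.assert_array_equal(q.values, np.eye(3))

    def test_empty_spot_and_conservation(self):
        A = AssignmentMatrix(np.array([[1, 0], [1, 0], [1, 0]]))
        types = np.array([0, 0, 1])
        q = proportions_from_assignment(A, types, 2)
        np.testing.assert_allclose(q.values, [[2 / 3, 1 / 3], [0, 0]])
        counts = q.values * A.entries.sum(axis=0)[:, None]
        np.testing.assert_allclose(counts.sum(axis=0), [2, 1])


class TestReconstruct:
    def test_exact_scaled_orthogonal(self):
        X = np.eye(2)
        A = AssignmentMatrix(np.eye(2))
        recon, cos = reconstruct_and_score(X, A, 3 * np.eye(2))
        np.testing.assert_array_equal(recon, np.eye(2))
        np.testing.assert_allclose(cos, [1.0, 1.0])
        _, cos0 = reconstruct_and_score(X, A, np.eye(2)[::-1])
        np.testing.assert_allclose(cos0, [0.0, 0.0])


class TestDeconvolve:
    def test_determinism_and_seed_isolation(self, tiny_instance, tiny_params,
                                            tiny_sched):
        X, Y = tiny_instance.cells.expr, tiny_instance.spots_expr
        ct, nt = tiny_instance.cells.cell_types, tiny_instance.cells.n_types
        r1 = deconvolve(X, Y, tiny_params, tiny_sched, seed=4, cell_types=ct,
                        n_types=nt)
        r2 = deconvolve(X, Y, tiny_params, tiny_sched, seed=4, cell_types=ct,
                        n_types=nt)
        np.testing.assert_array_equal(r1.assignment.entries,
                                      r2.assignment.entries)
        r3 = deconvolve(X, Y, tiny_params, tiny_sched, seed=5, cell_types=ct,
                        n_types=nt)
        assert r1.assignment.is_feasible() and r3.assignment.is_feasible()

    def test_uniform_model_gives_global_frequencies(self, tiny_instance):
        """With a zeroed decoder every edge scores 0.5; argmax then puts all
        cells on spot 0, whose proportions are the global type frequencies."""
        params = DenoiserParams.init(tiny_config(), seed=0)
        for k in params.decoder_block_names():
            params.blocks[k].data[:] = 0.0
        sched = make_schedule(10, 1e-3, 0.1, tau_count=2)
        X, Y = tiny_instance.cells.expr, tiny_instance.spots_expr
        ct, nt = tiny_instance.cells.cell_types, tiny_instance.cells.n_types
        res = deconvolve(X, Y, params, sched, seed=0, cell_types=ct,
                         n_types=nt)
        freqs = np.bincount(ct, minlength=nt) / len(ct)
        np.testing.assert_allclose(res.proportions.values[0], freqs)

    def test_trajectory_endpoint_matches_result(self, tiny_instance,
                                                tiny_params):
        sched = make_schedule(10, 1e-3, 0.1, tau_count=3)
        X, Y = tiny_instance.cells.expr, tiny_instance.spots_expr
        ct, nt = tiny_instance.cells.cell_types, tiny_instance.cells.n_types
        res = deconvolve(X, Y, tiny_params, sched, seed=1, cell_types=ct,
                         n_types=nt, capture_trajectory=True)
        assert res.trajectory is not None
        last = res.trajectory[-1]
        np.testing.assert_array_equal(last.proportions,
                                      res.proportions.values)
        np.testing.assert_array_equal(last.per_spot_cosine,
                                      res.per_spot_cosine)
        assert res.reconstruction.shape == Y.shape
        np.testing.assert_array_equal(
            res.reconstruction, X @ res.assignment.entries)

    def test_best_of_never_costlier_than_first(self, tiny_instance,
                                               tiny_params, tiny_sched):
        X, Y = tiny_instance.cells.expr, tiny_instance.spots_expr
        ct, nt = tiny_instance.cells.cell_types, tiny_instance.cells.n_types
        single = deconvolve(X, Y, tiny_params, tiny_sched, seed=2,
                            cell_types=ct, n_types=nt)
        best = deconvolve_best_of(X, Y, tiny_params, tiny_sched,
                                  n_candidates=3, seed=2, cell_types=ct,
                                  n_types=nt)
        assert assignment_cost(X, best.assignment, Y) <= \
            assignment_cost(X, single.assignment, Y)


class TestUncertainty:
    def test_interval_count_and_ordering(self, tiny_instance, tiny_params,
                                         tiny_sched):
        X, Y = tiny_instance.cells.expr, tiny_instance.spots_expr
        ct, nt = tiny_instance.cells.cell_types, tiny_instance.cells.n_types
        rep = estimate_uncertainty(X, Y, tiny_params, tiny_sched, ct, nt,
                                   n_repeats=4, n_bootstrap=200, seed=0)
        assert rep.n_intervals == tiny_instance.n_spots * nt
        assert np.all(rep.ci_lower <= rep.mean + 1e-12)
        assert np.all(rep.mean <= rep.ci_upper + 1e-12)
        assert np.all((rep.ci_upper - rep.ci_lower) <= 1.0 + 1e-12)

    def test_zero_variance_degenerate_intervals(self, tiny_instance):
        # a zeroed decoder is deterministic across seeds in its proportions
        params = DenoiserParams.init(tiny_config(), seed=0)
        for k in params.decoder_block_names():
            params.blocks[k].data[:] = 0.0
        sched = make_schedule(10, 1e-3, 0.1, tau_count=2)
        X, Y = tiny_instance.cells.expr, tiny_instance.spots_expr
        ct, nt = tiny_instance.cells.cell_types, tiny_instance.cells.n_types
        rep = estimate_uncertainty(X, Y, params, sched, ct, nt, n_repeats=3,
                                   n_bootstrap=100, seed=0)
        np.testing.assert_allclose(rep.ci_lower, rep.mean, atol=1e-12)
        np.testing.assert_allclose(rep.ci_upper, rep.mean, atol=1e-12)

    def test_requires_two_repeats(self, tiny_instance, tiny_params,
                                  tiny_sched):
        with pytest.raises(ValueError):
            estimate_uncertainty(tiny_instance.cells.expr,
                                 tiny_instance.spots_expr, tiny_params,
                                 tiny_sched, tiny_instance.cells.cell_types,
                                 3, n_repeats=1)
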