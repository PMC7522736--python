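import numpy as np
import pytest

from qsmtfir import (
    ScalarVolume,
    TFIRParams,
    VoxelGrid,
    apply_kspace,
    dipole_field,
    dipole_kernel,
    objective,
    prepare_inversion_inputs,
    reconstruct,
    smv_kernel,
    weight_mask_r,
)
from qsmtfir.solver import DivergenceError, grid_search
from qsmtfir.volumes import VolumeError


def _tiny_problem(rng, n=8):
    g = VoxelGrid((n, n, n))
    chi = ScalarVolume(g, rng.standard_normal(g.dims), "susceptibility_ppm")
    f = ScalarVolume(g, rng.standard_normal(g.dims), "field_ppm")
    w = ScalarVolume(g, rng.uniform(0.1, 2.0, g.dims), "weight")
    mg = tuple(
        ScalarVolume(g, (rng.random(g.dims) > 0.1).astype(float), "mask") for _ in range(3)
    )
    r = ScalarVolume(g, rng.uniform(0.1, 1.0, g.dims), "weight")
    return g, chi, f, w, mg, r


class TestObjective:
    def test_zero_chi_leaves_only_data_term(self, rng):
        g, chi, f, w, mg, r = _tiny_problem(rng)
        zero = ScalarVolume(g, np.zeros(g.dims), "susceptibility_ppm")
        p = TFIRParams(lambda1=0.01, lambda2=0.02, smv_radius_mm=1.0)
        total, (data, tv, l2) = objective(zero, f, w, mg, r, p)
        assert tv == 0.0 and l2 == 0.0
        assert np.isclose(data, 0.5 * np.sum((w.values * f.values) ** 2))
        assert np.isclose(total, data)

    def test_truth_zeroes_data_term_on_consistent_field(self, small_brain):
        chi, head = small_brain["chi"], small_brain["head"]
        g = chi.grid
        f = dipole_field(chi, padded=False)  # periodic-consistent field
        w = ScalarVolume(g, head.values, "weight")
        ones = [ScalarVolume(g, np.ones(g.dims), "mask")] * 3
        r = ScalarVolume(g, np.ones(g.dims), "weight")
        p = TFIRParams(lambda1=0.0, lambda2=0.0)
        total, (data, _, _) = objective(chi, f, w, ones, r, p)
        ref = 0.5 * np.sum((w.values * f.values) ** 2)
        assert data < 1e-12 * ref

    def test_terms_match_brute_force_sums(self, rng):
        g, chi, f, w, mg, r = _tiny_problem(rng)
        p = TFIRParams(lambda1=0.013, lambda2=0.07, smv_radius_mm=1.0)
        total, (data, tv, l2) = objective(chi, f, w, mg, r, p)
        d_chi = apply_kspace(dipole_kernel(g), chi).values
        data_bf = 0.5 * sum(
            (w.values[i, j, k] * (f.values[i, j, k] - d_chi[i, j, k])) ** 2
            for i in range(8) for j in range(8) for k in range(8)
        )
        tv_bf = 0.0
        for a in range(3):
            ga = np.roll(chi.values, -1, axis=a) - chi.values
            tv_bf += sum(
                abs(mg[a].values[i, j, k] * ga[i, j, k])
                for i in range(8) for j in range(8) for k in range(8)
            )
        tv_bf *= p.lambda1
        l_chi = apply_kspace(smv_kernel(g, 1.0), chi).values
        l2_bf = p.lambda2 * sum(
            (r.values[i, j, k] * l_chi[i, j, k]) ** 2
            for i in range(8) for j in range(8) for k in range(8)
        )
        assert np.isclose(data, data_bf, rtol=1e-10)
        assert np.isclose(tv, tv_bf, rtol=1e-10)
        assert np.isclose(l2, l2_bf, rtol=1e-10)
        assert np.isclose(total, data_bf + tv_bf + l2_bf, rtol=1e-10)

    def test_nonfinite_input_rejected(self, rng):
        g, chi, f, w, mg, r = _tiny_problem(rng)
        bad = ScalarVolume(g, np.full(g.dims, np.nan), "susceptibility_ppm")
        with pytest.raises(VolumeError):
            objective(bad, f, w, mg, r, TFIRParams())


class TestReconstruct:
    def test_zero_field_fixed_point(self, rng):
        g, chi, f, w, mg, r = _tiny_problem(rng)
        zero_f = ScalarVolume(g, np.zeros(g.dims), "field_ppm")
        mask = ScalarVolume(g, np.ones(g.dims), "mask")
        res = reconstruct(zero_f, w, mask, mg, r, TFIRParams(max_outer=10))
        assert np.allclose(res.chi.values, 0.0)
        assert res.converged and res.n_outer == 1

    def test_all_zero_weight_rejected(self, rng):
        g, chi, f, w, mg, r = _tiny_problem(rng)
        wz = ScalarVolume(g, np.zeros(g.dims), "weight")
        mask = ScalarVolume(g, np.ones(g.dims), "mask")
        with pytest.raises(VolumeError):
            reconstruct(f, wz, mask, mg, r, TFIRParams())

    def test_lambda2_zero_matches_tfi_plain_bitwise(self, small_brain):
        chi, r2s, head = small_brain["chi"], small_brain["r2s"], small_brain["head"]
        p = TFIRParams(lambda1=1e-3, lambda2=0.0, max_outer=4)
        bundle = prepare_inversion_inputs(chi, r2s, head, p)
        res_a = reconstruct(
            bundle["f"], bundle["w"], head, bundle["mg_masks"], bundle["r"], p
        )
        res_b = reconstruct(
            bundle["f"], bundle["w"], head, bundle["mg_masks"], bundle["r"],
            TFIRParams(lambda1=1e-3, lambda2=0.0, variant="tfi_plain", max_outer=4),
        )
        assert np.array_equal(res_a.chi.values, res_b.chi.values)

    def test_tau_zero_subvoxel_k_equals_least_norm(self, small_brain):
        # tau = 0 and k below one voxel: the adaptive term degenerates to an
        # unweighted least-norm penalty, identical to the ln_qsm variant on a
        # full-grid mask
        chi, r2s = small_brain["chi"], small_brain["r2s"]
        g = chi.grid
        f = dipole_field(chi, padded=False)
        ones = ScalarVolume(g, np.ones(g.dims), "mask")
        w = ScalarVolume(g, small_brain["head"].values, "weight")
        mg = [ones] * 3
        r = weight_mask_r(r2s, 0.0, smv_kernel(g, 0.4), ones)
        assert np.allclose(r.values, 1.0)
        p_t = TFIRParams(lambda1=1e-3, lambda2=0.02, tau_s=0.0, smv_radius_mm=0.4,
                         variant="tfir", max_outer=4)
        p_l = TFIRParams(lambda1=1e-3, lambda2=0.02, tau_s=0.0, smv_radius_mm=0.4,
                         variant="ln_qsm", max_outer=4)
        res_t = reconstruct(f, w, ones, mg, r, p_t)
        res_l = reconstruct(f, w, ones, mg, r, p_l)
        assert np.allclose(res_t.chi.values, res_l.chi.values, atol=1e-8)

    def test_objective_trace_non_increasing(self, small_brain):
        chi, r2s, head = small_brain["chi"], small_brain["r2s"], small_brain["head"]
        for variant in ("tfir", "tfi_plain", "ln_qsm", "medi_smv_linear"):
            p = TFIRParams(lambda1=1e-3, lambda2=0.05, variant=variant, max_outer=6,
                           medi_smv_radius_mm=3.0)
            bundle = prepare_inversion_inputs(chi, r2s, head, p)
            res = reconstruct(bundle["f"], bundle["w"], head, bundle["mg_masks"],
                              bundle["r"], p)
            tr = np.array(res.objective_trace)
            assert np.all(np.diff(tr) <= 1e-6 * tr[:-1])

    def test_scale_covariance_without_tv(self, rng):
        # data and L2 terms are quadratic, so with lambda1 = 0 the minimizer
        # scales linearly with the field; checked on a well-conditioned
        # instance (w, r bounded away from 0) so CG converges to the minimum
        g, chi, f, w, mg, r = _tiny_problem(rng)
        mask = ScalarVolume(g, np.ones(g.dims), "mask")
        p = TFIRParams(lambda1=0.0, lambda2=0.5, max_outer=2, cg_tol=1e-12,
                       cg_max=3000, stop_rel_change=1e-12)
        res1 = reconstruct(f, w, mask, mg, r, p)
        f2 = ScalarVolume(g, 3.0 * f.values, "field_ppm")
        res2 = reconstruct(f2, w, mask, mg, r, p)
        denom = max(np.abs(res2.chi.values).max(), 1e-12)
        assert np.abs(res2.chi.values - 3.0 * res1.chi.values).max() / denom < 1e-6

    def test_divergence_error_carries_trace(self):
        err = DivergenceError("boom", [1.0, 2.0])
        assert err.trace == [1.0, 2.0]


class TestGridSearch:
    def test_single_combination_matches_direct_rmse(self, small_brain):
        from qsmtfir import rmse

        chi, r2s, head, brain = (
            small_brain["chi"], small_brain["r2s"], small_brain["head"], small_brain["brain"],
        )
        p = TFIRParams(lambda1=1e-3, max_outer=3)
        bundle = prepare_inversion_inputs(chi, r2s, head, p)
        bundle["eval_mask"] = brain
        table = grid_search(chi, bundle, [0.05], [0.05], [1.0], p)
        assert len(table) == 1 and bool(table["is_argmin"].iloc[0])
        res = reconstruct(bundle["f"], bundle["w"], head, bundle["mg_masks"],
                          bundle["r"], TFIRParams(lambda1=1e-3, lambda2=0.05, max_outer=3))
        assert np.isclose(table["rmse_ppm"].iloc[0], rmse(res.chi, chi, brain))

    def test_regularization_wins_under_contamination(self):
        # argmin over lambda2 in {0, 0.1} on a shadow-contaminated phantom
        from qsmtfir import PhantomSpec, make_shadow_phantom

        spec = PhantomSpec(grid=VoxelGrid((32, 32, 32)), seed=9)
        ph = make_shadow_phantom(spec)
        p = TFIRParams(lambda1=1e-3, max_outer=6)
        bundle = prepare_inversion_inputs(
            ph.chi_true, ph.r2star_true, ph.head_mask, p, field=ph.f_contaminated
        )
        bundle["eval_mask"] = ph.brain_mask
        table = grid_search(ph.chi_true, bundle, [0.0, 0.1], [0.05], [1.0], p)
        winner = table.loc[table["is_argmin"], "lambda2"].iloc[0]
        assert winner == 0.1
        # permuting candidate order does not change the winning combination
        table_rev = grid_search(ph.chi_true, bundle, [0.1, 0.0], [0.05], [1.0], p)
        assert table_rev.loc[table_rev["is_argmin"], "lambda2"].iloc[0] == 0.1

    def test_empty_candidate_list_rejected(self, small_brain):
        p = TFIRParams()
        bundle = prepare_inversion_inputs(
            small_brain["chi"], small_brain["r2s"], small_brain["head"], p
        )
        with pytest.raises(VolumeError):
            grid_search(small_brain["chi"], bundle, [], [0.05], [1.0], p)
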