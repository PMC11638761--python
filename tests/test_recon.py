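"""CS-SENSE-LR solver: recovery, monotonicity, lipid projection, B0 handling."""

import numpy as np
import pytest

import eccentric_mrsi as em
from eccentric_mrsi.recon import (ReconConfig, apply_lipid_projection,
                                  b0_correct_adjoint, lipid_projection_update,
                                  reconstruct)
from eccentric_mrsi.trajectories import design_eccentric_2d


def rank_k_scene(n, T, K, sbw=2000.0, seed=1):
    """Smooth rank-K ground truth image series on an n x n grid."""
    xs = np.linspace(-1, 1, n)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    shapes = [np.exp(-(X**2 + Y**2) / 0.3),
              X * np.exp(-(X**2 + Y**2) / 0.5),
              (X**2 - Y**2) * np.exp(-(X**2 + Y**2) / 0.4),
              Y * np.exp(-(X**2 + Y**2) / 0.35)]
    U = np.stack(shapes[:K], axis=-1).reshape(-1, K).astype(complex)
    t = np.arange(T) / sbw
    fs = [60.0, -110.0, 170.0, -240.0]
    ds = [30.0, 25.0, 40.0, 35.0]
    V = np.stack([np.exp((2j * np.pi * fs[k] - ds[k]) * t) for k in range(K)])
    return U, V, (U @ V).reshape(n, n, T)


@pytest.fixture(scope="module")
def small_problem():
    grid = em.GridSpec(16, 0.22)
    plan = design_eccentric_2d(grid, grid.kmax / 2, af=1.0, seed=3,
                               sbw=2000.0, n_time=32)
    U, V, rho = rank_k_scene(16, 32, 2)
    op = em.EncodingOperator(plan, weighting="hamming")
    s = op.forward(rho)
    return grid, plan, op, rho, s


class TestReconstruct:
    def test_zero_data_gives_zero_model(self, small_problem):
        grid, plan, op, rho, s = small_problem
        cfg = ReconConfig(lam=1e-6, K=2, outer_iters=3, v_cg_iters=4,
                          u_fista_iters=4, tgv_inner_iters=10)
        lr, lip, diag = reconstruct(np.zeros_like(s), op, cfg=cfg)
        assert np.max(np.abs(lr.U @ lr.V)) < 1e-12
        assert np.max(np.abs(lip.L)) == 0.0

    def test_noiseless_exact_recovery_small(self, small_problem):
        grid, plan, op, rho, s = small_problem
        cfg = ReconConfig(lam=1e-8, K=2, outer_iters=8, v_cg_iters=8,
                          u_fista_iters=10, tgv_inner_iters=10, tol=1e-9)
        lr, _, diag = reconstruct(s, op, cfg=cfg)
        err = np.abs(lr.rho - rho).max() / np.abs(rho).max()
        assert err < 0.01

    def test_objective_non_increasing(self, small_problem):
        grid, plan, op, rho, s = small_problem
        rng = np.random.default_rng(0)
        noisy = s + 0.01 * np.abs(s).max() * (
            rng.standard_normal(s.shape) + 1j * rng.standard_normal(s.shape))
        cfg = ReconConfig(lam=1e-4, K=2, outer_iters=8, v_cg_iters=5,
                          u_fista_iters=8, tgv_inner_iters=15, tol=0.0)
        _, _, diag = reconstruct(noisy, op, cfg=cfg)
        obj = np.array(diag["objective"])
        assert np.all(obj[2:] <= obj[1:-1] * 1.001)

    def test_output_rank_bounded_by_K(self, small_problem):
        grid, plan, op, rho, s = small_problem
        cfg = ReconConfig(lam=1e-6, K=2, outer_iters=3, v_cg_iters=4,
                          u_fista_iters=4, tgv_inner_iters=10)
        lr, _, _ = reconstruct(s, op, cfg=cfg)
        sv = np.linalg.svd((lr.U @ lr.V), compute_uv=False)
        assert lr.K == 2
        assert sv.size == min(lr.U.shape[0], lr.V.shape[1])
        assert np.sum(sv > sv[0] * 1e-10) <= 2

    def test_v_rows_orthonormal(self, small_problem):
        grid, plan, op, rho, s = small_problem
        cfg = ReconConfig(lam=1e-6, K=2, outer_iters=3, v_cg_iters=4,
                          u_fista_iters=4, tgv_inner_iters=10)
        lr, _, _ = reconstruct(s, op, cfg=cfg)
        gram = lr.V @ lr.V.conj().T
        assert np.allclose(gram, np.eye(2), atol=1e-8)

    def test_seeded_determinism(self, small_problem):
        grid, plan, op, rho, s = small_problem
        cfg = ReconConfig(lam=1e-5, K=2, outer_iters=3, v_cg_iters=4,
                          u_fista_iters=4, tgv_inner_iters=10)
        a, _, _ = reconstruct(s, op, cfg=cfg)
        b, _, _ = reconstruct(s, op, cfg=cfg)
        assert np.array_equal(a.U, b.U) and np.array_equal(a.V, b.V)

    def test_mask_overlap_rejected(self, small_problem):
        grid, plan, op, rho, s = small_problem
        m = np.ones((16, 16), bool)
        with pytest.raises(ValueError):
            reconstruct(s, op, {"brain": m, "lipid": m})


class TestLipid:
    def test_projection_annihilates_subspace_members(self):
        rng = np.random.default_rng(1)
        T, r = 48, 3
        basis_raw = rng.standard_normal((T, r)) + 1j * rng.standard_normal((T, r))
        q, _ = np.linalg.qr(basis_raw)
        inside = (rng.standard_normal((5, r)) + 1j * rng.standard_normal((5, r))) @ q.conj().T
        out = apply_lipid_projection(inside, q)
        assert np.linalg.norm(out) < 1e-8 * np.linalg.norm(inside)

    def test_orthogonal_signals_untouched(self):
        rng = np.random.default_rng(2)
        T = 32
        q, _ = np.linalg.qr(rng.standard_normal((T, 2)) + 0j)
        x = rng.standard_normal((4, T)) + 1j * rng.standard_normal((4, T))
        x_perp = apply_lipid_projection(x, q)  # already the complement
        again = apply_lipid_projection(x_perp, q)
        assert np.allclose(again, x_perp, atol=1e-10)

    def test_projector_idempotent(self):
        rng = np.random.default_rng(3)
        T = 40
        q, _ = np.linalg.qr(rng.standard_normal((T, 4)) + 0j)
        x = rng.standard_normal((6, T)) + 1j * rng.standard_normal((6, T))
        p1 = apply_lipid_projection(x, q, complement=False)
        p2 = apply_lipid_projection(p1, q, complement=False)
        assert np.allclose(p1, p2, atol=1e-10)

    def test_empty_mask_returns_identity_projection(self):
        L = np.zeros((16, 8), complex)
        basis = lipid_projection_update(L, np.zeros(16, bool), 4)
        assert basis is None
        x = np.ones((3, 8), complex)
        assert np.array_equal(apply_lipid_projection(x, basis), x)

    def test_basis_spans_lipid_timecourses(self):
        rng = np.random.default_rng(4)
        T, Nr = 24, 30
        mask = np.zeros(Nr, bool)
        mask[:8] = True
        v1 = np.exp(2j * np.pi * 0.1 * np.arange(T))
        v2 = np.exp((2j * np.pi * 0.02 - 0.05) * np.arange(T))
        L = np.zeros((Nr, T), complex)
        L[:8] = np.outer(rng.standard_normal(8), v1) + np.outer(rng.standard_normal(8), v2)
        basis = lipid_projection_update(L, mask, lipid_rank=2)
        assert basis.shape == (T, 2)
        resid = apply_lipid_projection(L[:8], basis)
        assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(L[:8])

    def test_reconstruction_keeps_lipid_on_its_support(self, small_problem):
        grid, plan, op, rho, s = small_problem
        lipid_mask = np.zeros((16, 16), bool)
        lipid_mask[0:2, :] = True
        brain = np.zeros((16, 16), bool)
        brain[5:12, 5:12] = True
        cfg = ReconConfig(lam=1e-5, K=2, outer_iters=4, v_cg_iters=4,
                          u_fista_iters=5, tgv_inner_iters=10, lipid_rank=3)
        lr, lip, _ = reconstruct(s, op, {"brain": brain, "lipid": lipid_mask},
                                 cfg=cfg)
        L_img = lip.L.reshape(16, 16, -1)
        assert np.all(L_img[~lipid_mask] == 0)
        U_img = lr.U.reshape(16, 16, -1)
        assert np.all(U_img[~brain] == 0)


class TestB0Adjoint:
    def test_zero_field_map_matches_plain_adjoint(self, small_problem):
        grid, plan, op, rho, s = small_problem
        img = b0_correct_adjoint(s, op)
        assert np.allclose(img, op.adjoint_dcf(s), atol=1e-12)

    def test_uniform_offset_restored_to_carrier(self, grid16, basis):
        sbw, T = 512.0, 64
        plan = design_eccentric_2d(grid16, grid16.kmax / 2, seed=5,
                                   sbw=sbw, n_time=T)
        scene = em.build_derenzo(grid16, tube_diameters_mm=(), n_coils=1,
                                 bath_water_amp=1.0)
        scene.coil_maps = np.ones((1, 16, 16), complex)
        scene.b0_map = np.where(scene.tissue_masks > 0, 20.0, 0.0)
        kd = em.forward_encode(scene, basis, plan, water_scale=1.0)
        freqs = np.fft.fftshift(np.fft.fftfreq(T, d=1 / sbw))
        df = sbw / T
        centre = scene.tissue_masks > 0

        def peak_freq(op):
            img = b0_correct_adjoint(kd, op)
            spec = np.abs(np.fft.fftshift(np.fft.fft(img, axis=-1), axes=-1))
            vox = np.unravel_index(np.argmax(centre), centre.shape)
            return freqs[np.argmax(spec[vox])]

        op_plain = em.EncodingOperator(plan, weighting="none")
        op_corr = em.EncodingOperator(plan, b0_map=scene.b0_map, weighting="none")
        assert abs(peak_freq(op_plain) - 20.0) <= df  # shifted without correction
        assert abs(peak_freq(op_corr)) <= df  # restored with correction


class TestModelResultsApi:
    def test_fit_returns_results_with_summary(self, small_problem, grid16):
        grid, plan, op, rho, s = small_problem
        data = em.SpectroKData(values=s, plan=plan)
        cfg = ReconConfig(lam=1e-6, K=2, outer_iters=3, v_cg_iters=4,
                          u_fista_iters=4, tgv_inner_iters=10)
        res = em.CSSenseLR(data, operator=op, config=cfg).fit()
        assert res.rho.shape == (16, 16, 32)
        assert res.U.shape == (256, 2)
        text = res.summary()
        assert "rank K" in text and "objective" in text
        spec = res.spectrum(8, 8)
        assert spec.shape == (32,)
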