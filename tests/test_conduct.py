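import numpy as np
import pytest

from cardiohomog.conduct import (
    ConductivityModel,
    align_to_axes,
    analytic_block_conductivity,
    applied_field,
    blocks_mask,
    build_model,
    conductivity_tensor,
    direction_conductivity,
    homogenized_conductivity,
    mean_current_density,
    solve_potential,
    verify_blocks,
)
from cardiohomog.phantom import PhantomSpec, generate_labels
from cardiohomog.volumes import DIRECTION_AXES, EXTRACELLULAR, MYOCYTE, LabelVolume

from _oracles import dense_homogenized_sigma, random_porous_mask


def _model(mask, **kw):
    return ConductivityModel(conductive=np.asarray(mask, bool), **kw)


class TestBuildModel:
    def test_all_extracellular_is_fully_conductive(self):
        lab = LabelVolume(labels=np.full((4, 4, 4), EXTRACELLULAR))
        assert build_model(lab).conductive.all()

    def test_all_myocyte_rejected(self):
        lab = LabelVolume(labels=np.full((4, 4, 4), MYOCYTE))
        with pytest.raises(ValueError):
            build_model(lab)

    def test_interface_addition_must_lie_in_myocytes(self):
        arr = np.full((4, 4, 4), EXTRACELLULAR)
        arr[0] = MYOCYTE
        lab = LabelVolume(labels=arr)
        bad = np.zeros((4, 4, 4), bool)
        bad[1] = True  # extracellular voxels flagged as addition
        with pytest.raises(ValueError):
            build_model(lab, interface_addition=bad)
        good = np.zeros((4, 4, 4), bool)
        good[0, 0, 0] = True
        model = build_model(lab, interface_addition=good)
        assert model.conductive[0, 0, 0]


class TestSolvePotential:
    def test_uniform_model_gives_linear_potential(self):
        model = _model(np.ones((12, 10, 8)))
        field = solve_potential(model, "l")
        expected = 1.0 - 2.0 * np.arange(10) / 9.0
        assert np.max(np.abs(field.phi - expected[None, :, None])) < 1e-12

    def test_single_column_linear_profile(self):
        mask = np.zeros((5, 5, 9), bool)
        mask[2, 2, :] = True
        field = solve_potential(_model(mask), "n")
        prof = field.phi[2, 2, :]
        assert np.allclose(prof, np.linspace(1, -1, 9), atol=1e-10)

    def test_maximum_principle(self):
        rng = np.random.default_rng(0)
        mask = random_porous_mask((10, 10, 10), rng)
        field = solve_potential(_model(mask), "t")
        vals = field.phi[np.isfinite(field.phi)]
        # slack at the scale of the iterative residual
        assert vals.min() >= -1.0 - 1e-8 and vals.max() <= 1.0 + 1e-8

    def test_non_percolating_flagged_zero(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[:, :3, :] = True  # slab not reaching the far y electrode
        model = _model(mask)
        field = solve_potential(model, "l")
        assert not field.percolating
        assert mean_current_density(field, model) == 0.0


class TestHomogenization:
    def test_uniform_identity_all_directions(self):
        model = _model(np.ones((20, 20, 20)))
        for d in "ltn":
            sigma, _ = direction_conductivity(model, d, rtol=1e-10)
            assert abs(sigma - 2.0) <= 1e-10

    def test_ohms_law_on_uniform_model(self):
        model = _model(np.ones((8, 8, 8)), voxel_size=200.0)
        field = solve_potential(model, "l")
        j = mean_current_density(field, model)
        length = 7 * 200e-9
        assert j == pytest.approx(2.0 * 2.0 / length, rel=1e-12)

    def test_parallel_slab_scales_with_cross_fraction(self):
        mask = np.zeros((8, 10, 8), bool)
        mask[:4, :, :] = True  # half the cross-section spans y
        model = _model(mask)
        sigma, _ = direction_conductivity(model, "l")
        assert sigma == pytest.approx(1.0, abs=1e-12)

    def test_conductivity_independent_of_voxel_size(self):
        rng = np.random.default_rng(5)
        mask = random_porous_mask((8, 8, 8), rng)
        s1, _ = direction_conductivity(_model(mask, voxel_size=200.0), "l")
        s2, _ = direction_conductivity(_model(mask, voxel_size=800.0), "l")
        assert s1 == pytest.approx(s2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_dense_direct_solve(self, seed):
        """Iterative σ equals a dense brute-force solve on small masks."""
        rng = np.random.default_rng(seed)
        mask = random_porous_mask((9, 9, 9), rng, fill=0.55)
        model = _model(mask)
        for d in "ltn":
            oracle = dense_homogenized_sigma(mask, d)
            sigma, _ = direction_conductivity(model, d, rtol=1e-12)
            assert sigma == pytest.approx(oracle, abs=1e-8)

    def test_wiener_bound(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            mask = random_porous_mask((8, 8, 8), rng, fill=0.6)
            model = _model(mask)
            for d in "ltn":
                sigma, _ = direction_conductivity(model, d)
                assert -1e-12 <= sigma <= 2.0 * mask.mean() + 1e-9

    def test_mirror_symmetry_leaves_tensor_unchanged(self):
        rng = np.random.default_rng(3)
        mask = random_porous_mask((8, 8, 8), rng)
        t1 = conductivity_tensor(_model(mask))
        t2 = conductivity_tensor(_model(mask[::-1, :, :]))
        assert t1.sigma_l == pytest.approx(t2.sigma_l, abs=1e-9)
        assert t1.sigma_t == pytest.approx(t2.sigma_t, abs=1e-9)
        assert t1.sigma_n == pytest.approx(t2.sigma_n, abs=1e-9)

    def test_axis_permutation_permutes_components(self):
        rng = np.random.default_rng(4)
        mask = random_porous_mask((8, 8, 8), rng)
        t1 = conductivity_tensor(_model(mask))
        t2 = conductivity_tensor(_model(mask.transpose(1, 0, 2)))
        assert t2.sigma_l == pytest.approx(t1.sigma_t, abs=1e-9)
        assert t2.sigma_t == pytest.approx(t1.sigma_l, abs=1e-9)

    def test_adding_conductive_voxels_never_decreases_sigma(self):
        rng = np.random.default_rng(6)
        small = random_porous_mask((8, 8, 8), rng, fill=0.45)
        grow = small | random_porous_mask((8, 8, 8), rng, fill=0.2)
        t_small = conductivity_tensor(_model(small))
        t_big = conductivity_tensor(_model(grow))
        for d in "ltn":
            assert t_big.sigma(d) >= t_small.sigma(d) - 1e-10

    def test_permutation_symmetric_mask_is_isotropic(self):
        """A mask invariant under axis permutations has equal components."""
        rng = np.random.default_rng(7)
        base = random_porous_mask((10, 10, 10), rng, fill=0.4)
        sym = base.copy()
        for perm in [(0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]:
            sym |= base.transpose(perm)
        t = conductivity_tensor(_model(sym))
        mean = (t.sigma_l + t.sigma_t + t.sigma_n) / 3
        assert abs(t.sigma_l - t.sigma_t) <= 0.05 * mean
        assert abs(t.sigma_t - t.sigma_n) <= 0.05 * mean


class TestBlockVerification:
    def test_half_cross_section_block(self):
        rep = verify_blocks([((0, 10), (0, 24), (0, 20))], (20, 24, 20))
        assert rep["l"]["analytic"] == pytest.approx(1.0)
        assert rep["l"]["abs_error"] <= 1e-8

    def test_two_disjoint_spanning_blocks_add(self):
        blocks = [((0, 4), (0, 30), (0, 10)), ((10, 18), (0, 30), (12, 17))]
        grid = (20, 30, 20)
        analytic = analytic_block_conductivity(blocks, grid)
        assert analytic["l"] == pytest.approx(2.0 * (40 + 40) / 400)
        rep = verify_blocks(blocks, grid)
        assert rep["max_abs_error"] <= 1e-8

    def test_non_spanning_block_contributes_zero(self):
        rep = verify_blocks([((5, 10), (5, 10), (5, 10))], (16, 16, 16))
        for d in "ltn":
            assert rep[d]["analytic"] == 0.0
            assert rep[d]["estimated"] == 0.0

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError):
            blocks_mask([((0, 8), (0, 8), (0, 8)), ((4, 12), (4, 12), (4, 12))],
                        (16, 16, 16))


class TestPhantomTensor:
    def test_clefts_in_plane_make_normal_sigma_smallest(self, small_phantom):
        t = conductivity_tensor(small_phantom, rtol=1e-8)
        assert t.sigma_n < t.sigma_t
        assert t.sigma_n < t.sigma_l

    def test_longitudinal_matches_prismatic_bound(self, small_phantom):
        """All extracellular structures are prismatic along the fiber axis,
        so σ_l equals the Wiener bound exactly."""
        t = conductivity_tensor(small_phantom, rtol=1e-10)
        assert t.sigma_l == pytest.approx(2.0 * t.conductive_fraction,
                                          abs=1e-8)


class TestAlignment:
    def test_aligned_phantom_reports_identity(self, small_phantom):
        out, report = align_to_axes(small_phantom)
        assert not report["rotated"]
        assert report["fiber_deviation_deg"] <= 1.0
        assert out is small_phantom

    def test_rotated_phantom_detected_and_realigned(self, simple_targets):
        spec = PhantomSpec(grid_shape=(96, 96, 120), voxel_size=400.0,
                           target_fractions=simple_targets,
                           rotation_angle=10.0, seed=11)
        lab = generate_labels(spec)
        aligned, report = align_to_axes(lab)
        assert report["rotated"]
        assert report["fiber_deviation_deg"] == pytest.approx(10.0, abs=1.0)
        _, report2 = align_to_axes(aligned)
        assert report2["fiber_deviation_deg"] <= 5.0

    def test_no_myocytes_rejected(self):
        lab = LabelVolume(labels=np.full((6, 6, 6), EXTRACELLULAR))
        with pytest.raises(ValueError):
            align_to_axes(lab)
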