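import numpy as np
import pytest
import scipy.ndimage as ndi

from cardiohomog.metrics import volume_fractions
from cardiohomog.phantom import PhantomSpec, generate_labels, render_channels
from cardiohomog.segment import (
    SegmentationParams,
    classify_fibro_myofibro,
    detect_clefts,
    extracellular_residual,
    mode_sd_threshold,
    refine_interface,
    segment_myocytes,
    segment_vessels,
    segment_volume,
)
from cardiohomog.volumes import CLEFT, EXTRACELLULAR, MYOCYTE

from conftest import jaccard


def _params(**kw):
    defaults = dict(voxel_size=200.0)
    defaults.update(kw)
    return SegmentationParams(**defaults)


class TestMyocyteWatershed:
    def test_two_rods_separated_by_bright_sheet(self):
        wga = np.full((40, 30, 40), 200.0)
        wga[5:15, :, 10:30] = 20.0
        wga[25:35, :, 10:30] = 20.0
        p = _params(min_myocyte_volume=10.0, min_myocyte_half_thickness=0.4,
                    seed_edt_min=0.2)
        inst = segment_myocytes(wga, p)
        assert inst.max() == 2
        assert (inst[5:15, :, 10:30] > 0).all()
        assert (inst[18:22] == 0).all()

    def test_all_high_wga_gives_no_instances(self):
        wga = np.full((10, 10, 10), 200.0)
        with pytest.warns(UserWarning):
            inst = segment_myocytes(wga, _params())
        assert inst.max() == 0

    def test_phantom_rod_count_recovered(self, small_phantom, small_stack):
        truth_inst, n_truth = ndi.label(
            small_phantom.labels == MYOCYTE,
            structure=ndi.generate_binary_structure(3, 1))
        p = _params(voxel_size=400.0, min_myocyte_volume=200.0)
        inst = segment_myocytes(small_stack["WGA"], p)
        assert inst.max() == pytest.approx(n_truth, rel=0.10)


class TestVessels:
    def _tube_fixture(self, radius_um=2.0):
        wga = np.full((60, 100, 60), 200.0)
        x = (np.arange(60) + 0.5) * 0.2
        d2 = (x[:, None] - 6.0) ** 2 + (x[None, :] - 6.0) ** 2
        lumen2d = d2 <= radius_um ** 2
        wga[np.broadcast_to(lumen2d[:, None, :], wga.shape)] = 25.0
        return wga, lumen2d

    def test_dilation_grows_radius(self):
        wga, lumen2d = self._tube_fixture()
        p = _params(vessel_dilation=1.0)
        mask = segment_vessels(wga, np.zeros(wga.shape, bool), p)
        x = (np.arange(60) + 0.5) * 0.2
        d = np.sqrt((x[:, None] - 6.0) ** 2 + (x[None, :] - 6.0) ** 2)
        radius = d[mask[:, 50, :]].max()
        assert radius == pytest.approx(3.0, abs=0.25)  # ± 1 voxel

    def test_zero_dilation_returns_lumen(self):
        wga, lumen2d = self._tube_fixture()
        mask = segment_vessels(wga, np.zeros(wga.shape, bool),
                               _params(vessel_dilation=0.0))
        expected = np.broadcast_to(lumen2d[:, None, :], wga.shape)
        assert np.array_equal(mask, expected)

    def test_no_tubes_gives_empty_mask(self):
        wga = np.full((40, 100, 40), 200.0)
        wga[5:35, :, 5:35] = 20.0  # a fat rod (6 μm half-width), not a capillary
        myo = np.zeros(wga.shape, bool)
        p = _params(capillary_radius=1.0, capillary_scale=1.2)
        assert not segment_vessels(wga, myo, p).any()


class TestCellClassification:
    def _fixture(self, asma_on=False, vessel_near=False):
        shape = (40, 60, 40)
        dapi = np.full(shape, 5.0)
        vim = np.zeros(shape)
        asma = np.zeros(shape)
        xx, yy, zz = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        cell = (((xx - 20) / 10.0) ** 2 + ((yy - 30) / 20.0) ** 2
                + ((zz - 20) / 8.0) ** 2) <= 1.0
        nucleus = ((xx - 20) ** 2 + (yy - 30) ** 2 + (zz - 20) ** 2) <= 36
        vim[cell] = 150.0
        dapi[nucleus] = 180.0
        if asma_on:
            asma[cell] = 130.0
        vessel = np.zeros(shape, bool)
        if vessel_near:
            vessel[:, :, 24:28] = True  # wall within 2 μm of the nucleus
        myo = np.zeros(shape, bool)
        return dapi, vim, asma, myo, vessel

    def test_vimentin_only_cell_is_fibroblast(self):
        dapi, vim, asma, myo, vessel = self._fixture()
        fibro, myofibro = classify_fibro_myofibro(dapi, vim, asma, myo,
                                                  vessel, _params())
        assert fibro.sum() > 0 and myofibro.sum() == 0
        assert fibro[20, 30, 20]

    def test_asma_positive_cell_is_myofibroblast(self):
        dapi, vim, asma, myo, vessel = self._fixture(asma_on=True)
        fibro, myofibro = classify_fibro_myofibro(dapi, vim, asma, myo,
                                                  vessel, _params())
        assert myofibro.sum() > 0 and fibro.sum() == 0

    def test_vessel_proximal_nucleus_is_excluded(self):
        dapi, vim, asma, myo, vessel = self._fixture(vessel_near=True)
        fibro, myofibro = classify_fibro_myofibro(dapi, vim, asma, myo,
                                                  vessel, _params())
        assert fibro.sum() == 0 and myofibro.sum() == 0

    def test_all_flat_dapi_gives_empty_masks(self):
        shape = (10, 10, 10)
        fibro, myofibro = classify_fibro_myofibro(
            np.zeros(shape), np.zeros(shape), np.zeros(shape),
            np.zeros(shape, bool), np.zeros(shape, bool), _params())
        assert not fibro.any() and not myofibro.any()


class TestResidualAndClefts:
    def test_residual_is_exact_complement(self):
        shape = (10, 10, 10)
        myo = np.zeros(shape, bool)
        myo[:8] = True  # 80 %
        empty = np.zeros(shape, bool)
        ecs = extracellular_residual(myo, empty, empty, empty)
        assert ecs.sum() == 200
        assert not (ecs & myo).any()

    def test_empty_masks_give_whole_volume(self):
        empty = np.zeros((5, 5, 5), bool)
        assert extracellular_residual(empty, empty, empty, empty).all()

    def test_overlapping_masks_abort(self):
        m = np.zeros((5, 5, 5), bool)
        m[0] = True
        with pytest.raises(ValueError, match="overlap"):
            extracellular_residual(m, m, np.zeros_like(m), np.zeros_like(m))

    def test_uniform_high_wga_gives_no_clefts(self):
        ecs = np.ones((20, 20, 20), bool)
        wga = np.full((20, 20, 20), 200.0)
        assert not detect_clefts(ecs, wga, _params()).any()

    def test_two_planar_gaps_give_two_components(self):
        shape = (30, 30, 40)
        ecs = np.ones(shape, bool)
        wga = np.full(shape, 200.0)
        wga[:, :, 8:12] = 40.0
        wga[:, :, 28:32] = 40.0
        cleft = detect_clefts(ecs, wga, _params(cleft_rim_margin=0,
                                                cleft_min_volume=10.0))
        _, n = ndi.label(cleft, structure=ndi.generate_binary_structure(3, 1))
        assert n == 2

    def test_raising_threshold_never_shrinks_cleft_mask(self):
        rng = np.random.default_rng(0)
        shape = (20, 20, 30)
        ecs = np.ones(shape, bool)
        wga = 120 + 60 * rng.random(shape)
        wga[:, :, 10:14] = 60.0
        p_lo = _params(cleft_wga_threshold=100.0, cleft_min_volume=1.0)
        p_hi = _params(cleft_wga_threshold=150.0, cleft_min_volume=1.0)
        lo = detect_clefts(ecs, wga, p_lo)
        hi = detect_clefts(ecs, wga, p_hi)
        assert (lo <= hi).all()

    def test_small_speckle_filtered(self):
        shape = (20, 20, 20)
        ecs = np.ones(shape, bool)
        wga = np.full(shape, 200.0)
        wga[10, 10, 10] = 40.0  # a single dark voxel
        assert not detect_clefts(ecs, wga, _params()).any()


class TestInterfaceRefinement:
    def test_mode_plus_sd_threshold_arithmetic(self):
        vals = np.concatenate([np.full(900, 100.0), np.full(50, 60.0),
                               np.full(50, 140.0)])
        rng = np.random.default_rng(1)
        img = rng.permutation(vals).reshape(10, 10, 10)
        thr = mode_sd_threshold(img, k=1.0)
        expected = 100.0 + img.std()
        assert thr == pytest.approx(expected, abs=(140 - 60) / 256 + 1e-9)

    def test_bright_rim_inside_myocytes_recovered(self):
        # myocyte-dominated volume so the WGA mode sits at the interior level
        shape = (40, 20, 20)
        wga = np.full(shape, 200.0)
        myo = np.zeros(shape, bool)
        myo[2:38] = True
        wga[myo] = 20.0
        rim = myo & ~ndi.binary_erosion(myo)
        wga[rim] = 200.0
        addition = refine_interface(myo, wga, k=1.0)
        assert (addition & rim).sum() >= 0.9 * rim.sum()
        assert not (addition & ~myo).any()

    def test_subthreshold_interior_gives_empty_addition(self):
        shape = (10, 10, 10)
        wga = np.full(shape, 200.0)
        myo = np.zeros(shape, bool)
        myo[:5] = True
        wga[myo] = 10.0
        with pytest.warns(UserWarning):
            addition = refine_interface(myo, wga, k=5.0)
        assert not addition.any()


class TestRoundTrip:
    def test_noiseless_phantom_domains_recovered(self, small_phantom,
                                                 small_stack):
        """On a blur-free rendered phantom the segmentation recovers the
        generator's domains; at this coarse 400 nm voxel size the cleft
        slab is only a few voxels thick, so the voxel-limited boundary
        layer caps its Jaccard near 0.8 (the 200 nm check lives in the
        acceptance suite)."""
        p = SegmentationParams(voxel_size=400.0, min_myocyte_volume=200.0)
        seg = segment_volume(small_stack, p)
        truth = small_phantom.labels
        for code in (MYOCYTE, EXTRACELLULAR):
            assert jaccard(truth == code, seg.labels == code) >= 0.9, code
        assert jaccard(truth == CLEFT, seg.labels == CLEFT) >= 0.8
        vt = volume_fractions(small_phantom).as_dict()
        vs = volume_fractions(seg).as_dict()
        for key in vt:
            assert abs(vt[key] - vs[key]) <= 2.0, key
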