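"""Spin-echo synthesis: closed-form limits, monotonicity, linearity, geometry."""

import numpy as np
import pytest

from contrastsweep.relaxometry import (AcquisitionParams, QuantitativeMaps,
                                       quantize_12bit, synthesize_image,
                                       synthesize_ir_image)

from conftest import random_maps


class TestSignalEquation:
    @pytest.mark.parametrize("tr,te,expected", [
        (1e9, 0.0, 1.0),                 # full recovery, no decay
        (1e9, 100.0, np.exp(-1.0)),      # TE equals T2
        (1000.0, 0.0, -np.expm1(-1.0)),  # TR equals T1
    ])
    def test_single_voxel_limits(self, single_voxel_maps, tr, te, expected):
        maps = single_voxel_maps(t1=1000.0, t2=100.0, pd=1.0)
        s = synthesize_image(maps, AcquisitionParams(tr=tr, te=te), gain=1.0)
        assert s.shape == (1, 1, 1)
        assert s[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_long_tr_zero_te_recovers_pd(self):
        rng = np.random.default_rng(3)
        maps = random_maps(rng)
        tr = 50.0 * maps.t1_map.max()
        s = synthesize_image(maps, AcquisitionParams(tr=tr, te=0.0))
        np.testing.assert_allclose(s, maps.pd_map, rtol=1e-8)

    def test_background_voxels_stay_zero(self):
        t1 = np.array([[[1000.0, 0.0]]])
        t2 = np.array([[[100.0, 0.0]]])
        pd = np.array([[[1.0, 0.0]]])
        maps = QuantitativeMaps(t1_map=t1, t2_map=t2, pd_map=pd,
                                spacing=(1, 1, 1))
        s = synthesize_image(maps, AcquisitionParams(tr=500.0, te=20.0))
        assert s[0, 0, 1] == 0.0
        assert s[0, 0, 0] > 0.0

    def test_monotone_in_te_and_tr(self):
        rng = np.random.default_rng(11)
        maps = random_maps(rng)
        for _ in range(20):
            tr = rng.uniform(300.0, 5000.0)
            te1, te2 = sorted(rng.uniform(0.0, 250.0, size=2))
            s1 = synthesize_image(maps, AcquisitionParams(tr=tr, te=te1))
            s2 = synthesize_image(maps, AcquisitionParams(tr=tr, te=te2))
            assert (s2 <= s1 + 1e-15).all()  # non-increasing in TE
            te = rng.uniform(0.0, 250.0)
            tr1, tr2 = sorted(rng.uniform(300.0, 5000.0, size=2))
            s1 = synthesize_image(maps, AcquisitionParams(tr=tr1, te=te))
            s2 = synthesize_image(maps, AcquisitionParams(tr=tr2, te=te))
            assert (s2 >= s1 - 1e-15).all()  # non-decreasing in TR

    def test_linear_in_gain_and_pd(self):
        rng = np.random.default_rng(5)
        maps = random_maps(rng)
        params = AcquisitionParams(tr=1500.0, te=80.0)
        s = synthesize_image(maps, params, gain=1.0)
        np.testing.assert_array_equal(synthesize_image(maps, params, gain=2.0),
                                      2.0 * s)
        doubled = QuantitativeMaps(t1_map=maps.t1_map, t2_map=maps.t2_map,
                                   pd_map=2.0 * maps.pd_map,
                                   spacing=maps.spacing)
        np.testing.assert_array_equal(synthesize_image(doubled, params), 2.0 * s)

    def test_b1_is_multiplicative(self):
        rng = np.random.default_rng(9)
        maps = random_maps(rng)
        b1 = rng.uniform(0.8, 1.2, size=maps.shape)
        biased = QuantitativeMaps(t1_map=maps.t1_map, t2_map=maps.t2_map,
                                  pd_map=maps.pd_map, spacing=maps.spacing,
                                  b1_field=b1)
        params = AcquisitionParams(tr=2000.0, te=60.0)
        np.testing.assert_allclose(synthesize_image(biased, params),
                                   b1 * synthesize_image(maps, params))

    def test_output_geometry_matches_maps(self, test_phantom):
        spec, maps, _ = test_phantom
        s = synthesize_image(maps, AcquisitionParams(tr=1535.0, te=212.0))
        assert s.shape == maps.shape
        assert maps.spacing == spec.spacing


class TestInversionRecovery:
    def test_null_point(self, single_voxel_maps):
        maps = single_voxel_maps(t1=1000.0)
        ti = 1000.0 * np.log(2.0)
        s = synthesize_ir_image(maps, AcquisitionParams(tr=1e9, te=0.0, ti=ti))
        assert s[0, 0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_long_ti_long_tr_approaches_spin_echo(self, single_voxel_maps):
        maps = single_voxel_maps()
        tr = 1e9
        se = synthesize_image(maps, AcquisitionParams(tr=tr, te=50.0))
        ir = synthesize_ir_image(maps,
                                 AcquisitionParams(tr=tr, te=50.0, ti=tr / 2))
        np.testing.assert_allclose(ir, se, rtol=1e-6)

    def test_scalar_arithmetic_oracle(self, single_voxel_maps):
        # direct evaluation of the IR magnitude formula for one voxel
        t1, t2, pd, ti, tr, te = 1000.0, 100.0, 2.0, 200.0, 4000.0, 50.0
        expected = abs(
            pd * (1 - 2 * np.exp(-ti / t1) + np.exp(-tr / t1))
            * np.exp(-te / t2))
        maps = single_voxel_maps(t1=t1, t2=t2, pd=pd)
        s = synthesize_ir_image(maps, AcquisitionParams(tr=tr, te=te, ti=ti))
        assert s[0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_requires_ti(self, single_voxel_maps):
        with pytest.raises(ValueError, match="TI"):
            synthesize_ir_image(single_voxel_maps(),
                                AcquisitionParams(tr=1000.0, te=10.0))


class TestValidation:
    def test_te_not_smaller_than_tr_rejected(self, single_voxel_maps):
        with pytest.raises(ValueError, match="TE"):
            synthesize_image(single_voxel_maps(),
                             AcquisitionParams(tr=100.0, te=100.0))

    def test_shape_mismatch_names_offender(self):
        with pytest.raises(ValueError, match="t2_map"):
            QuantitativeMaps(t1_map=np.ones((2, 2, 2)),
                             t2_map=np.ones((2, 2, 3)),
                             pd_map=np.ones((2, 2, 2)), spacing=(1, 1, 1))

    def test_t2_above_t1_warns_not_raises(self):
        with pytest.warns(UserWarning, match="T2 > T1"):
            QuantitativeMaps(t1_map=np.full((1, 1, 1), 100.0),
                             t2_map=np.full((1, 1, 1), 200.0),
                             pd_map=np.ones((1, 1, 1)), spacing=(1, 1, 1))

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            QuantitativeMaps(t1_map=np.ones((2, 2)), t2_map=np.ones((2, 2)),
                             pd_map=np.ones((2, 2)), spacing=(1.0, 0.0))


def test_quantize_12bit_spans_range():
    rng = np.random.default_rng(2)
    vol = rng.random((4, 4, 2))
    q = quantize_12bit(vol)
    assert q.dtype == np.uint16
    assert q.min() == 0 and q.max() == 4095
    assert quantize_12bit(np.ones((3, 3))).max() == 0  # constant image
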