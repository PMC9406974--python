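import dataclasses

import numpy as np
import pytest

from strokeperf.deconv import ScalingConstants
from strokeperf.errors import GeometryError, ParameterError
from strokeperf.kinetics import GammaVariateParams, gamma_variate_curve
from strokeperf.phantom import (
    Ellipsoid,
    PhantomSpec,
    make_adc_phantom,
    make_phantom,
    synthesize_tissue_curve,
    truth_volumes_ml,
)

TIMES = np.arange(40) * 1.5
AIF_PARAMS = GammaVariateParams(amplitude=10.0, t0=8.0, alpha=3.0, beta=1.5)


class TestGammaVariate:
    def test_zero_before_arrival(self):
        t = np.array([AIF_PARAMS.t0 - 1.0, AIF_PARAMS.t0])
        assert np.all(gamma_variate_curve(AIF_PARAMS, t) == 0)

    def test_argmax_at_closed_form_mode(self):
        t = np.linspace(0, 40, 4001)
        curve = gamma_variate_curve(AIF_PARAMS, t)
        mode = t[np.argmax(curve)]
        expected = AIF_PARAMS.t0 + AIF_PARAMS.alpha * AIF_PARAMS.beta
        assert abs(mode - expected) <= t[1] - t[0]

    def test_linear_in_amplitude(self):
        doubled = dataclasses.replace(AIF_PARAMS, amplitude=2 * AIF_PARAMS.amplitude)
        np.testing.assert_allclose(
            gamma_variate_curve(doubled, TIMES),
            2 * gamma_variate_curve(AIF_PARAMS, TIMES),
        )

    def test_nonnegative_everywhere(self):
        assert np.all(gamma_variate_curve(AIF_PARAMS, np.linspace(-10, 100, 500)) >= 0)

    @pytest.mark.parametrize("field,value", [("alpha", -1.0), ("beta", 0.0), ("amplitude", 0.0)])
    def test_bad_params_rejected(self, field, value):
        with pytest.raises(ParameterError):
            dataclasses.replace(AIF_PARAMS, **{field: value})

    def test_decreasing_times_rejected(self):
        with pytest.raises(ParameterError):
            gamma_variate_curve(AIF_PARAMS, np.array([1.0, 0.5]))


class TestSynthesizeTissueCurve:
    def setup_method(self):
        self.ca = gamma_variate_curve(AIF_PARAMS, TIMES)
        self.constants = ScalingConstants()

    def test_zero_flow_zero_curve(self):
        ct = synthesize_tissue_curve(self.ca, 0.0, 4.0, 0.0, 1.5, self.constants)
        assert np.all(ct == 0)

    @pytest.mark.parametrize("cbf,mtt", [(60.0, 4.0), (20.0, 8.0), (80.0, 3.0), (10.0, 12.0)])
    def test_central_volume_identity(self, cbf, mtt):
        # independent oracle: rectangle-rule area ratio must equal
        # (rho/(100 k_av)) * (1-h_lv)/(1-h_sv) * CBV_true, CBV_true = CBF*MTT/60
        # long acquisition so the convolution tail is not truncated
        times = np.arange(80) * 1.5
        ca = gamma_variate_curve(AIF_PARAMS, times)
        c = self.constants
        ct = synthesize_tissue_curve(ca, cbf, mtt, 0.0, 1.5, c)
        ratio = (ct.sum() * 1.5) / (ca.sum() * 1.5)
        expected = (
            (c.rho / (100.0 * c.k_av))
            * ((1 - c.h_lv) / (1 - c.h_sv))
            * cbf * mtt / 60.0
        )
        assert ratio == pytest.approx(expected, rel=0.02)

    def test_delay_is_frame_shift(self):
        ct0 = synthesize_tissue_curve(self.ca, 60.0, 4.0, 0.0, 1.5, self.constants)
        ct3 = synthesize_tissue_curve(self.ca, 60.0, 4.0, 3.0, 1.5, self.constants)
        shift = round(3.0 / 1.5)
        np.testing.assert_allclose(ct3[shift:], ct0[:-shift], atol=1e-12)
        assert np.all(ct3[:shift] == 0)

    def test_linearity_in_cbf(self):
        ct1 = synthesize_tissue_curve(self.ca, 30.0, 4.0, 0.0, 1.5, self.constants)
        ct2 = synthesize_tissue_curve(self.ca, 60.0, 4.0, 0.0, 1.5, self.constants)
        np.testing.assert_allclose(ct2, 2 * ct1, rtol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            synthesize_tissue_curve(self.ca, -1.0, 4.0, 0.0, 1.5)
        with pytest.raises(ParameterError):
            synthesize_tissue_curve(self.ca, 60.0, 0.0, 0.0, 1.5)
        with pytest.raises(ParameterError):
            synthesize_tissue_curve(self.ca, 60.0, 4.0, -1.0, 1.5)


class TestMakePhantom:
    def test_seeded_determinism(self):
        spec = PhantomSpec(grid_shape=(20, 20, 6), noise_sd=0.5, seed=42,
                           core_region=Ellipsoid((10, 8, 3), (9, 9, 6)),
                           penumbra_region=Ellipsoid((10, 9, 3), (16, 16, 8)))
        a = make_phantom(spec)
        b = make_phantom(spec)
        assert a.series.data.tobytes() == b.series.data.tobytes()
        assert a.truth_adc.tobytes() == b.truth_adc.tobytes()

    def test_noiseless_core_voxel_matches_synthesis(self, phantom_ds, default_spec):
        from strokeperf.kinetics import gamma_variate_curve

        times = default_spec.frame_times
        ca = gamma_variate_curve(default_spec.aif, times)
        expected = synthesize_tissue_curve(
            ca, default_spec.cbf_core, default_spec.tissue_mtt_normal,
            default_spec.delay_penumbra, default_spec.dt, default_spec.constants,
        )
        voxel = np.argwhere(phantom_ds.truth_core_mask)[0]
        curve = phantom_ds.series.data[tuple(voxel)] - default_spec.baseline
        np.testing.assert_allclose(curve, expected, atol=1e-12)

    def test_truth_core_volume_matches_enumeration_oracle(self, phantom_ds, default_spec):
        # brute force: count voxel centers inside the ellipsoid with python loops
        center = default_spec.core_region.center
        semi = default_spec.core_region.semi_axes_mm
        vs = default_spec.voxel_size
        count = 0
        nx, ny, nz = default_spec.grid_shape
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    q = sum(
                        ((i - c) * v / a) ** 2
                        for i, c, v, a in zip((x, y, z), center, vs, semi)
                    )
                    if q <= 1.0:
                        count += 1
        expected_ml = count * np.prod(vs) / 1000.0
        assert truth_volumes_ml(phantom_ds)["core_ml"] == pytest.approx(expected_ml)

    def test_core_subset_of_penumbra(self, phantom_ds):
        assert not np.any(phantom_ds.truth_core_mask & ~phantom_ds.truth_penumbra_mask)

    def test_masks_inside_brain(self, phantom_ds):
        assert not np.any(phantom_ds.truth_penumbra_mask & ~phantom_ds.brain_mask)

    def test_doubling_cbf_doubles_tissue_curves(self, default_spec):
        spec2 = dataclasses.replace(
            default_spec,
            tissue_cbf_normal=2 * default_spec.tissue_cbf_normal,
            cbf_core=2 * default_spec.cbf_core,
        )
        a = make_phantom(default_spec)
        b = make_phantom(spec2)
        normal = a.brain_mask & ~a.truth_penumbra_mask
        voxel = tuple(np.argwhere(normal)[0])
        base = default_spec.baseline
        np.testing.assert_allclose(
            b.series.data[voxel] - base, 2 * (a.series.data[voxel] - base), rtol=1e-10
        )

    def test_lesion_outside_grid_rejected(self):
        spec = PhantomSpec(core_region=Ellipsoid((2.0, 2.0, 2.0), (50.0, 50.0, 50.0)))
        with pytest.raises(GeometryError):
            make_phantom(spec)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ParameterError):
            PhantomSpec(cbf_core=80.0)  # not below normal
        with pytest.raises(ParameterError):
            PhantomSpec(adc_core=700e-6)  # not below the core limit
        with pytest.raises(ParameterError):
            PhantomSpec(noise_sd=-1.0)


class TestAdcPhantom:
    def test_core_below_threshold_everywhere(self, phantom_ds):
        adc = phantom_ds.truth_adc
        assert np.all(adc[phantom_ds.truth_core_mask] < 620e-6)

    def test_noncore_brain_at_or_above_threshold(self, phantom_ds):
        adc = phantom_ds.truth_adc
        viable = phantom_ds.brain_mask & ~phantom_ds.truth_core_mask
        assert np.all(adc[viable] >= 620e-6)

    def test_segmentation_round_trip(self, phantom_ds, default_spec):
        from strokeperf.lesion import segment_core_adc

        core = segment_core_adc(
            phantom_ds.truth_adc, phantom_ds.brain_mask,
            voxel_size=default_spec.voxel_size,
        )
        np.testing.assert_array_equal(core, phantom_ds.truth_core_mask)

    def test_standalone_matches_dataset(self, default_spec, phantom_ds):
        np.testing.assert_array_equal(make_adc_phantom(default_spec), phantom_ds.truth_adc)
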