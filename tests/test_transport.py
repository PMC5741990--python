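"""Monte Carlo photon transport: physics checks against diffusion theory
and the statistical contract of the DTOF-level recording simulator."""

import numpy as np
import pytest
from scipy import stats

from trfnirs.diffusion import annulus_tof_moments, td_reflectance
from trfnirs.paradigm import BlockDesign, build_timeline
from trfnirs.transport import (
    SPEED_OF_LIGHT_CM_PS,
    DetectionGeometry,
    DTOFSimConfig,
    OpticalLayerStack,
    TransportError,
    dtof_expected_counts,
    run_transport,
    simulate_dtof_recording,
    weighted_tof_moments,
)

MUA, MUSP, NREFR = 0.17, 10.0, 1.4


class TestStack:
    def test_boundaries_include_substrate(self, head_stack):
        b = head_stack.boundaries_cm
        assert b.size == head_stack.n_layers + 2
        assert b[0] == 0.0 and b[-2] == pytest.approx(2.0)

    def test_invalid_properties_rejected(self):
        with pytest.raises(ValueError):
            OpticalLayerStack(mua=(0.0,) * 10)
        with pytest.raises(ValueError):
            OpticalLayerStack(mua=(0.1,) * 9)  # length mismatch with defaults


class TestAgainstDiffusion:
    def test_mean_tof_matches_closed_form(self, homogeneous_bank_1e6, geometry):
        _, m, _ = weighted_tof_moments(homogeneous_bank_1e6)
        dm, _ = annulus_tof_moments(MUA, MUSP, NREFR, geometry.rho_range_cm,
                                    geometry.t_max_ps)
        assert m == pytest.approx(dm, rel=0.05)

    def test_global_absorption_derivative_matches_closed_form(
            self, homogeneous_bank_1e6, geometry, deep_homogeneous_stack):
        d = 0.005
        mua = np.asarray(deep_homogeneous_stack.mua)
        _, mp, _ = weighted_tof_moments(homogeneous_bank_1e6, mua + d)
        _, mm, _ = weighted_tof_moments(homogeneous_bank_1e6, mua - d)
        mc = (mp - mm) / (2 * d)
        _, var = annulus_tof_moments(MUA, MUSP, NREFR, geometry.rho_range_cm,
                                     geometry.t_max_ps)
        analytic = -(SPEED_OF_LIGHT_CM_PS / NREFR) * var
        assert mc == pytest.approx(analytic, rel=0.05)

    def test_derivative_equals_minus_v_times_variance(self, homogeneous_bank_1e6,
                                                      deep_homogeneous_stack):
        # internal consistency: total path = v t, so d<t>/dmua = -v Var(t)
        d = 0.001
        mua = np.asarray(deep_homogeneous_stack.mua)
        _, mp, _ = weighted_tof_moments(homogeneous_bank_1e6, mua + d)
        _, mm, _ = weighted_tof_moments(homogeneous_bank_1e6, mua - d)
        _, _, var = weighted_tof_moments(homogeneous_bank_1e6)
        v = SPEED_OF_LIGHT_CM_PS / NREFR
        assert (mp - mm) / (2 * d) == pytest.approx(-v * var, rel=0.01)

    def test_reflectance_formula_normalizes(self):
        # sanity on the closed form itself: finite, positive, single peak
        t = np.linspace(1, 12000, 5000)
        r = td_reflectance(t, 3.0, MUA, MUSP, NREFR)
        assert np.all(r >= 0) and np.isfinite(r).all()
        peak = t[r.argmax()]
        assert 200 < peak < 2000


class TestTransportBasics:
    def test_seeded_runs_identical(self, head_stack, geometry):
        a = run_transport(head_stack, geometry, 50_000, seed=3)
        b = run_transport(head_stack, geometry, 50_000, seed=3)
        np.testing.assert_array_equal(a.tof_ps, b.tof_ps)
        np.testing.assert_array_equal(a.path_cm, b.path_cm)

    def test_tof_consistent_with_total_path(self, head_banks):
        bank = head_banks[760.0]
        v = SPEED_OF_LIGHT_CM_PS / NREFR
        np.testing.assert_allclose(bank.path_cm.sum(axis=1) / v, bank.tof_ps,
                                   rtol=1e-9)

    def test_no_detection_raises(self, head_stack):
        geo = DetectionGeometry(source_detector_cm=40.0,
                                annulus_halfwidth_cm=0.01)
        with pytest.raises(TransportError):
            run_transport(head_stack, geo, 2_000, seed=0)

    def test_brain_absorption_increase_shortens_mean_tof(self, head_banks):
        bank = head_banks[830.0]
        mua = np.asarray(bank.stack.mua)
        bumped = mua.copy()
        bumped[4:] += 0.01  # intracerebral layers
        _, m0, _ = weighted_tof_moments(bank, mua)
        _, m1, _ = weighted_tof_moments(bank, bumped)
        assert m1 < m0


@pytest.fixture(scope="module")
def short_timeline():
    return build_timeline(BlockDesign(6, 1, 6, 6, 0.3))


class TestRecordingSimulator:
    def test_null_course_gives_stationary_expected_dtof(self, head_banks):
        bank = head_banks[760.0]
        a = dtof_expected_counts(bank)
        b = dtof_expected_counts(bank, np.asarray(bank.stack.mua))
        np.testing.assert_array_equal(a, b)

    def test_frame_totals_poisson(self, head_stack, geometry, head_banks,
                                  short_timeline):
        lam = 5000.0
        cfg = DTOFSimConfig(stack=head_stack, geometry=geometry,
                            photons_per_frame=lam, seed=17)
        frames = simulate_dtof_recording(cfg, short_timeline, channels=("ch1",),
                                         banks=head_banks)
        totals = np.concatenate([arr.sum(axis=1) for arr in frames.values()])
        # index of dispersion test: Var/mean ~ 1 for Poisson
        disp = totals.var(ddof=1) / totals.mean()
        n = totals.size
        lo, hi = stats.chi2.ppf([0.005, 0.995], n - 1) / (n - 1)
        assert lo < disp < hi
        assert totals.mean() == pytest.approx(lam, rel=0.05)

    def test_mismatched_course_rejected(self, head_stack, geometry,
                                        short_timeline, head_banks):
        cfg = DTOFSimConfig(stack=head_stack, geometry=geometry,
                            chromophore_timecourse=np.zeros((5, 2)))
        with pytest.raises(TransportError):
            simulate_dtof_recording(cfg, short_timeline, banks=head_banks)

    def test_seeded_recording_reproducible(self, head_stack, geometry,
                                           short_timeline, head_banks):
        cfg = DTOFSimConfig(stack=head_stack, geometry=geometry,
                            photons_per_frame=2000, seed=23)
        a = simulate_dtof_recording(cfg, short_timeline, channels=("ch1",),
                                    banks=head_banks)
        b = simulate_dtof_recording(cfg, short_timeline, channels=("ch1",),
                                    banks=head_banks)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
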