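import numpy as np
import pytest

from petquant.core import (
    FrameSchedule,
    TimeActivityCurve,
    UNIT_KBQ_ML,
    ValidationError,
    VoxelMask,
    DynamicImage,
)
from petquant.kinetics import (
    PlasmaInput,
    expconv_uniform,
    fine_grid,
    fur,
    logan_plasma,
    logan_ref,
    patlak_plasma,
    patlak_ref,
    srtm_basis_fit,
    srtm_fit,
    suvr,
    tcm2_fit,
    weights_from_frames,
)
from petquant.synthdata import (
    forward_1tcm,
    forward_2tcm,
    forward_srtm,
)

from conftest import TRUE_SRTM


def tac_like(other, value):
    return TimeActivityCurve(t_mid=other.t_mid, value=value, unit=other.unit,
                             frame_dur=other.frame_dur)


@pytest.fixture(scope="module")
def srtm_curves(schedule90, plasma90, cr_dense):
    cr = forward_1tcm(plasma90, 0.4, 0.1, schedule90)
    ct = forward_srtm(cr_dense, TRUE_SRTM["R1"], TRUE_SRTM["k2"],
                      TRUE_SRTM["BP_ND"], schedule90)
    return ct, cr


class TestExpconv:
    def test_against_quadrature_oracle(self):
        """expconv must agree with direct numerical evaluation of the
        convolution integral for a known input."""
        from scipy.integrate import quad

        dt = 0.001
        t = np.arange(0, 5, dt)
        c = t * np.exp(-t)  # smooth input, c(0)=0
        theta = 0.7
        y = expconv_uniform(c, dt, theta)
        for T in (1.0, 2.5, 4.9):
            ref, _ = quad(lambda s, T=T: s * np.exp(-s) * np.exp(-theta * (T - s)),
                          0, T, limit=200)
            i = int(round(T / dt))
            assert y[i] == pytest.approx(ref, rel=1e-6)

    def test_theta_zero_is_running_integral(self):
        dt = 0.01
        t = np.arange(0, 3, dt)
        y = expconv_uniform(np.ones_like(t), dt, 0.0)
        assert y[-1] == pytest.approx(t[-1], rel=1e-10)


class TestSrtmFit:
    def test_identity_tissue(self, srtm_curves):
        _, cr = srtm_curves
        fit = srtm_fit(cr, cr)
        assert abs(fit.params["BP_ND"]) < 1e-6
        assert fit.params["R1"] == pytest.approx(1.0, abs=1e-4)

    def test_noiseless_roundtrip(self, srtm_curves):
        ct, cr = srtm_curves
        fit = srtm_fit(ct, cr)
        for name, true in TRUE_SRTM.items():
            assert fit.params[name] == pytest.approx(true, rel=0.005), name

    def test_bp_equals_dvr_minus_one(self, srtm_curves):
        ct, cr = srtm_curves
        fit = srtm_fit(ct, cr)
        assert fit.params["BP_ND"] == pytest.approx(fit.params["DVR"] - 1.0, abs=1e-12)

    def test_joint_rescaling_invariance(self, srtm_curves):
        ct, cr = srtm_curves
        f1 = srtm_fit(ct, cr)
        f2 = srtm_fit(tac_like(ct, 3.7 * ct.value), tac_like(cr, 3.7 * cr.value))
        for name in ("R1", "k2", "BP_ND"):
            assert f2.params[name] == pytest.approx(f1.params[name], rel=1e-4)

    def test_noisy_monte_carlo(self, srtm_curves, schedule90):
        """5% Gaussian noise, 100 replicates: mean BP_ND within 3% of truth."""
        ct, cr = srtm_curves
        rng = np.random.default_rng(2024)
        bps = []
        for _ in range(100):
            noisy = ct.value + rng.normal(0, 0.05 * ct.value.max(), ct.n_frames)
            fit = srtm_fit(tac_like(ct, noisy), cr, n_starts=1, dt_sec=1.0)
            bps.append(fit.params["BP_ND"])
        assert np.mean(bps) == pytest.approx(TRUE_SRTM["BP_ND"], rel=0.03)

    def test_too_few_frames(self):
        t = np.arange(1.0, 6.0)
        tac = TimeActivityCurve(t, np.ones(5), UNIT_KBQ_ML, np.ones(5))
        with pytest.raises(ValidationError, match="6 frames"):
            srtm_fit(tac, tac)

    def test_mismatched_grids(self, srtm_curves):
        ct, cr = srtm_curves
        shifted = TimeActivityCurve(cr.t_mid + 0.5, cr.value, cr.unit, cr.frame_dur)
        with pytest.raises(ValidationError, match="frame grid"):
            srtm_fit(ct, shifted)


class TestSrtmBasisFit:
    def _single_voxel_image(self, ct, schedule):
        vox = np.zeros((1, 1, 1, ct.n_frames))
        vox[0, 0, 0] = ct.value
        img = DynamicImage(vox, np.eye(4), schedule)
        mask = VoxelMask(np.ones((1, 1, 1), bool), np.eye(4))
        return img, mask

    def test_phantom_region_median(self, phantom30, srtm_curves):
        from conftest import region_mask
        from petquant.core import extract_tac

        labels = phantom30["labels"]
        ref_tac = extract_tac(phantom30["image"], region_mask(labels, 8))
        m17 = region_mask(labels, 17)
        maps = srtm_basis_fit(phantom30["image"], ref_tac, m17)
        med = np.nanmedian(maps.maps["BP_ND"][m17.voxels])
        assert med == pytest.approx(TRUE_SRTM["BP_ND"], rel=0.01)

    def test_null_region(self, phantom30):
        from conftest import region_mask
        from petquant.core import extract_tac

        labels = phantom30["labels"]
        ref_tac = extract_tac(phantom30["image"], region_mask(labels, 8))
        m18 = region_mask(labels, 18)
        maps = srtm_basis_fit(phantom30["image"], ref_tac, m18)
        assert np.nanmedian(np.abs(maps.maps["BP_ND"][m18.voxels])) < 0.01

    def test_exact_basis_point(self, srtm_curves, schedule90):
        """Basis of one point at the true k2a: recovery to linear-algebra
        precision (the only remaining error is frame binning)."""
        ct, cr = srtm_curves
        true_k2a = TRUE_SRTM["k2"] / (1 + TRUE_SRTM["BP_ND"])
        img, mask = self._single_voxel_image(ct, schedule90)
        maps = srtm_basis_fit(img, cr, mask, basis=np.array([true_k2a]))
        assert maps.maps["BP_ND"][0, 0, 0] == pytest.approx(TRUE_SRTM["BP_ND"],
                                                            rel=5e-3)

    def test_matches_regional_fit_dense_basis(self, srtm_curves, schedule90):
        ct, cr = srtm_curves
        regional = srtm_fit(ct, cr)
        img, mask = self._single_voxel_image(ct, schedule90)
        dense = np.geomspace(0.006, 0.6, 512)
        maps = srtm_basis_fit(img, cr, mask, basis=dense)
        assert maps.maps["BP_ND"][0, 0, 0] == pytest.approx(
            regional.params["BP_ND"], rel=0.01)
        assert maps.maps["R1"][0, 0, 0] == pytest.approx(regional.params["R1"],
                                                         rel=0.01)

    def test_nan_voxel_counted(self, srtm_curves, schedule90):
        ct, cr = srtm_curves
        vox = np.zeros((2, 1, 1, ct.n_frames))
        vox[0, 0, 0] = ct.value
        vox[1, 0, 0] = np.nan
        img = DynamicImage(vox, np.eye(4), schedule90)
        mask = VoxelMask(np.ones((2, 1, 1), bool), np.eye(4))
        maps = srtm_basis_fit(img, cr, mask)
        assert maps.n_failed == 1
        assert np.isnan(maps.maps["BP_ND"][1, 0, 0])


class TestLoganRef:
    def test_identity(self, srtm_curves):
        _, cr = srtm_curves
        fit = logan_ref(cr, cr, t_star=30)
        assert fit.params["DVR"] == pytest.approx(1.0, abs=1e-9)
        assert fit.params["BP_ND"] == pytest.approx(0.0, abs=1e-9)

    def test_forward_srtm_recovery(self, srtm_curves):
        ct, cr = srtm_curves
        k2prime = TRUE_SRTM["k2"] / TRUE_SRTM["R1"]  # reference efflux
        fit = logan_ref(ct, cr, t_star=30, k2prime=k2prime)
        assert fit.params["BP_ND"] == pytest.approx(TRUE_SRTM["BP_ND"], rel=0.02)

    def test_scaling_invariance(self, srtm_curves):
        ct, cr = srtm_curves
        f1 = logan_ref(ct, cr, 30)
        f2 = logan_ref(tac_like(ct, 2.5 * ct.value), tac_like(cr, 2.5 * cr.value), 30)
        assert f2.params["DVR"] == pytest.approx(f1.params["DVR"], rel=1e-12)

    def test_slope_matches_independent_regression(self, srtm_curves):
        """Regression oracle: recompute Logan coordinates independently and
        fit with np.polyfit; slopes must agree to 1e-10."""
        ct, cr = srtm_curves
        fit = logan_ref(ct, cr, t_star=30)
        t = np.concatenate(([0.0], ct.t_mid))
        int_ct = np.array([np.trapezoid(np.concatenate(([0.0], ct.value))[:i + 2],
                                        t[:i + 2]) for i in range(ct.n_frames)])
        int_cr = np.array([np.trapezoid(np.concatenate(([0.0], cr.value))[:i + 2],
                                        t[:i + 2]) for i in range(cr.n_frames)])
        keep = ct.t_mid >= 30
        slope = np.polyfit((int_cr / ct.value)[keep], (int_ct / ct.value)[keep], 1)[0]
        assert fit.params["DVR"] == pytest.approx(slope, abs=1e-10)

    def test_too_few_late_points(self, srtm_curves):
        ct, cr = srtm_curves
        with pytest.raises(ValidationError, match=">= 3"):
            logan_ref(ct, cr, t_star=90)


class TestLoganPlasma:
    @pytest.mark.parametrize("K1,VT", [(0.1, 1.0), (0.3, 3.0)])
    def test_1tcm_vt_oracle(self, plasma90, schedule90, K1, VT):
        ct = forward_1tcm(plasma90, K1, 0.1, schedule90)
        fit = logan_plasma(ct, plasma90, t_star=40)
        assert fit.params["V_T"] == pytest.approx(VT, rel=0.02)

    def test_joint_scaling_invariance(self, plasma90, schedule90):
        ct = forward_1tcm(plasma90, 0.2, 0.1, schedule90)
        f1 = logan_plasma(ct, plasma90, 40)
        scaled = PlasmaInput(plasma90.t, 2.0 * plasma90.cp)
        f2 = logan_plasma(tac_like(ct, 2.0 * ct.value), scaled, 40)
        assert f2.params["V_T"] == pytest.approx(f1.params["V_T"], rel=1e-12)

    def test_slope_matches_independent_regression(self, plasma90, schedule90):
        ct = forward_1tcm(plasma90, 0.15, 0.1, schedule90)
        fit = logan_plasma(ct, plasma90, 40)
        from scipy.integrate import cumulative_trapezoid

        F = cumulative_trapezoid(plasma90.cp, plasma90.t, initial=0.0)
        int_cp = np.interp(ct.t_mid, plasma90.t, F)
        t = np.concatenate(([0.0], ct.t_mid))
        int_ct = np.array([np.trapezoid(np.concatenate(([0.0], ct.value))[:i + 2],
                                        t[:i + 2]) for i in range(ct.n_frames)])
        keep = ct.t_mid >= 40
        slope = np.polyfit((int_cp / ct.value)[keep], (int_ct / ct.value)[keep], 1)[0]
        assert fit.params["V_T"] == pytest.approx(slope, abs=1e-10)


class TestPatlak:
    def test_irreversible_ki_oracle(self, plasma90, schedule90):
        # K_i = K1*k3/(k2+k3) = 0.1*0.05/0.2 = 0.025 for k4 = 0
        ct = forward_2tcm(plasma90, 0.1, 0.15, 0.05, 0.0, schedule90)
        fit = patlak_plasma(ct, plasma90, t_star=30)
        assert fit.params["K_i"] == pytest.approx(0.025, rel=0.02)

    def test_no_trapping(self, plasma90, schedule90):
        ct = forward_2tcm(plasma90, 0.1, 0.15, 0.0, 0.0, schedule90)
        fit = patlak_plasma(ct, plasma90, t_star=30)
        assert abs(fit.params["K_i"]) < 1e-3

    def test_joint_scaling_invariance(self, plasma90, schedule90):
        ct = forward_2tcm(plasma90, 0.1, 0.15, 0.05, 0.0, schedule90)
        f1 = patlak_plasma(ct, plasma90, 30)
        f2 = patlak_plasma(tac_like(ct, 4.0 * ct.value),
                           PlasmaInput(plasma90.t, 4.0 * plasma90.cp), 30)
        assert f2.params["K_i"] == pytest.approx(f1.params["K_i"], rel=1e-12)

    def test_ref_identity(self, srtm_curves):
        _, cr = srtm_curves
        fit = patlak_ref(cr, cr, t_star=30)
        assert abs(fit.params["K_i"]) < 1e-9
        assert fit.params["intercept"] == pytest.approx(1.0, abs=1e-9)

    def test_ref_irreversible_slope_matches_regression(self, plasma90, schedule90):
        cr = forward_1tcm(plasma90, 0.4, 0.1, schedule90)
        ct = forward_2tcm(plasma90, 0.1, 0.15, 0.05, 0.0, schedule90)
        fit = patlak_ref(ct, cr, t_star=30)
        t = np.concatenate(([0.0], cr.t_mid))
        int_cr = np.array([np.trapezoid(np.concatenate(([0.0], cr.value))[:i + 2],
                                        t[:i + 2]) for i in range(cr.n_frames)])
        keep = ct.t_mid >= 30
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.polyfit((int_cr / cr.value)[keep],
                               (ct.value / cr.value)[keep], 1)[0]
        assert fit.params["K_i"] > 0
        assert fit.params["K_i"] == pytest.approx(slope, abs=1e-10)

    def test_ref_too_few_late_points(self, srtm_curves):
        ct, cr = srtm_curves
        with pytest.raises(ValidationError, match=">= 3"):
            patlak_ref(ct, cr, t_star=92)


class TestSuvr:
    def test_identity(self, srtm_curves):
        _, cr = srtm_curves
        assert suvr(cr, cr, [60, 90]).params["SUVR"] == 1.0

    def test_linearity(self, srtm_curves):
        _, cr = srtm_curves
        fit = suvr(tac_like(cr, 2.0 * cr.value), cr, [60, 90])
        assert fit.params["SUVR"] == pytest.approx(2.0, rel=1e-12)

    def test_zero_reference_error(self, srtm_curves):
        _, cr = srtm_curves
        with pytest.raises(ValidationError, match="zero"):
            suvr(cr, tac_like(cr, np.zeros(cr.n_frames)), [60, 90])


class TestFur:
    def test_constant_closed_form(self):
        """Constant tissue c, plasma p from (just after) 0: the trapezoidal
        plasma integral is p*(T - eps/2), exact to 1e-10."""
        c, p, eps = 5.0, 2.0, 1e-6
        t = np.concatenate(([0.0, eps], np.linspace(1, 60, 60)))
        plasma = PlasmaInput(t, np.concatenate(([0.0], np.full(61, p))))
        T = np.array([30.0, 45.0, 60.0])
        ct = TimeActivityCurve(T, np.full(3, c), UNIT_KBQ_ML, np.full(3, 5.0))
        fit = fur(ct, plasma)
        expected = c / (p * (T - eps / 2))
        assert np.allclose(fit.fitted.value, expected, rtol=1e-10)
        assert fit.params["FUR"] == pytest.approx(float(expected.mean()), rel=1e-10)

    def test_asymptotic_ki(self):
        """FUR approaches the Patlak K_i at large T (3-hour schedule)."""
        from petquant.synthdata import InputModelParams, plasma_curve

        durs = [15.0] * 4 + [30.0] * 4 + [60.0] * 3 + [120.0] * 3 + [240.0] * 3 \
            + [300.0] * 32
        ends = np.cumsum(durs)
        sch = FrameSchedule(ends - np.asarray(durs), ends)
        plasma = plasma_curve(InputModelParams(), fine_grid(sch.end_min[-1]))
        ct = forward_2tcm(plasma, 0.1, 0.15, 0.05, 0.0, sch)
        ki = patlak_plasma(ct, plasma, 30).params["K_i"]
        late = TimeActivityCurve(ct.t_mid[-4:], ct.value[-4:], ct.unit,
                                 ct.frame_dur[-4:])
        fit = fur(late, plasma)
        assert fit.params["FUR"] == pytest.approx(ki, rel=0.10)

    def test_doubling_plasma_halves_fur(self):
        t = np.linspace(0, 60, 61)
        cp = np.where(t > 0, 2.0, 0.0)
        plasma = PlasmaInput(t, cp)
        ct = TimeActivityCurve([40.0, 50.0, 58.0], [5.0, 5.0, 5.0], UNIT_KBQ_ML,
                               [5.0, 5.0, 5.0])
        f1 = fur(ct, plasma)
        f2 = fur(ct, PlasmaInput(t, 2 * cp))
        assert f2.params["FUR"] == pytest.approx(f1.params["FUR"] / 2, rel=1e-12)

    def test_plasma_not_covering_error(self):
        t = np.linspace(0, 30, 31)
        plasma = PlasmaInput(t, np.where(t > 0, 1.0, 0.0))
        ct = TimeActivityCurve([40.0, 50.0, 60.0], [1.0, 1.0, 1.0], UNIT_KBQ_ML,
                               [5.0, 5.0, 5.0])
        with pytest.raises(ValidationError, match="ends at"):
            fur(ct, plasma)


class TestTcm2:
    TRUE = {"K1": 0.1, "k2": 0.12, "k3": 0.07, "k4": 0.04}

    def test_noiseless_roundtrip(self, plasma90, schedule90):
        ct = forward_2tcm(plasma90, *self.TRUE.values(), schedule90)
        fit = tcm2_fit(ct, plasma90,
                       weights=weights_from_frames(schedule90, scheme="duration"))
        for name, true in self.TRUE.items():
            assert fit.params[name] == pytest.approx(true, rel=0.02), name
        vt_true = (0.1 / 0.12) * (1 + 0.07 / 0.04)
        assert fit.params["V_T"] == pytest.approx(vt_true, rel=0.01)

    def test_nested_1tcm_limit(self, plasma90, schedule90):
        ct = forward_2tcm(plasma90, 0.1, 0.12, 0.0, 0.0, schedule90)
        fit = tcm2_fit(ct, plasma90, n_starts=5)
        assert fit.params["k3"] < 1e-3
        assert fit.params["K1"] == pytest.approx(0.1, rel=0.02)

    def test_negative_plasma_error(self, schedule90, plasma90):
        t = np.linspace(0, 90, 91)
        with pytest.raises(ValidationError):
            PlasmaInput(t, np.where(t > 0, -1.0, 0.0))

    def test_blood_required_for_vb(self, plasma90, schedule90):
        ct = forward_2tcm(plasma90, 0.1, 0.12, 0.05, 0.03, schedule90)
        with pytest.raises(ValidationError, match="whole-blood"):
            tcm2_fit(ct, plasma90, vB_mode="fit")

    def test_irreversible_flag(self, plasma90, schedule90):
        ct = forward_2tcm(plasma90, 0.1, 0.15, 0.05, 0.0, schedule90)
        fit = tcm2_fit(ct, plasma90, n_starts=3)
        assert fit.diagnostics["irreversible"]
        assert "V_T" not in fit.params


class TestWeights:
    def test_uniform(self, schedule90):
        w = weights_from_frames(schedule90, scheme="uniform")
        assert np.allclose(w, 1.0)

    def test_duration_equal_frames(self):
        sch = FrameSchedule([0, 60, 120], [60, 120, 180])
        assert np.allclose(weights_from_frames(sch, scheme="duration"), 1.0)

    def test_duration_proportional(self):
        sch = FrameSchedule([0, 60, 180], [60, 180, 360])
        w = weights_from_frames(sch, scheme="duration")
        assert np.allclose(w, np.array([1, 2, 3]) / 2.0)
        assert w.sum() == pytest.approx(3.0)

    def test_duration_over_activity_zero_frame_warns(self):
        sch = FrameSchedule([0, 60], [60, 120])
        tac = TimeActivityCurve([0.5, 1.5], [0.0, 2.0], UNIT_KBQ_ML, [1.0, 1.0])
        with pytest.warns(UserWarning, match="zero-activity"):
            w = weights_from_frames(sch, tac, scheme="duration_over_activity")
        assert np.all(w > 0)

    def test_unknown_scheme(self, schedule90):
        with pytest.raises(ValidationError):
            weights_from_frames(schedule90, scheme="bogus")
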