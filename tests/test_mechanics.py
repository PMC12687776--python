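"""Bend-curve analysis: preprocessing, beam transforms, stiffness window,
offset yield, landmarks and the summary integrals."""

import numpy as np
import pytest

from bonescore.cohort import generate_bend_curve
from bonescore.errors import UnusableCurveError
from bonescore.mechanics import (
    ForceDisplacementCurve,
    StressStrainCurve,
    analyze_curve,
    find_ultimate_failure,
    find_yield,
    fit_stiffness,
    modulus_gpa,
    preprocess_curve,
    to_stress_strain,
    strain_per_displacement,
    stress_per_force,
    summarize_mechanics,
)

GEOM = dict(span_mm=6.0, c_mm=1.0, i_mm4=0.7363)


def _linear_curve(stiffness=100.0, n=200, d_max_um=400.0, f0=0.2):
    d = np.linspace(0.0, d_max_um, n)
    return ForceDisplacementCurve(d, f0 + stiffness * d / 1000.0, **GEOM)


class TestPreprocess:
    def test_curve_starting_at_preload_unchanged(self):
        c = _linear_curve()
        p = preprocess_curve(c)
        assert p.displacement_um[0] == 0.0
        assert np.array_equal(p.force_n, c.force_n)

    def test_toe_samples_removed_and_rezeroed(self):
        toe_d = np.linspace(0, 45, 10)
        toe_f = np.linspace(0.02, 0.18, 10)
        body_d = np.linspace(50, 400, 50)
        body_f = 0.2 + (body_d - 50) * 0.1
        c = ForceDisplacementCurve(np.concatenate([toe_d, body_d]),
                                   np.concatenate([toe_f, body_f]), **GEOM)
        p = preprocess_curve(c)
        # the 10 toe samples are gone; zero sits at the 0.2 N crossing
        assert len(p) == 50
        assert p.displacement_um[0] == 0.0 and p.force_n[0] == 0.2

    def test_interpolated_crossing_position(self):
        """Crossing between samples at 0.15 N and 0.25 N lands at the linear 0.2 N point."""
        c = ForceDisplacementCurve([0.0, 10.0, 20.0], [0.15, 0.25, 0.35], **GEOM)
        p = preprocess_curve(c)
        # 0.2 N is halfway between 0.15 and 0.25 -> crossing at 5 um
        assert p.displacement_um[0] == 0.0
        assert p.displacement_um[1] == pytest.approx(5.0)

    def test_never_reaching_preload_rejected(self):
        c = ForceDisplacementCurve([0.0, 1.0, 2.0], [0.01, 0.05, 0.1], **GEOM)
        with pytest.raises(UnusableCurveError):
            preprocess_curve(c)


class TestStressStrain:
    def test_stress_closed_form(self):
        """F = 10 N, L = 6 mm, c = 1 mm, I = 0.7363 mm^4 -> sigma ~ 20.37 MPa."""
        c = ForceDisplacementCurve([0.0, 1.0], [10.0, 10.001], **GEOM)
        ss = to_stress_strain(c)
        assert ss.stress_mpa[0] == pytest.approx(10 * 6 * 1 / (4 * 0.7363), abs=1e-9)
        assert ss.stress_mpa[0] == pytest.approx(20.37, abs=0.01)

    def test_strain_closed_form(self):
        """d = 0.1 mm, c = 1 mm, L = 6 mm -> 16,667 microstrain."""
        c = ForceDisplacementCurve([0.0, 100.0], [1.0, 2.0], **GEOM)
        ss = to_stress_strain(c)
        assert ss.strain_ue[1] == pytest.approx(1e6 * 6 * 1 * 0.1 / 36, rel=1e-9)
        assert ss.strain_ue[1] == pytest.approx(16666.7, abs=0.1)

    def test_doubling_i_halves_stress_only(self):
        c1 = ForceDisplacementCurve([0.0, 50.0], [1.0, 5.0], **GEOM)
        c2 = ForceDisplacementCurve([0.0, 50.0], [1.0, 5.0], span_mm=6.0, c_mm=1.0,
                                    i_mm4=2 * 0.7363)
        s1, s2 = to_stress_strain(c1), to_stress_strain(c2)
        assert np.allclose(s2.stress_mpa, s1.stress_mpa / 2)
        assert np.allclose(s2.strain_ue, s1.strain_ue)


class TestStiffness:
    def test_exactly_linear_curve(self):
        fit = fit_stiffness(_linear_curve(stiffness=100.0))
        assert fit.stiffness_n_mm == pytest.approx(100.0, abs=1e-9)
        assert not fit.low_linearity

    def test_modulus_closed_form(self):
        """E = k L^3 / 48 I: 100 N/mm, L=6, I=0.7363 -> 0.6112 GPa."""
        assert modulus_gpa(100.0, 6.0, 0.7363) == pytest.approx(0.6112, abs=1e-4)

    def test_bilinear_window_stays_in_first_segment(self):
        """Best window avoids the kink; slope = first-segment slope (oracle check)."""
        curve, _ = generate_bend_curve(stiffness=120.0, yield_force=12.0,
                                       postyield_slope=20.0,
                                       failure_displacement=150.0, step_um=2.0)
        pre = preprocess_curve(curve)
        land = find_ultimate_failure(pre)
        fit = fit_stiffness(pre, ultimate_index=land.ultimate_index)
        assert fit.stiffness_n_mm == pytest.approx(120.0, abs=1e-9)
        kink_idx = np.searchsorted(pre.displacement_um, (12.0 - 0.2) / 120.0 * 1000)
        assert fit.window[1] <= kink_idx

    def test_brute_force_window_oracle(self, rng):
        """The selected window R^2 is the max over an exhaustive enumeration."""
        d = np.linspace(0, 300, 60)
        f = 0.2 + 0.08 * d + rng.normal(0, 0.05, 60)
        f = np.maximum.accumulate(f)  # keep monotone-ish
        c = ForceDisplacementCurve(d, f, **GEOM)
        fit = fit_stiffness(c)
        i_ult = int(np.argmax(f))
        f_ult = f[i_ult]
        qual = np.nonzero((f[:i_ult + 1] >= 0.1 * f_ult) & (f[:i_ult + 1] <= 0.9 * f_ult))[0]
        lo, hi = qual[0], qual[-1]
        min_len = max(2, int(np.ceil(0.15 * (i_ult + 1))))
        best = -np.inf
        for s in range(lo, hi + 1):
            for e in range(s + min_len - 1, hi + 1):
                x, y = d[s:e + 1] / 1000.0, f[s:e + 1]
                r = np.corrcoef(x, y)[0, 1] ** 2
                best = max(best, r)
        assert fit.r_squared == pytest.approx(best, abs=1e-9)

    def test_too_few_preultimate_samples_rejected(self):
        c = ForceDisplacementCurve(np.linspace(0, 10, 10),
                                   0.2 + np.linspace(0, 5, 10), **GEOM)
        with pytest.raises(UnusableCurveError, match="need >= 20"):
            fit_stiffness(c)


class TestYield:
    def test_bilinear_offset_intersection(self):
        """E = 1000 MPa then plateau at 50 MPa: yield at 52,000 microstrain."""
        eps = np.linspace(0.0, 120000.0, 1201)
        sig = np.minimum(1000.0 * eps * 1e-6, 50.0)
        yp = find_yield(StressStrainCurve(eps, sig), elastic_slope_mpa=1000.0)
        assert not yp.no_yield
        e_y = eps[yp.index_before] + yp.frac * (eps[yp.index_before + 1] - eps[yp.index_before])
        s_y = sig[yp.index_before] + yp.frac * (sig[yp.index_before + 1] - sig[yp.index_before])
        assert e_y == pytest.approx(52000.0, rel=1e-9)
        assert s_y == pytest.approx(50.0, rel=1e-9)

    def test_linear_curve_never_yields(self):
        eps = np.linspace(0.0, 50000.0, 500)
        sig = 1000.0 * eps * 1e-6
        yp = find_yield(StressStrainCurve(eps, sig), 1000.0, ultimate_index=499)
        assert yp.no_yield and yp.index_before == 499

    def test_grid_refinement_invariance(self):
        """Refining the sample grid moves the yield point by < 0.1%."""
        results = []
        for step in (4.0, 1.0):
            curve, _ = generate_bend_curve(stiffness=100.0, yield_force=15.0,
                                           postyield_slope=10.0,
                                           failure_displacement=250.0, step_um=step)
            s = analyze_curve(curve)
            results.append((s.yield_force_n, s.strain_to_yield_ue))
        assert results[0][0] == pytest.approx(results[1][0], rel=1e-3)
        assert results[0][1] == pytest.approx(results[1][1], rel=1e-3)


class TestLandmarks:
    def test_cliff_failure_detected(self):
        d = np.linspace(0, 100, 50)
        f = np.concatenate([np.linspace(0.2, 10, 45), [0.3, 0.2, 0.2, 0.1, 0.1]])
        land = find_ultimate_failure(ForceDisplacementCurve(d, f, **GEOM))
        assert land.ultimate_index == 44
        assert land.failure_index == 45
        assert not land.no_failure

    def test_monotone_curve_flagged_no_failure(self):
        c = _linear_curve()
        land = find_ultimate_failure(c)
        assert land.no_failure and land.failure_index == len(c) - 1

    def test_tied_maxima_take_first(self):
        d = np.linspace(0, 100, 40)
        f = np.concatenate([np.linspace(0.2, 10, 20), np.full(20, 10.0)])
        land = find_ultimate_failure(ForceDisplacementCurve(d, f, **GEOM))
        assert land.ultimate_index == 19


class TestSummary:
    def test_triangle_work(self):
        """Linear ramp to 10 N at 0.5 mm: total work = 2.5 mJ."""
        curve, _ = generate_bend_curve(stiffness=100.0, yield_force=80.0,
                                       postyield_slope=0.0, failure_displacement=900.0,
                                       step_um=2.0, preload_n=0.2)
        # analyze only the elastic ramp portion: build explicit linear curve
        d = np.linspace(0.0, 500.0, 100)
        f = d / 50.0
        c = ForceDisplacementCurve(d, f, **GEOM)
        s = analyze_curve(c)
        # preload trimming removes the 0-0.2 N toe (area 0.5*0.2*0.01 = 0.001 mJ)
        assert s.total_work_mj == pytest.approx(0.5 * (0.2 + 10.0) * 0.49, rel=1e-9)
        assert s.no_yield and s.no_failure

    @pytest.mark.parametrize("postyield_slope,failure_um", [(0.0, 700.0), (15.0, 250.0)])
    def test_noiseless_recovery_machine_precision(self, postyield_slope, failure_um):
        """End-to-end: noiseless bilinear curves reproduce generator truth."""
        curve, truth = generate_bend_curve(stiffness=110.0, yield_force=14.0,
                                           postyield_slope=postyield_slope,
                                           failure_displacement=failure_um, step_um=2.0)
        s = analyze_curve(curve)
        for key in ("stiffness_n_mm", "yield_force_n", "ultimate_force_n",
                    "displacement_to_yield_um", "postyield_displacement_um",
                    "total_displacement_um", "work_to_yield_mj", "postyield_work_mj",
                    "total_work_mj", "modulus_gpa", "yield_stress_mpa",
                    "ultimate_stress_mpa", "strain_to_yield_ue", "total_strain_ue",
                    "resilience_mpa", "toughness_mpa"):
            assert getattr(s, key) == pytest.approx(truth[key], rel=1e-9), key
        assert not s.no_failure and not s.no_yield

    def test_work_and_displacement_additivity(self):
        curve, _ = generate_bend_curve(stiffness=90.0, yield_force=12.0,
                                       postyield_slope=5.0, failure_displacement=220.0,
                                       noise_sd=0.05, seed=3, step_um=2.0)
        s = analyze_curve(curve)
        assert s.work_to_yield_mj + s.postyield_work_mj == pytest.approx(s.total_work_mj, abs=1e-9)
        assert (s.displacement_to_yield_um + s.postyield_displacement_um
                == pytest.approx(s.total_displacement_um, abs=1e-6))
        assert s.ultimate_force_n >= s.yield_force_n - 1e-12

    def test_toe_region_does_not_bias_recovery(self):
        curve, truth = generate_bend_curve(stiffness=110.0, yield_force=14.0,
                                           postyield_slope=10.0, toe_displacement=60.0,
                                           failure_displacement=250.0, step_um=2.0)
        s = analyze_curve(curve)
        assert s.stiffness_n_mm == pytest.approx(truth["stiffness_n_mm"], rel=1e-9)
        assert s.yield_force_n == pytest.approx(truth["yield_force_n"], rel=1e-9)

    def test_noisy_yield_force_unbiased(self):
        """50 seeded noisy curves: mean recovered yield within 2 SEM of truth."""
        errs = []
        for seed in range(50):
            curve, truth = generate_bend_curve(stiffness=110.0, yield_force=14.0,
                                               postyield_slope=10.0, noise_sd=0.05,
                                               failure_displacement=250.0,
                                               seed=seed, step_um=2.0)
            s = analyze_curve(curve)
            errs.append(s.yield_force_n - truth["yield_force_n"])
        errs = np.array(errs)
        sem = errs.std(ddof=1) / np.sqrt(len(errs))
        assert abs(errs.mean()) < 2 * max(sem, 1e-6)
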