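"""Closed-form mean-field theory against generic numerical oracles."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from homeoplast.params import MFParams, TripletParams, ConfigurationError
from homeoplast import meanfield as mf

VARIANTS = ["metaplastic_ltd", "weight_decay", "synaptic_scaling"]


@pytest.fixture(scope="module")
def params() -> MFParams:
    return MFParams()  # F0=0.3 Hz, F1=5, tau_w ~ 2975 s, eta=6.25, kappa=3


def _params_for(params: MFParams, variant: str) -> MFParams:
    if variant == "weight_decay":
        return params.replace(decay_rate=1.0 / 36000.0)
    return params


class TestStaticResponse:
    def test_rate_without_recurrence_is_the_offset(self, params):
        assert mf.steady_rate(0.0, params) == params.F0

    def test_response_pole_raises(self, params):
        with pytest.raises(ConfigurationError):
            mf.steady_rate(1.0 / params.F1, params)


class TestPoissonDrift:
    def test_zero_crossing_at_the_target_rate(self, triplet_unit):
        r = mf.bcm_fixed_point_rate(triplet_unit)
        assert r == pytest.approx(triplet_unit.kappa, abs=1e-9)

    def test_bcm_shape_with_clamped_estimate(self, triplet_unit):
        k = triplet_unit.kappa
        assert mf.poisson_drift(2.0, 2.0, k, triplet_unit) < 0
        assert mf.poisson_drift(5.0, 5.0, k, triplet_unit) > 0

    def test_effective_tau_w_reproduces_the_drift(self, triplet_unit):
        # the rate rule with tau_w must equal the closed-form expectation
        p = triplet_unit
        tau_w = mf.effective_tau_w(p)
        assert tau_w > 0
        for r, rb in [(2.0, 3.0), (3.0, 3.0), (5.0, 2.0)]:
            gamma = p.kappa * (rb / p.kappa) ** 2
            rate_rule = p.eta * p.w0 / (tau_w * p.kappa ** 3) * r * r * (r - gamma)
            assert rate_rule == pytest.approx(
                mf.poisson_drift(r, r, rb, p), rel=1e-12)


class TestVectorField:
    def test_background_and_quiescent_fixed_points(self, params):
        dr, drb = mf.vector_field(mf.MFState(3.0, 3.0), params, "metaplastic_ltd")
        assert dr == 0.0 and drb == 0.0
        dr0, _ = mf.vector_field(mf.MFState(0.0, 1.0), params, "metaplastic_ltd")
        assert dr0 == 0.0

    def test_matches_finite_differences_of_a_trajectory(self, params):
        sol = solve_ivp(lambda t, y: mf.vector_field(mf.MFState(*y), params,
                                                     "metaplastic_ltd"),
                        (0, 50.0), [4.0, 2.0], rtol=1e-10, atol=1e-12,
                        dense_output=True)
        h = 1e-4
        for t in [5.0, 20.0, 40.0]:
            num = (sol.sol(t + h) - sol.sol(t - h)) / (2 * h)
            ana = mf.vector_field(mf.MFState(*sol.sol(t)), params,
                                  "metaplastic_ltd")
            assert np.allclose(num, ana, rtol=1e-5)

    def test_unknown_variant_rejected(self, params):
        with pytest.raises(ConfigurationError):
            mf.vector_field(mf.MFState(1.0, 1.0), params, "nope")


class TestJacobian:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_closed_form_matches_finite_differences(self, params, variant):
        p = _params_for(params, variant)
        J = mf.jacobian_at_fixed_point(p, variant)
        fp = mf.fixed_point(p, variant)
        eps = 1e-6
        Jn = np.zeros((2, 2))
        for j in range(2):
            up = list(fp); up[j] += eps
            dn = list(fp); dn[j] -= eps
            fu = mf.vector_field(mf.MFState(*up), p, variant)
            fd = mf.vector_field(mf.MFState(*dn), p, variant)
            Jn[:, j] = (np.array(fu) - np.array(fd)) / (2 * eps)
        assert np.abs(J - Jn).max() < 1e-8

    def test_zero_decay_reduces_to_the_metaplastic_jacobian(self, params):
        J0 = mf.jacobian_at_fixed_point(params, "metaplastic_ltd")
        J1 = mf.jacobian_at_fixed_point(params.replace(decay_rate=0.0),
                                        "weight_decay")
        assert np.array_equal(J0, J1)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_trace_equals_eigenvalue_sum(self, params, variant):
        p = _params_for(params, variant)
        J = mf.jacobian_at_fixed_point(p, variant)
        lam = mf.eigenvalues(p, variant)
        assert (lam[0] + lam[1]).real == pytest.approx(J[0, 0] + J[1, 1],
                                                       rel=1e-12)
        assert abs((lam[0] + lam[1]).imag) < 1e-12


class TestEigenvalues:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_closed_form_agrees_with_numeric_eigensolver(self, params, variant):
        p = _params_for(params, variant)
        lam = np.sort_complex(np.asarray(mf.eigenvalues(p, variant)))
        num = np.sort_complex(np.linalg.eigvals(
            mf.jacobian_at_fixed_point(p, variant)))
        assert np.allclose(lam, num, rtol=1e-10, atol=1e-14)

    def test_marginal_at_the_critical_timescale(self, params):
        tc = mf.critical_tau(params, "metaplastic_ltd")
        lam = mf.eigenvalues(params.replace(tau_bar=tc), "metaplastic_ltd")
        assert abs(max(l.real for l in lam)) < 1e-10
        assert max(abs(l.imag) for l in lam) > 0  # oscillatory crossing
        lam = mf.eigenvalues(params.replace(tau_bar=1.01 * tc), "metaplastic_ltd")
        assert max(l.real for l in lam) > 0

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_stable_iff_detector_faster_than_critical(self, params, variant):
        p = _params_for(params, variant)
        tc = mf.critical_tau(p, variant)
        for f, expect in [(0.5, True), (1.5, False)]:
            rep = mf.stability_report(p.replace(tau_bar=f * tc), variant)
            assert rep.stable is expect


class TestCriticalTau:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_bisection_on_eigenvalues_reproduces_closed_form(self, params,
                                                             variant):
        p = _params_for(params, variant)

        def max_re(tb):
            return max(l.real for l in
                       mf.eigenvalues(p.replace(tau_bar=tb), variant))

        tc = brentq(max_re, 1.0, 5000.0, xtol=1e-12, rtol=1e-15)
        assert tc == pytest.approx(mf.critical_tau(p, variant), rel=1e-6)

    def test_independent_of_the_ltd_exponent(self, params):
        vals = [mf.critical_tau(params.replace(beta=b), "metaplastic_ltd")
                for b in (1.0, 2.0, 3.0)]
        assert vals[0] == vals[1] == vals[2]

    def test_slow_decay_shifts_the_critical_timescale_slightly_up(self, params):
        tc0 = mf.critical_tau(params, "metaplastic_ltd")
        tc1 = mf.critical_tau(params.replace(decay_rate=1 / 36000.0),
                              "weight_decay")
        assert tc0 < tc1 < 1.2 * tc0

    def test_fourth_power_dependence_on_the_background_rate(self, triplet_unit):
        base = MFParams()
        kappas = np.array([1.5, 3.0, 6.0, 12.0])
        tcs = [mf.critical_tau(
            base.replace(kappa=k, tau_w=mf.effective_tau_w(triplet_unit, k)),
            "metaplastic_ltd") for k in kappas]
        slope = np.polyfit(np.log(kappas), np.log(tcs), 1)[0]
        assert slope == pytest.approx(-4.0, abs=1e-10)


class TestSynapticScalingStability:
    def test_too_slow_scaling_destabilizes_despite_fast_detector(self, params):
        tc = mf.critical_tau(params, "synaptic_scaling")
        bound = mf.max_stable_tau_scaling(params)
        slow = params.replace(tau_bar=0.5 * tc, tau_scaling=2.0 * bound)
        assert not mf.stability_report(slow, "synaptic_scaling").stable

    def test_fast_scaling_oscillates_but_stays_stable(self, params):
        tc = mf.critical_tau(params, "synaptic_scaling")
        fast = params.replace(tau_bar=0.5 * tc, tau_scaling=5.0)
        rep = mf.stability_report(fast, "synaptic_scaling")
        assert rep.stable
        assert max(abs(l.imag) for l in rep.eigenvalues) > 0

    def test_necessary_condition_matches_the_metaplastic_one(self, params):
        assert mf.critical_tau(params, "synaptic_scaling") == \
            pytest.approx(mf.critical_tau(params, "metaplastic_ltd"), rel=1e-12)


class TestPhasePlane:
    def test_nullcline_intersections_coincide_with_fixed_points(self, params):
        for variant in ["metaplastic_ltd", "weight_decay"]:
            p = _params_for(params, variant)
            fp = mf.fixed_point(p, variant)
            nc = mf.nullclines(p, variant, np.array([fp[0]]))
            assert nc["r_nullcline_rbar"][0] == pytest.approx(fp[1], abs=1e-8)

    def test_fates_inside_and_outside_the_basin(self, params):
        p = params.replace(tau_bar=10.0)
        assert mf.classify_fate(p, "metaplastic_ltd", (3.2, 3.0),
                                t_max=3000.0) == "converged"
        assert mf.classify_fate(p, "metaplastic_ltd", (12.0, 3.0),
                                t_max=3000.0) == "diverged"

    def test_basin_shrinks_as_the_detector_slows(self, params):
        tc = mf.critical_tau(params, "metaplastic_ltd")

        def basin_radius(tau_bar):
            p = params.replace(tau_bar=tau_bar)
            lo, hi = 0.0, 6.0 * params.kappa
            for _ in range(18):
                mid = 0.5 * (lo + hi)
                fate = mf.classify_fate(p, "metaplastic_ltd",
                                        (params.kappa + mid, params.kappa),
                                        t_max=3000.0, conv_tol=1e-2)
                if fate == "converged":
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)

        radii = [basin_radius(f * tc) for f in (0.2, 0.5, 0.9)]
        assert radii[0] > radii[1] > radii[2] > 0

    def test_separatrix_points_classify_correctly(self, params):
        p = params.replace(tau_bar=20.0)
        pts = mf.separatrix(p, "metaplastic_ltd", n_rays=6, tol=5e-3,
                            t_max=2000.0)
        fp = np.array(mf.fixed_point(p, "metaplastic_ltd"))
        finite = pts[np.all(np.isfinite(pts), axis=1)]
        assert finite.shape[0] >= 3
        for q in finite:
            inner = fp + 0.9 * (q - fp)
            assert mf.classify_fate(p, "metaplastic_ltd", tuple(inner),
                                    t_max=3000.0, conv_tol=1e-2) == "converged"

    def test_phase_portrait_bundles_trajectories_and_nullclines(self, params):
        p = params.replace(tau_bar=10.0)
        pp = mf.phase_portrait(p, "metaplastic_ltd",
                               [(3.2, 3.0), (12.0, 3.0)], t_max=1000.0)
        fates = [t["fate"] for t in pp.trajectories]
        assert fates == ["converged", "diverged"]
        assert pp.fixed_point == (3.0, 3.0)
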