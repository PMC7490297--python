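"""FvCB rate equations and A-Ci fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sunfleck as sf
from sunfleck.fvcb import ci_transition_point


class TestRubiscoLimitedRate:
    def test_compensation_point_gives_minus_rd(self, params_ln, kin):
        assert sf.rubisco_limited_rate(kin.gamma_star, params_ln, kin) == pytest.approx(
            -kin.Rd
        )

    def test_hand_evaluated_value_at_400(self, params_ln, kin):
        # 85*(400-55.22)/(400+690.05*(1+210/353.02)) - 1.37, checked by hand
        assert sf.rubisco_limited_rate(400.0, params_ln, kin) == pytest.approx(
            18.1605, abs=1e-3
        )

    def test_saturates_toward_vcmax_minus_rd(self, params_ln, kin):
        assert sf.rubisco_limited_rate(1e9, params_ln, kin) == pytest.approx(
            params_ln.Vcmax - kin.Rd, rel=1e-5
        )

    def test_strictly_increasing_above_compensation(self, params_ln, kin):
        ci = np.linspace(60.0, 2000.0, 200)
        a = sf.rubisco_limited_rate(ci, params_ln, kin)
        assert np.all(np.diff(a) > 0)

    def test_rejects_nonpositive_ci(self, params_ln, kin):
        with pytest.raises(ValueError):
            sf.rubisco_limited_rate(0.0, params_ln, kin)


class TestJLightResponse:
    def test_zero_light_gives_zero(self, params_ln):
        assert sf.j_light_response(0.0, params_ln) == 0.0

    def test_asymptote_is_jmax(self, params_ln):
        assert sf.j_light_response(1e9, params_ln) == pytest.approx(
            params_ln.Jmax, rel=1e-3
        )

    def test_equals_smaller_quadratic_root(self):
        # independent root: numpy.roots on theta*J^2 - (aI+Jm)*J + aI*Jm
        p = sf.FvCBParams(85.0, 125.0, theta=0.7, alpha=0.3)
        ai = 0.3 * 1500.0
        roots = np.roots([0.7, -(ai + 125.0), ai * 125.0])
        assert sf.j_light_response(1500.0, p) == pytest.approx(
            float(np.min(roots)), rel=1e-12
        )

    @given(ppfd=st.floats(0.0, 5000.0))
    @settings(deadline=None, max_examples=50)
    def test_bounded_by_jmax_and_nonnegative(self, ppfd):
        p = sf.FvCBParams(85.0, 125.0)
        j = sf.j_light_response(ppfd, p)
        assert 0.0 <= j <= p.Jmax + 1e-9


class TestRubpLimitedRate:
    def test_compensation_point_gives_minus_rd(self, kin):
        assert sf.rubp_limited_rate(kin.gamma_star, 120.0, kin) == pytest.approx(
            -kin.Rd
        )

    def test_asymptote_j_over_4_minus_rd(self, kin):
        assert sf.rubp_limited_rate(1e9, 120.0, kin) == pytest.approx(
            30.0 - kin.Rd, rel=1e-5
        )

    def test_hand_evaluated_value(self, kin):
        expected = 160.0 * (800.0 - 55.22) / (4 * 800.0 + 8 * 55.22) - 1.37
        assert sf.rubp_limited_rate(800.0, 160.0, kin) == pytest.approx(expected)


class TestNetAssimilation:
    def test_darkness_gives_minus_rd(self, params_ln, kin):
        assert sf.net_assimilation(400.0, 0.0, params_ln, kin) == pytest.approx(
            -kin.Rd
        )

    def test_low_ci_selects_rubisco_branch(self, kin):
        p = sf.FvCBParams(85.0, 1000.0, alpha=0.45)
        a = sf.net_assimilation(100.0, 2000.0, p, kin)
        assert a == pytest.approx(sf.rubisco_limited_rate(100.0, p, kin))

    def test_equals_brute_force_minimum_on_random_draws(self, kin):
        # independent oracle: re-coded branch formulas, elementwise min
        rng = np.random.default_rng(42)
        for _ in range(1000):
            ci = rng.uniform(10.0, 2000.0)
            ppfd = rng.uniform(0.0, 2500.0)
            p = sf.FvCBParams(rng.uniform(20, 200), rng.uniform(30, 300))
            km = kin.Kc * (1 + kin.O / kin.Ko)
            ac = p.Vcmax * (ci - kin.gamma_star) / (ci + km) - kin.Rd
            ai = p.alpha * ppfd
            j = ((ai + p.Jmax)
                 - np.sqrt((ai + p.Jmax) ** 2 - 4 * p.theta * ai * p.Jmax)
                 ) / (2 * p.theta)
            aj = j * (ci - kin.gamma_star) / (4 * ci + 8 * kin.gamma_star) - kin.Rd
            expected = min(ac, aj)
            got = sf.net_assimilation(ci, ppfd, p, kin)
            assert got == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_monotone_in_ci_and_ppfd(self, params_ln, kin):
        ci = np.linspace(60.0, 1500.0, 60)
        ppfd = np.linspace(0.0, 2000.0, 50)
        grid = np.array([[sf.net_assimilation(c, q, params_ln, kin) for c in ci]
                         for q in ppfd])
        assert np.all(np.diff(grid, axis=1) > -1e-12)  # in Ci
        assert np.all(np.diff(grid, axis=0) > -1e-12)  # in PPFD


class TestFitAci:
    def test_noiseless_round_trip(self, leaf):
        curve = sf.generate_aci_curve(leaf, noise_sd=0.0)
        fit = sf.fit_aci(curve)
        assert fit.params.Vcmax == pytest.approx(85.0, rel=5e-3)
        assert fit.params.Jmax == pytest.approx(125.0, rel=5e-3)
        assert fit.jmax_vcmax_ratio == pytest.approx(
            fit.params.Jmax / fit.params.Vcmax, rel=1e-12
        )
        assert fit.n_rubisco_pts + fit.n_rubp_pts <= len(curve)
        assert fit.transition_in_range

    def test_all_rubisco_curve_degenerate_for_rubp_branch(self, params_ln, kin):
        # points generated far below the transition carry no Jmax signal
        p_true = sf.FvCBParams(85.0, 5000.0, alpha=0.45)
        ci = np.array([80.0, 110.0, 140.0, 170.0, 200.0, 230.0])
        a = np.asarray(sf.rubisco_limited_rate(ci, p_true, kin))
        curve = sf.ACiCurve(ci=tuple(ci), a=tuple(a))
        with pytest.raises(sf.FitDegenerateError) as err:
            sf.fit_aci(curve, kin)
        assert err.value.branch == "RuBP"

    def test_noisy_bias_small_over_replicates(self, leaf):
        # 200 seeded replicates, Gaussian sd 0.5 on A, 12 points
        vc, jm = [], []
        for seed in range(200):
            curve = sf.generate_aci_curve(leaf, noise_sd=0.5, seed=seed)
            fit = sf.fit_aci(curve)
            vc.append(fit.params.Vcmax)
            jm.append(fit.params.Jmax)
        assert np.median(np.abs(np.array(vc) - 85.0)) / 85.0 < 0.03
        assert np.median(np.abs(np.array(jm) - 125.0)) / 125.0 < 0.03

    def test_error_shrinks_with_more_points(self, leaf):
        # median |Vcmax error| should not grow as curves get denser
        med = {}
        for n in (8, 12, 24):
            ca = np.geomspace(60.0, 1500.0, n)  # denser at low CO2
            errs = []
            for seed in range(40):
                curve = sf.generate_aci_curve(leaf, Ca_sequence=ca,
                                              noise_sd=0.5, seed=seed)
                fit = sf.fit_aci(curve)
                errs.append(abs(fit.params.Vcmax - 85.0))
            med[n] = float(np.median(errs))
        assert med[24] < med[8]

    def test_ratio_invariant_to_point_order(self, leaf, kin):
        curve = sf.generate_aci_curve(leaf, noise_sd=0.3, seed=7)
        pts = list(zip(curve.ci, curve.a))
        rng = np.random.default_rng(0)
        shuffled = [pts[i] for i in rng.permutation(len(pts))]
        curve2 = sf.ACiCurve.from_points(shuffled, ppfd=curve.ppfd)
        f1, f2 = sf.fit_aci(curve, kin), sf.fit_aci(curve2, kin)
        assert sf.jmax_vcmax_ratio(f1) == pytest.approx(
            sf.jmax_vcmax_ratio(f2), rel=1e-9
        )


class TestJmaxVcmaxRatio:
    @pytest.mark.parametrize(
        "vcmax,jmax,expected",
        [(85.0, 125.0, 1.47), (184.0, 202.0, 1.10),
         (120.0, 157.0, 1.31), (169.0, 177.0, 1.05),
         (100.0, 100.0, 1.00)],
    )
    def test_printed_ratios(self, vcmax, jmax, expected):
        fit = sf.ACiFit(
            params=sf.FvCBParams(vcmax, jmax), ci_transition=300.0, rmse=0.0,
            n_rubisco_pts=5, n_rubp_pts=5, jmax_vcmax_ratio=jmax / vcmax,
        )
        assert round(sf.jmax_vcmax_ratio(fit), 2) == expected


class TestDomainTypes:
    def test_kinetics_km_exceeds_kc(self, kin):
        assert kin.Km > kin.Kc

    def test_kinetics_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sf.LeafKinetics(Kc=-1.0)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            sf.FvCBParams(-5.0, 100.0)
        with pytest.raises(ValueError):
            sf.FvCBParams(85.0, 125.0, theta=1.5)
        with pytest.raises(ValueError):
            sf.FvCBParams(85.0, 125.0, alpha=0.6)

    def test_curve_needs_five_increasing_points(self):
        with pytest.raises(ValueError):
            sf.ACiCurve(ci=(100.0, 200.0, 300.0), a=(5.0, 10.0, 12.0))
        with pytest.raises(ValueError):
            sf.ACiCurve(ci=(100.0, 90.0, 300.0, 400.0, 500.0),
                        a=(5.0, 4.0, 12.0, 14.0, 15.0))

    def test_transition_point_continuity(self, params_ln, kin):
        # Ac and Aj agree at the analytic transition Ci
        j = sf.j_light_response(1500.0, params_ln)
        ci_t = ci_transition_point(params_ln, j, kin)
        ac = sf.rubisco_limited_rate(ci_t, params_ln, kin)
        aj = sf.rubp_limited_rate(ci_t, j, kin)
        assert ac == pytest.approx(aj, rel=1e-9)
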