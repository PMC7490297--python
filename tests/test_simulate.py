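"""Light regimes, the supply-demand Ci solver and the dynamic leaf."""

import numpy as np
import pytest

import sunfleck as sf


class TestStepLightProtocol:
    def test_default_counts(self):
        reg = sf.step_light_protocol()
        assert np.sum(reg.ppfd == 50.0) == 120
        assert np.sum(reg.ppfd == 1500.0) == 180
        assert len(reg) == (1200 + 1800) / 10

    def test_zero_low_duration_starts_high(self):
        reg = sf.step_light_protocol(t_low=0.0)
        assert reg.ppfd[0] == 1500.0

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            sf.step_light_protocol(low=1500.0, high=50.0)


class TestGenerateDiurnalRegime:
    def test_no_shade_gives_pure_half_sine(self):
        reg = sf.generate_diurnal_regime(shade_fraction=1.0, seed=0)
        expected = 1200.0 * np.sin(np.pi * reg.time / 43200.0)
        assert np.allclose(reg.ppfd, np.clip(expected, 0, None))
        assert reg.ppfd.max() == pytest.approx(1200.0, rel=1e-4)

    def test_seed_determinism(self):
        a = sf.generate_diurnal_regime(seed=5)
        b = sf.generate_diurnal_regime(seed=5)
        c = sf.generate_diurnal_regime(seed=6)
        assert np.array_equal(a.ppfd, b.ppfd)
        assert not np.array_equal(a.ppfd, c.ppfd)
        # envelope identical across seeds: fleck pattern differs only
        assert a.ppfd.max() <= 1200.0 and c.ppfd.max() <= 1200.0

    def test_telegraph_sun_fraction_near_stationary(self):
        # the sun/shade process should spend ~p_sun of the day in sun
        fracs = []
        for seed in range(5):
            reg = sf.generate_diurnal_regime(seed=seed, shade_fraction=0.2)
            env = 1200.0 * np.sin(np.pi * reg.time / 43200.0)
            mid = env > 1.0
            sun = np.isclose(reg.ppfd[mid] / env[mid], 1.0, atol=1e-6)
            fracs.append(float(np.mean(sun)))
        assert abs(np.mean(fracs) - 0.5) < 0.02

    def test_invalid_dwell_bounds_rejected(self):
        with pytest.raises(ValueError):
            sf.generate_diurnal_regime(dwell_bounds=(300.0, 10.0))


class TestSolveCi:
    def test_dark_limit(self, leaf, kin):
        ci, a = sf.solve_ci(0.4, 400.0, 0.0, leaf)
        assert a == pytest.approx(-kin.Rd, abs=1e-6)
        assert ci == pytest.approx(400.0 + 1.6 * kin.Rd / 0.4, abs=0.01)
        assert ci > 400.0

    def test_infinite_supply_pins_ci_at_ca(self, params_ln):
        leaf = sf.SimLeaf(fvcb=params_ln)
        ci, _ = sf.solve_ci(500.0, 400.0, 1500.0, leaf)
        assert ci == pytest.approx(400.0, abs=0.5)

    def test_matches_grid_scan_oracle(self, leaf, kin):
        # brute-force oracle: densely sample the mismatch and take argmin
        rng = np.random.default_rng(17)
        for _ in range(1000):
            gs = rng.uniform(0.02, 0.8)
            ca = rng.uniform(200.0, 1200.0)
            ppfd = rng.uniform(0.0, 2000.0)
            act = rng.uniform(0.2, 1.0)
            ci, _ = sf.solve_ci(gs, ca, ppfd, leaf, activation=act)
            hi = ca + 1.6 * (kin.Rd + 5.0) / gs
            grid = np.linspace(1e-6, hi, 100_000)
            p = leaf.fvcb
            km = kin.Km
            ac = act * p.Vcmax * (grid - kin.gamma_star) / (grid + km) - kin.Rd
            j = sf.j_light_response(ppfd, p)
            aj = j * (grid - kin.gamma_star) / (4 * grid + 8 * kin.gamma_star) - kin.Rd
            mismatch = np.minimum(ac, aj) - (gs / 1.6) * (ca - grid)
            ci_oracle = grid[np.argmin(np.abs(mismatch))]
            assert abs(ci - ci_oracle) < 0.02

    def test_rejects_invalid_inputs(self, leaf):
        with pytest.raises(ValueError):
            sf.solve_ci(0.0, 400.0, 1000.0, leaf)
        with pytest.raises(ValueError):
            sf.solve_ci(0.3, 400.0, 1000.0, leaf, activation=1.5)


class TestSimulateLeaf:
    def test_steady_state_matches_fvcb_fixed_point(self, params_ln, kin):
        leaf = sf.SimLeaf(fvcb=params_ln)
        t = np.arange(0.0, 7200.0, 10.0)
        reg = sf.LightRegime(time=t, ppfd=np.full(len(t), 1500.0))
        tr = sf.simulate_leaf(reg, leaf, noise=sf.NoiseModel.none())
        a_end = tr.column("A")[-1]
        ci_end = tr.column("Ci")[-1]
        expected = sf.net_assimilation(ci_end, 1500.0, params_ln, kin)
        assert a_end == pytest.approx(expected, rel=1e-3)

    def test_instant_kinetics_give_instant_induction(self, params_ln):
        leaf = sf.SimLeaf(fvcb=params_ln, tau_gs_open=1e-3, tau_gs_close=1e-3,
                          tau_act=1e-3)
        reg = sf.step_light_protocol()
        tr = sf.simulate_leaf(reg, leaf, noise=sf.NoiseModel.none())
        ccf = sf.cumulative_fixation(tr, 1200.0)
        a_f = tr.column("A")[-1]
        assert ccf == pytest.approx(a_f * 600.0 * 1e-3, rel=5e-3)

    def test_seed_determinism_bit_identical(self, step_regime, leaf):
        a = sf.simulate_leaf(step_regime, leaf, noise=sf.NoiseModel(), seed=2)
        b = sf.simulate_leaf(step_regime, leaf, noise=sf.NoiseModel(), seed=2)
        assert a.data.equals(b.data)

    def test_step_halving_invariance_of_carbon_gain(self, leaf):
        gains = []
        for dt in (20.0, 10.0):
            reg = sf.generate_diurnal_regime(seed=1, interval=dt)
            tr = sf.simulate_leaf(reg, leaf, noise=sf.NoiseModel.none(), seed=1)
            gains.append(sf.integrate_assimilation(tr))
        assert gains[0] == pytest.approx(gains[1], rel=5e-3)

    def test_cultivar_contrast_brackets_printed_value(self):
        # capacities from the low-N groups; the higher-capacity leaf also
        # opens stomata wider, and its steady A sits 25-35% higher
        lk = sf.SimLeaf(fvcb=sf.FvCBParams(85.0, 125.0), gs_max=0.40)
        lt = sf.SimLeaf(fvcb=sf.FvCBParams(120.0, 157.0), gs_max=0.55)
        _, a_k = sf.solve_ci(lk.gs_target(1500.0), 400.0, 1500.0, lk)
        _, a_t = sf.solve_ci(lt.gs_target(1500.0), 400.0, 1500.0, lt)
        contrast = sf.percent_difference(a_k, a_t)
        assert 25.0 < contrast < 35.0

    def test_elevated_co2_raises_ccf_and_daily_gain(self, step_regime, leaf):
        ccf = {}
        for co2 in (400.0, 800.0):
            tr = sf.simulate_leaf(step_regime, leaf, co2=co2,
                                  noise=sf.NoiseModel.none())
            ccf[co2] = sf.cumulative_fixation(tr, 1200.0)
        assert ccf[800.0] > ccf[400.0]

    def test_elevated_co2_lowers_diffusional_limitation(self, step_regime, leaf):
        dl = {}
        for co2 in (400.0, 800.0):
            tr = sf.simulate_leaf(step_regime, leaf, co2=co2,
                                  noise=sf.NoiseModel.none())
            dl[co2] = sf.limitation_partition(tr, t_step=1200.0).mean_DL
        assert dl[800.0] < dl[400.0]

    def test_recovered_ranking_of_stomatal_speed(self, params_ln, step_regime):
        # closing the loop: the analysis stack must rank fast vs slow leaves
        stats = {}
        for tau, tag in ((100.0, "fast"), (600.0, "slow")):
            leaf = sf.SimLeaf(fvcb=params_ln, tau_gs_open=tau)
            tr = sf.simulate_leaf(step_regime, leaf, noise=sf.NoiseModel.none())
            res = sf.analyze_induction(tr, t_step=1200.0)
            stats[tag] = res
        assert stats["fast"].it50 < stats["slow"].it50
        assert stats["fast"].ccf > stats["slow"].ccf
        assert stats["fast"].limitation.mean_DL < stats["slow"].limitation.mean_DL

    def test_fluorescence_consistent_with_assimilation(self, induction_trace,
                                                       params_ln, kin):
        # recomputing ETR from synthesized Fs/Fm' returns 4*(A+Rd) capped at J
        df = induction_trace.data
        lit = df["ppfd"] > 0
        etr_back = sf.etr(df["Fs"][lit], df["Fm_prime"][lit], df["ppfd"][lit])
        j = np.asarray(sf.j_light_response(df["ppfd"][lit].to_numpy(), params_ln))
        expected = np.minimum(4.0 * (df["A"][lit] + kin.Rd), j)
        assert np.allclose(etr_back, expected, rtol=1e-9)


class TestGenerateAciCurve:
    def test_zero_noise_points_on_model_curve(self, leaf, params_ln, kin):
        curve = sf.generate_aci_curve(leaf, noise_sd=0.0)
        for ci, a in zip(curve.ci, curve.a):
            assert a == pytest.approx(
                sf.net_assimilation(ci, curve.ppfd, params_ln, kin), abs=1e-3
            )

    def test_seed_reproducibility(self, leaf):
        a = sf.generate_aci_curve(leaf, noise_sd=0.5, seed=3)
        b = sf.generate_aci_curve(leaf, noise_sd=0.5, seed=3)
        assert a.ci == b.ci and a.a == b.a

    def test_nonpositive_ca_rejected(self, leaf):
        with pytest.raises(ValueError):
            sf.generate_aci_curve(leaf, Ca_sequence=[-50.0, 100.0])


class TestGeneratePamTrace:
    def _regime(self):
        t = np.arange(0.0, 43200.0 + 1, 180.0)
        ppfd = np.clip(800.0 * np.sin(np.pi * t / 43200.0), 0.0, None)
        return sf.LightRegime(time=t, ppfd=ppfd, kind="field-PAM")

    def test_dark_record_has_phi0(self):
        reg = self._regime()
        pam = sf.generate_pam_trace(reg, phi0=0.78, noise_sd=0.0)
        phi_dark = 1.0 - pam["Fs"].iloc[0] / pam["Fm_prime"].iloc[0]
        assert phi_dark == pytest.approx(0.78)

    def test_round_trip_reproduces_phi_model(self):
        reg = self._regime()
        pam = sf.generate_pam_trace(reg, phi0=0.78, K=450.0, noise_sd=0.0)
        trace = sf.etr_trace(pam)
        expected = 0.42 * 0.78 * reg.ppfd / (1.0 + reg.ppfd / 450.0)
        assert np.allclose(trace.etr, expected, rtol=1e-9)
        # saturating, monotone light response of ETR
        order = np.argsort(reg.ppfd)
        assert np.all(np.diff(trace.etr[order]) > -1e-9)

    def test_invalid_phi0_rejected(self):
        with pytest.raises(ValueError):
            sf.generate_pam_trace(self._regime(), phi0=1.2)
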