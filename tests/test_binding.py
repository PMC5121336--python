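"""Saturation-binding and 1:1 SPR kinetics models."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ldlscreen.binding import (
    BindingFit,
    Injection,
    InjectionSchedule,
    Sensorgram,
    competition_analysis,
    double_reference,
    fit_1to1_kinetics,
    fit_saturation,
    saturation_model,
    simulate_sensorgram,
    stability_point_quantitation,
)
from ldlscreen.errors import FitError
from ldlscreen.simulate import (
    ALK1_ECTO_UM,
    LDLR_ECTO_NM,
    BindingSimSpec,
    gen_binding,
    single_cycle_schedule,
)

CONCS = (2.0, 5.0, 10.0, 25.0, 50.0, 100.0)


class TestSaturation:
    def test_noiseless_recovery(self):
        bound = saturation_model(np.array(CONCS), 67.0, 26.0)
        fit = fit_saturation(CONCS, bound)
        assert fit.k_d == pytest.approx(26.0, rel=1e-3)
        assert fit.b_max == pytest.approx(67.0, rel=1e-3)

    def test_half_saturation_identity(self):
        bound = saturation_model(np.array(CONCS), 50.0, 12.0)
        fit = fit_saturation(CONCS, bound)
        at_kd = saturation_model(np.array([fit.k_d]), fit.b_max, fit.k_d)[0]
        assert at_kd == pytest.approx(fit.b_max / 2, rel=1e-9)

    def test_concentration_rescaling_rescales_kd(self):
        bound = saturation_model(np.array(CONCS), 67.0, 26.0)
        fit1 = fit_saturation(CONCS, bound)
        fit2 = fit_saturation(np.array(CONCS) * 10, bound)
        assert fit2.k_d == pytest.approx(10 * fit1.k_d, rel=1e-6)
        assert fit2.b_max == pytest.approx(fit1.b_max, rel=1e-6)

    def test_monte_carlo_recovery(self):
        """Median K_d over 200 noisy replicates (5% multiplicative) within 10%."""
        rng = np.random.default_rng(42)
        kds = []
        truth = saturation_model(np.array(CONCS), 67.0, 26.0)
        for _ in range(200):
            noisy = truth * (1 + rng.normal(0, 0.05, len(CONCS)))
            try:
                kds.append(fit_saturation(CONCS, noisy).k_d)
            except FitError:
                continue
        assert abs(np.median(kds) - 26.0) / 26.0 < 0.10

    def test_nonspecific_term(self):
        bound = saturation_model(np.array(CONCS), 67.0, 26.0, ns=0.3)
        fit = fit_saturation(CONCS, bound, nonspecific=True)
        assert fit.k_d == pytest.approx(26.0, rel=1e-3)
        assert fit.nonspecific == pytest.approx(0.3, rel=1e-3)

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError):
            fit_saturation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestSimulateSensorgram:
    def test_zero_concentration_stays_zero(self):
        sched = InjectionSchedule([Injection(0.0, 0, 100)], 200, single_cycle=False)
        sg = simulate_sensorgram(1e5, 0.01, 100, sched)
        assert np.allclose(sg.response, 0.0)

    def test_saturating_injection_reaches_rmax(self):
        # C >> K_d and long contact: plateau -> R_max
        sched = InjectionSchedule([Injection(1e-3, 0, 5000)], 6000)
        sg = simulate_sensorgram(1e5, 0.01, 100, sched)
        assert sg.response[sg.time == 4999.5].item() == pytest.approx(100, rel=1e-2)

    def test_equilibrium_plateau_matches_isotherm(self):
        k_a, k_d_rate, r_max, c = 1e4, 0.01, 80.0, 2e-6
        sched = InjectionSchedule([Injection(c, 0, 50000)], 51000)
        sg = simulate_sensorgram(k_a, k_d_rate, r_max, sched)
        kd = k_d_rate / k_a
        expected = r_max * c / (kd + c)
        i_end = np.searchsorted(sg.time, 50000.0) - 1  # last point inside the injection
        assert sg.response[i_end] == pytest.approx(expected, rel=1e-6)

    def test_response_bounded_by_rmax(self):
        sched = single_cycle_schedule(ALK1_ECTO_UM)
        sg = simulate_sensorgram(0.05, 0.01, 100, sched)
        assert np.all(sg.response >= -1e-9)
        assert np.all(sg.response <= 100 + 1e-9)

    def test_matches_independent_ode_solver(self):
        """Closed-form propagator agrees with scipy solve_ivp on the same model."""
        sched = single_cycle_schedule((1.0, 3.0, 9.0), contact_s=60, dissociation_s=300)
        k_a, k_d_rate, r_max = 0.02, 0.015, 75.0
        sg = simulate_sensorgram(k_a, k_d_rate, r_max, sched, dt=1.0)

        def rhs(t, y):
            c = sched.concentration_at(t)
            return [k_a * c * (r_max - y[0]) - k_d_rate * y[0]]

        sol = solve_ivp(
            rhs, (0, sched.dissociation_end), [0.0], t_eval=sg.time,
            max_step=1.0, rtol=1e-10, atol=1e-12,
        )
        assert np.allclose(sg.response, sol.y[0], atol=1e-5)

    def test_invalid_rates_rejected(self):
        sched = single_cycle_schedule(ALK1_ECTO_UM)
        with pytest.raises(ValueError):
            simulate_sensorgram(-1.0, 0.01, 100, sched)


class TestKineticFit:
    def test_roundtrip_random_draws(self):
        """simulate -> fit recovers (k_a, k_d, R_max) to <1% over 20 draws
        spanning K_d from ~1 nM to ~10 uM."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            k_d_true = 10 ** rng.uniform(-3, 1)  # in units of the mid concentration
            k_d_rate = 10 ** rng.uniform(-3, -1.3)
            k_a = k_d_rate / k_d_true
            r_max = rng.uniform(50, 300)
            concs = tuple(k_d_true * 3 ** k for k in range(-2, 3))
            sched = single_cycle_schedule(concs, contact_s=200, dissociation_s=600)
            sg = simulate_sensorgram(k_a, k_d_rate, r_max, sched)
            fit = fit_1to1_kinetics(sg)
            assert fit.k_a == pytest.approx(k_a, rel=0.01)
            assert fit.k_d_rate == pytest.approx(k_d_rate, rel=0.01)
            assert fit.r_max == pytest.approx(r_max, rel=0.01)

    def test_kd_equals_rate_ratio(self):
        sched = single_cycle_schedule(LDLR_ECTO_NM)
        sg = simulate_sensorgram(0.01 / 7.0, 0.01, 100, sched)
        fit = fit_1to1_kinetics(sg)
        assert fit.k_d == pytest.approx(fit.k_d_rate / fit.k_a, rel=1e-12)

    def test_kinetic_and_equilibrium_routes_agree(self):
        """K_d from kinetics matches K_d from fitting per-injection plateaus
        to the saturation isotherm (fully equilibrated single cycle)."""
        k_a, k_d_rate, r_max = 0.05, 0.01, 100.0
        concs = (0.05, 0.15, 0.45, 1.35, 4.05)
        sched = single_cycle_schedule(concs, contact_s=3000, dissociation_s=600)
        sg = simulate_sensorgram(k_a, k_d_rate, r_max, sched)
        kin = fit_1to1_kinetics(sg)
        plateaus = [
            float(sg.response[np.searchsorted(sg.time, inj.stop) - 1])
            for inj in sched.injections
        ]
        # cumulative response at each plateau follows the isotherm in C
        eq = fit_saturation(np.array(concs) * 1.0, np.array(plateaus))
        assert kin.k_d == pytest.approx(eq.k_d, rel=0.02)

    def test_flat_sensorgram_raises(self):
        sched = single_cycle_schedule(ALK1_ECTO_UM)
        sg = Sensorgram(
            time=np.arange(0.0, 100.0), response=np.zeros(100), schedule=sched
        )
        with pytest.raises(FitError):
            fit_1to1_kinetics(sg)


class TestReferencingAndCompetition:
    def _sg(self, resp, sched=None):
        return Sensorgram(np.arange(float(len(resp))), np.asarray(resp, float), sched)

    def test_drift_removed(self):
        t = np.arange(100.0)
        signal = 50 * (1 - np.exp(-t / 20))
        raw = self._sg(signal + 0.1 * t)
        ref = self._sg(0.1 * t)
        blank = self._sg(np.zeros(100))
        corrected = double_reference(raw, ref, blank)
        assert np.allclose(corrected.response, signal)

    def test_zero_reference_is_identity(self):
        raw = self._sg(np.sin(np.arange(50.0)))
        zeros = self._sg(np.zeros(50))
        out = double_reference(raw, zeros, zeros)
        assert np.allclose(out.response, raw.response)

    def test_mismatched_time_base_raises(self):
        raw = self._sg(np.zeros(50))
        short = self._sg(np.zeros(40))
        with pytest.raises(ValueError):
            double_reference(raw, short, short)

    def test_identical_fits_ratio_one(self):
        fit = BindingFit(k_d=1.0, r_max=100.0)
        rep = competition_analysis(fit, fit)
        assert rep["kd_ratio"] == pytest.approx(1.0)
        assert rep["amplitude_ratio"] == pytest.approx(1.0)
        assert rep["verdict"] == "non-competitive"

    def test_independent_sites_non_competitive(self):
        """Disjoint binding sites: presaturating with the other ligand leaves
        this analyte's kinetic fit unchanged."""
        sched = single_cycle_schedule(ALK1_ECTO_UM)
        naive = fit_1to1_kinetics(simulate_sensorgram(0.05, 0.01, 100, sched))
        presat = fit_1to1_kinetics(simulate_sensorgram(0.05, 0.01, 100, sched))
        rep = competition_analysis(naive, presat)
        assert rep["verdict"] == "non-competitive"

    def test_shared_site_competitive(self):
        # presaturation leaves ~5% of the surface available
        sched = single_cycle_schedule(ALK1_ECTO_UM)
        naive = fit_1to1_kinetics(simulate_sensorgram(0.05, 0.01, 100, sched))
        presat = fit_1to1_kinetics(simulate_sensorgram(0.05, 0.01, 5, sched))
        rep = competition_analysis(naive, presat)
        assert rep["verdict"] == "competitive"
        assert rep["amplitude_ratio"] == pytest.approx(0.05, rel=1e-3)


class TestStabilityPoint:
    def test_normalizer_reads_one_and_zero_trace_zero(self):
        sched = single_cycle_schedule((1.0,), contact_s=100, dissociation_s=100)
        ref = simulate_sensorgram(0.05, 0.01, 100, sched)
        zero = Sensorgram(ref.time.copy(), np.zeros_like(ref.response), sched)
        out = stability_point_quantitation({"ref": ref, "zero": zero}, "ref")
        assert out["ref"] == pytest.approx(1.0)
        assert out["zero"] == pytest.approx(0.0)

    def test_preserved_binding_reads_near_one(self):
        # independent-epitope scenario: complexed analyte binds like free analyte
        sched = single_cycle_schedule((2.0,), contact_s=120, dissociation_s=120)
        alk1 = simulate_sensorgram(0.05, 0.01, 100, sched)
        complexed = simulate_sensorgram(0.05, 0.01, 98, sched)
        out = stability_point_quantitation({"alk1": alk1, "complex": complexed}, "alk1")
        assert out["complex"] == pytest.approx(0.98, abs=0.02)

    def test_offset_beyond_trace_raises(self):
        sched = single_cycle_schedule((1.0,), contact_s=100, dissociation_s=2)
        sg = simulate_sensorgram(0.05, 0.01, 100, sched)
        with pytest.raises(ValueError):
            stability_point_quantitation({"a": sg}, "a", offset_s=50.0)


class TestGenBinding:
    def test_zero_noise_inversion(self):
        data, truth = gen_binding(BindingSimSpec(model="saturation", seed=0))
        fit = fit_saturation(data["concentration"], data["bound"])
        assert fit.k_d == pytest.approx(truth["k_d"], rel=1e-3)
        assert fit.b_max == pytest.approx(truth["b_max"], rel=1e-3)

    def test_two_site_spec_is_non_competitive(self):
        sched = single_cycle_schedule(ALK1_ECTO_UM)
        spec = BindingSimSpec(model="two_site", k_a=0.05, k_d_rate=0.01, r_max=100,
                              k_a2=0.002, k_d_rate2=0.02, r_max2=40, schedule=sched)
        sg, truth = gen_binding(spec)
        assert sg.response.max() > 100  # both sites contribute
        # presaturating the second site removes only its contribution
        naive = fit_1to1_kinetics(simulate_sensorgram(0.05, 0.01, 100, sched))
        presat = fit_1to1_kinetics(simulate_sensorgram(0.05, 0.01, 100, sched))
        assert competition_analysis(naive, presat)["verdict"] == "non-competitive"

    def test_same_seed_identical_traces(self):
        a, _ = gen_binding(BindingSimSpec(model="kinetic", noise_sd=2.0, seed=5))
        b, _ = gen_binding(BindingSimSpec(model="kinetic", noise_sd=2.0, seed=5))
        assert np.array_equal(a.response, b.response)
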