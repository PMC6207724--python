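"""Conformational-selection binding: forward model, rate analysis, K_D."""

import numpy as np
import pytest

import shp2kin as sk
from shp2kin import binding_kinetics as bk
from shp2kin.errors import (
    DataInconsistencyError,
    InsufficientDataError,
    UnidentifiableError,
)


class TestEigenRates:
    def test_matches_numpy_eigenvalues(self, rng):
        """Closed-form rates equal the rate-matrix eigenvalue magnitudes."""
        for _ in range(25):
            sch = bk.ConfSelScheme(*np.exp(rng.uniform(-2, 2, 4)))
            ligand = float(np.exp(rng.uniform(-1, 3)))
            kl = sch.k_on * ligand
            m = np.array(
                [
                    [-sch.k_close, sch.k_open, 0.0],
                    [sch.k_close, -(sch.k_open + kl), sch.k_off],
                    [0.0, kl, -sch.k_off],
                ]
            )
            ev = np.sort(np.abs(np.linalg.eigvals(m)))
            lam_fast, lam_slow = bk.eigen_rates(sch, ligand)
            assert lam_fast == pytest.approx(ev[2], rel=1e-9)
            assert lam_slow == pytest.approx(ev[1], rel=1e-9)
            # invariants of the characteristic polynomial
            assert lam_fast + lam_slow == pytest.approx(
                sch.k_open + sch.k_close + kl + sch.k_off, rel=1e-12
            )
            assert lam_fast * lam_slow == pytest.approx(
                sch.k_close * kl + (sch.k_close + sch.k_open) * sch.k_off,
                rel=1e-9,
            )

    def test_zero_ligand_decouples(self, wt_scheme):
        lam_fast, lam_slow = bk.eigen_rates(wt_scheme, 0.0)
        assert lam_fast == pytest.approx(
            wt_scheme.k_open + wt_scheme.k_close, rel=1e-12
        )
        assert lam_slow == pytest.approx(wt_scheme.k_off, rel=1e-9)


class TestSimulateScheme:
    def test_flat_trace_at_equilibrium_without_ligand(self, wt_scheme):
        trace = sk.simulate_scheme(
            wt_scheme, 1.0, 0.0, t_grid=np.linspace(0, 10, 50)
        )
        assert np.ptp(trace.signal) < 1e-9 * abs(trace.signal[0])

    def test_long_time_species_match_analytic_equilibrium(self, wt_scheme):
        eq = sk.equilibrium_species(wt_scheme, 0.5, 5.0)
        t_grid = np.linspace(0, 400.0, 60)
        _, species = sk.simulate_scheme(
            wt_scheme, 0.5, 5.0, t_grid=t_grid, return_species=True
        )
        for name in ("open", "closed", "complex", "ligand"):
            assert species[name][-1] == pytest.approx(eq[name], rel=1e-6)

    def test_conservation_of_protein_and_ligand(self, wt_scheme):
        trace, species = sk.simulate_scheme(
            wt_scheme, 0.5, 5.0, t_grid=np.linspace(0, 50, 200),
            return_species=True,
        )
        protein = species["open"] + species["closed"] + species["complex"]
        ligand = species["ligand"] + species["complex"]
        assert np.max(np.abs(protein - 0.5)) < 1e-9 * 0.5
        assert np.max(np.abs(ligand - 5.0)) < 1e-9 * 5.0


class TestExponentialFits:
    def test_single_exponential_exact(self):
        t = np.linspace(0, 4, 120)
        trace = bk.Trace(t, 3.0 + 2.0 * np.exp(-2.0 * t))
        fit = bk.fit_exponentials(trace, 1)
        assert fit.rates[0] == pytest.approx(2.0, rel=1e-6)
        assert fit.offset == pytest.approx(3.0, rel=1e-6)

    def test_double_exponential_exact(self):
        t = np.linspace(0, 12, 400)
        trace = bk.Trace(t, 1.0 + 1.5 * np.exp(-5.0 * t) + 0.8 * np.exp(-0.5 * t))
        fit = bk.fit_exponentials(trace, 2)
        assert fit.rates[0] == pytest.approx(5.0, rel=1e-6)
        assert fit.rates[1] == pytest.approx(0.5, rel=1e-6)

    def test_drift_term_recovered(self):
        t = np.linspace(0, 6, 200)
        trace = bk.Trace(t, 2.0 + 1.0 * np.exp(-1.5 * t) + 0.05 * t)
        fit = bk.fit_exponentials(trace, 1, allow_drift=True)
        assert fit.rates[0] == pytest.approx(1.5, rel=1e-6)
        assert fit.drift == pytest.approx(0.05, rel=1e-5)

    def test_noisy_replicate_average_recovers_within_3se(self, rng):
        """Five averaged 2%-noise replicates bracket the true rates."""
        t = np.linspace(0, 12, 400)
        clean = 1.0 + 1.5 * np.exp(-5.0 * t) + 0.8 * np.exp(-0.5 * t)
        amp = np.ptp(clean)
        reps = [
            bk.Trace(t, clean + rng.normal(0, 0.02 * amp, t.size))
            for _ in range(5)
        ]
        fit = bk.fit_exponentials(bk.average_traces(reps), 2)
        ses = fit.rate_ses
        assert abs(fit.rates[0] - 5.0) < 3 * ses[0]
        assert abs(fit.rates[1] - 0.5) < 3 * ses[1]

    def test_phase_count_selection(self):
        t = np.linspace(0, 8, 300)
        single = bk.Trace(t, 2.0 + 1.0 * np.exp(-1.0 * t))
        double = bk.Trace(t, 1.0 + 1.5 * np.exp(-5.0 * t) + 0.8 * np.exp(-0.5 * t))
        assert bk.select_phase_count(single) == 1
        assert bk.select_phase_count(double) == 2


class TestFastPhase:
    def test_observed_slope_yields_true_on_rate(self):
        """Observed slope 0.394 with the WT equilibrium gives k_on = 0.44."""
        conc = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 60.0])
        data = bk.RateVsConc(conc, 0.394 * conc + 0.029)
        fit = bk.fit_fast_phase(data, 0.1161)
        assert fit.k_on == pytest.approx(0.394 * 1.1161, rel=1e-6)
        assert fit.k_on == pytest.approx(0.44, rel=2e-3)
        assert fit.k_off == pytest.approx(0.029, abs=1e-9)

    def test_fully_closed_protein_needs_no_correction(self):
        conc = np.array([1.0, 5.0, 20.0])
        data = bk.RateVsConc(conc, 0.5 * conc + 0.01)
        fit = bk.fit_fast_phase(data, 0.0)
        assert fit.k_on == pytest.approx(0.5, rel=1e-9)

    def test_negative_slope_rejected(self):
        conc = np.array([1.0, 5.0, 20.0])
        data = bk.RateVsConc(conc, 2.0 - 0.01 * conc)
        with pytest.raises(DataInconsistencyError):
            bk.fit_fast_phase(data, 0.1)


class TestSlowPhase:
    def test_formula_limits(self, wt_scheme):
        assert bk.pseudo_slow_rate(wt_scheme, 0.0) == pytest.approx(
            wt_scheme.k_off, rel=1e-12
        )
        assert bk.pseudo_slow_rate(wt_scheme, 1e9) == pytest.approx(
            wt_scheme.k_close, rel=1e-6
        )

    def test_roundtrip_on_generated_hyperbola(self):
        """Rates generated from the hyperbola return k_close = 2.9 exactly."""
        sch = bk.ConfSelScheme(k_open=0.34, k_close=2.9, k_on=0.44, k_off=0.029)
        conc = np.array([1.0, 3.0, 7.0, 15.0, 30.0, 60.0])
        data = bk.RateVsConc(conc, conc, k_slow=bk.pseudo_slow_rate(sch, conc))
        fit = bk.fit_slow_phase(data, sch.k_on, sch.k_off)
        assert fit.k_close == pytest.approx(2.9, rel=1e-6)
        assert fit.k_open == pytest.approx(0.34, rel=1e-4)

    def test_flat_data_unidentifiable(self):
        conc = np.array([1.0, 3.0, 7.0, 15.0])
        data = bk.RateVsConc(conc, conc, k_slow=np.full(4, 2.9))
        with pytest.raises(UnidentifiableError):
            bk.fit_slow_phase(data, 0.44, 0.029)

    def test_too_few_concentrations(self):
        data = bk.RateVsConc(np.array([1.0, 2.0, 3.0]), np.ones(3),
                             k_slow=np.array([0.1, 0.5, 1.0]))
        with pytest.raises(InsufficientDataError):
            bk.fit_slow_phase(data, 0.44, 0.029)


class TestDissociation:
    def test_pure_exponential_trace(self):
        t = np.linspace(0, 150, 300)
        trace = bk.Trace(t, np.exp(-0.029 * t))
        k_off, _ = bk.fit_dissociation(trace)
        assert k_off == pytest.approx(0.029, rel=1e-6)

    def test_dilution_chase_with_negligible_rebinding(self, wt_scheme):
        """Post-dilution ligand far below K_D_obs: off-rate within 5%."""
        sc = sk.StopFlowScenario(
            scheme=wt_scheme, noise_sd=0.0, n_replicates=1,
            dissociation_premix_uM=(0.05, 0.05), dilution_factor=100.0,
        )
        data = sk.gen_stopflow(sc)
        k_off, _ = bk.fit_dissociation(data.dissociation[0])
        assert k_off == pytest.approx(wt_scheme.k_off, rel=0.05)

    def test_rebinding_regime_biases_high(self, wt_scheme):
        """At the bench concentrations rebinding inflates the fitted rate."""
        sc = sk.StopFlowScenario(scheme=wt_scheme, noise_sd=0.0, n_replicates=1)
        data = sk.gen_stopflow(sc)  # premix 0.6/0.6 uM, 11-fold dilution
        k_off, _ = bk.fit_dissociation(data.dissociation[0])
        assert k_off > 1.2 * wt_scheme.k_off


class TestApparentKd:
    def test_wt_reported_consistency(self):
        res = bk.apparent_kd_from(0.44, 0.029, 0.104 / 0.896)
        assert res.value == pytest.approx(0.0736, abs=5e-4)

    def test_fully_closed_limit(self):
        res = bk.apparent_kd_from(0.5, 0.05, 0.0)
        assert res.value == pytest.approx(0.1, rel=1e-12)

    def test_e76k_calculated_affinity_within_reported_band(self):
        """Sevenfold-reduced observed slope gives K_D inside 1.5 +/- 0.9 uM."""
        k = 0.958 / 0.042
        slope = 0.44 / (0.104 / 0.896 + 1.0) / 7.0
        res = bk.apparent_kd_from(slope * (k + 1.0), 0.10, k)
        assert 1.5 - 0.9 <= res.value <= 1.5 + 0.9

    def test_delta_method_agrees_with_monte_carlo(self):
        """First-order propagation within 25% of MC for CVs <= 10%."""
        res = bk.apparent_kd_from(
            0.44, 0.029, 0.1161,
            k_on_se=0.02, k_off_se=0.002, k_open_close_se=0.01,
            seed=5,
        )
        assert res.se_delta == pytest.approx(res.se_mc, rel=0.25)

    def test_scheme_interface_uses_stored_errors(self, wt_scheme):
        res = bk.apparent_kd(wt_scheme, seed=2)
        assert res.value == pytest.approx(wt_scheme.K_D_obs, rel=1e-12)
        assert res.se_delta > 0


class TestAsymptoticApproximations:
    def test_bounds_for_nearly_closed_scheme(self):
        """For p_open ~2% and k_off ~ k_close the textbook bounds hold."""
        sch = bk.ConfSelScheme(k_open=0.02, k_close=1.0, k_on=1.0, k_off=0.9)
        exch = sch.k_open + sch.k_close
        for ratio, fast_tol, slow_tol in [(10.0, 0.05, 0.05), (100.0, 0.05, 0.005)]:
            ligand = (ratio * exch - sch.k_off) / sch.k_on
            lam_fast, lam_slow = bk.eigen_rates(sch, ligand)
            assert abs(lam_fast - bk.pseudo_fast_rate(sch, ligand)) < fast_tol * lam_fast
            assert abs(lam_slow - bk.pseudo_slow_rate(sch, ligand)) < slow_tol * lam_slow

    def test_slow_phase_error_decays_with_separation(self, wt_scheme):
        exch = wt_scheme.k_open + wt_scheme.k_close
        errs = []
        for ratio in (10.0, 30.0, 100.0, 300.0):
            ligand = (ratio * exch - wt_scheme.k_off) / wt_scheme.k_on
            _, lam_slow = bk.eigen_rates(wt_scheme, ligand)
            errs.append(
                abs(lam_slow - float(bk.pseudo_slow_rate(wt_scheme, ligand)))
                / lam_slow
            )
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_fast_phase_error_floor_is_open_fraction(self, wt_scheme):
        """The population-scaled slope differs from the exact fast eigenvalue
        by the open fraction even at large separation (it is a fast-exchange
        expression)."""
        ligand = 1e4
        lam_fast, _ = bk.eigen_rates(wt_scheme, ligand)
        rel = abs(lam_fast - float(bk.pseudo_fast_rate(wt_scheme, ligand))) / lam_fast
        assert rel == pytest.approx(wt_scheme.p_open, abs=0.01)
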