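import numpy as np
import pytest

from bridgescope.nmr_relax import (
    DispersionSeries,
    ModelFreeParams,
    NmrConstants,
    RelaxationRecord,
    bloch_mcconnell_rex,
    cpmg_delta_rex,
    fit_dispersion,
    fit_rate,
    modelfree_fit,
    noe_ratio,
    predict_relaxation,
    rex_fast_exchange,
)
from bridgescope.synthetic_data import (
    CPMG_TAU_CP_S,
    R1_DELAYS_S,
    gen_dispersion,
    gen_relax_decay,
    gen_relax_record,
)

TAU_M = 11.0e-9


class TestFitRate:
    def test_exact_inversion_on_reference_delay_grid(self):
        tbl = gen_relax_decay(1.3, delays=R1_DELAYS_S)
        fit = fit_rate(tbl)
        assert fit.rate == pytest.approx(1.3, abs=1e-6)
        assert fit.i0 == pytest.approx(100.0, rel=1e-6)

    def test_constant_intensities_give_zero_rate(self):
        tbl = gen_relax_decay(0.0, delays=R1_DELAYS_S)
        fit = fit_rate(tbl)
        assert fit.rate == pytest.approx(0.0, abs=1e-9)
        assert "non_decaying" in fit.flags

    def test_noisy_replicates_mean_within_one_percent(self):
        rates = [fit_rate(gen_relax_decay(1.3, seed=k, noise_frac=0.02)).rate
                 for k in range(1000)]
        assert np.mean(rates) == pytest.approx(1.3, rel=0.01)

    def test_bootstrap_uncertainty_tracks_noise(self):
        tbl = gen_relax_decay(1.3, seed=5, noise_frac=0.02)
        fit = fit_rate(tbl, bootstrap=200, seed=1)
        assert 0.001 < fit.rate_err < 0.2


class TestNoeRatio:
    @pytest.mark.parametrize("sat,unsat,expected",
                             [(80.0, 100.0, 0.8), (100.0, 100.0, 1.0),
                              (-20.0, 100.0, -0.2)])
    def test_ratio(self, sat, unsat, expected):
        assert noe_ratio(sat, unsat) == expected

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            noe_ratio(1.0, 0.0)


class TestForwardModel:
    def test_rigid_limit_matches_single_lorentzian(self):
        """At S²=1 the spectral density collapses to the rigid-rotor
        Lorentzian, so the prediction must equal one computed directly."""
        p = ModelFreeParams(1.0, 0.0, 0.0, TAU_M)
        c = NmrConstants()
        wh, wn = c.frequencies(600.0)

        def j_rigid(w):
            return 0.4 * TAU_M / (1 + (w * TAU_M) ** 2)

        d2_4 = c.dipolar**2 / 4
        c2 = (wn * c.csa) ** 2 / 3
        r1_direct = d2_4 * (j_rigid(wh - wn) + 3 * j_rigid(wn)
                            + 6 * j_rigid(wh + wn)) + c2 * j_rigid(wn)
        r1, r2, noe = predict_relaxation(p)
        assert r1 == pytest.approx(r1_direct, rel=1e-12)
        assert r2 > r1  # slow tumbling regime

    def test_rex_is_purely_additive_to_r2(self):
        base = ModelFreeParams(0.85, 30e-12, 0.0, TAU_M)
        bumped = ModelFreeParams(0.85, 30e-12, 3.7, TAU_M)
        r1a, r2a, noea = predict_relaxation(base)
        r1b, r2b, noeb = predict_relaxation(bumped)
        assert r2b - r2a == pytest.approx(3.7, abs=1e-12)
        assert r1b == r1a and noeb == noea

    def test_typical_folded_protein_magnitudes(self):
        # sanity: a rigid residue on an ~11 ns tumbler at 600 MHz relaxes
        # with R1 of order 1 s^-1 and R2 in the teens
        r1, r2, noe = predict_relaxation(ModelFreeParams(0.87, 30e-12, 0.0, TAU_M))
        assert 0.8 < r1 < 2.0
        assert 10.0 < r2 < 20.0
        assert 0.6 < noe < 0.9


class TestModelFree:
    def _tight(self, rec):
        rec.r1_err = 1e-4 * rec.r1
        rec.r2_err = 1e-4 * rec.r2
        rec.noe_err = 1e-4 * abs(rec.noe)
        return rec

    def test_round_trip_without_exchange_drops_rex_term(self):
        p = ModelFreeParams(0.9, 20e-12, 0.0, TAU_M)
        fit = modelfree_fit(self._tight(gen_relax_record(p)), TAU_M)
        assert "Rex" not in fit.model
        assert fit.s2 == pytest.approx(0.9, rel=1e-3)
        assert fit.tau_e == pytest.approx(20e-12, rel=1e-3)
        assert fit.r_ex == 0.0

    def test_round_trip_with_exchange_selects_rex_model(self):
        p = ModelFreeParams(0.85, 50e-12, 5.0, TAU_M)
        fit = modelfree_fit(self._tight(gen_relax_record(p)), TAU_M)
        assert "Rex" in fit.model
        assert fit.r_ex == pytest.approx(5.0, rel=1e-3)
        assert fit.s2 == pytest.approx(0.85, rel=1e-3)

    def test_rex_at_two_percent_noise_within_ten_percent(self):
        p = ModelFreeParams(0.85, 50e-12, 5.0, TAU_M)
        fits = [modelfree_fit(gen_relax_record(p, seed=k, noise_frac=0.02),
                              TAU_M, model="S2+te+Rex") for k in range(10)]
        assert np.mean([f.r_ex for f in fits]) == pytest.approx(5.0, rel=0.10)

    def test_rigid_limit_recovers_s2_near_one(self):
        p = ModelFreeParams(1.0, 0.0, 0.0, TAU_M)
        fit = modelfree_fit(self._tight(gen_relax_record(p)), TAU_M)
        assert fit.s2 >= 0.99

    def test_fitted_rex_tracks_offset_injected_into_r2(self):
        p = ModelFreeParams(0.85, 50e-12, 2.0, TAU_M)
        rec = self._tight(gen_relax_record(p))
        delta = 1.5
        rec2 = RelaxationRecord(rec.residue_number, rec.r1, rec.r2 + delta,
                                rec.noe, rec.r1_err, rec.r2_err, rec.noe_err)
        fit1 = modelfree_fit(rec, TAU_M)
        fit2 = modelfree_fit(rec2, TAU_M)
        assert fit2.r_ex - fit1.r_ex == pytest.approx(delta, abs=1e-3)


class TestCpmg:
    def test_flat_intensities_give_zero_profile(self):
        tbl = gen_dispersion(0.0 + 1e-12, 1e-3)
        d = cpmg_delta_rex(tbl)
        assert np.allclose(d.delta_rex, 0.0, atol=1e-12)

    def test_log_ratio_closed_form(self):
        from bridgescope.structure_io import IntensityTable

        tbl = IntensityTable(1, [(0.001, 100.0), (0.02, 100.0 * np.exp(-0.16))],
                             modality="CPMG")
        d = cpmg_delta_rex(tbl, total_period=0.080)
        assert d.delta_rex[1] == pytest.approx(2.0, rel=1e-12)

    def test_transform_round_trips_generator_profile(self):
        phi, tau = 8e4, 1.5e-3
        tbl = gen_dispersion(phi, tau)
        d = cpmg_delta_rex(tbl)
        expected = (rex_fast_exchange(phi, tau, d.tau_cp)
                    - rex_fast_exchange(phi, tau, d.tau_cp.min()))
        np.testing.assert_allclose(d.delta_rex, expected, atol=1e-10)

    def test_fast_exchange_limits(self):
        phi, tau = 1e5, 1e-3
        small = float(rex_fast_exchange(phi, tau, 1e-9))
        assert small == pytest.approx(0.0, abs=1e-3)
        free = float(rex_fast_exchange(phi, tau, 10.0))
        assert free == pytest.approx(phi * tau, rel=1e-3)

    def test_agrees_with_bloch_mcconnell_in_fast_exchange(self):
        pa, dw, kex = 0.9, 300.0, 5000.0
        phi, tau = pa * (1 - pa) * dw**2, 1 / kex
        for tcp in CPMG_TAU_CP_S:
            bm = bloch_mcconnell_rex(pa, dw, kex, float(tcp))
            lm = float(rex_fast_exchange(phi, tau, tcp))
            assert lm == pytest.approx(bm, rel=0.05)


class TestFitDispersion:
    def test_noiseless_recovery_on_reference_grid(self):
        tbl = gen_dispersion(1e5, 1e-3)
        fit = fit_dispersion(cpmg_delta_rex(tbl))
        assert fit.phi_ex == pytest.approx(1e5, rel=0.01)
        assert fit.tau_ex == pytest.approx(1e-3, rel=0.01)

    def test_flat_profile_flagged(self):
        d = DispersionSeries(1, [(t, 0.0) for t in CPMG_TAU_CP_S])
        fit = fit_dispersion(d)
        assert fit.phi_ex == 0.0
        assert "flat_profile" in fit.flags

    def test_noisy_replicates_median_tau_within_fifteen_percent(self):
        taus = []
        # sigma = 0.2 s^-1 on dRex maps to fractional intensity noise of
        # sigma*T = 0.016 under the log-ratio transform
        for k in range(500):
            tbl = gen_dispersion(1e5, 1e-3, seed=k, noise_frac=0.016)
            fit = fit_dispersion(cpmg_delta_rex(tbl))
            taus.append(fit.tau_ex)
        med = np.median(taus)
        assert med == pytest.approx(1e-3, rel=0.15)
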