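"""Michaelis–Menten and Arrhenius fitting, KIE decomposition."""

import numpy as np
import pytest

from kemplab.constants import GAS_CONSTANT_KCAL
from kemplab.kinetics import (
    Arrhenius,
    ArrheniusResults,
    MichaelisMenten,
    RateTable,
    fit_arrhenius_from_table,
    kie_decomposition,
    kie_table,
)


def mm_velocities(conc, kcat, km):
    conc = np.asarray(conc, float)
    return kcat * conc / (km + conc)


CONCS = np.array([0.01, 0.025, 0.05, 0.1, 0.2, 0.35, 0.55, 0.8, 1.1])


class TestMichaelisMenten:
    def test_noiseless_recovery(self):
        v = mm_velocities(CONCS, kcat=1.43, km=0.53)
        fit = MichaelisMenten(CONCS, v).fit()
        assert fit.converged
        assert fit.kcat == pytest.approx(1.43, abs=1e-8)
        assert fit.KM == pytest.approx(0.53, abs=1e-8)

    def test_efficiency_from_fitted_values(self):
        # kcat=1.43 s^-1, KM=0.53 mM -> kcat/KM ~ 2698 s^-1 M^-1
        v = mm_velocities(CONCS, kcat=1.43, km=0.53)
        fit = MichaelisMenten(CONCS, v).fit()
        assert fit.efficiency == pytest.approx(1.43 / 0.53e-3, rel=1e-6)
        assert fit.efficiency == pytest.approx(2698.1, abs=0.1)

    def test_background_subtracted_before_fit(self):
        bg = 0.05
        v = mm_velocities(CONCS, kcat=1.43, km=0.53) + bg
        fit = MichaelisMenten(CONCS, v, background=bg).fit()
        assert fit.kcat == pytest.approx(1.43, abs=1e-8)

    def test_all_background_refused(self):
        bg = 0.02
        v = np.full_like(CONCS, bg)
        with pytest.raises(ValueError, match="no signal"):
            MichaelisMenten(CONCS, v, background=bg).fit()

    def test_too_few_concentrations_refused(self):
        with pytest.raises(ValueError, match="distinct substrate"):
            MichaelisMenten([0.1, 0.2, 0.4, 0.8],
                            [0.1, 0.15, 0.2, 0.25])

    def test_parameter_recovery_bias(self):
        """Planted (kcat, KM) recovered with <1% bias at 1% noise,
        11 concentrations, 500 seeds."""
        concs = np.linspace(0.01, 1.1, 11)
        kcat_t, km_t = 1.43, 0.53
        v0 = mm_velocities(concs, kcat_t, km_t)
        kcats, kms = [], []
        rng = np.random.default_rng(42)
        for _ in range(500):
            v = v0 * np.exp(rng.normal(0.0, 0.01, size=v0.shape))
            fit = MichaelisMenten(concs, v).fit()
            kcats.append(fit.kcat)
            kms.append(fit.KM)
        assert abs(np.mean(kcats) / kcat_t - 1) < 0.01
        assert abs(np.mean(kms) / km_t - 1) < 0.01


class TestArrhenius:
    TEMPS = np.array([283.0, 293.0, 303.0, 313.0, 323.0])

    def rates(self, ea, lna, temps=None):
        T = self.TEMPS if temps is None else np.asarray(temps, float)
        return np.exp(lna - ea / (GAS_CONSTANT_KCAL * T))

    def test_noiseless_recovery_and_roundtrip(self):
        fit = Arrhenius(self.TEMPS, self.rates(10.0, 15.0)).fit()
        assert fit.Ea == pytest.approx(10.0, abs=1e-9)
        assert fit.lnA == pytest.approx(15.0, abs=1e-9)
        # round-trip: every input point reproduced to >=10 significant digits
        back = fit.predict_rate(self.TEMPS)
        np.testing.assert_allclose(back, self.rates(10.0, 15.0), rtol=1e-10)

    def test_two_point_closed_form(self):
        T1, T2, k1, k2 = 290.0, 310.0, 0.02, 0.15
        slope = np.log(k2 / k1) / (1 / T2 - 1 / T1)
        ea = -slope * GAS_CONSTANT_KCAL
        lna = np.log(k1) + ea / (GAS_CONSTANT_KCAL * T1)
        # three temperatures required; use an exact midpoint to stay linear
        Tm = 1.0 / ((1 / T1 + 1 / T2) / 2)
        km = np.exp(lna - ea / (GAS_CONSTANT_KCAL * Tm))
        fit = Arrhenius([T1, Tm, T2], [k1, km, k2]).fit()
        assert fit.Ea == pytest.approx(ea, rel=1e-9)
        assert fit.lnA == pytest.approx(lna, rel=1e-9)

    def test_monte_carlo_recovery(self):
        """Mean recovered Ea over 1000 noisy replicas within 2 SE of truth."""
        k0 = self.rates(10.0, 15.0)
        rng = np.random.default_rng(7)
        eas, ses = [], []
        for _ in range(1000):
            k = k0 * np.exp(rng.normal(0.0, 0.02, size=k0.shape))
            fit = Arrhenius(self.TEMPS, k).fit()
            eas.append(fit.Ea)
            ses.append(fit.se_Ea)
        mean_ea = np.mean(eas)
        se_mean = np.std(eas, ddof=1) / np.sqrt(len(eas))
        assert abs(mean_ea - 10.0) < 2 * se_mean + 1e-3

    def test_nonpositive_rate_refused(self):
        with pytest.raises(ValueError, match="positive"):
            Arrhenius(self.TEMPS, [0.1, 0.2, -0.1, 0.4, 0.5])

    def test_single_temperature_refused(self):
        with pytest.raises(ValueError, match="temperatures"):
            Arrhenius([300.0, 300.0, 300.0], [0.1, 0.1, 0.1])

    def test_evaluate_rate_direct_substitution(self):
        fit = ArrheniusResults.from_params(Ea=5.6, lnA=9.1)
        expected = np.exp(9.1 - 5.6 / (GAS_CONSTANT_KCAL * 303.0))
        assert fit.predict_rate(303.0) == pytest.approx(expected, rel=1e-12)

    def test_flat_arrhenius(self):
        fit = ArrheniusResults.from_params(Ea=0.0, lnA=2.0)
        for T in (10.0, 300.0, 5000.0):
            assert fit.predict_rate(T) == pytest.approx(np.exp(2.0))

    def test_printed_rate_constant_consistency(self):
        # tabulated (Ea, lnA) = (10.8, 14.0) evaluates to ~0.02 s^-1 at 303 K
        fit = ArrheniusResults.from_params(Ea=10.8, lnA=14.0)
        assert fit.predict_rate(303.0) == pytest.approx(0.02, abs=0.005)


class TestKIE:
    def test_identity(self):
        f = ArrheniusResults.from_params(Ea=10.0, lnA=15.0, se_Ea=0.5, se_lnA=0.8)
        dec = kie_decomposition(f, f, 303.0)
        assert dec.delta_Ea == 0.0
        assert dec.A_ratio == 1.0
        assert dec.kie_at_T == 1.0

    def test_consistency_by_construction(self):
        fH = ArrheniusResults.from_params(Ea=10.8, lnA=14.0)
        fD = ArrheniusResults.from_params(Ea=15.1, lnA=19.6)
        dec = kie_decomposition(fH, fD, 303.0)
        RT = GAS_CONSTANT_KCAL * 303.0
        assert dec.kie_at_T == pytest.approx(
            dec.A_ratio * np.exp(dec.delta_Ea / RT), rel=1e-12)

    def test_brute_force_formula(self):
        # delta_Ea=4.4, A_ratio=0.005 at 303 K: kie = 0.005*exp(4.4/0.602122)
        RT = GAS_CONSTANT_KCAL * 303.0
        expected = 0.005 * np.exp(4.4 / RT)
        fH = ArrheniusResults.from_params(Ea=0.0, lnA=0.0)
        fD = ArrheniusResults.from_params(Ea=4.4, lnA=-np.log(0.005))
        dec = kie_decomposition(fH, fD, 303.0)
        assert dec.kie_at_T == pytest.approx(expected, rel=1e-12)

    def test_common_lnA_shift_cancels(self):
        fH = ArrheniusResults.from_params(Ea=10.8, lnA=14.0)
        fD = ArrheniusResults.from_params(Ea=15.1, lnA=19.6)
        base = kie_decomposition(fH, fD, 303.0).kie_at_T
        for c in (-3.0, 2.5):
            fH2 = ArrheniusResults.from_params(Ea=10.8, lnA=14.0 + c)
            fD2 = ArrheniusResults.from_params(Ea=15.1, lnA=19.6 + c)
            assert kie_decomposition(fH2, fD2, 303.0).kie_at_T == \
                pytest.approx(base, rel=1e-12)

    def test_delta_method_vs_bootstrap(self):
        """First-order propagated SE of the KIE agrees with a parametric
        bootstrap (1000 resamples) within 15%."""
        temps = np.array([283.0, 293.0, 303.0, 313.0, 323.0])
        rng = np.random.default_rng(11)
        sigma = 0.03

        def noisy_fit(ea, lna, rng):
            k = np.exp(lna - ea / (GAS_CONSTANT_KCAL * temps))
            k = k * np.exp(rng.normal(0, sigma, size=temps.shape))
            return Arrhenius(temps, k).fit()

        fH = noisy_fit(10.8, 14.0, rng)
        fD = noisy_fit(15.1, 19.6, rng)
        dec = kie_decomposition(fH, fD, 303.0)
        boot = []
        for _ in range(1000):
            bH = noisy_fit(fH.Ea, fH.lnA, rng)
            bD = noisy_fit(fD.Ea, fD.lnA, rng)
            boot.append(kie_decomposition(bH, bD, 303.0).kie_at_T)
        se_boot = np.std(boot, ddof=1)
        assert dec.se_kie_at_T == pytest.approx(se_boot, rel=0.15)


class TestKIETable:
    def test_planted_values_recovered_at_zero_noise(self, noiseless_rates):
        table, truth = noiseless_rates
        df = kie_table(table)
        for variant, spec in truth["variants"].items():
            row = df[df["variant"] == variant].iloc[0]
            ea_h, lna_h = spec["H"]
            ea_d, lna_d = spec["D"]
            assert row["delta_Ea_kcal_per_mol"] == pytest.approx(ea_d - ea_h, abs=1e-6)
            assert row["A_ratio"] == pytest.approx(np.exp(lna_h - lna_d), rel=1e-6)

    def test_order_invariance(self, noiseless_rates):
        table, _ = noiseless_rates
        shuffled = RateTable(
            table.frame.sample(frac=1.0, random_state=3).reset_index(drop=True))
        df1 = kie_table(table)
        df2 = kie_table(shuffled)
        assert list(df1["variant"]) == list(df2["variant"])
        np.testing.assert_allclose(df1["kie"], df2["kie"], rtol=1e-12)

    def test_missing_isotope_skipped_with_warning(self, noiseless_rates):
        table, _ = noiseless_rates
        df_h_only = table.frame[~((table.frame["variant"] == "R1")
                                  & (table.frame["isotope"] == "D"))]
        with pytest.warns(UserWarning, match="R1"):
            df = kie_table(RateTable(df_h_only))
        assert "R1" not in set(df["variant"])

    def test_fit_from_table_matches_direct(self, noiseless_rates):
        table, truth = noiseless_rates
        res = fit_arrhenius_from_table(table, "R1", "H")
        assert res.Ea == pytest.approx(truth["variants"]["R1"]["H"][0], abs=1e-6)
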