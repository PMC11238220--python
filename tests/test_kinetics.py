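"""Kinetics fitting: rate-law algebra, parameter recovery against
independent grid-search oracles, F-test arithmetic, and the activity-panel
and profile utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from loxsense.datasets import ActivityProfile, RateDataset
from loxsense.errors import InputError
from loxsense.kinetics import (extra_ss_f_test, fit_inhibition,
                               fit_michaelis_menten, fit_thermal_inactivation,
                               inhibition_rate, michaelis_menten,
                               ph_activity_window, relative_activity_panel,
                               thermal_sigmoid)
from loxsense.synthetic import (KineticGroundTruth, StabilityGroundTruth,
                                gen_inhibition_dataset, gen_mm_dataset,
                                gen_thermal_profile)


class TestRateLaws:
    @pytest.mark.parametrize("model", ["competitive", "uncompetitive",
                                       "noncompetitive", "mixed"])
    def test_zero_inhibitor_reduces_to_michaelis_menten(self, model):
        S = np.array([0.05, 0.5, 5.0, 50.0])
        v = inhibition_rate(model, S, 0.0, Vmax=10.0, Km=0.5, Ki=2.0, alpha=1.5)
        assert v == pytest.approx(michaelis_menten(S, 10.0, 0.5), rel=1e-14)

    def test_mixed_with_alpha_one_is_noncompetitive(self):
        S = np.linspace(0.1, 20, 7)
        for I in (0.5, 3.0, 10.0):
            vm = inhibition_rate("mixed", S, I, 10.0, 0.5, 2.0, alpha=1.0)
            vn = inhibition_rate("noncompetitive", S, I, 10.0, 0.5, 2.0)
            assert vm == pytest.approx(vn, rel=1e-14)

    def test_competitive_half_maximal_point(self):
        """Direct algebra: at S = Km·(1+I/Ki) the competitive rate is Vmax/2."""
        Km, Ki, I, Vmax = 0.5, 2.0, 3.0, 10.0
        S = Km * (1 + I / Ki)
        assert inhibition_rate("competitive", S, I, Vmax, Km, Ki) == pytest.approx(Vmax / 2)

    def test_mixed_rate_hand_evaluation(self):
        """At S=Km, I=Ki, alpha=1 the mixed law gives Vmax·Km/(2Km·2) = Vmax/4."""
        assert inhibition_rate("mixed", 0.33, 7.94, 46.26, 0.33, 7.94,
                               alpha=1.0) == pytest.approx(46.26 / 4, rel=1e-14)

    def test_unknown_model_rejected(self):
        with pytest.raises(InputError):
            inhibition_rate("allosteric", 1.0, 1.0, 1.0, 1.0, 1.0)


class TestMichaelisMentenFit:
    def test_saturating_only_design_flagged_unidentifiable(self):
        df = pd.DataFrame({"substrate_mM": [50, 60, 70, 80, 90, 100.0],
                           "inhibitor_mM": 0.0, "replicate": 1,
                           "rate": [10.0] * 6})
        fit = fit_michaelis_menten(RateDataset("x", df))
        assert not fit.converged

    def test_inhibited_rows_rejected(self, avlox_mixed_truth):
        ds = gen_inhibition_dataset(avlox_mixed_truth)
        with pytest.raises(InputError):
            fit_michaelis_menten(ds)

    def test_noisy_fit_matches_grid_search_oracle(self):
        """curve_fit optimum agrees with a dense SSE grid search."""
        t = KineticGroundTruth(Km=0.62, kcat=14.06, noise_cv=0.03, seed=21)
        ds = gen_mm_dataset(t)
        fit = fit_michaelis_menten(ds)
        kms = np.linspace(0.3, 1.2, 181)  # 0.005 mM resolution
        vms = np.linspace(10, 18, 161)  # 0.05 1/s resolution
        KM, VM = np.meshgrid(kms, vms)
        sse = ((ds.rate[:, None, None]
                - VM * ds.substrate[:, None, None] / (KM + ds.substrate[:, None, None]))
               ** 2).sum(axis=0)
        j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.Km == pytest.approx(KM[j], abs=0.005)
        assert fit.Vmax == pytest.approx(VM[j], abs=0.05)

    def test_specificity_is_kcat_over_km(self):
        t = KineticGroundTruth(Km=0.62, kcat=14.06, noise_cv=0.0, seed=0)
        fit = fit_michaelis_menten(gen_mm_dataset(t))
        assert fit.specificity == fit.kcat / fit.Km

    def test_volumetric_rates_convert_to_kcat(self):
        """uM/min rates with a known monomer concentration give the same
        kcat as turnover-unit rates."""
        t = KineticGroundTruth(Km=0.5, kcat=30.0, enzyme_conc_uM=0.2,
                               noise_cv=0.0, seed=0)
        ds = gen_mm_dataset(t)
        vol = ds.data.copy()
        vol["rate"] = vol["rate"] * 60.0 * t.enzyme_conc_uM
        fit = fit_michaelis_menten(RateDataset("x", vol, "uM_per_min", 0.2))
        assert fit.kcat == pytest.approx(30.0, rel=1e-8)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(km=st.floats(0.1, 10.0), kcat=st.floats(1.0, 100.0))
def test_noiseless_mm_recovery_to_six_digits(km, kcat):
    """Noiseless model data anywhere in (Km, kcat) ∈ [0.1,10]×[1,100] is
    recovered to at least six significant digits."""
    t = KineticGroundTruth(Km=km, kcat=kcat, noise_cv=0.0, seed=0)
    fit = fit_michaelis_menten(gen_mm_dataset(t))
    assert fit.converged
    assert fit.Km == pytest.approx(km, rel=1e-6)
    assert fit.kcat == pytest.approx(kcat, rel=1e-6)


class TestFTest:
    def test_hand_computed_value(self):
        F, p = extra_ss_f_test(10.0, 10, 5.0, 9)
        assert F == pytest.approx(9.0, abs=1e-12)

    def test_matches_incomplete_beta_reference(self):
        """p-value agrees with the independent regularized-incomplete-beta
        form of the F survival function to 1e-10."""
        for rss_s, dof_s, rss_c, dof_c in [(10.0, 10, 5.0, 9), (3.0, 40, 2.5, 39),
                                           (7.0, 25, 5.0, 22)]:
            F, p = extra_ss_f_test(rss_s, dof_s, rss_c, dof_c)
            d1, d2 = dof_s - dof_c, dof_c
            p_ref = special.betainc(d2 / 2, d1 / 2, d2 / (d2 + d1 * F))
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_identical_fits_give_f_zero_p_one(self):
        assert extra_ss_f_test(5.0, 10, 5.0, 9) == (0.0, 1.0)

    def test_non_nested_dof_rejected(self):
        with pytest.raises(InputError):
            extra_ss_f_test(10.0, 9, 5.0, 9)


class TestInhibitionFitting:
    def test_noiseless_mixed_truth_recovered_and_selected(self, avlox_mixed_truth):
        fits, sel = fit_inhibition(gen_inhibition_dataset(avlox_mixed_truth))
        assert sel.chosen_model == "mixed"
        chosen = next(f for f in fits if f.model == "mixed")
        assert chosen.Ki == pytest.approx(avlox_mixed_truth.Ki, rel=1e-4)
        assert chosen.alpha == pytest.approx(1.5, rel=1e-3)

    def test_noiseless_competitive_truth_selects_competitive(self):
        """Both laws interpolate competitive-generated data to round-off;
        the extra parameter must not be declared significant."""
        t = KineticGroundTruth(Km=0.5, kcat=20.0, inhibition_model="competitive",
                               Ki=2.0, noise_cv=0.0, seed=0)
        fits, sel = fit_inhibition(gen_inhibition_dataset(t))
        assert sel.chosen_model == "competitive"
        for simple, cplx, F, p, winner in sel.pairwise:
            if simple == "competitive":
                assert p > sel.alpha_level

    def test_all_zero_inhibitor_rejected(self, avlox_mixed_truth):
        ds = gen_inhibition_dataset(avlox_mixed_truth, inhibitor_concs=[0.0])
        with pytest.raises(InputError):
            fit_inhibition(ds)

    def test_noisy_selection_recovers_generating_model_mostly(self):
        """At CV 3%, n=3 and the assayed concentration design, selection
        recovers a mixed truth (alpha=2) in >= 90% of seeded simulations."""
        hits = 0
        for seed in range(40):
            t = KineticGroundTruth(Km=0.33, kcat=46.26, inhibition_model="mixed",
                                   Ki=7.94, alpha=2.0, noise_cv=0.03, seed=seed)
            _, sel = fit_inhibition(gen_inhibition_dataset(t))
            hits += sel.chosen_model == "mixed"
        assert hits >= 36


class TestActivityUtilities:
    def test_reference_condition_is_100pct(self):
        df = pd.DataFrame({"electron_acceptor": ["O2"], "electron_donor": ["L-lactate"],
                           "rate": [2.0]})
        out = relative_activity_panel(df)
        assert out["relative_activity_pct"].iloc[0] == 100.0

    def test_two_percent_ratio(self):
        df = pd.DataFrame({
            "electron_acceptor": ["O2", "O2"],
            "electron_donor": ["L-lactate", "glycolate"],
            "rate": [2.0, 0.04]})
        out = relative_activity_panel(df)
        assert out.loc[out["electron_donor"] == "glycolate",
                       "relative_activity_pct"].iloc[0] == pytest.approx(2.0)

    def test_negative_rate_rejected(self):
        df = pd.DataFrame({"electron_acceptor": ["O2"], "electron_donor": ["L-lactate"],
                           "rate": [-1.0]})
        with pytest.raises(InputError):
            relative_activity_panel(df)

    def test_flat_ph_profile_returns_full_range(self):
        prof = ActivityProfile("pH", np.arange(4.5, 9.6, 0.5),
                               np.full(11, 90.0))
        win = ph_activity_window(prof)
        assert (win.pH_low, win.pH_high) == (4.5, 9.5)

    def test_window_endpoints_on_measured_grid(self):
        """A profile above 80% exactly at pH 7.0–8.5 yields that window."""
        ph = np.arange(4.5, 9.6, 0.5)
        act = np.where((ph >= 7.0) & (ph <= 8.5), 90.0, 50.0)
        act[ph == 7.5] = 100.0
        win = ph_activity_window(ActivityProfile("pH", ph, act))
        assert (win.pH_low, win.pH_high) == (7.0, 8.5)

    def test_single_point_window_degenerate(self):
        ph = np.arange(6.0, 9.1, 0.5)
        act = np.array([10, 20, 30, 100, 30, 20, 10.0])
        win = ph_activity_window(ActivityProfile("pH", ph, act))
        assert win.pH_low == win.pH_high == 7.5


class TestThermalFit:
    def test_noiseless_t50_recovery(self):
        prof = gen_thermal_profile(StabilityGroundTruth(T50=54.9, noise_cv=0.0))
        fit = fit_thermal_inactivation(prof)
        assert fit.converged
        assert round(fit.T50, 1) == 54.9

    def test_reflection_symmetry(self):
        """Reflecting the profile about T50 leaves the fitted T50 unchanged
        (logistic symmetry)."""
        t50 = 48.0
        temps = np.arange(30.0, 66.5, 2.5)
        act = thermal_sigmoid(temps, t50, 2.0)
        fit_a = fit_thermal_inactivation(ActivityProfile("temperature_C", temps, act))
        fit_b = fit_thermal_inactivation(
            ActivityProfile("temperature_C", 2 * t50 - temps, 100.0 - act))
        assert fit_a.T50 == pytest.approx(t50, abs=1e-6)
        assert fit_b.T50 == pytest.approx(t50, abs=1e-6)

    def test_noisy_t50_matches_grid_oracle(self):
        """Fitted T50 agrees with a 0.01 °C grid-search SSE minimizer."""
        prof = gen_thermal_profile(StabilityGroundTruth(T50=42.5, noise_cv=0.02, seed=3))
        fit = fit_thermal_inactivation(prof)
        t50s = np.arange(40.0, 45.0, 0.01)
        widths = np.arange(1.0, 4.0, 0.01)
        T50G, WG = np.meshgrid(t50s, widths)
        sse = ((prof.activity_pct[:, None, None]
                - thermal_sigmoid(prof.x[:, None, None], T50G, WG)) ** 2).sum(axis=0)
        j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.T50 == pytest.approx(T50G[j], abs=0.01)

    def test_flat_profile_flagged(self):
        prof = ActivityProfile("temperature_C", np.arange(30, 55, 5.0),
                               np.full(5, 80.0))
        assert not fit_thermal_inactivation(prof).converged
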