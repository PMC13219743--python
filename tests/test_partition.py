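"""Slope fitting, the potential formula, background subtraction and the
guild partition arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nitrisip import partition as P
from nitrisip import synthetic as syn

TIMES = (2.0, 4.0, 8.0, 20.0, 22.0, 24.0)


def series(conc, combo=frozenset({"NaClO3"}), analyte="NO2", rep="r1",
           times=TIMES):
    return P.SlurryTimeSeries(
        soil="s", substrate="urea", inhibitor_combo=combo, analyte=analyte,
        replicate=rep, times_h=times, conc_mgN_L=tuple(float(c) for c in conc),
    )


class TestFitRate:
    def test_exact_line(self):
        s = series([0.2 * t + 1 for t in TIMES])
        fit = P.fit_rate(s)
        assert fit.slope == pytest.approx(0.2)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.qc_pass

    def test_flat_series_degenerate(self):
        fit = P.fit_rate(series([1.0] * 6))
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0
        assert not fit.qc_pass
        assert "constant_concentration" in fit.flags

    def test_against_closed_form_ols(self):
        """Hand least-squares on the six-point fixture."""
        conc = (1.1, 1.9, 4.2, 10.1, 10.9, 12.2)
        t = np.array(TIMES)
        c = np.array(conc)
        sxy = ((t - t.mean()) * (c - c.mean())).sum()
        sxx = ((t - t.mean()) ** 2).sum()
        syy = ((c - c.mean()) ** 2).sum()
        fit = P.fit_rate(series(conc))
        assert fit.slope == pytest.approx(sxy / sxx, rel=1e-12)
        assert fit.intercept == pytest.approx(c.mean() - sxy / sxx * t.mean(), rel=1e-12)
        assert fit.r_squared == pytest.approx(sxy**2 / (sxx * syy), rel=1e-12)


class TestPotentialFormula:
    def test_zero_rate(self):
        fit = P.fit_rate(series([1.0] * 6))
        assert P.nitrification_potential(fit, V=0.01, m=0.01).np_mg_kg_d == 0.0

    def test_direct_arithmetic(self):
        fit = P.RateFit(slope=0.5, intercept=0, r_squared=1, qc_pass=True, n_points=6)
        a = P.nitrification_potential(fit, V=0.005, m=0.0095)
        assert a.np_mg_kg_d == pytest.approx(0.5 * (0.105 / 0.0095) * 24)
        assert a.np_mg_kg_d == pytest.approx(132.63, abs=0.01)

    def test_linearity(self):
        f1 = P.RateFit(0.3, 0, 1, True, 6)
        f2 = P.RateFit(0.6, 0, 1, True, 6)
        np1 = P.nitrification_potential(f1, 0.005, 0.01).np_mg_kg_d
        assert P.nitrification_potential(f2, 0.005, 0.01).np_mg_kg_d == pytest.approx(2 * np1)
        assert P.nitrification_potential(f1, 0.005, 0.02).np_mg_kg_d == pytest.approx(np1 / 2)

    @given(
        st.floats(0.0, 10.0), st.floats(0.0, 0.05),
        st.floats(1e-4, 0.1),
    )
    @settings(max_examples=200, deadline=None)
    def test_closed_form_identity(self, r, v, m):
        fit = P.RateFit(r, 0.0, 1.0, True, 6)
        got = P.nitrification_potential(fit, v, m).np_mg_kg_d
        assert got == pytest.approx(r * (0.1 + v) / m * 24.0, rel=1e-9, abs=1e-12)

    def test_nonpositive_mass_rejected(self):
        fit = P.RateFit(0.1, 0, 1, True, 6)
        with pytest.raises(ValueError, match="dry mass"):
            P.nitrification_potential(fit, 0.005, 0.0)


class TestBackgroundSubtraction:
    def assay(self, np_val, analyte="NO2"):
        return P.PotentialAssay(soil="s", substrate="urea",
                                inhibitor_combo=frozenset({"NaClO3"}),
                                analyte=analyte, np_mg_kg_d=np_val)

    def test_simple_subtraction(self):
        net = P.subtract_background(self.assay(10.0), self.assay(2.0))
        assert net.np_mg_kg_d == pytest.approx(8.0)
        assert net.background_subtracted

    def test_negative_net_flagged_not_clamped(self):
        net = P.subtract_background(self.assay(1.0), self.assay(3.0))
        assert net.np_mg_kg_d == pytest.approx(-2.0)
        assert "negative_net_potential" in net.flags

    def test_zero_background_flagged(self):
        net = P.subtract_background(self.assay(5.0), self.assay(0.0))
        assert net.np_mg_kg_d == pytest.approx(5.0)
        assert "zero_background" in net.flags

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            P.subtract_background(self.assay(5.0), self.assay(1.0, analyte="NO3"))


def assay_set(np_aoa, np_aob, np_com, np_ab=None, np_com_co=None):
    vals = {
        (frozenset({"NaClO3"}), "NO2"): np_ab if np_ab is not None else np_aoa + np_aob,
        (frozenset({"NaClO3"}), "NO3"): np_com_co if np_com_co is not None else np_com,
        (frozenset({"NaClO3", "Sim"}), "NO2"): np_aob,
        (frozenset({"NaClO3", "DMPP"}), "NO2"): np_aoa,
        (frozenset({"NaClO3", "Sim", "DMPP"}), "NO3"): np_com,
    }
    return {
        k: P.PotentialAssay(soil="s", substrate="urea", inhibitor_combo=k[0],
                            analyte=k[1], np_mg_kg_d=v)
        for k, v in vals.items()
    }


class TestPartition:
    def test_ck_like_scheme_i_percentages(self):
        """AOA 1.9, AOB 12.4, comammox 8.4 -> 8.4% / 54.6% / 37.0%."""
        r = P.partition_contributions(assay_set(1.9, 12.4, 8.4))
        assert r.pct_scheme_i["AOA"] == pytest.approx(8.4, abs=0.05)
        assert r.pct_scheme_i["AOB"] == pytest.approx(54.6, abs=0.05)
        assert r.pct_scheme_i["comammox"] == pytest.approx(37.0, abs=0.05)

    def test_scheme_u_symmetry(self):
        r = P.partition_contributions(assay_set(1.0, 2.0, 5.0, np_ab=5.0, np_com_co=5.0))
        assert r.pct_scheme_u["AOA+AOB"] == pytest.approx(50.0)
        assert r.pct_scheme_u["comammox"] == pytest.approx(50.0)

    def test_percentages_sum_to_100(self):
        r = P.partition_contributions(assay_set(1.3, 8.1, 6.7))
        assert sum(r.pct_scheme_i.values()) == pytest.approx(100.0, abs=1e-9)
        assert sum(r.pct_scheme_u.values()) == pytest.approx(100.0, abs=1e-9)

    def test_negative_component_floored_with_warning(self):
        r = P.partition_contributions(assay_set(-0.5, 4.0, 4.0))
        assert r.pct_scheme_i["AOA"] == 0.0
        assert sum(r.pct_scheme_i.values()) == pytest.approx(100.0)
        assert any("floored" in f for f in r.flags)

    def test_missing_assay_names_the_arm(self):
        assays = assay_set(1.0, 2.0, 3.0)
        del assays[(frozenset({"NaClO3", "Sim", "DMPP"}), "NO3")]
        with pytest.raises(KeyError, match="comammox_alone"):
            P.partition_contributions(assays)

    def test_interaction_indices(self):
        r = P.partition_contributions(
            assay_set(2.0, 3.0, 4.0, np_ab=4.0, np_com_co=6.0)
        )
        assert r.delta_ab == pytest.approx(4.0 - 5.0)
        assert r.delta_c == pytest.approx(6.0 - 4.0)


class TestGeneratorRecovery:
    PROTO0 = syn.SlurryProtocol(measurement_sd=0.0)

    def run_partition(self, rates, proto, seed=0):
        rows = []
        for k, combo in enumerate(syn.SCENARIO_COMBOS):
            rows.extend(
                syn.simulate_slurry(rates, syn.InhibitorDesign(), proto, combo,
                                    seed=seed * 100 + k)
            )
        df = syn._slurry_table(rows)
        results, _ = P.partition_from_table(
            df, V=proto.soil_water_volume, m=proto.soil_dry_mass
        )
        return results[0]

    def test_noise_free_recovery_exact(self):
        """Noise-free slurry: recovered Np equals rate*(0.1+V)/m*24 per arm."""
        rates = syn.GuildRates(aoa_rate=0.006, aob_rate=0.041,
                               comammox_nitrate_rate=0.033, interaction_ab=0.85,
                               heterotrophic_background_rate=0.001)
        r = self.run_partition(rates, self.PROTO0)
        factor = 0.105 / 0.0095 * 24
        design = syn.InhibitorDesign()
        for (combo, analyte), role in P.ASSAY_ROLES.items():
            truth = syn.effective_rates(rates, design, combo)[analyte] * factor
            got = {
                "AOA": r.np_aoa, "AOB": r.np_aob,
                "comammox_alone": r.np_comammox_alone,
                "AOA+AOB": r.np_aoa_plus_aob,
                "comammox_coexist": r.np_comammox_coexist,
            }[role]
            assert got == pytest.approx(truth, rel=1e-6)

    def test_additive_truth_gives_zero_delta(self):
        rates = syn.GuildRates(aoa_rate=0.01, aob_rate=0.03,
                               comammox_nitrate_rate=0.02, interaction_ab=1.0)
        r = self.run_partition(rates, self.PROTO0)
        assert r.delta_ab == pytest.approx(0.0, abs=1e-9)
        assert r.delta_c == pytest.approx(0.0, abs=1e-9)


class TestInteractionReport:
    def test_additivity_classification(self):
        r = P.partition_contributions(assay_set(2.0, 3.0, 4.0))
        rep = P.interaction_report([r])
        assert rep.loc[0, "class_AB"] == "additivity"
        assert rep.loc[0, "class_C"] == "additivity"

    def test_antagonism_classification(self):
        r = P.partition_contributions(assay_set(2.0, 3.0, 4.0, np_ab=3.0))
        rep = P.interaction_report([r])
        assert rep.loc[0, "class_AB"] == "antagonism"

    def test_wi2_boost_raises_scheme_u_share(self, wi2_scenario):
        results, _ = P.partition_from_table(wi2_scenario.slurry, V=0.005, m=0.0095)
        rep = P.interaction_report(results)
        assert rep.loc[0, "comammox_share_U"] > rep.loc[0, "comammox_share_I"]

    def test_ck_shares_agree_within_tolerance(self, ck_scenario):
        results, _ = P.partition_from_table(ck_scenario.slurry, V=0.005, m=0.0095)
        r = results[0]
        # no coexistence boost: shares differ only through the (mild)
        # interaction and noise
        assert abs(r.pct_scheme_u["comammox"] - r.pct_scheme_i["comammox"]) < 8.0

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            P.interaction_report([])
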