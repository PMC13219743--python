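"""Generator correctness: closed-form gradient oracle, inhibitor kinetics
arithmetic, planted ASV enrichment, and determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import ks_2samp, norm

from nitrisip import synthetic as syn
from nitrisip.partition import ASSAY_ROLES

from conftest import single_gene_truth


class TestGradient:
    def test_no_label_identity(self):
        """With p = 0 and no noise the 13C profiles equal the 12C control."""
        pairs = syn.simulate_gradient(
            single_gene_truth(0.0), syn.GradientProtocol(noise_cv=0.0), seed=1
        )
        pair = pairs["gene"]
        for p12, p13 in zip(pair.profiles_12C, pair.profiles_13C):
            assert p12.copies == p13.copies

    def test_labeled_peak_position_and_tail_mass_quadrature(self):
        """gc=0.5, full labeling -> labeled peak at 1.745 g/ml; the noise-free
        mass at densities >= 1.727 matches numerical quadrature of the
        two-component mixture density."""
        p_true = 0.6
        truth = single_gene_truth(p_true, gc=0.5, atom_excess=1.0)
        g = truth.genes["gene"]
        assert g.unlabeled_peak == pytest.approx(1.709)
        assert g.labeled_peak == pytest.approx(1.745)

        proto = syn.GradientProtocol(noise_cv=0.0, n_replicates=1)
        pair = syn.simulate_gradient(truth, proto, seed=0)["gene"]
        prof = pair.profiles_13C[0]
        copies = np.asarray(prof.copies)
        dens = np.asarray(prof.densities)
        edges = proto.bin_edges()
        # empirical mass in whole bins lying at density >= 1.727
        sel = dens >= 1.727
        lo_edge = edges[1:][sel].min()

        def mixture(x):
            return (1 - p_true) * norm.pdf(x, 1.709, proto.peak_sd) + \
                p_true * norm.pdf(x, 1.745, proto.peak_sd)

        expected, _ = quad(mixture, lo_edge, edges[0])
        observed = copies[sel].sum() / g.total_copies
        assert observed == pytest.approx(expected, abs=1e-6)
        # nearly all of that mass is the labeled subpopulation
        assert observed == pytest.approx(p_true, abs=0.01)

    def test_fraction_one_is_densest_and_decreasing(self):
        proto = syn.GradientProtocol()
        mids = proto.midpoints()
        assert np.all(np.diff(mids) < 0)
        assert mids[0] > 1.75

    def test_noise_free_relative_abundance_sums_to_one(self):
        pairs = syn.simulate_gradient(
            single_gene_truth(0.4), syn.GradientProtocol(noise_cv=0.0), seed=0
        )
        copies = np.asarray(pairs["gene"].profiles_13C[0].copies)
        rel = copies / copies.sum()
        assert rel.sum() == pytest.approx(1.0, abs=1e-9)

    def test_determinism_same_seed(self):
        a = syn.simulate_gradient(single_gene_truth(0.3), seed=42)
        b = syn.simulate_gradient(single_gene_truth(0.3), seed=42)
        assert a["gene"].profiles_13C[0].copies == b["gene"].profiles_13C[0].copies

    def test_different_seeds_distributionally_identical(self):
        """Heavy-tail mass summary statistic from two seed streams comes from
        the same distribution (KS test)."""
        proto = syn.GradientProtocol(n_replicates=1)
        truth = single_gene_truth(0.5)

        def draws(seed0, n=1000):
            out = np.empty(n)
            for i in range(n):
                prof = syn.simulate_gradient(truth, proto, seed=seed0 + i)["gene"].profiles_13C[0]
                c = np.asarray(prof.copies)
                out[i] = c[:5].sum() / c.sum()
            return out

        stat = ks_2samp(draws(0), draws(10_000))
        assert stat.pvalue > 0.01

    def test_rejects_labeled_peak_beyond_gradient(self):
        truth = single_gene_truth(0.5, gc=0.9)  # d0 = 1.7482, labeled 1.7842
        with pytest.raises(ValueError, match="labeled peak"):
            syn.simulate_gradient(truth, syn.GradientProtocol(), seed=0)


class TestSlurry:
    RATES = syn.GuildRates(
        aoa_rate=1.0, aob_rate=2.0, comammox_nitrate_rate=0.5,
        interaction_ab=0.7, heterotrophic_background_rate=0.1,
    )
    DESIGN = syn.InhibitorDesign()

    def test_full_inhibition_isolates_comammox(self):
        """NaClO3+Sim+DMPP: NO2- carries only background, NO3- the comammox
        rate without boost."""
        r = syn.effective_rates(self.RATES, self.DESIGN,
                                frozenset({"NaClO3", "Sim", "DMPP"}))
        assert r["NO2"] == pytest.approx(0.1)
        assert r["NO3"] == pytest.approx(0.5 + 0.1)

    def test_interaction_multiplier_arithmetic(self):
        """NaClO3 alone with interaction 0.7: NO2- rate = 0.7*(1+2)."""
        rates = syn.GuildRates(aoa_rate=1.0, aob_rate=2.0, comammox_nitrate_rate=0.0,
                               interaction_ab=0.7)
        r = syn.effective_rates(rates, self.DESIGN, frozenset({"NaClO3"}))
        assert r["NO2"] == pytest.approx(2.1)

    def test_additivity_invariant_without_interaction(self):
        """With interaction 1: rate(NaClO3) = rate(+Sim) + rate(+DMPP) - bg."""
        rates = syn.GuildRates(aoa_rate=0.8, aob_rate=1.7, comammox_nitrate_rate=0.4,
                               interaction_ab=1.0, heterotrophic_background_rate=0.15)
        e = lambda c: syn.effective_rates(rates, self.DESIGN, frozenset(c))["NO2"]
        assert e({"NaClO3"}) == pytest.approx(
            e({"NaClO3", "Sim"}) + e({"NaClO3", "DMPP"}) - 0.15
        )

    def test_nob_transfers_nitrite_to_nitrate(self):
        """Without NaClO3, surviving NOB move the ammonia-oxidizer flux to NO3-."""
        r = syn.effective_rates(self.RATES, self.DESIGN, frozenset())
        ao = 0.7 * (1.0 + 2.0)
        assert r["NO2"] == pytest.approx(0.1)
        assert r["NO3"] == pytest.approx(0.5 + ao + 0.1)

    def test_boost_requires_active_ammonia_oxidizers(self):
        rates = syn.GuildRates(aoa_rate=1.0, aob_rate=1.0, comammox_nitrate_rate=1.0,
                               comammox_coexistence_boost=2.0)
        with_ao = syn.effective_rates(rates, self.DESIGN, frozenset({"NaClO3"}))
        without = syn.effective_rates(rates, self.DESIGN,
                                      frozenset({"NaClO3", "Sim", "DMPP"}))
        assert with_ao["NO3"] == pytest.approx(2.0)
        assert without["NO3"] == pytest.approx(1.0)

    def test_null_process_is_flat(self):
        rates = syn.GuildRates(aoa_rate=0, aob_rate=0, comammox_nitrate_rate=0)
        proto = syn.SlurryProtocol(measurement_sd=0.0, initial_conc=0.3)
        for s in syn.simulate_slurry(rates, self.DESIGN, proto, frozenset()):
            assert s.conc_mgN_L == tuple([0.3] * 6)

    def test_unknown_inhibitor_rejected(self):
        with pytest.raises(ValueError, match="unknown inhibitor"):
            syn.effective_rates(self.RATES, self.DESIGN, frozenset({"ATU"}))


class TestAsvCounts:
    def test_near_zero_dispersion_counts_match_mean(self):
        df = syn.simulate_asv_counts({"a": "unlabeled"}, base_means=500.0,
                                     dispersion=1e-8, n_replicates=50, seed=0)
        assert df["count"].mean() == pytest.approx(500.0, rel=0.05)

    def test_planted_fold_change_by_context(self):
        """organic_only at fold 8: 13C/12C mean ratio ~8 under acetylene and
        ~1 without inhibitor (sample-mean oracle on 10,000 draws)."""
        classes = {f"a{i}": "organic_only" for i in range(100)}
        df = syn.simulate_asv_counts(classes, base_means=200.0, fold_change=8.0,
                                     dispersion=0.1, n_replicates=25, seed=3)
        m = df.groupby(["context", "isotope"])["count"].mean()
        assert m["ace"]["13C"] / m["ace"]["12C"] == pytest.approx(8.0, rel=0.1)
        assert m["no_inhibitor"]["13C"] / m["no_inhibitor"]["12C"] == pytest.approx(1.0, rel=0.1)

    def test_both_class_enriched_in_both_contexts(self):
        df = syn.simulate_asv_counts({f"a{i}": "both" for i in range(50)},
                                     fold_change=8.0, n_replicates=10, seed=1)
        m = df.groupby(["context", "isotope"])["count"].mean()
        for ctx in ("ace", "no_inhibitor"):
            assert m[ctx]["13C"] > 3 * m[ctx]["12C"]

    def test_dispersion_must_be_positive(self):
        with pytest.raises(ValueError, match="dispersion"):
            syn.simulate_asv_counts({"a": "both"}, dispersion=0.0)


class TestScenario:
    def test_wi2_truth_encodes_boost_and_antagonism(self, wi2_scenario):
        t = wi2_scenario.truth.guild_rates
        assert t.comammox_coexistence_boost > 1
        assert t.interaction_ab < 1

    def test_ck_has_no_boost(self, ck_scenario):
        assert ck_scenario.truth.guild_rates.comammox_coexistence_boost == 1.0

    def test_truth_json_roundtrip_and_determinism(self):
        a = syn.make_scenario("WI1", seed=9)
        b = syn.make_scenario("WI1", seed=9)
        assert a.truth.to_json() == b.truth.to_json()
        assert syn.ScenarioTruth.from_json(a.truth.to_json()) == a.truth
        pd.testing.assert_frame_equal(a.slurry, b.slurry)
        pd.testing.assert_frame_equal(a.gradients, b.gradients)

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            syn.make_scenario("XX", seed=0)

    def test_scenario_covers_required_assays(self, ck_scenario):
        combos = {
            (frozenset(c.split("+")) if c != "none" else frozenset(), a)
            for c, a in ck_scenario.slurry.groupby(["inhibitor_combo", "analyte"]).groups
        }
        assert set(ASSAY_ROLES) <= combos

    def test_write_outputs(self, tmp_path):
        syn.make_scenario("CK", seed=0, out_dir=tmp_path)
        for f in ("gradients.tsv", "slurry.tsv", "totals.tsv", "asv_counts.tsv",
                  "truth.json"):
            assert (tmp_path / f).exists()
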