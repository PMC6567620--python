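"""Generator contracts: factorial design, determinism, planted effects, truncation."""
import numpy as np
import pandas as pd
import pytest

import bloomline as bl
from bloomline.exceptions import DegenerateInputError, InvalidParameterError
from bloomline.simulate import (
    GeneratorParams,
    default_taxonomy,
    generate_community,
    generate_design,
    generate_metabolites,
    generate_survival,
    sequence_sample,
    standardize,
)


class TestDesign:
    def test_full_factorial_cell_counts(self):
        d = generate_design(12, seed=0)
        assert len(d) == 144
        cells = d.groupby(["site", "sex", "treatment"], observed=True).size()
        assert (cells == 12).all() and len(cells) == 12

    def test_single_mouse_per_cell(self):
        d = generate_design(1, seed=0)
        assert len(d) == 12

    def test_one_mouse_per_cage_and_age_window(self):
        d = generate_design(12, seed=3)
        assert d["cage_id"].is_unique
        assert d["sampling_age"].between(762, 973).all()

    def test_seed_determinism(self):
        a, b, c = generate_design(4, seed=5), generate_design(4, seed=5), generate_design(4, seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert not a["sampling_age"].equals(c["sampling_age"])

    @pytest.mark.parametrize("bad", [0, -1, 2.5])
    def test_invalid_n_per_cell(self, bad):
        with pytest.raises(InvalidParameterError):
            generate_design(bad, seed=0)


class TestCommunity:
    def test_unknown_site_bloom_map(self):
        d = generate_design(1, seed=0)
        params = GeneratorParams(bloom_otu_by_site={"TJL": "OTU-1"})
        with pytest.raises(InvalidParameterError):
            generate_community(d, params, seed=0)

    def test_null_mode_no_treatment_shift(self):
        # under null params treated and control bloom-OTU densities share a distribution
        d = generate_design(40, seed=1)
        dens = generate_community(d, GeneratorParams.null(), seed=1)
        trt = d["treatment"].astype(str) == "ACA"
        ratio = dens.loc[trt, "OTU-1"].median() / dens.loc[~trt, "OTU-1"].median()
        assert 0.7 < ratio < 1.4

    def test_planted_folds_recovered_in_densities(self):
        d = generate_design(60, seed=2)
        params = GeneratorParams()
        dens = generate_community(d, params, seed=2)
        trt = (d["treatment"].astype(str) == "ACA").to_numpy()
        tjl = (d["site"].astype(str) == "TJL").to_numpy()
        ratio = dens.loc[trt & tjl, "OTU-1"].median() / dens.loc[~trt & tjl, "OTU-1"].median()
        assert ratio == pytest.approx(4.3, rel=0.25)
        other = dens["OTU-12"]
        r_other = other[trt].median() / other[~trt].median()
        assert r_other == pytest.approx(0.5, rel=0.35)

    def test_site_restricted_otu_absent_elsewhere(self):
        d = generate_design(6, seed=0)
        dens = generate_community(d, GeneratorParams(), seed=0)
        outside = d["site"].astype(str) != "UT"
        assert (dens.loc[outside, "OTU-4"] < 1e-10).all()


class TestSequencing:
    def test_all_spike_when_community_empty(self):
        params = GeneratorParams(n_otus=3, sequencing_depth=500)
        counts, spike = sequence_sample(np.zeros(3), 0.05, 10.0, params, seed=0)
        assert counts.sum() == 0 and spike == 500

    def test_degenerate_no_spike_no_community(self):
        params = GeneratorParams(n_otus=2, spike_copies_per_uL=0.0)
        with pytest.raises(DegenerateInputError):
            sequence_sample(np.zeros(2), 0.05, 10.0, params, seed=0)

    def test_expected_spike_fraction_closed_form(self):
        # MC mean of the spike read fraction matches spike/(spike+endemic)
        params = GeneratorParams(n_otus=2, sequencing_depth=1000, spike_copies_per_uL=1e5)
        dens = np.array([1e7, 3e7])
        weight, vol = 0.05, 10.0
        expected = (1e5 * vol) / (1e5 * vol + dens.sum() * weight)
        fracs = [
            sequence_sample(dens, weight, vol, params, seed=s)[1] / 1000 for s in range(300)
        ]
        assert np.mean(fracs) == pytest.approx(expected, rel=0.05)

    def test_doubling_depth_preserves_proportions(self):
        dens = np.array([2e6, 6e6, 2e6])
        p1 = GeneratorParams(n_otus=3, sequencing_depth=2000)
        p2 = GeneratorParams(n_otus=3, sequencing_depth=4000)
        c1 = np.mean([sequence_sample(dens, 0.05, 10.0, p1, seed=s)[0] for s in range(200)], axis=0)
        c2 = np.mean([sequence_sample(dens, 0.05, 10.0, p2, seed=s)[0] for s in range(200)], axis=0)
        np.testing.assert_allclose(c2 / c1, 2.0, rtol=0.05)


class TestMetabolites:
    def test_negative_noise_sd_rejected(self):
        with pytest.raises(InvalidParameterError):
            GeneratorParams(metabolite_noise_sd=-0.1)

    def test_null_coupling_independence(self):
        d = generate_design(40, seed=4)
        params = GeneratorParams.null()
        dens = generate_community(d, params, seed=4)
        panel = generate_metabolites(dens, d, params, seed=4)
        rho, p = bl.spearman_with_t(np.log1p(dens["OTU-1"]), np.log(panel["propionate"]))
        assert abs(rho) < 0.15

    def test_planted_propionate_coupling_sign(self):
        d = generate_design(40, seed=4)
        params = GeneratorParams()
        dens = generate_community(d, params, seed=4)
        panel = generate_metabolites(dens, d, params, seed=4)
        site = d["site"].astype(str) == "TJL"  # within one site, coupling is positive
        rho, p = bl.spearman_with_t(dens.loc[site, "OTU-1"], panel.loc[site, "propionate"])
        assert rho > 0.2 and p < 0.01

    def test_acetate_butyrate_latent_correlation(self):
        d = generate_design(40, seed=5)
        params = GeneratorParams()
        dens = generate_community(d, params, seed=5)
        panel = generate_metabolites(dens, d, params, seed=5)
        rho, p = bl.spearman_with_t(panel["acetate"], panel["butyrate"])
        assert rho > 0.3 and p < 1e-4


class TestSurvival:
    def _table(self, n_per_cell, params, seed, betas=True):
        d = generate_design(n_per_cell, seed=seed)
        rng = np.random.default_rng(seed)
        scfa = pd.DataFrame(
            rng.normal(size=(len(d), 3)), index=d.index, columns=["propionate", "butyrate", "acetate"]
        )
        scfa = standardize(scfa, scfa.columns)
        return d, scfa, generate_survival(d, scfa, params, seed=seed)

    def test_truncation_contract(self):
        _, _, t = self._table(12, GeneratorParams(), seed=0)
        assert (t["time"] > t["entry"]).all()
        assert (t["event"] == 1).all()

    def test_null_betas_independence(self):
        d, scfa, t = self._table(40, GeneratorParams.null(), seed=1)
        rho, p = bl.spearman_with_t(scfa["propionate"], t["time"])
        assert abs(rho) < 0.1

    def test_planted_betas_recovered_by_cox(self):
        _, _, t = self._table(167, GeneratorParams(), seed=2)  # ~2000 mice
        fit = bl.cox_fit(t, ["propionate", "butyrate", "acetate"])
        assert fit.hr["propionate"] == pytest.approx(0.674, rel=0.10)
        assert fit.hr["butyrate"] == pytest.approx(0.586, rel=0.10)
        assert fit.hr["acetate"] == pytest.approx(1.576, rel=0.10)

    def test_invalid_weibull(self):
        with pytest.raises(InvalidParameterError):
            GeneratorParams(weibull_shape=-1.0)


class TestCohortDeterminism:
    def test_identical_seed_bit_identical(self):
        a = bl.simulate_cohort(seed=9, n_per_cell=2)
        b = bl.simulate_cohort(seed=9, n_per_cell=2)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.metabolites, b.metabolites)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)

    def test_different_seed_differs(self):
        a = bl.simulate_cohort(seed=9, n_per_cell=2)
        c = bl.simulate_cohort(seed=10, n_per_cell=2)
        assert not a.counts.equals(c.counts)

    def test_roundtrip_write_read(self, tmp_path):
        cohort = bl.simulate_cohort(seed=9, n_per_cell=1)
        cohort.write(tmp_path)
        counts = bl.io.read_counts(tmp_path / "counts.tsv")
        tax = bl.io.read_taxonomy(tmp_path / "taxonomy.tsv")
        meta = bl.io.read_metadata(tmp_path / "metadata.tsv")
        cm = bl.io.build_count_matrix(counts, tax, meta)
        pd.testing.assert_frame_equal(cm.counts, cohort.counts, check_names=False)
        assert (cm.spike_counts == cohort.spike_counts).all()

    def test_taxonomy_families(self):
        tax = default_taxonomy(200)
        assert tax.loc["OTU-1", "family"] == "Muribaculaceae"
        assert tax.loc["OTU-4", "family"] == "Muribaculaceae"
        assert tax.loc["OTU-2", "family"] == "Lactobacillaceae"
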