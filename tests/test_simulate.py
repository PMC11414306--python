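"""Generator correctness: residual-intake construction, count model limits,
compositional clade structure and the VFA arithmetic identities."""

import numpy as np
import pandas as pd
import pytest

import rumennet as rn
from rumennet.simulate import COMPONENT_ACIDS, VFA_NAMES


class TestPhenotypes:
    def test_zero_noise_zero_shift_gives_zero_rfi(self):
        params = rn.PhenotypeParams(noise_sd=0.0, group_shift=0.0)
        table = rn.simulate_phenotypes(rn.CohortDesign(n_per_group=4, seed=0), params)
        assert np.allclose(table["rfi"], 0.0, atol=1e-9)

    def test_within_breed_residual_properties(self, small_cohort):
        # least-squares residuals: zero mean and exact orthogonality to the
        # regressors inside each breed
        for _, grp in small_cohort.phenotypes.groupby("breed"):
            assert abs(grp["rfi"].mean()) < 1e-9
            for reg in ("adg", "metabolic_weight"):
                assert abs(np.corrcoef(grp["rfi"], grp[reg])[0, 1]) < 1e-8

    def test_high_rfi_group_eats_more(self, small_cohort):
        means = small_cohort.phenotypes.groupby("rfi_group")["dmi"].mean()
        assert means["High"] > means["Low"]

    def test_group_separation_recovered(self):
        # +-0.8 divergent shift => ~1.6 kg DMI separation, recovered by
        # refitting the generating model on the simulated table
        design = rn.CohortDesign(n_per_group=25, seed=3)
        table = rn.simulate_phenotypes(design, rn.PhenotypeParams(group_shift=0.8, noise_sd=0.5))
        sep = (
            table.loc[table.rfi_group == "High", "rfi"].mean()
            - table.loc[table.rfi_group == "Low", "rfi"].mean()
        )
        mc_err = 3 * 0.5 / np.sqrt(design.n_observations / 2)
        assert abs(sep - 1.6) < 3 * mc_err

    def test_degenerate_design_fails(self):
        with pytest.raises(ValueError, match="n_per_group"):
            rn.CohortDesign(n_per_group=1)

    def test_too_few_observations_per_breed_fails(self):
        design = rn.CohortDesign(n_per_group=2, diets=("hc",), rfi_groups=("High",), seed=0)
        with pytest.raises(ValueError, match="at least"):
            rn.simulate_phenotypes(design)


class TestGeneCounts:
    def test_fixed_seed_is_deterministic(self, small_design, small_planted):
        a = rn.simulate_gene_counts(small_design, small_planted, n_genes=300)
        b = rn.simulate_gene_counts(small_design, small_planted, n_genes=300)
        pd.testing.assert_frame_equal(a, b)

    def test_poisson_limit_mean_variance(self, small_design):
        planted = rn.PlantedStructure(
            de_genes={}, phenotype_taxa={}, vfa_producers={}, taxonomy=rn.default_taxonomy(4)
        )
        counts = rn.simulate_gene_counts(
            small_design, planted, n_genes=500, nb_dispersion=1e-13, libsize_range=(5e5, 5e5)
        )
        mean = counts.mean(axis=1)
        var = counts.var(axis=1, ddof=1)
        keep = mean > 50  # high-count genes: ratio concentrates at 1
        ratio = (var[keep] / mean[keep]).mean()
        assert 0.9 < ratio < 1.1

    def test_overdispersion_exceeds_poisson(self, small_design):
        planted = rn.PlantedStructure(
            de_genes={}, phenotype_taxa={}, vfa_producers={}, taxonomy=rn.default_taxonomy(4)
        )
        counts = rn.simulate_gene_counts(
            small_design, planted, n_genes=500, nb_dispersion=0.5, libsize_range=(5e5, 5e5)
        )
        mean = counts.mean(axis=1)
        keep = mean > 50
        ratio = (counts.var(axis=1, ddof=1)[keep] / mean[keep]).mean()
        assert ratio > 2

    def test_planted_genes_rank_top_of_de_ordering(self, small_design, small_planted):
        counts = rn.simulate_gene_counts(small_design, small_planted, n_genes=300)
        cpm = rn.compute_cpm(counts)
        kept = rn.filter_expressed(cpm)
        results = rn.fit_contrasts(cpm.values.loc[kept], rn.simulate_phenotypes(small_design))
        for contrast, res in results.items():
            planted_ids = {f"gene{i:05d}" for i in small_planted.de_genes[contrast]}
            planted_ids &= set(res.table.index)
            others = res.table.index.difference(planted_ids)
            assert res.table.loc[sorted(planted_ids), "padj"].median() < res.table.loc[others, "padj"].median()

    def test_out_of_range_planted_index_fails(self, small_design):
        bad = rn.PlantedStructure(
            de_genes={"rfi": {500: 2.0}},
            phenotype_taxa={},
            vfa_producers={},
            taxonomy=rn.default_taxonomy(4),
        )
        with pytest.raises(ValueError, match="out of range"):
            rn.simulate_gene_counts(small_design, bad, n_genes=300)


class TestMicrobiome:
    def test_leaf_columns_close_to_simplex(self, small_cohort, small_planted):
        leaves = small_planted.leaves()
        sums = small_cohort.taxa_abundance.loc[leaves].sum(axis=0)
        assert np.allclose(sums, 1.0)

    def test_parent_rows_equal_sum_of_children(self, small_cohort, small_planted):
        tree = small_planted.clade_tree
        abund = small_cohort.taxa_abundance
        children = {}
        for child, parent in tree.items():
            children.setdefault(parent, []).append(child)
        for parent, kids in children.items():
            np.testing.assert_allclose(
                abund.loc[parent].to_numpy(), abund.loc[kids].sum(axis=0).to_numpy(), rtol=0, atol=1e-12
            )

    def test_planted_negative_rfi_taxon_is_significantly_negative(self):
        from scipy import stats as sps

        design = rn.CohortDesign(n_per_group=10, seed=5)  # 80 observations
        planted = rn.default_planted_structure(n_leaf_taxa=16, taxa_effect=1.0)
        phen = rn.simulate_phenotypes(design)
        abund, _ = rn.simulate_microbiome(design, planted, phenotypes=phen)
        taxon = next(iter(planted.phenotype_taxa["RFI"]))
        r, p = sps.pearsonr(abund.loc[taxon], phen["rfi"])
        assert r < 0 and p < 0.05

    def test_cycle_in_clade_tree_fails(self):
        tax = rn.default_taxonomy(4)
        tax.loc[tax.index[-1], "parent"] = tax.index[0]  # root now child of a leaf
        with pytest.raises(ValueError, match="cycle"):
            rn.PlantedStructure(de_genes={}, phenotype_taxa={}, vfa_producers={}, taxonomy=tax)


class TestVfa:
    def test_exactly_thirteen_named_variables(self, small_cohort):
        assert list(small_cohort.vfa.index) == list(VFA_NAMES)
        assert len(VFA_NAMES) == 13

    def test_arithmetic_identities_hold_exactly(self, small_cohort):
        v = small_cohort.vfa
        np.testing.assert_allclose(
            v.loc["total_scfa"], v.loc[list(COMPONENT_ACIDS)].sum(axis=0), rtol=0, atol=1e-12
        )
        np.testing.assert_allclose(
            v.loc["acetic_propionic_ratio"], v.loc["acetic"] / v.loc["propionic"], rtol=0, atol=1e-12
        )
        np.testing.assert_allclose(
            v.loc["dl_lactic"], v.loc["d_lactic"] + v.loc["l_lactic"], rtol=0, atol=1e-12
        )

    def test_zero_noise_component_tracks_producer(self, small_cohort, small_planted):
        vfa = rn.simulate_vfa(small_cohort.taxa_abundance, small_planted, noise_scale=0.0)
        producers = list(small_planted.vfa_producers["butyric"])
        signal = small_cohort.taxa_abundance.loc[producers].sum(axis=0)
        # exact affine function of producer abundance at zero noise
        assert abs(np.corrcoef(vfa.loc["butyric"], signal)[0, 1] - 1) < 1e-12

    def test_unknown_producer_taxon_fails(self, small_cohort, small_planted):
        bad = rn.PlantedStructure(
            de_genes={},
            phenotype_taxa={},
            vfa_producers={"acetic": ("nope",)},
            taxonomy=small_planted.taxonomy,
        )
        with pytest.raises(ValueError, match="producer"):
            rn.simulate_vfa(small_cohort.taxa_abundance, bad)


def test_cohort_fixed_seed_bit_identical(small_design, small_planted):
    a = rn.simulate_cohort(small_design, planted=small_planted, n_genes=300, n_leaf_taxa=8)
    b = rn.simulate_cohort(small_design, planted=small_planted, n_genes=300, n_leaf_taxa=8)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    pd.testing.assert_frame_equal(a.gene_counts, b.gene_counts)
    pd.testing.assert_frame_equal(a.taxa_abundance, b.taxa_abundance)
    pd.testing.assert_frame_equal(a.vfa, b.vfa)


def test_phenotype_model_parameter_recovery():
    # refitting the generating regression at n >= 100 recovers b1, b2 within 3 SE
    design = rn.CohortDesign(n_per_group=15, seed=9)  # 120 observations
    params = rn.PhenotypeParams()
    table = rn.simulate_phenotypes(design, params)
    X = np.column_stack(
        [
            np.ones(len(table)),
            table["adg"],
            table["metabolic_weight"],
            np.where(table["rfi_group"] == "High", 1.0, -1.0),
        ]
    )
    y = table["dmi"].to_numpy()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = (resid**2).sum() / (len(y) - 4)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    for j, truth in ((1, params.b_adg), (2, params.b_mw), (3, params.group_shift)):
        assert abs(beta[j] - truth) < 3 * np.sqrt(cov[j, j])
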