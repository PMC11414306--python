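"""Node assembly, correlation, the PCIT trio rule and the significance test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import rumennet as rn
from rumennet.network import _pcit_keep_fast, _pcit_keep_naive

from conftest import profiles_with_correlation


def _corr(R, labels=None):
    R = np.asarray(R, dtype=float)
    labels = labels or [f"n{i}" for i in range(R.shape[0])]
    return rn.CorrelationMatrix(pd.DataFrame(R, index=labels, columns=labels), n_samples=24)


class TestAssembleNodes:
    def test_published_style_counts(self):
        lists = {
            "rfi": [f"g{i}" for i in range(608)],
            "breed": [f"g{i}" for i in range(608, 1213)],
            "diet": [f"g{i}" for i in range(1213, 1842)],
        }
        taxa = pd.DataFrame(
            {"rank": "genus", "lineage": ""}, index=[f"t{i}" for i in range(159)]
        )
        nodes = rn.assemble_nodes(lists, taxa, vfa_names=[f"v{i}" for i in range(13)])
        assert len(nodes) == 2017
        assert nodes["node_type"].value_counts().to_dict() == {
            "gene": 1842, "microbe": 159, "vfa": 13, "phenotype": 3,
        }

    def test_empty_gene_lists_leaves_phenotypes(self):
        nodes = rn.assemble_nodes({"rfi": [], "breed": [], "diet": []})
        assert len(nodes) == 3
        assert set(nodes.index) == {"DMI", "RFI", "ADG"}

    def test_multi_contrast_gene_has_provenance_of_three(self):
        with pytest.warns(UserWarning, match="unique gene nodes"):
            nodes = rn.assemble_nodes({"rfi": ["gX"], "breed": ["gX"], "diet": ["gX"]})
        assert nodes.loc["gX", "contrasts"] == "breed;diet;rfi"

    def test_id_collision_across_types_fails(self):
        taxa = pd.DataFrame({"rank": ["genus"], "lineage": [""]}, index=["shared"])
        with pytest.raises(ValueError, match="collision"):
            rn.assemble_nodes({"rfi": ["shared"]}, taxa)


class TestComputeCorrelations:
    def test_self_and_mirror_correlations(self):
        base = np.random.default_rng(0).normal(size=10)
        profiles = pd.DataFrame(
            [base, base, -base], index=["a", "b", "c"], columns=[f"s{i}" for i in range(10)]
        )
        corr = rn.compute_correlations(profiles)
        assert corr.values.loc["a", "a"] == 1.0
        assert corr.values.loc["a", "b"] == pytest.approx(1.0)
        assert corr.values.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_naive_per_pair_formula(self):
        rng = np.random.default_rng(1)
        profiles = pd.DataFrame(rng.normal(size=(10, 30)), index=[f"n{i}" for i in range(10)])
        corr = rn.compute_correlations(profiles)
        X = profiles.to_numpy()
        for i in range(10):
            for j in range(i + 1, 10):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                ref = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert corr.values.iloc[i, j] == pytest.approx(ref, abs=1e-12)

    def test_too_few_samples_fails(self):
        with pytest.raises(ValueError, match=">= 4"):
            rn.compute_correlations(pd.DataFrame(np.ones((3, 3))))

    def test_constant_profiles_flagged_and_droppable(self):
        profiles = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]], index=["ok", "flat"]
        )
        corr = rn.compute_correlations(profiles)
        assert corr.constant_nodes == ["flat"]
        assert np.isnan(corr.values.loc["flat", "ok"])
        with pytest.warns(UserWarning, match="flat"):
            clean = rn.drop_constant_nodes(corr)
        assert list(clean.values.index) == ["ok"]


class TestPcitFilter:
    def test_fast_equals_naive_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            m = int(rng.integers(5, 41))
            R = np.corrcoef(rng.normal(size=(m, 18)))
            assert (_pcit_keep_fast(R) == _pcit_keep_naive(R)).all()

    def test_strong_mediated_chain_all_edges_survive(self):
        # r_xy = r_yz = 0.8, r_xz = 0.64: the tolerance is
        # eps = (0.78088 + 0 + 0.78088)/3 = 0.52059 and the x-z test compares
        # 0.64 <= 0.41647, so no edge is dominated at this correlation level
        R = [[1, 0.8, 0.64], [0.8, 1, 0.8], [0.64, 0.8, 1]]
        edges = rn.pcit_filter(_corr(R), method="naive")
        assert edges.pairs() == {("n0", "n1"), ("n0", "n2"), ("n1", "n2")}

    def test_weak_mediated_chain_eliminates_indirect_edge(self):
        # same chain shape at r = 0.5: eps = 0.59628 and
        # 0.25 <= 0.29814 on both comparisons, so x-z is eliminated
        R = [[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1]]
        edges = rn.pcit_filter(_corr(R), method="naive")
        assert edges.pairs() == {("n0", "n1"), ("n1", "n2")}

    def test_chain_elimination_threshold_closed_form(self):
        # for the chain (r, r, r^2) the mediated edge dies iff r <= 1/sqrt(3)
        for r, eliminated in ((0.40, True), (0.55, True), (0.60, False), (0.80, False)):
            R = [[1, r, r * r], [r, 1, r], [r * r, r, 1]]
            pairs = rn.pcit_filter(_corr(R), method="fast").pairs()
            assert (("n0", "n2") not in pairs) is eliminated

    def test_exact_zero_correlations_fall_to_guard(self):
        # all directs below delta: eps = 1 and |0| <= |1*0| holds, so the
        # degenerate all-zero trio keeps no edges
        edges = rn.pcit_filter(_corr(np.eye(3)), method="naive")
        assert len(edges) == 0

    def test_never_creates_edges_and_respects_pair_universe(self):
        rng = np.random.default_rng(7)
        R = np.corrcoef(rng.normal(size=(12, 15)))
        edges = rn.pcit_filter(_corr(R))
        m = 12
        assert len(edges) <= m * (m - 1) // 2
        universe = {(f"n{i}", f"n{j}") for i in range(m) for j in range(i + 1, m)}
        assert edges.pairs() <= universe

    def test_node_permutation_permutes_edges(self):
        rng = np.random.default_rng(8)
        R = np.corrcoef(rng.normal(size=(9, 16)))
        labels = [f"n{i}" for i in range(9)]
        edges = rn.pcit_filter(_corr(R, labels))
        perm = rng.permutation(9)
        Rp = R[np.ix_(perm, perm)]
        edges_p = rn.pcit_filter(_corr(Rp, [labels[i] for i in perm]))
        canon = lambda es: {tuple(sorted(p)) for p in es.pairs()}
        assert canon(edges) == canon(edges_p)

    def test_sign_matches_correlation(self):
        rng = np.random.default_rng(9)
        R = np.corrcoef(rng.normal(size=(8, 12)))
        edges = rn.pcit_filter(_corr(R))
        for row in edges.df.itertuples():
            assert row.sign == ("+" if row.r >= 0 else "-")

    def test_nan_matrix_names_nodes(self):
        R = np.eye(4)
        R[0, 1] = R[1, 0] = np.nan
        with pytest.raises(ValueError, match="n0"):
            rn.pcit_filter(_corr(R))

    @given(st.floats(0.0, 2.0), st.floats(-0.9, 0.9), st.floats(-0.9, 0.9), st.floats(-0.9, 0.9))
    def test_elimination_is_monotone_in_eps(self, eps, rxy, rxz, ryz):
        # at fixed correlations, if an edge is dominated at eps it stays
        # dominated at any larger eps
        def dominated(e):
            return abs(rxy) <= abs(e * rxz) and abs(rxy) <= abs(e * ryz)

        if dominated(eps):
            assert dominated(eps * 1.5 + 0.1)


class TestTrioTolerance:
    def test_hand_computed_chain_value(self):
        eps = rn.trio_tolerance(0.8, 0.64, 0.8)
        partial = (0.8 - 0.64 * 0.8) / np.sqrt((1 - 0.64**2) * (1 - 0.8**2))
        assert eps == pytest.approx((partial / 0.8 + 0.0 + partial / 0.8) / 3)

    def test_all_directs_below_guard_gives_unity(self):
        assert rn.trio_tolerance(0.0, 0.0, 0.0) == 1.0


class TestSignificanceFilter:
    @staticmethod
    def _edges(rs):
        df = pd.DataFrame(
            {
                "node_a": [f"a{i}" for i in range(len(rs))],
                "node_b": [f"b{i}" for i in range(len(rs))],
                "r": rs,
                "sign": ["+" if r >= 0 else "-" for r in rs],
            }
        )
        return rn.EdgeSet(df)

    def test_zero_correlation_removed(self):
        assert len(rn.significance_filter(self._edges([0.0]), n=24)) == 0

    def test_reference_t_tail_value(self):
        out = rn.significance_filter(self._edges([0.5]), n=24)
        assert len(out) == 1
        t = 0.5 * np.sqrt(22) / np.sqrt(1 - 0.25)
        assert t == pytest.approx(2.708, abs=1e-3)
        assert out.df.loc[0, "p"] == pytest.approx(2 * sps.t.sf(t, 22), rel=1e-12)
        assert out.df.loc[0, "p"] == pytest.approx(0.0128, abs=5e-4)

    def test_alpha_one_keeps_all_survivors(self):
        edges = self._edges([0.0, 0.3, -0.9])
        assert len(rn.significance_filter(edges, n=24, alpha=1.0)) == 3

    def test_perfect_correlation_kept_and_flagged(self):
        out = rn.significance_filter(self._edges([1.0]), n=10)
        assert len(out) == 1 and bool(out.df.loc[0, "saturated"])
        assert out.df.loc[0, "p"] == 0.0


def test_planted_associations_survive_to_edges(study_cohort):
    """Strong planted phenotype-taxon links appear among significant edges."""
    import rumennet.expression as ex
    import rumennet.microbiome as mb

    cohort = study_cohort
    cpm = ex.compute_cpm(cohort.gene_counts)
    kept = ex.filter_expressed(cpm)
    contrasts = ex.fit_contrasts(cpm.values.loc[kept], cohort.phenotypes)
    lists = {c: ex.select_top_fraction(r) for c, r in contrasts.items()}
    rel = mb.relative_abundance(cohort.taxa_abundance)
    taxa_prof = mb.transform_abundance(rel)
    genes_prof = np.log2(cpm.values.loc[sorted(set().union(*lists.values()))] + 0.5)
    stack = mb.align_samples(genes_prof, taxa_prof, cohort.vfa, cohort.phenotypes)
    profiles = pd.concat([stack.taxa, stack.phenotype_profiles()])
    corr = rn.compute_correlations(profiles)
    edges = rn.significance_filter(rn.pcit_filter(corr), n=corr.n_samples)
    recovered = 0
    total = 0
    for phen, taxa in cohort.planted.phenotype_taxa.items():
        neigh = set(edges.neighbours(phen))
        total += len(taxa)
        recovered += len(set(taxa) & neigh)
    assert recovered / total >= 0.5
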